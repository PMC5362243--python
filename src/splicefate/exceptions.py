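"""Exception hierarchy shared across the pipeline."""


class SplicefateError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SplicefateError, ValueError):
    """A caller-supplied argument is out of its documented domain."""


class PedigreeError(SplicefateError):
    """Structurally invalid pedigree (cycle, missing parent, duplicate id)."""


class AlignmentError(SplicefateError):
    """Individual/sample sets of two inputs do not match."""


class MonomorphicVariantError(SplicefateError):
    """Genotype vector is constant; association is undefined."""


class CollinearityError(SplicefateError):
    """Design matrix is rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class DegeneratePhenotypeError(SplicefateError):
    """Phenotype has no residual variance after adjustment."""


class SeparationError(SplicefateError):
    """Complete separation in a logistic fit; no finite MLE exists."""


class ConfigurationError(SplicefateError):
    """Unknown variant class or malformed threshold configuration."""


class LdConfigurationError(SplicefateError):
    """Requested LD target exceeds the frequency-constrained maximum r^2."""


class UndefinedLdError(SplicefateError):
    """LD is undefined (monomorphic variant in the sample)."""
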
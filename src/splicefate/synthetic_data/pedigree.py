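"""Pedigree simulation and kinship computation.

The cohorts analysed downstream are family structured: phenotypic covariance
between relatives is modelled as ``2 * sigma^2 * Phi`` where ``Phi`` is the
kinship matrix.  This module generates multi-generation pedigrees made of
independent families and computes ``Phi`` by the standard recursive
identity-by-descent algorithm (diagonal 1/2 for non-inbred individuals,
off-diagonal the kinship coefficient ``k_ij``), so that ``2 * Phi`` is the
additive (numerator) relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from ..exceptions import InvalidArgumentError, PedigreeError

__all__ = ["Individual", "Pedigree", "KinshipMatrix", "simulate_pedigree", "kinship_from_pedigree"]


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str | None
    mother_id: str | None
    sex: int  # 1 male, 2 female
    family_id: str
    generation: int = 0

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """Individuals in topological order: parents always precede children."""

    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def validate(self) -> None:
        seen: set[str] = set()
        for ind in self.individuals:
            if ind.id in seen:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            if (ind.father_id is None) != (ind.mother_id is None):
                raise PedigreeError(f"{ind.id!r} has exactly one known parent; need both or neither")
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in seen:
                    raise PedigreeError(
                        f"parent {pid!r} of {ind.id!r} not defined before child (cycle or missing)"
                    )
            seen.add(ind.id)

    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    def family_ids(self) -> list[str]:
        return sorted({ind.family_id for ind in self.individuals})


@dataclass
class KinshipMatrix:
    """Kinship coefficients Phi; model covariance is 2*sigma^2*Phi.

    Family cohorts make Phi block diagonal (up to ordering), so large
    matrices are held in sparse form; consumers work block-wise via
    ``block_indices``/``dense_block``.
    """

    ids: list[str]
    phi: "np.ndarray | sparse.spmatrix"

    def __post_init__(self) -> None:
        n = len(self.ids)
        if sparse.issparse(self.phi):
            self.phi = self.phi.tocsr()
            if self.phi.shape != (n, n):
                raise InvalidArgumentError("phi shape does not match ids")
            asym = self.phi - self.phi.T
            if asym.nnz and np.abs(asym.data).max() > 1e-12:
                raise InvalidArgumentError("phi must be symmetric")
        else:
            self.phi = np.asarray(self.phi, dtype=float)
            if self.phi.shape != (n, n):
                raise InvalidArgumentError("phi shape does not match ids")
            if not np.allclose(self.phi, self.phi.T, atol=1e-12):
                raise InvalidArgumentError("phi must be symmetric")

    @property
    def is_sparse(self) -> bool:
        return sparse.issparse(self.phi)

    def toarray(self) -> np.ndarray:
        return self.phi.toarray() if self.is_sparse else self.phi

    @property
    def relationship(self) -> "np.ndarray | sparse.spmatrix":
        """The additive relationship matrix 2*Phi."""
        return 2.0 * self.phi

    def block_indices(self) -> list[np.ndarray]:
        """Index groups of the connected components of the sparsity graph."""
        adj = self.phi if self.is_sparse else sparse.csr_matrix(np.abs(self.phi) > 1e-12)
        n_comp, labels = connected_components(adj, directed=False)
        order = np.argsort(labels, kind="stable")
        bounds = np.searchsorted(labels[order], np.arange(n_comp + 1))
        return [order[bounds[c]:bounds[c + 1]] for c in range(n_comp)]

    def dense_block(self, idx: np.ndarray) -> np.ndarray:
        """Dense Phi submatrix for one block of individuals."""
        if self.is_sparse:
            return self.phi[idx][:, idx].toarray()
        return self.phi[np.ix_(idx, idx)]

    def index_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise InvalidArgumentError(f"id {exc.args[0]!r} not in kinship matrix") from exc

    def subset(self, ids) -> "KinshipMatrix":
        idx = self.index_of(ids)
        if self.is_sparse:
            return KinshipMatrix(list(ids), self.phi[idx][:, idx])
        return KinshipMatrix(list(ids), self.phi[np.ix_(idx, idx)])


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    mean_offspring: float = 2.5,
    seed: int = 0,
) -> Pedigree:
    """Simulate independent families over discrete generations.

    Founders are paired into couples, one family per couple.  Each couple has
    a Poisson(``mean_offspring``) number of children; children marry
    newly created founders (married-in, same family) to avoid inbreeding, and
    the resulting couples reproduce in the next generation.  With
    ``n_generations=1`` only the founders are returned.
    """
    if n_founders < 2:
        raise InvalidArgumentError("n_founders must be >= 2")
    if n_generations < 1:
        raise InvalidArgumentError("n_generations must be >= 1")
    if mean_offspring <= 0:
        raise InvalidArgumentError("mean_offspring must be positive")
    rng = np.random.default_rng(seed)

    individuals: list[Individual] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:06d}"

    couples: list[tuple[Individual, Individual]] = []
    n_couples = n_founders // 2
    for c in range(n_couples):
        fam = f"F{c + 1:04d}"
        dad = Individual(new_id(), None, None, 1, fam, 0)
        mom = Individual(new_id(), None, None, 2, fam, 0)
        individuals += [dad, mom]
        couples.append((dad, mom))
    if n_founders % 2:  # leftover unpaired founder forms a singleton family
        fam = f"F{n_couples + 1:04d}"
        individuals.append(Individual(new_id(), None, None, 1, fam, 0))

    for gen in range(1, n_generations):
        next_couples: list[tuple[Individual, Individual]] = []
        for dad, mom in couples:
            n_kids = rng.poisson(mean_offspring)
            for _ in range(n_kids):
                sex = int(rng.integers(1, 3))
                child = Individual(new_id(), dad.id, mom.id, sex, dad.family_id, gen)
                individuals.append(child)
                # married-in spouse is a new founder within the same family
                spouse = Individual(new_id(), None, None, 3 - sex, dad.family_id, gen)
                individuals.append(spouse)
                pair = (child, spouse) if sex == 1 else (spouse, child)
                next_couples.append(pair)
        couples = next_couples
    return Pedigree(individuals)


def simulate_family_cohort(
    n_individuals: int,
    max_family_size: int = 20,
    mean_offspring: float = 3.0,
    seed: int = 0,
) -> Pedigree:
    """Cohort of independent small families totalling >= ``n_individuals``.

    Families are two-generation sibships (two founders plus their children),
    truncated so no family exceeds ``max_family_size``; convenient for
    block-diagonal kinship at large n.
    """
    if n_individuals < 1:
        raise InvalidArgumentError("n_individuals must be positive")
    rng = np.random.default_rng(seed)
    individuals: list[Individual] = []
    counter = 0
    fam_no = 0
    while len(individuals) < n_individuals:
        fam_no += 1
        fam = f"F{fam_no:05d}"
        counter += 1
        dad = Individual(f"I{counter:06d}", None, None, 1, fam, 0)
        counter += 1
        mom = Individual(f"I{counter:06d}", None, None, 2, fam, 0)
        individuals += [dad, mom]
        n_kids = min(int(rng.poisson(mean_offspring)), max_family_size - 2)
        for _ in range(n_kids):
            counter += 1
            individuals.append(
                Individual(f"I{counter:06d}", dad.id, mom.id, int(rng.integers(1, 3)), fam, 1)
            )
    return Pedigree(individuals)


_DENSE_LIMIT = 4000  # above this, assemble Phi in sparse block form


def _family_kinship(members: list[Individual]) -> np.ndarray:
    """Recursive kinship within one family (members in topological order)."""
    pos = {ind.id: i for i, ind in enumerate(members)}
    n = len(members)
    phi = np.zeros((n, n))
    for j, ind in enumerate(members):
        if ind.is_founder:
            phi[j, j] = 0.5
        else:
            try:
                f, m = pos[ind.father_id], pos[ind.mother_id]
            except KeyError as exc:
                raise PedigreeError(
                    f"parent {exc.args[0]!r} of {ind.id!r} outside family {ind.family_id!r}"
                ) from exc
            phi[j, j] = 0.5 * (1.0 + phi[f, m])
            phi[:j, j] = phi[j, :j] = 0.5 * (phi[:j, f] + phi[:j, m])
    return phi


def kinship_from_pedigree(ped: Pedigree) -> KinshipMatrix:
    """Kinship Phi by the standard recursive algorithm.

    k_ii = 1/2 * (1 + k_fm) with f, m the parents (1/2 for founders);
    k_ij = 1/2 * (k_i,father(j) + k_i,mother(j)) for j a non-founder listed
    after i.  Founder pairs are unrelated.  Families are independent, so the
    recursion runs per family; large cohorts come back sparse.
    """
    ids = ped.ids
    n = len(ids)
    families: dict[str, list[int]] = {}
    for i, ind in enumerate(ped.individuals):
        families.setdefault(ind.family_id, []).append(i)

    if n <= _DENSE_LIMIT:
        phi = np.zeros((n, n))
        for idx in families.values():
            block = _family_kinship([ped.individuals[i] for i in idx])
            phi[np.ix_(idx, idx)] = block
        return KinshipMatrix(ids, phi)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for idx in families.values():
        block = _family_kinship([ped.individuals[i] for i in idx])
        r, c = np.nonzero(block)
        g = np.asarray(idx)
        rows.append(g[r])
        cols.append(g[c])
        vals.append(block[r, c])
    phi = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    return KinshipMatrix(ids, phi)
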
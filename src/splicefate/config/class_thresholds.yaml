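# Genome-wide significance thresholds by functional-impact class.
# Variants with a higher prior probability of affecting gene function get
# less stringent thresholds (a weighted Bonferroni scheme); values follow
# the five-tier impact classification in wide use for sequence-variant
# association scans.  Override with a YAML file of the same shape.
class_thresholds:
  loss_of_function: 2.6e-7   # high impact: stop/frameshift/splice donor-acceptor
  missense: 5.1e-8           # moderate impact
  splice_region: 5.1e-8      # moderate impact
  synonymous: 4.6e-9         # low impact
  upstream: 4.6e-9           # low impact (regulatory-proximal)
  intronic: 7.9e-10          # remaining non-coding
  intergenic: 7.9e-10        # remaining non-coding
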
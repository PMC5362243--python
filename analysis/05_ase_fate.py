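#!/usr/bin/env python
"""Allele-specific expression analysis under the transcript-fate model.

Simulates RNA read counts for heterozygous carriers of the splice-acceptor
mutation (NMD survival s = 0.25, intron retention rho = 0.5) and
non-carriers, summarizes the three observables — total expression, allelic
fraction at the phased tagging SNP, intron/exon coverage — and inverts the
fate-model identities to recover (s, rho).  Writes results/ase_fate.json.
"""

import argparse
import json
from pathlib import Path

from splicefate.study import ase_fate_study

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    out = ase_fate_study(n_carriers=50, n_noncarriers=50, seed=args.seed)
    fit = out["fate_fit"]
    print("observables (carriers vs non-carriers):")
    print(f"  expression reduction: {out['expression_percent_reduction']:.1f}% "
          f"(het/non ratio {out['het_expression_ratio']:.3f})")
    print(f"  carrier allelic fraction: {out['carrier_alt_fraction']:.3f} "
          f"(non-carriers {out['noncarrier_alt_fraction']:.3f})")
    print(f"  carrier intron/exon share: {out['carrier_intron_share']:.4f}")
    print("fate-model fit:")
    print(f"  NMD survival s = {fit.s_hat:.3f}  (generating value 0.25)")
    print(f"  intron retention rho = {fit.rho_hat:.3f}  (generating value 0.5)")
    print(f"  predicted het/non ratio = {fit.predicted_het_ratio:.3f}, "
          f"consistency residual = {fit.consistency_residual:.4f}")

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "ase_fate.json").write_text(json.dumps({
        "expression_percent_reduction": out["expression_percent_reduction"],
        "het_expression_ratio": out["het_expression_ratio"],
        "carrier_alt_fraction": out["carrier_alt_fraction"],
        "noncarrier_alt_fraction": out["noncarrier_alt_fraction"],
        "carrier_intron_share": out["carrier_intron_share"],
        "s_hat": fit.s_hat,
        "rho_hat": fit.rho_hat,
        "predicted_het_ratio": fit.predicted_het_ratio,
    }, indent=2))
    print(f"wrote {OUT}/ase_fate.json")


if __name__ == "__main__":
    main()
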
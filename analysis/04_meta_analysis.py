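#!/usr/bin/env python
"""Combine the published per-cohort estimates for the splice variant.

Fixed-effect inverse-variance meta-analysis of the five published asthma
cohorts (ORs with 95% CIs) and the two eosinophil cohorts (SD-unit betas),
with Cochran's Q / I^2 heterogeneity.  Writes both combined results to
results/meta_analysis.json.
"""

import json
from pathlib import Path

from splicefate.meta_analysis import fixed_effect_meta
from splicefate.study import published_cohorts

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = {}
    for trait, label in (("asthma", "OR"), ("eosinophils", "beta (SD)")):
        cohorts = published_cohorts(trait)
        res = fixed_effect_meta(cohorts)
        out[trait] = res.to_dict()
        print(f"{trait}: {len(cohorts)} cohorts")
        for e in cohorts:
            print(f"  {e.cohort:12s} {label}={e.estimate:+.2f} "
                  f"({e.ci_low:.2f}, {e.ci_high:.2f})")
        print(f"  combined {label} = {res.estimate:.3f} "
              f"(95% CI {res.ci_low:.3f}, {res.ci_high:.3f}), p = {res.p:.2e}")
        if res.q is not None:
            print(f"  heterogeneity: Q = {res.q:.3f} on {res.df} df, "
                  f"P_het = {res.p_het:.3f}, I2 = {res.i2:.1f}%\n")

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "meta_analysis.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {OUT}/meta_analysis.json")


if __name__ == "__main__":
    main()
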
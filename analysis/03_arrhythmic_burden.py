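"""Arrhythmic burden vs inFAT and scar mass (Poisson regression).

Generates the per-heart VT-count table at the study-calibrated defaults
and fits the multivariable Poisson model of count on inFAT and scar
mass, reporting the rate ratio per 5.55 g.
"""

import sys
from pathlib import Path

from fatvt.stats import poisson_regression
from fatvt.synth import SynthConfig, gen_cohort_counts

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main(seed: int = 1, n: int = 5000) -> None:
    cfg = SynthConfig(seed=seed)
    table = gen_cohort_counts(cfg, n)
    table.to_csv(OUT / "cohort_counts.csv", index=False)
    fit = poisson_regression(table.vt_count, table[["fat_g", "scar_g"]])
    print(f"cohort n = {n}; mean VT count {table.vt_count.mean():.2f}")
    for name in ("fat_g", "scar_g"):
        pct = fit.percent_per_increment[name]
        print(f"  {name}: {pct:+.2f}% VTs per 5.55 g "
              f"(rate ratio {fit.rate_ratios[name]:.4f}, "
              f"p = {fit.pvalues[name]:.2g})")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
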
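#!/usr/bin/env python
"""Cycloheximide-chase half-lives and the blood-vs-carcinoma contrast.

Simulates duplicate chase series over a 12-hour window for three
cell-type groups — labile MM-like lines (t1/2 = 3.5 h), intermediate
lymphoma/leukemia-like lines (t1/2 = 5 h), and stable adenocarcinoma-
like lines (t1/2 = 14 h) — fits each line jointly over replicates, and
estimates the stable-vs-labile fold ratio with a bootstrap CI.
"""

from pathlib import Path

import pandas as pd

from ras_stability import kinetics, simdata

OUT = Path(__file__).resolve().parents[1] / "results" / "kinetics"
TIMEPOINTS = [0, 2, 4, 6, 8, 12]

GROUPS = {  # group -> (true t1/2 hours, line labels, seed base)
    "MM": (3.5, ["XG7-like", "RPMI8226-like", "MM1S-like", "SKMM1-like", "INA6-like"], 1000),
    "DLBCL_AML": (5.0, ["WSU-like", "Toledo-like", "WILL2-like", "HL60-like", "THP1-like"], 2000),
    "adenocarcinoma": (14.0, ["LOVO-like", "GP2D-like", "ASPC1-like", "PANC1-like", "MIAPACA-like"], 0),
}

fits, rows = {}, []
for group, (t_half, lines, base) in GROUPS.items():
    fits[group] = []
    for i, line in enumerate(lines):
        reps = [
            simdata.simulate_chase(
                t_half, TIMEPOINTS, cv_noise=0.1, seed=base + 2 * i + r,
                label=line, replicate=r + 1,
            )
            for r in range(2)
        ]
        fit = kinetics.fit_series(reps, label=line)
        fits[group].append(fit)
        rows.append(
            {"group": group, "label": line, "true_t_half_h": t_half,
             "t_half_h": fit.t_half, "se": fit.se_t_half,
             "r_squared": fit.r_squared, "censored": fit.censored}
        )
        print(fit)

OUT.mkdir(parents=True, exist_ok=True)
pd.DataFrame(rows).to_csv(OUT / "halflife_fits.tsv", sep="\t", index=False)

ratio, (lo, hi) = kinetics.stability_ratio(fits["adenocarcinoma"], fits["MM"], seed=0)
pd.DataFrame(
    [{"comparison": "adenocarcinoma_vs_MM", "ratio": ratio, "ci_low": lo, "ci_high": hi}]
).to_csv(OUT / "stability_ratio.tsv", sep="\t", index=False)
print(f"\nadenocarcinoma vs MM half-life ratio: {ratio:.2f} "
      f"(95% bootstrap CI {lo:.2f}-{hi:.2f}; planted 4.0)")
print(f"wrote {OUT / 'halflife_fits.tsv'}")
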
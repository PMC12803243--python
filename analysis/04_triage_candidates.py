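#!/usr/bin/env python
"""Intersect the stability, proteomics and dependency axes.

Builds the gene-keyed bundle from the scored screen (02), the
enrichment table (03), and a simulated dependency (CSS) table in which
10 of the planted bait-proximal destabilizers are also essential in
RAS-dependent lines, then applies the regulator profile
(score <= -0.8, p <= 0.05, enrichment >= 1.0, CSS <= -1.0) and writes
candidate sets and Venn region counts.
"""

from pathlib import Path

import pandas as pd

from ras_stability import simdata, triage

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "triage"

stability = pd.read_csv(ROOT / "screen" / "gene_scores.tsv", sep="\t", index_col=0)
enrichment = pd.read_csv(ROOT / "bioid" / "enrichment.tsv", sep="\t", index_col=0)

genes = [f"GENE{i + 1:05d}" for i in range(1000)]
essential = genes[:10]  # proximal destabilizers that are also dependencies
css_table = simdata.simulate_css(
    n_genes=1000,
    dependent_lines=["XG7-like", "RPMI8226-like", "MM1S-like"],
    independent_lines=["indep1", "indep2"],
    essential_set=essential,
    noise_sd=0.2,
    seed=33,
)
bundle = triage.OmicsBundle.from_tables(
    stability, enrichment, css_table,
    dependent_lines=["XG7-like", "RPMI8226-like", "MM1S-like"],
)

OUT.mkdir(parents=True, exist_ok=True)
css_table.to_csv(OUT / "css.tsv", sep="\t")

candidates = triage.apply_profile(bundle, triage.PROFILES["regulator"])
candidates.provenance.to_csv(OUT / "candidates_regulator.tsv", sep="\t")
venn = triage.venn_counts(
    {k: v for k, v in candidates.axis_sets.items() if k in ("score", "enrichment", "css")}
)
pd.DataFrame(
    {"region": ["&".join(k) for k in venn], "count": list(venn.values())}
).to_csv(OUT / "venn_regulator.tsv", sep="\t", index=False)

print("regulator profile axes:",
      {k: len(v) for k, v in candidates.axis_sets.items()})
print(f"triple-overlap candidates ({len(candidates.intersection)}): "
      f"{sorted(candidates.intersection)}")
print(f"planted triple-overlap genes recovered: "
      f"{len(candidates.intersection & set(essential))}/{len(essential)}")
print(f"wrote {OUT / 'candidates_regulator.tsv'}")
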
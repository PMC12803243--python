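"""Threshold-profile candidate triage over aligned gene-keyed tables.

Each profile intersects up to four axes — stability score, screen
p-value, proximity-proteomics enrichment, and CRISPR dependency (CSS)
averaged over declared RAS-dependent lines — with directional cuts.
Three named profiles ship with the thresholds used for regulator,
ubiquitin-ligase, and kinase candidate calling; all are overridable.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdProfile",
    "OmicsBundle",
    "CandidateSet",
    "PROFILES",
    "apply_profile",
    "venn_counts",
]

_OPS = {"<=": operator.le, ">=": operator.ge, "<": operator.lt, ">": operator.gt}


@dataclass(frozen=True)
class ThresholdProfile:
    """Named set of directional cuts; a ``None`` cut drops that axis."""

    name: str
    score_cut: tuple[str, float] | None = None
    p_max: float | None = None
    enrich_min: float | None = None
    css_cut: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        for cut in (self.score_cut, self.css_cut):
            if cut is not None:
                op, val = cut
                if op not in _OPS:
                    raise ValueError(f"unknown direction {op!r}")
                if not np.isfinite(val):
                    raise ValueError("cuts must be finite")


#: Built-in profiles: candidate regulators of reporter stability
#: (decreased reporter + proximal + essential), ubiquitin-machinery
#: candidates (increased reporter + proximal + tumor-suppressor-like
#: dependency), and kinase candidates (decreased reporter + proximal +
#: essential, no p cut).
PROFILES: dict[str, ThresholdProfile] = {
    "regulator": ThresholdProfile(
        "regulator", score_cut=("<=", -0.8), p_max=0.05, enrich_min=1.0, css_cut=("<=", -1.0)
    ),
    "ubiquitin": ThresholdProfile(
        "ubiquitin", score_cut=(">", 0.0), p_max=0.05, enrich_min=1.0, css_cut=(">=", 0.5)
    ),
    "kinase": ThresholdProfile(
        "kinase", score_cut=("<=", -0.5), enrich_min=0.8, css_cut=("<", -1.0)
    ),
}


def _harmonize(index) -> pd.Index:
    return pd.Index([str(g).upper() for g in index], name="gene")


@dataclass
class OmicsBundle:
    """Gene-keyed stage outputs feeding triage.

    stability carries ``stability_score`` and ``p_value`` columns;
    enrichment carries ``log2_enrichment``; css is a per-gene Series
    (mean over declared dependent lines).  Gene symbols are upper-cased
    on construction; genes absent from a table simply fail that axis
    and are recorded in ``missing``.
    """

    stability: pd.DataFrame
    enrichment: pd.DataFrame
    css: pd.Series
    universe: set[str] | None = None
    missing: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stability = self.stability.set_axis(_harmonize(self.stability.index))
        self.enrichment = self.enrichment.set_axis(_harmonize(self.enrichment.index))
        self.css = self.css.set_axis(_harmonize(self.css.index))
        if self.universe is not None:
            self.universe = {str(g).upper() for g in self.universe}
        union = set(self.stability.index) | set(self.enrichment.index) | set(self.css.index)
        for name, idx in (
            ("stability", self.stability.index),
            ("enrichment", self.enrichment.index),
            ("css", self.css.index),
        ):
            self.missing[name] = sorted(union - set(idx))

    @classmethod
    def from_tables(
        cls,
        stability: pd.DataFrame,
        enrichment: pd.DataFrame,
        css_table: pd.DataFrame,
        dependent_lines: list[str] | None = None,
        universe: set[str] | None = None,
    ) -> "OmicsBundle":
        """Build from raw stage outputs; CSS per gene is the mean over
        the declared dependent lines of the line-level table."""
        lines = dependent_lines if dependent_lines is not None else list(css_table.columns)
        css = css_table[lines].mean(axis=1)
        return cls(stability=stability, enrichment=enrichment, css=css, universe=universe)


@dataclass
class CandidateSet:
    """Per-axis pass sets, their intersection, and provenance."""

    profile: str
    axis_sets: dict[str, set[str]]
    intersection: set[str]
    provenance: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.provenance.loc[sorted(self.intersection)]


def apply_profile(bundle: OmicsBundle, profile: ThresholdProfile) -> CandidateSet:
    """Intersect the profile's axes over the bundle.

    The optional gene universe restricts all axes first; a gene missing
    from a table fails that table's axes.  Output ordering is
    lexicographic for reproducibility.
    """
    overlap = (
        set(bundle.stability.index) & set(bundle.enrichment.index) & set(bundle.css.index)
    )
    if not overlap:
        raise ValueError("no genes shared by all three tables; check symbol harmonization")

    def restrict(genes: set[str]) -> set[str]:
        return genes & bundle.universe if bundle.universe is not None else genes

    axis_sets: dict[str, set[str]] = {}
    if profile.score_cut is not None:
        op, val = profile.score_cut
        s = bundle.stability["stability_score"]
        axis_sets["score"] = restrict(set(s.index[_OPS[op](s, val)]))
    if profile.p_max is not None:
        p = bundle.stability["p_value"]
        axis_sets["p"] = restrict(set(p.index[p <= profile.p_max]))
    if profile.enrich_min is not None:
        e = bundle.enrichment["log2_enrichment"]
        axis_sets["enrichment"] = restrict(set(e.index[e >= profile.enrich_min]))
    if profile.css_cut is not None:
        op, val = profile.css_cut
        axis_sets["css"] = restrict(set(bundle.css.index[_OPS[op](bundle.css, val)]))
    if not axis_sets:
        raise ValueError("profile has no active axes")

    intersection = set.intersection(*axis_sets.values())
    union = sorted(set.union(*axis_sets.values()))
    prov = pd.DataFrame(
        {axis: [g in s for g in union] for axis, s in axis_sets.items()},
        index=pd.Index(union, name="gene"),
    )
    prov["passes_all"] = prov.all(axis=1)
    return CandidateSet(
        profile=profile.name,
        axis_sets=axis_sets,
        intersection=intersection,
        provenance=prov,
    )


def venn_counts(sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts of a 2- or 3-set Venn partition.

    Keys are tuples of the set names whose exclusive region the count
    belongs to; counts sum to the size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sets")
    names = list(sets)
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            regions[combo] = len(inside - outside)
    return regions
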
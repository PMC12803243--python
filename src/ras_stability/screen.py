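"""Gene-level stability scores from sorted-bin sgRNA count tables.

The statistic follows the sorted-reporter screen design: for every
guide and experiment a log2 fold change of the reporter-high bin vs the
input and of the reporter-low bin vs the input is estimated on
median-of-ratios-normalized counts, the high-vs-low contrast is
averaged over a gene's surviving guides, and the per-experiment gene
scores are centered on the mode of their distribution and scaled by the
root-mean-square deviation from that mode.  The combined stability
score is the mean of the per-experiment normalized scores; p-values
come from a Stouffer normal combination (or a guide-permutation null),
with Benjamini-Hochberg FDR alongside.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "QcReport",
    "parse_sample_columns",
    "size_factors",
    "guide_lfc",
    "filter_guides",
    "gene_score",
    "mode_rmsd_normalize",
    "kde_mode",
    "stability_scores",
    "score_pvalues",
    "reporter_ratio",
    "score_screen",
    "read_counts_tsv",
]

_SAMPLE_RE = re.compile(r"^(?P<experiment>.+)_(?P<bin>input|high|low)$")


@dataclass
class QcReport:
    """Guide-filtering bookkeeping."""

    n_guides_total: int
    n_guides_removed: int
    reasons: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def removal_fraction(self) -> float:
        return self.n_guides_removed / self.n_guides_total

    @property
    def removal_percent(self) -> int:
        """Removal fraction rounded to integer percent."""
        return int(round(100.0 * self.removal_fraction))


def parse_sample_columns(columns) -> dict[str, dict[str, str]]:
    """Map ``<experiment>_<input|high|low>`` column names to
    ``{experiment: {bin: column}}``, requiring all three bins."""
    layout: dict[str, dict[str, str]] = {}
    for col in columns:
        m = _SAMPLE_RE.match(str(col))
        if m:
            layout.setdefault(m["experiment"], {})[m["bin"]] = col
    if not layout:
        raise ValueError("no sample columns matching <experiment>_<input|high|low>")
    for exp, bins in layout.items():
        missing = {"input", "high", "low"} - set(bins)
        if missing:
            raise ValueError(f"experiment {exp!r} missing bins: {sorted(missing)}")
    return layout


def read_counts_tsv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a combined library+counts TSV (guide_id, gene, samples)
    into ``(library, counts)``."""
    df = pd.read_csv(path, sep="\t")
    if "guide_id" not in df.columns or "gene" not in df.columns:
        raise ValueError("counts TSV must carry guide_id and gene columns")
    library = df[["guide_id", "gene"]].copy()
    counts = df.drop(columns=["gene"]).set_index("guide_id")
    return library, counts


# ---------------------------------------------------------------------------
# normalization and guide LFCs
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame, min_guides: int = 100) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only guides observed in every sample enter the medians; when fewer
    than ``min_guides`` qualify the estimate falls back to total-count
    scaling.  A sample with no counts at all is rejected.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[1] == 0:
        raise ValueError("counts must have at least one sample column")
    zero_samples = [c for c, tot in zip(counts.columns, mat.sum(axis=0)) if tot == 0]
    if zero_samples:
        raise ValueError(f"samples with all-zero counts: {zero_samples}")
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")

    positive = np.all(mat > 0, axis=1)
    if positive.sum() >= min_guides:
        sub = mat[positive]
        log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
        factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    else:
        logger.warning(
            "only %d guides nonzero in all samples; falling back to total-count scaling",
            int(positive.sum()),
        )
        factors = mat.sum(axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def guide_lfc(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    pseudocount: float = 0.5,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-guide, per-experiment log2 fold changes and the sorting contrast.

    ``lfc_bin = log2((n_bin/s_bin + c) / (n_input/s_input + c))`` and
    ``contrast = lfc_high - lfc_low``.  Long-format output with columns
    guide_id, gene, experiment, lfc_high, lfc_low, contrast, flagged.
    """
    layout = parse_sample_columns(counts.columns)
    if factors is None:
        factors = size_factors(counts)
    gene_map = library.set_index("guide_id")["gene"]

    frames = []
    for exp, bins in sorted(layout.items()):
        norm = {
            b: counts[col].to_numpy(dtype=float) / factors[col] for b, col in bins.items()
        }
        lfc_high = np.log2(norm["high"] + pseudocount) - np.log2(norm["input"] + pseudocount)
        lfc_low = np.log2(norm["low"] + pseudocount) - np.log2(norm["input"] + pseudocount)
        frames.append(
            pd.DataFrame(
                {
                    "guide_id": counts.index,
                    "gene": gene_map.reindex(counts.index).to_numpy(),
                    "experiment": exp,
                    "lfc_high": lfc_high,
                    "lfc_low": lfc_low,
                    "contrast": lfc_high - lfc_low,
                    "flagged": False,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# guide QC filtering
# ---------------------------------------------------------------------------


def filter_guides(
    stats_df: pd.DataFrame,
    blocklist: set[str] | None = None,
    reference_lfcs: pd.DataFrame | None = None,
    essential_genes: set[str] | None = None,
    tau: float = 0.13,
) -> tuple[pd.DataFrame, QcReport]:
    """Flag poor-performing guides before gene aggregation.

    Two policies, applied to whichever inputs are given:

    * blocklist — remove listed guide_ids outright (unknown ids are
      ignored with a warning).
    * reference screens — ``reference_lfcs`` is a guide x screen table
      of depletion LFCs from experiments where a declared essential
      gene set should drop out.  Each essential-gene guide is ranked by
      depletion among essential-gene guides within each screen (rank
      percentile; higher = worse depletion), percentiles averaged over
      screens, and the worst fraction ``tau`` flagged.

    Returns a copy of the stats with the ``flagged`` column updated, and
    a QcReport over unique guides.
    """
    out = stats_df.copy()
    guides = out["guide_id"].unique()
    reasons: dict[str, str] = {}

    if blocklist:
        unknown = set(blocklist) - set(guides)
        if unknown:
            logger.warning("blocklist names %d unknown guides; ignored", len(unknown))
        for g in set(blocklist) & set(guides):
            reasons[g] = "blocklist"

    if reference_lfcs is not None:
        if not 0 < tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if not essential_genes:
            raise ValueError("reference policy requires a declared essential gene set")
        gene_map = out.drop_duplicates("guide_id").set_index("guide_id")["gene"]
        ess_guides = [
            g for g in reference_lfcs.index if gene_map.get(g) in essential_genes
        ]
        if not ess_guides:
            raise ValueError("no guides of declared essential genes in reference table")
        ref = reference_lfcs.loc[ess_guides]
        # rank percentile of each guide's LFC per screen: depleting guides
        # (very negative LFC) rank low, inert guides rank high (= worse)
        pct = ref.rank(axis=0, pct=True)
        performance = pct.mean(axis=1)
        n_flag = int(np.ceil(tau * len(performance)))
        worst = performance.sort_values(ascending=False).index[:n_flag]
        for g in worst:
            reasons.setdefault(g, "reference_performance")

    flagged = set(reasons)
    out["flagged"] = out["flagged"] | out["guide_id"].isin(flagged)
    report = QcReport(
        n_guides_total=len(guides),
        n_guides_removed=len(flagged & set(guides)),
        reasons=pd.DataFrame(
            {"guide_id": list(reasons), "reason": list(reasons.values())}
        ),
    )
    return out, report


# ---------------------------------------------------------------------------
# gene aggregation and normalization
# ---------------------------------------------------------------------------


def gene_score(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Average the contrast of a gene's unflagged guides per experiment.

    Returns a gene x experiment table of raw scores plus
    ``n_guides_used`` (minimum across experiments).  Genes with no
    surviving guide are dropped and logged.
    """
    usable = stats_df.loc[~stats_df["flagged"]]
    dropped = set(stats_df["gene"].unique()) - set(usable["gene"].unique())
    if dropped:
        logger.info("genes dropped (all guides flagged): %s", sorted(dropped)[:10])
    raw = usable.pivot_table(
        index="gene", columns="experiment", values="contrast", aggfunc="mean"
    )
    n_used = usable.pivot_table(
        index="gene", columns="experiment", values="contrast", aggfunc="count"
    ).min(axis=1)
    raw["n_guides_used"] = n_used.astype(int)
    return raw


def kde_mode(values: np.ndarray, grid_points: int = 512) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on a uniform grid
    spanning [min - 3h, max + 3h]; ties break toward the smallest grid
    value."""
    x = np.asarray(values, dtype=float)
    kde = stats.gaussian_kde(x, bw_method="silverman")
    h = kde.factor * np.std(x, ddof=1)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_points)
    density = kde(grid)
    return float(grid[int(np.argmax(density))])


def mode_rmsd_normalize(values, grid_points: int = 512) -> np.ndarray:
    """Center on the KDE mode and scale by the RMS deviation from it.

    Rejects fewer than 10 finite values and (near-)constant input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 10 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 10 finite values")
    mode = kde_mode(x, grid_points=grid_points)
    rmsd = float(np.sqrt(np.mean((x - mode) ** 2)))
    if rmsd < 1e-12:
        raise ValueError("degenerate input: all values (almost) equal")
    return (x - mode) / rmsd


def stability_scores(raw: pd.DataFrame) -> pd.DataFrame:
    """Normalize each experiment's raw gene scores (mode/RMSD) and
    combine as the mean over experiments where the gene is present.

    Input is the gene x experiment table from :func:`gene_score`;
    output adds ``score_<experiment>`` columns and ``stability_score``.
    """
    exp_cols = [c for c in raw.columns if c != "n_guides_used"]
    if not exp_cols:
        raise ValueError("no experiment columns")
    out = pd.DataFrame(index=raw.index)
    for exp in exp_cols:
        vals = raw[exp].dropna()
        z = mode_rmsd_normalize(vals.to_numpy())
        out[f"score_{exp}"] = pd.Series(z, index=vals.index)
    score_cols = [f"score_{e}" for e in exp_cols]
    out["stability_score"] = out[score_cols].mean(axis=1)
    out["n_experiments"] = out[score_cols].notna().sum(axis=1)
    out = out.loc[out["n_experiments"] > 0]
    if "n_guides_used" in raw.columns:
        out["n_guides_used"] = raw.loc[out.index, "n_guides_used"]
    return out


# ---------------------------------------------------------------------------
# p-values
# ---------------------------------------------------------------------------


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def score_pvalues(
    table: pd.DataFrame,
    method: str = "stouffer",
    stats_df: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach two-sided p-values and BH q-values to a score table.

    ``stouffer`` combines the per-experiment normalized scores as
    ``Z = sum_e z_e / sqrt(k)`` against a standard normal.
    ``permutation`` rebuilds the null by shuffling the guide-to-gene
    assignment of (unflagged) guide contrasts ``n_perm`` times,
    re-running aggregation + normalization, and taking the empirical
    two-sided tail of the combined score among permuted genes with the
    same guide count.
    """
    out = table.copy()
    score_cols = [c for c in out.columns if c.startswith("score_")]
    if method == "stouffer":
        z = out[score_cols].to_numpy(dtype=float)
        k = np.sum(np.isfinite(z), axis=1)
        zsum = np.nansum(z, axis=1)
        combined = zsum / np.sqrt(np.maximum(k, 1))
        p = 2.0 * stats.norm.sf(np.abs(combined))
    elif method == "permutation":
        if stats_df is None:
            raise ValueError("permutation method needs the guide stats table")
        p = _permutation_pvalues(out, stats_df, n_perm=n_perm, seed=seed)
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    out["p_value"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["q_value"] = _bh(out["p_value"].to_numpy())
    return out


def _permutation_pvalues(
    table: pd.DataFrame, stats_df: pd.DataFrame, n_perm: int, seed: int
) -> np.ndarray:
    usable = stats_df.loc[~stats_df["flagged"]]
    rng = np.random.default_rng(seed)
    # null combined scores pooled by n_guides_used
    null_by_k: dict[int, list[np.ndarray]] = {}
    genes = usable.drop_duplicates("guide_id")[["guide_id", "gene"]]
    for _ in range(n_perm):
        perm_map = pd.Series(
            rng.permutation(genes["gene"].to_numpy()), index=genes["guide_id"].to_numpy()
        )
        shuffled = usable.copy()
        shuffled["gene"] = perm_map.reindex(shuffled["guide_id"]).to_numpy()
        raw = shuffled.pivot_table(
            index="gene", columns="experiment", values="contrast", aggfunc="mean"
        )
        counts_k = shuffled.pivot_table(
            index="gene", columns="experiment", values="contrast", aggfunc="count"
        ).min(axis=1)
        z = pd.DataFrame(index=raw.index)
        for exp in raw.columns:
            vals = raw[exp].dropna()
            z[exp] = pd.Series(mode_rmsd_normalize(vals.to_numpy()), index=vals.index)
        combined = z.mean(axis=1).to_numpy()
        for k in np.unique(counts_k):
            null_by_k.setdefault(int(k), []).append(combined[counts_k.to_numpy() == k])
    null_pool = {k: np.concatenate(v) for k, v in null_by_k.items()}
    all_null = np.concatenate(list(null_pool.values()))

    obs = table["stability_score"].to_numpy(dtype=float)
    kk = table["n_guides_used"].to_numpy() if "n_guides_used" in table.columns else None
    p = np.empty(obs.size)
    for i, s in enumerate(obs):
        pool = null_pool.get(int(kk[i]), all_null) if kk is not None else all_null
        p[i] = (1.0 + np.sum(np.abs(pool) >= abs(s))) / (pool.size + 1.0)
    return p


# ---------------------------------------------------------------------------
# reporter-ratio FACS normalization
# ---------------------------------------------------------------------------


def reporter_ratio(
    mfi_mng: float, mfi_lyt2: float, control_mng: float, control_lyt2: float
) -> float:
    """Reporter level relative to the expression marker, normalized so
    the control construct scores 1:
    ``(mNG/Lyt2) / (control mNG / control Lyt2)``."""
    vals = (mfi_mng, mfi_lyt2, control_mng, control_lyt2)
    if any(not (v > 0) for v in vals):
        raise ValueError("all fluorescence intensities must be positive")
    return (mfi_mng / mfi_lyt2) / (control_mng / control_lyt2)


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------


def score_screen(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    blocklist: set[str] | None = None,
    reference_lfcs: pd.DataFrame | None = None,
    essential_genes: set[str] | None = None,
    tau: float = 0.13,
    pseudocount: float = 0.5,
    pvalue_method: str = "stouffer",
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, QcReport]:
    """Counts -> gene score table: LFCs, QC, aggregation, mode/RMSD
    normalization, combination, p/q values."""
    stats_df = guide_lfc(counts, library, pseudocount=pseudocount)
    stats_df, report = filter_guides(
        stats_df,
        blocklist=blocklist,
        reference_lfcs=reference_lfcs,
        essential_genes=essential_genes,
        tau=tau,
    )
    raw = gene_score(stats_df)
    table = stability_scores(raw)
    table = score_pvalues(
        table, method=pvalue_method, stats_df=stats_df, n_perm=n_perm, seed=seed
    )
    return table, report
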
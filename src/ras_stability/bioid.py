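"""Bait-vs-control enrichment from replicate proximity-labeling
intensity tables (BioID-style streptavidin pulldowns quantified in
multiplexed channels).

Channels are floor-imputed and median-aligned in log2 space; the
enrichment of each protein is the mean over replicates of the paired
log2 difference bait - control, with a one-sample t-test against 0.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["parse_channels", "normalize_channels", "enrichment"]

_CHANNEL_RE = re.compile(r"^(?P<condition>bait|control)_rep(?P<replicate>\d+)$")


def parse_channels(columns) -> dict[str, dict[int, str]]:
    """Map ``<bait|control>_rep<k>`` columns to {condition: {k: col}},
    requiring >= 2 paired replicates."""
    layout: dict[str, dict[int, str]] = {"bait": {}, "control": {}}
    for col in columns:
        m = _CHANNEL_RE.match(str(col))
        if m:
            layout[m["condition"]][int(m["replicate"])] = col
    for cond in ("bait", "control"):
        if not layout[cond]:
            raise ValueError(f"no {cond} channels found")
    paired = sorted(set(layout["bait"]) & set(layout["control"]))
    if len(paired) < 2:
        raise ValueError("need >= 2 paired bait/control replicates")
    return layout


def normalize_channels(table: pd.DataFrame, floor_quantile: float = 0.01) -> pd.DataFrame:
    """Impute zeros/missing to each channel's floor quantile (of its
    positive intensities) and median-center every channel's log2
    intensities to the grand median."""
    parse_channels(table.columns)  # validates layout
    out = table.astype(float).copy()
    for col in out.columns:
        vals = out[col]
        positive = vals[vals > 0]
        if positive.empty:
            raise ValueError(f"channel {col!r} has no positive intensities")
        floor = positive.quantile(floor_quantile)
        bad = ~(vals > 0) | vals.isna()
        if bad.any():
            logger.info("channel %s: imputed %d values to floor %.3g", col, int(bad.sum()), floor)
            out.loc[bad, col] = floor
    log2 = np.log2(out)
    grand = float(np.median(log2.to_numpy()))
    shifts = log2.median(axis=0) - grand
    return (2.0 ** (log2 - shifts)).astype(float)


def enrichment(table: pd.DataFrame) -> pd.DataFrame:
    """Per-protein log2 enrichment of bait over control.

    ``d_r = log2(bait_r) - log2(control_r)`` per paired replicate;
    ``log2_enrichment = mean(d_r)``; p is the two-sided one-sample
    t-test of d_r against 0 (n-1 df).  With all d_r exactly 0 the test
    is degenerate and p is set to 1; with < 2 replicates p is NaN.
    """
    layout = parse_channels(table.columns)
    paired = sorted(set(layout["bait"]) & set(layout["control"]))
    diffs = np.column_stack(
        [
            np.log2(table[layout["bait"][r]].to_numpy(dtype=float))
            - np.log2(table[layout["control"][r]].to_numpy(dtype=float))
            for r in paired
        ]
    )
    mean = diffs.mean(axis=1)
    n = diffs.shape[1]
    if n >= 2:
        sd = diffs.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
        zero_var = sd == 0
        p[zero_var & (mean == 0)] = 1.0
        p[zero_var & (mean != 0)] = 0.0
    else:
        p = np.full(mean.shape, np.nan)
    return pd.DataFrame(
        {"log2_enrichment": mean, "p_value": p, "n_replicates": n},
        index=table.index,
    )
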
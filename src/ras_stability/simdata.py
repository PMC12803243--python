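"""Synthetic inputs with known ground truth for every pipeline stage.

The screen generator emulates a FACS-sorted reporter-stability CRISPR
screen: each cell carries one guide, its log2 reporter ratio (stability
readout, e.g. mNG-KRAS relative to a co-translated surface marker) is
``delta_g + noise``, the cytometer gates the top and bottom tails of the
pooled population, and sequencing counts are drawn negative-binomially
around the expected guide shares of each sorted fraction.  The exact
per-guide tail probabilities used are returned as ground truth so that
downstream estimators can be checked against them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ScreenSimConfig",
    "SimTruth",
    "PlaSimConfig",
    "ChaseSeries",
    "planted_effect_table",
    "simulate_screen",
    "simulate_bioid",
    "simulate_chase",
    "simulate_css",
    "simulate_pla_field",
    "render_spot_field",
    "sample_separated_coords",
    "write_counts_tsv",
    "write_pla_field",
]

#: Tail probabilities are clamped here before share normalization so that
#: extreme planted effects cannot underflow the multinomial allocation.
TAIL_PROB_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimConfig:
    """Generative settings for one sorted-bin reporter screen.

    Defaults are desk scale: 1,000 genes x 4 guides with per-guide
    sorted-cell coverage of ~26 cells/tail (the full-scale screen sorted
    ~2e6 cells per 5% tail over 77,441 guides) and a mean input
    sequencing depth of 500 reads/guide.
    """

    n_genes: int = 1000
    guides_per_gene: int = 4
    effect_table: Mapping[str, float] = field(default_factory=dict)
    reporter_sd: float = 1.0
    sort_fraction: float = 0.05
    cells_sorted_per_tail: int | None = None  # default: 26 * n_guides
    input_depth: float = 500.0
    nb_dispersion: float = 0.05
    library_skew_sd: float = 0.25
    n_experiments: int = 1
    seed: int = 0

    @property
    def n_guides(self) -> int:
        return self.n_genes * self.guides_per_gene

    @property
    def genes(self) -> list[str]:
        return [f"GENE{i + 1:05d}" for i in range(self.n_genes)]

    def resolved_cells_per_tail(self) -> int:
        if self.cells_sorted_per_tail is not None:
            return int(self.cells_sorted_per_tail)
        return 26 * self.n_guides

    def validate(self) -> None:
        if not (0 < self.sort_fraction < 0.5):
            raise ValueError("sort_fraction must lie in (0, 0.5)")
        if self.guides_per_gene < 1:
            raise ValueError("guides_per_gene must be >= 1")
        if not np.isfinite(self.reporter_sd) or self.reporter_sd <= 0:
            raise ValueError("reporter_sd must be finite and positive")
        if self.nb_dispersion < 0 or not np.isfinite(self.nb_dispersion):
            raise ValueError("nb_dispersion must be >= 0 and finite")
        if self.n_genes < 1 or self.n_experiments < 1:
            raise ValueError("counts must be positive")
        if self.input_depth <= 0 or self.resolved_cells_per_tail() <= 0:
            raise ValueError("depth and sorted-cell counts must be positive")
        if self.library_skew_sd < 0:
            raise ValueError("library_skew_sd must be >= 0")
        deltas = np.asarray(list(self.effect_table.values()), dtype=float)
        if deltas.size and not np.all(np.isfinite(deltas)):
            raise ValueError("effect_table values must be finite")
        unknown = set(self.effect_table) - set(self.genes)
        if unknown:
            raise ValueError(f"effect_table genes not in library: {sorted(unknown)[:5]}")


@dataclass
class SimTruth:
    """Ground truth for a simulated screen.

    ``guides`` holds, per guide, the planted effect, the library input
    share ``p_input``, the conditional probabilities ``p_high``/``p_low``
    of a cell carrying the guide landing in each sorted tail, the
    normalized tail shares, and the expected high-vs-low log2 contrast.
    ``genes`` labels every gene null / destabilizer / stabilizer.
    """

    guides: pd.DataFrame
    genes: pd.DataFrame
    gate_low: float
    gate_high: float

    def expected_gene_contrast(self) -> pd.Series:
        return self.guides.groupby("gene")["expected_contrast"].mean()


@dataclass
class PlaSimConfig:
    """Settings for one synthetic PLA image field."""

    field_shape: tuple[int, int] = (256, 256)
    n_cells: int = 12
    nucleus_radius: float = 10.0
    puncta_rate: float = 20.0  # mean spots per cell (Poisson)
    psf_sigma: float = 1.5
    spot_amplitude: float = 800.0
    background_level: float = 100.0
    background_noise_sd: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.puncta_rate < 0:
            raise ValueError("puncta_rate must be >= 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.spot_amplitude <= 0:
            raise ValueError("spot_amplitude must be > 0")
        if self.n_cells < 1 or min(self.field_shape) < 16:
            raise ValueError("need at least one cell and a 16-px field")
        if self.background_noise_sd < 0 or self.background_level < 0:
            raise ValueError("background must be non-negative")


@dataclass
class ChaseSeries:
    """One cycloheximide-chase series: target and loading-control band
    intensities at each timepoint."""

    timepoints: np.ndarray
    target: np.ndarray
    loading: np.ndarray
    label: str = ""
    replicate: int = 1


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------


def planted_effect_table(
    n_genes: int,
    n_destabilizers: int = 50,
    delta: float = -1.5,
    n_stabilizers: int = 0,
    delta_stab: float = 1.5,
) -> dict[str, float]:
    """Effect table planting the first genes as destabilizers.

    delta < 0 means knockout of the gene lowers reporter stability, so
    the guide is enriched in the reporter-low tail and the gene receives
    a negative stability score.
    """
    if n_destabilizers + n_stabilizers > n_genes:
        raise ValueError("more planted genes than genes")
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    table = {g: delta for g in genes[:n_destabilizers]}
    table.update({g: delta_stab for g in genes[n_destabilizers : n_destabilizers + n_stabilizers]})
    return table


def _mixture_gate(deltas: np.ndarray, weights: np.ndarray, sd: float, q: float) -> float:
    """Quantile q of the pooled per-cell reporter-ratio mixture.

    The population is a weighted Normal mixture (one component per
    guide); the cytometer gates on this pooled distribution.
    """

    def cdf(t: float) -> float:
        return float(np.sum(weights * stats.norm.cdf((t - deltas) / sd)))

    lo = float(deltas.min() - 10 * sd)
    hi = float(deltas.max() + 10 * sd)
    return float(optimize.brentq(lambda t: cdf(t) - q, lo, hi, xtol=1e-10))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (gamma-Poisson);
    dispersion 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_screen(
    config: ScreenSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a sorted-bin reporter screen.

    Returns ``(library, counts, truth)``: a guide->gene library table, a
    guide x sample count table with columns ``<exp>_input``,
    ``<exp>_high``, ``<exp>_low`` per experiment, and the ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = config.genes
    gene_per_guide = np.repeat(genes, config.guides_per_gene)
    guide_ids = [
        f"{g}_sg{k + 1}" for g in genes for k in range(config.guides_per_gene)
    ]
    deltas = np.array([config.effect_table.get(g, 0.0) for g in gene_per_guide])

    # library abundance skew (plasmid prep + transduction), shared by bins
    abundance = np.exp(rng.normal(0.0, config.library_skew_sd, size=config.n_guides))
    abundance /= abundance.sum()

    sd = config.reporter_sd
    gate_low = _mixture_gate(deltas, abundance, sd, config.sort_fraction)
    gate_high = _mixture_gate(deltas, abundance, sd, 1.0 - config.sort_fraction)

    p_low = stats.norm.cdf((gate_low - deltas) / sd)
    p_high = stats.norm.sf((gate_high - deltas) / sd)
    if np.any(p_low < TAIL_PROB_FLOOR) or np.any(p_high < TAIL_PROB_FLOOR):
        warnings.warn(
            "tail probabilities clamped to floor for extreme planted effects",
            RuntimeWarning,
            stacklevel=2,
        )
    p_low = np.clip(p_low, TAIL_PROB_FLOOR, 1.0)
    p_high = np.clip(p_high, TAIL_PROB_FLOOR, 1.0)

    share_high = abundance * p_high
    share_high /= share_high.sum()
    share_low = abundance * p_low
    share_low /= share_low.sum()

    cells_tail = config.resolved_cells_per_tail()
    total_input = config.input_depth * config.n_guides

    data: dict[str, np.ndarray] = {}
    for e in range(1, config.n_experiments + 1):
        prefix = f"exp{e}"
        data[f"{prefix}_input"] = _nb_draw(rng, total_input * abundance, config.nb_dispersion)
        data[f"{prefix}_high"] = _nb_draw(rng, cells_tail * share_high, config.nb_dispersion)
        data[f"{prefix}_low"] = _nb_draw(rng, cells_tail * share_low, config.nb_dispersion)

    library = pd.DataFrame({"guide_id": guide_ids, "gene": gene_per_guide})
    counts = pd.DataFrame(data, index=pd.Index(guide_ids, name="guide_id"))

    expected_contrast = np.log2(share_high / abundance) - np.log2(share_low / abundance)
    guides = pd.DataFrame(
        {
            "guide_id": guide_ids,
            "gene": gene_per_guide,
            "delta": deltas,
            "p_input": abundance,
            "p_high": p_high,
            "p_low": p_low,
            "share_high": share_high,
            "share_low": share_low,
            "expected_contrast": expected_contrast,
        }
    ).set_index("guide_id")

    gene_delta = pd.Series(
        {g: config.effect_table.get(g, 0.0) for g in genes}, name="delta"
    )
    label = np.where(gene_delta < 0, "destabilizer", np.where(gene_delta > 0, "stabilizer", "null"))
    gene_df = pd.DataFrame({"delta": gene_delta, "label": label})
    gene_df.index.name = "gene"

    truth = SimTruth(guides=guides, genes=gene_df, gate_low=gate_low, gate_high=gate_high)
    return library, counts, truth


def write_counts_tsv(library: pd.DataFrame, counts: pd.DataFrame, path) -> None:
    """Write the library + count table as one TSV (guide_id, gene, samples)."""
    out = library.set_index("guide_id").join(counts)
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# BioID proteomics
# ---------------------------------------------------------------------------


def simulate_bioid(
    n_proteins: int,
    enriched_set: Sequence[str],
    log2_shift: float = 2.0,
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    base_log2_sd: float = 1.0,
    protein_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Replicate bait / empty-vector intensity table with a planted
    bait-enriched protein set.

    noise_sd is the per-channel log2-scale multiplicative noise SD.
    Column names are ``bait_rep<k>`` and ``control_rep<k>``.  Protein
    ids default to ``PROT0001``... but can be supplied (e.g. gene
    symbols) via ``protein_names``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if protein_names is not None:
        if len(protein_names) != n_proteins:
            raise ValueError("protein_names length must equal n_proteins")
        proteins = list(protein_names)
    else:
        proteins = [f"PROT{i + 1:04d}" for i in range(n_proteins)]
    unknown = set(enriched_set) - set(proteins)
    if unknown:
        raise ValueError(f"enriched_set not a subset of proteins: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    base = 2.0 ** rng.normal(10.0, base_log2_sd, size=n_proteins)
    shift = np.where(np.isin(proteins, list(enriched_set)), log2_shift, 0.0)

    data = {}
    for r in range(1, n_replicates + 1):
        noise_b = 2.0 ** rng.normal(0.0, noise_sd, size=n_proteins) if noise_sd else 1.0
        noise_c = 2.0 ** rng.normal(0.0, noise_sd, size=n_proteins) if noise_sd else 1.0
        data[f"bait_rep{r}"] = base * 2.0**shift * noise_b
        data[f"control_rep{r}"] = base * noise_c
    return pd.DataFrame(data, index=pd.Index(proteins, name="protein"))


# ---------------------------------------------------------------------------
# cycloheximide chase
# ---------------------------------------------------------------------------


def simulate_chase(
    t_half: float,
    timepoints: Sequence[float],
    cv_noise: float = 0.1,
    seed: int = 0,
    i0: float = 1000.0,
    loading_level: float = 500.0,
    label: str = "",
    replicate: int = 1,
) -> ChaseSeries:
    """Exponential decay with multiplicative log-normal noise.

    ``intensity(t) = I0 * 2**(-t / t_half) * exp(eps)``; loading-control
    intensities carry independent noise of the same magnitude.  Infinite
    ``t_half`` yields a stable (non-decaying) series.
    """
    t = np.asarray(timepoints, dtype=float)
    if np.any(t < 0):
        raise ValueError("timepoints must be non-negative")
    if 0.0 not in t:
        raise ValueError("timepoints must include 0")
    if not (t_half > 0):  # rejects 0 and NaN; np.inf passes
        raise ValueError("t_half must be positive (or infinite)")
    if cv_noise < 0:
        raise ValueError("cv_noise must be >= 0")
    rng = np.random.default_rng(seed)
    decay = np.ones_like(t) if np.isinf(t_half) else 2.0 ** (-t / t_half)
    eps_t = rng.normal(0.0, cv_noise, size=t.size) if cv_noise else np.zeros(t.size)
    eps_l = rng.normal(0.0, cv_noise, size=t.size) if cv_noise else np.zeros(t.size)
    target = i0 * decay * np.exp(eps_t)
    loading = loading_level * np.exp(eps_l)
    return ChaseSeries(timepoints=t, target=target, loading=loading, label=label, replicate=replicate)


# ---------------------------------------------------------------------------
# CRISPR dependency (CSS) tables
# ---------------------------------------------------------------------------


def simulate_css(
    n_genes: int,
    dependent_lines: Sequence[str],
    independent_lines: Sequence[str],
    essential_set: Sequence[str] = (),
    suppressor_set: Sequence[str] = (),
    noise_sd: float = 0.2,
    seed: int = 0,
    css_essential: float = -1.5,
    css_suppressor: float = 0.8,
) -> pd.DataFrame:
    """Per-gene dependency scores across cell lines.

    Planted essential genes center at ``css_essential`` and planted
    tumor-suppressor-like genes at ``css_suppressor`` in the declared
    RAS-dependent lines only; everything else (and all genes in
    independent lines) centers at 0.
    """
    if set(essential_set) & set(suppressor_set):
        raise ValueError("essential_set and suppressor_set must be disjoint")
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    unknown = (set(essential_set) | set(suppressor_set)) - set(genes)
    if unknown:
        raise ValueError(f"planted genes outside universe: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    center_dep = np.zeros(n_genes)
    center_dep[np.isin(genes, list(essential_set))] = css_essential
    center_dep[np.isin(genes, list(suppressor_set))] = css_suppressor

    data = {}
    for line in dependent_lines:
        noise = rng.normal(0.0, noise_sd, size=n_genes) if noise_sd else 0.0
        data[line] = center_dep + noise
    for line in independent_lines:
        noise = rng.normal(0.0, noise_sd, size=n_genes) if noise_sd else 0.0
        data[line] = np.zeros(n_genes) + noise
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


# ---------------------------------------------------------------------------
# PLA image fields
# ---------------------------------------------------------------------------


def _gaussian_spot_patch(sigma: float, radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    return np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))


def render_spot_field(
    shape: tuple[int, int],
    coords: np.ndarray,
    amplitude: float,
    psf_sigma: float,
    background_level: float = 100.0,
    noise_sd: float = 8.0,
    seed: int = 0,
) -> np.ndarray:
    """Render 2-D Gaussian spots of a given amplitude at integer (row,
    col) coordinates over a noisy constant background.  Float image."""
    rng = np.random.default_rng(seed)
    img = np.full(shape, float(background_level))
    radius = max(1, int(np.ceil(4 * psf_sigma)))
    patch = amplitude * _gaussian_spot_patch(psf_sigma, radius)
    for r, c in np.asarray(coords, dtype=int):
        r0, r1 = max(0, r - radius), min(shape[0], r + radius + 1)
        c0, c1 = max(0, c - radius), min(shape[1], c + radius + 1)
        pr0 = r0 - (r - radius)
        pc0 = c0 - (c - radius)
        img[r0:r1, c0:c1] += patch[pr0 : pr0 + (r1 - r0), pc0 : pc0 + (c1 - c0)]
    if noise_sd:
        img += rng.normal(0.0, noise_sd, size=shape)
    return np.clip(img, 0.0, None)


def sample_separated_coords(
    n: int,
    shape: tuple[int, int],
    min_separation: float,
    rng: np.random.Generator,
    margin: int = 8,
    max_tries_factor: int = 200,
) -> np.ndarray:
    """Dart-throwing placement of n points with a minimum pairwise
    distance; warns and returns fewer points when the field is full."""
    coords: list[tuple[int, int]] = []
    tries = 0
    max_tries = max_tries_factor * max(n, 1)
    while len(coords) < n and tries < max_tries:
        tries += 1
        r = rng.integers(margin, shape[0] - margin)
        c = rng.integers(margin, shape[1] - margin)
        if all((r - r2) ** 2 + (c - c2) ** 2 >= min_separation**2 for r2, c2 in coords):
            coords.append((int(r), int(c)))
    if len(coords) < n:
        warnings.warn(
            f"placed only {len(coords)}/{n} spots at separation {min_separation}",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.asarray(coords, dtype=int).reshape(-1, 2)


def simulate_pla_field(config: PlaSimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate one multi-channel PLA field.

    Returns ``(field, truth)`` where ``field`` is a float array of shape
    (3, H, W) with channels ordered puncta, nuclei, membrane, and
    ``truth`` lists true spot centers (columns ``row``, ``col``) in
    0-based pixel coordinates, origin top-left.

    Cells are disks (membrane ring around a nuclear disk) placed by
    dart-throwing without overlap; puncta locations are uniform over the
    union of cell disks with count ~ Poisson(puncta_rate * n_cells).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.field_shape)
    nr = config.nucleus_radius
    cell_r = 2.0 * nr

    # cell centers: non-overlapping disks, bounded retries
    margin = int(np.ceil(cell_r)) + 2
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < config.n_cells and tries < 10 * config.n_cells * 10:
        tries += 1
        r = rng.integers(margin, shape[0] - margin)
        c = rng.integers(margin, shape[1] - margin)
        if all((r - r2) ** 2 + (c - c2) ** 2 >= (2 * cell_r) ** 2 for r2, c2 in centers):
            centers.append((int(r), int(c)))
    if len(centers) < config.n_cells:
        warnings.warn(
            f"placed only {len(centers)}/{config.n_cells} cells", RuntimeWarning, stacklevel=2
        )
    centers_arr = np.asarray(centers, dtype=float)

    rows, cols = np.indices(shape)
    nuclei = np.zeros(shape)
    membrane = np.zeros(shape)
    for r0, c0 in centers_arr:
        dist = np.sqrt((rows - r0) ** 2 + (cols - c0) ** 2)
        nuclei[dist <= nr] = 1.0
        membrane[(dist >= cell_r - 1.5) & (dist <= cell_r + 1.5)] = 1.0

    # puncta: Poisson count, uniform over cell disks, capped by rejection
    n_spots = int(rng.poisson(config.puncta_rate * max(len(centers), 0)))
    spot_coords: list[tuple[int, int]] = []
    attempts = 0
    while len(spot_coords) < n_spots and attempts < 50 * max(n_spots, 1):
        attempts += 1
        idx = rng.integers(0, len(centers_arr)) if len(centers_arr) else 0
        if not len(centers_arr):
            break
        r0, c0 = centers_arr[idx]
        rad = cell_r * np.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * np.pi)
        r = int(round(r0 + rad * np.cos(ang)))
        c = int(round(c0 + rad * np.sin(ang)))
        if 0 <= r < shape[0] and 0 <= c < shape[1]:
            spot_coords.append((r, c))
    if len(spot_coords) < n_spots:
        warnings.warn(
            f"placed only {len(spot_coords)}/{n_spots} puncta", RuntimeWarning, stacklevel=2
        )
    coords = np.asarray(spot_coords, dtype=int).reshape(-1, 2)

    puncta = render_spot_field(
        shape,
        coords,
        amplitude=config.spot_amplitude,
        psf_sigma=config.psf_sigma,
        background_level=config.background_level,
        noise_sd=config.background_noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    nuclei_img = np.clip(
        3000.0 * nuclei + config.background_level + rng.normal(0, config.background_noise_sd, shape),
        0,
        None,
    )
    membrane_img = np.clip(
        2000.0 * membrane
        + config.background_level
        + rng.normal(0, config.background_noise_sd, shape),
        0,
        None,
    )
    field = np.stack([puncta, nuclei_img, membrane_img])
    truth = pd.DataFrame(coords, columns=["row", "col"])
    return field, truth


def write_pla_field(field: np.ndarray, path) -> None:
    """Write a (3, H, W) field as a 16-bit multi-page TIFF (page order
    puncta, nuclei, membrane)."""
    import tifffile

    data = np.clip(np.round(field), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack", planarconfig="separate")
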
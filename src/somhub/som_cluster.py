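"""CV-based gene selection, profile scaling, PCA and hexagonal SOM
clustering of temporal expression profiles, with stage categorization
of the resulting units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from somhub.io_formats import ExpressionMatrix, TIMEPOINTS, ValidationError

CATEGORIES = ("neonatal", "juvenile", "adult", "atypical")


@dataclass(frozen=True)
class SomConfig:
    grid_rows: int = 3
    grid_cols: int = 6
    topology: str = "hexagonal"
    iterations: int = 100
    alpha_start: float = 0.009
    alpha_end: float = 0.006
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in ("hexagonal", "rectangular"):
            raise ValidationError(f"unknown topology {self.topology!r}")
        if not self.alpha_start >= self.alpha_end > 0:
            raise ValidationError("need alpha_start >= alpha_end > 0")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValidationError("grid dimensions must be positive")

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass
class SomResult:
    assignment: pd.Series  # gene -> unit index
    codebooks: np.ndarray  # n_units x n_timepoints
    categories: dict[int, str]  # non-empty unit -> stage category
    pca_scores: pd.DataFrame | None = None
    variance_explained: np.ndarray | None = None
    config: SomConfig | None = None

    def cluster_sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()


# ---------------------------------------------------------------------------
# gene selection and scaling
# ---------------------------------------------------------------------------


def timepoint_medians(
    matrix: ExpressionMatrix, genotype: str | None = "control"
) -> pd.DataFrame:
    """Per-gene median intensity across replicates at each timepoint."""
    cols = {}
    for tp in TIMEPOINTS:
        ids = matrix.columns_for(genotype=genotype, timepoint=tp)
        if not ids:
            ids = matrix.columns_for(timepoint=tp)
        if not ids:
            raise ValidationError(f"no samples at timepoint {tp}")
        cols[tp] = matrix.data[ids].median(axis=1)
    return pd.DataFrame(cols)


def cv_select(
    matrix: ExpressionMatrix,
    fraction: float = 0.30,
    genotype: str | None = "control",
    use_mean: bool = False,
) -> ExpressionMatrix:
    """Keep the floor(fraction * n) genes with the largest coefficient of
    variation across their (unlogged) per-timepoint median profiles.

    ``use_mean=True`` switches the summary from medians to means.  Ties
    are broken by gene id; genes with nonpositive mean profile are
    excluded with a warning.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    profiles = timepoint_medians(matrix, genotype=genotype)
    if use_mean:
        cols = {}
        for tp in TIMEPOINTS:
            ids = matrix.columns_for(genotype=genotype, timepoint=tp) or \
                matrix.columns_for(timepoint=tp)
            cols[tp] = matrix.data[ids].mean(axis=1)
        profiles = pd.DataFrame(cols)
    means = profiles.mean(axis=1)
    nonpositive = means[means <= 0].index
    if len(nonpositive):
        warnings.warn(
            f"{len(nonpositive)} genes with nonpositive mean excluded from CV ranking",
            stacklevel=2,
        )
        profiles = profiles.drop(index=nonpositive)
        means = means.drop(index=nonpositive)
    cv = profiles.std(axis=1, ddof=1) / means
    n_keep = int(np.floor(fraction * len(matrix.row_ids)))
    n_keep = min(n_keep, len(cv))
    # stable sort over an id-sorted index gives deterministic tie-breaks
    ranked = cv.loc[sorted(cv.index)].sort_values(ascending=False, kind="mergesort")
    keep = [g for g in matrix.row_ids if g in set(ranked.index[:n_keep])]
    return matrix.subset_rows(keep)


def scale_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score (mean 0, sd 1 with n-1 denominator)."""
    sd = profiles.std(axis=1, ddof=1)
    if (sd == 0).any():
        zero = list(profiles.index[sd == 0])[:3]
        raise ValidationError(f"zero-variance profiles cannot be scaled, e.g. {zero}")
    return profiles.sub(profiles.mean(axis=1), axis=0).div(sd, axis=0)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA with genes as observations and timepoints as variables.

    Returns (scores, loadings, variance_explained).  Columns are
    centered; the sign convention makes each component's
    largest-magnitude loading positive.
    """
    x = profiles.to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 genes and 2 timepoints")
    centered = x - x.mean(axis=0)
    if not np.any(centered):
        raise ValidationError("degenerate (rank-0) input")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for comp in range(vt.shape[0]):
        load = vt[comp]
        if load[np.argmax(np.abs(load))] < 0:
            vt[comp] = -load
            u[:, comp] = -u[:, comp]
    scores = u * s
    var = s**2
    variance_explained = var / var.sum()
    k = len(s)
    score_frame = pd.DataFrame(
        scores, index=profiles.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    loading_frame = pd.DataFrame(
        vt.T, index=profiles.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return score_frame, loading_frame, variance_explained


# ---------------------------------------------------------------------------
# SOM
# ---------------------------------------------------------------------------


def _unit_positions(config: SomConfig) -> np.ndarray:
    """2-D positions of grid units; odd rows offset for hexagonal packing."""
    positions = np.empty((config.n_units, 2))
    for r in range(config.grid_rows):
        for c in range(config.grid_cols):
            idx = r * config.grid_cols + c
            if config.topology == "hexagonal":
                positions[idx] = (c + 0.5 * (r % 2), r * np.sqrt(3.0) / 2.0)
            else:
                positions[idx] = (c, r)
    return positions


def train_som(profiles: pd.DataFrame, config: SomConfig) -> SomResult:
    """Online SOM on the unit grid.

    Learning rate decays linearly alpha_start -> alpha_end over all
    updates; the (bubble) neighborhood radius decays linearly from the
    2/3 quantile of inter-unit distances to zero, so late updates move
    the best-matching unit only.  Each iteration is one seeded-random
    pass over the genes; training is deterministic for a fixed seed.
    """
    x = profiles.to_numpy(dtype=float)
    n_genes, n_vars = x.shape
    if not np.isfinite(x).all():
        raise ValidationError("profiles must be finite")
    if config.n_units > n_genes:
        warnings.warn(
            f"grid has {config.n_units} units for {n_genes} genes; empty units expected",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    positions = _unit_positions(config)
    unit_dist = np.sqrt(
        ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(axis=2)
    )

    init_idx = rng.choice(n_genes, size=config.n_units, replace=n_genes < config.n_units)
    codebooks = x[init_idx].astype(float).copy()

    total_updates = config.iterations * n_genes
    radius_start = float(np.quantile(unit_dist[unit_dist > 0], 2.0 / 3.0)) \
        if config.n_units > 1 else 0.0
    step = 0
    for _ in range(config.iterations):
        for g in rng.permutation(n_genes):
            frac = step / max(total_updates - 1, 1)
            alpha = config.alpha_start + frac * (config.alpha_end - config.alpha_start)
            radius = radius_start * (1.0 - frac)
            sample = x[g]
            bmu = int(np.argmin(((codebooks - sample) ** 2).sum(axis=1)))
            neighbors = unit_dist[bmu] <= radius + 1e-12
            codebooks[neighbors] += alpha * (sample - codebooks[neighbors])
            step += 1

    d2 = ((x[:, None, :] - codebooks[None, :, :]) ** 2).sum(axis=2)
    assignment = pd.Series(d2.argmin(axis=1), index=profiles.index, name="unit")
    return SomResult(assignment=assignment, codebooks=codebooks, categories={}, config=config)


def categorize_clusters(
    unit_profiles: dict[int, np.ndarray], amplitude_threshold: float = 1.0
) -> dict[int, str]:
    """Stage category per unit from its median scaled profile.

    Amplitude below threshold -> atypical; otherwise peak at P1 ->
    neonatal, P7/P14 -> juvenile, P30/P60 -> adult.
    """
    categories: dict[int, str] = {}
    for unit, profile in unit_profiles.items():
        profile = np.asarray(profile, dtype=float)
        if profile.size == 0:
            continue
        if profile.max() - profile.min() < amplitude_threshold:
            categories[unit] = "atypical"
            continue
        peak = TIMEPOINTS[int(np.argmax(profile))]
        if peak == "P1":
            categories[unit] = "neonatal"
        elif peak in ("P7", "P14"):
            categories[unit] = "juvenile"
        else:
            categories[unit] = "adult"
    return categories


def cluster_stages(
    matrix: ExpressionMatrix,
    config: SomConfig | None = None,
    cv_fraction: float = 0.30,
    amplitude_threshold: float = 1.0,
    genotype: str | None = "control",
) -> SomResult:
    """CV selection -> scaling -> SOM -> PCA -> stage categorization."""
    config = config or SomConfig()
    selected = cv_select(matrix, fraction=cv_fraction, genotype=genotype)
    profiles = timepoint_medians(selected, genotype=genotype)
    scaled = scale_profiles(profiles)
    result = train_som(scaled, config)
    unit_medians = {}
    for unit in sorted(result.assignment.unique()):
        genes = result.assignment.index[result.assignment == unit]
        unit_medians[int(unit)] = scaled.loc[genes].median(axis=0).to_numpy()
    result.categories = categorize_clusters(unit_medians, amplitude_threshold)
    scores, _, variance = pca(scaled)
    result.pca_scores = scores
    result.variance_explained = variance
    return result
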
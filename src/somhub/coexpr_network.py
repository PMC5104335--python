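"""Weighted co-expression network core and bootstrap hub ranking.

Soft-threshold power selection by scale-free fit, powered-correlation
adjacency, topological overlap, TOM-based connectivity, and hub
inference by rank aggregation over bootstrap-resampled networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress, rankdata

from somhub.io_formats import ValidationError


class CriterionNotSatisfied(Exception):
    """No candidate soft power reached the scale-free fit target."""


@dataclass(frozen=True)
class NetworkConfig:
    power_candidates: tuple[int, ...] = tuple(range(1, 21))
    fit_target: float = 0.80
    n_bootstrap: int = 100
    hub_quantile: float = 0.05
    min_connectivity_export: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.hub_quantile < 1:
            raise ValidationError("hub_quantile must be in (0, 1)")
        if self.n_bootstrap < 1:
            raise ValidationError("n_bootstrap must be >= 1")


@dataclass
class HubRanking:
    table: pd.DataFrame  # index gene; columns mean_rank, sd_rank, hub
    beta: int

    @property
    def hub_genes(self) -> list[str]:
        return list(self.table.index[self.table["hub"]])


def scale_free_fit(connectivities: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log frequency/connectivity regression over
    equal-width connectivity bins, negated when the slope is positive.
    """
    k = np.asarray(connectivities, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        raise ValidationError(
            f"need >= {n_bins} positive connectivities, got {k.size}"
        )
    if np.allclose(k, k[0]):
        raise ValidationError("all-equal connectivities: fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 2:
        raise ValidationError("too few occupied bins for regression")
    fit = linregress(xs, ys)
    r2 = fit.rvalue**2
    return float(-r2 if fit.slope > 0 else r2)


def _correlation(x: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation between rows; raises on constants."""
    sd = x.std(axis=1)
    if (sd == 0).any():
        raise ValidationError("zero-variance gene in expression matrix")
    c = np.corrcoef(x)
    return np.clip(np.abs(c), 0.0, 1.0)


def adjacency(expr: np.ndarray, beta: int) -> np.ndarray:
    """Unsigned adjacency |cor|^beta with zero diagonal."""
    expr = np.asarray(expr, dtype=float)
    if expr.shape[1] < 3:
        raise ValidationError("adjacency needs >= 3 samples")
    a = _correlation(expr) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def pick_soft_power(expr: np.ndarray, config: NetworkConfig) -> int:
    """Smallest candidate power reaching the scale-free fit target.

    Raises :class:`CriterionNotSatisfied` when no candidate qualifies,
    in which case downstream hub calls must report "not determined".
    """
    expr = np.asarray(expr, dtype=float)
    corr = _correlation(expr)
    np.fill_diagonal(corr, 0.0)
    for beta in sorted(config.power_candidates):
        if config.fit_target <= 0:
            return int(beta)
        k = (corr**beta).sum(axis=0)
        try:
            fit = scale_free_fit(k)
        except ValidationError:
            continue
        if fit >= config.fit_target:
            return int(beta)
    raise CriterionNotSatisfied(
        f"no candidate power reached fit target {config.fit_target}"
    )


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with zero diagonal.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj and k_i the row sum; diagonal fixed at 1.
    """
    a = np.asarray(adj, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n) or not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric and square")
    if (a < 0).any() or (a > 1).any():
        raise ValidationError("adjacency values must lie in [0, 1]")
    if not np.allclose(np.diag(a), 0.0):
        raise ValidationError("adjacency diagonal must be zero")
    l = a @ a  # a_ii = 0 keeps u != i, j automatically
    k = a.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    return t


def tom_connectivity(t: np.ndarray) -> np.ndarray:
    """k^TOM_i = sum_{j != i} TOM_ij."""
    t = np.asarray(t, dtype=float)
    return t.sum(axis=0) - np.diag(t)


def _connectivity_ranks(expr: np.ndarray, beta: int) -> np.ndarray:
    """Descending TOM-connectivity ranks (1 = most connected, ties get
    the mean rank); constant genes get the worst rank."""
    n = expr.shape[0]
    sd = expr.std(axis=1)
    constant = sd == 0
    ranks = np.full(n, float(n))
    live = ~constant
    if live.sum() >= 2:
        a = adjacency(expr[live], beta)
        k = tom_connectivity(tom(a))
        ranks[live] = rankdata(-k, method="average")
    return ranks


def bootstrap_hub_ranking(
    expr: np.ndarray,
    gene_ids: list[str],
    config: NetworkConfig,
    beta: int | None = None,
    identity_resample: bool = False,
) -> HubRanking:
    """Aggregate TOM-connectivity ranks over bootstrap-resampled arrays.

    The soft power is fixed from the full data (chosen here when
    ``beta`` is None).  Each replicate resamples sample columns with
    replacement to the original size; replicates with fewer than 3
    distinct samples are redrawn (max 10 retries).  The hub flag marks
    the floor(hub_quantile * n) genes (minimum 1) with the smallest
    mean rank, ties broken by smaller rank s.d. then gene id.
    ``identity_resample`` is a test hook using the untouched data in
    every replicate.
    """
    expr = np.asarray(expr, dtype=float)
    n_genes, n_samples = expr.shape
    if len(gene_ids) != n_genes:
        raise ValidationError("gene_ids length mismatch")
    if n_samples < 4:
        raise ValidationError("bootstrap hub ranking needs >= 4 samples")
    if beta is None:
        beta = pick_soft_power(expr, config)

    rng = np.random.default_rng(config.seed)
    all_ranks = np.empty((config.n_bootstrap, n_genes))
    for b in range(config.n_bootstrap):
        if identity_resample:
            cols = np.arange(n_samples)
        else:
            for attempt in range(11):
                cols = rng.integers(0, n_samples, size=n_samples)
                if len(np.unique(cols)) >= 3:
                    break
            else:  # pragma: no cover - needs pathological sample counts
                raise ValidationError("could not draw a usable bootstrap replicate")
        all_ranks[b] = _connectivity_ranks(expr[:, cols], beta)

    mean_rank = all_ranks.mean(axis=0)
    sd_rank = all_ranks.std(axis=0, ddof=1) if config.n_bootstrap > 1 else np.zeros(n_genes)

    n_hubs = max(int(np.floor(config.hub_quantile * n_genes)), 1)
    order = sorted(
        range(n_genes), key=lambda i: (mean_rank[i], sd_rank[i], gene_ids[i])
    )
    hub = np.zeros(n_genes, dtype=bool)
    hub[order[:n_hubs]] = True

    table = pd.DataFrame(
        {"mean_rank": mean_rank, "sd_rank": sd_rank, "hub": hub},
        index=pd.Index(gene_ids, name="gene"),
    )
    table = table.iloc[order]
    return HubRanking(table=table, beta=int(beta))


def cluster_hub_rankings(
    matrix_data: pd.DataFrame,
    assignment: pd.Series,
    config: NetworkConfig,
    min_cluster_size: int = 10,
) -> dict[int, HubRanking | None]:
    """Per-cluster bootstrap hub ranking on log2 expression.

    Clusters whose networks never satisfy the scale-free criterion (or
    that are too small) map to ``None`` ("hub not determined").
    """
    results: dict[int, HubRanking | None] = {}
    for unit in sorted(assignment.unique()):
        genes = sorted(assignment.index[assignment == unit])
        if len(genes) < min_cluster_size:
            results[int(unit)] = None
            continue
        expr = matrix_data.loc[genes].to_numpy(dtype=float)
        try:
            beta = pick_soft_power(expr, config)
        except CriterionNotSatisfied:
            results[int(unit)] = None
            continue
        results[int(unit)] = bootstrap_hub_ranking(expr, genes, config, beta=beta)
    return results
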
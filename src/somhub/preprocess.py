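"""Raw-intensity preprocessing.

Background filtering against per-array negative-control cutoffs, probe
quality filtering, cross-timepoint presence filtering, probe-to-gene
collapse, quantile normalization and classical MDS for QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from somhub.io_formats import (
    ExpressionMatrix,
    ProbeAnnotation,
    TIMEPOINTS,
    ValidationError,
)


class InsufficientDataError(ValueError):
    pass


@dataclass
class BackgroundCutoff:
    """Per-array intensity cutoff: mean + 2 * sd of negative controls."""

    cutoff: pd.Series  # indexed by sample_id
    neg_mean: pd.Series
    neg_sd: pd.Series


@dataclass
class PreprocessReport:
    n_input: int
    n_removed_quality: int
    n_removed_negative_control: int
    n_removed_undetected: int
    n_output: int

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_quality
            + self.n_removed_negative_control
            + self.n_removed_undetected
        )
        if self.n_input - self.n_output != removed:
            raise ValidationError("preprocess report counts do not conserve rows")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [
                    "input",
                    "removed_quality",
                    "removed_negative_control",
                    "removed_undetected",
                    "output",
                ],
                "probes": [
                    self.n_input,
                    self.n_removed_quality,
                    self.n_removed_negative_control,
                    self.n_removed_undetected,
                    self.n_output,
                ],
            }
        )


def background_cutoff(negative_values: np.ndarray) -> float:
    """mean + 2 * sample standard deviation (n-1) of negative controls."""
    values = np.asarray(negative_values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            f"need >= 2 negative-control values, got {values.size}"
        )
    return float(values.mean() + 2.0 * values.std(ddof=1))


def compute_cutoffs(
    matrix: ExpressionMatrix, annotation: ProbeAnnotation
) -> BackgroundCutoff:
    """Per-array background cutoffs from the negative-control probes."""
    neg_ids = [
        p for p in matrix.row_ids
        if p in annotation.table.index and annotation.is_negative_control(p)
    ]
    if len(neg_ids) < 2:
        raise InsufficientDataError("fewer than 2 negative-control probes in matrix")
    neg = matrix.data.loc[neg_ids]
    mean = neg.mean(axis=0)
    sd = neg.std(axis=0, ddof=1)
    return BackgroundCutoff(cutoff=mean + 2.0 * sd, neg_mean=mean, neg_sd=sd)


def filter_probes(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    cutoffs: BackgroundCutoff,
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Apply quality, negative-control and detection filters.

    A probe counts as detected at a timepoint if it exceeds the
    per-array cutoff in at least one replicate of that timepoint;
    probes undetected at any timepoint are dropped.  Values of retained
    probes are kept as measured (filtering is probe-level).
    """
    missing = [p for p in matrix.row_ids if p not in annotation.table.index]
    if missing:
        raise ValidationError(f"annotation missing probes, e.g. {missing[:3]}")

    row_ids = matrix.row_ids
    quality = annotation.table.loc[row_ids, "quality"]
    is_neg = annotation.table.loc[row_ids, "is_negative_control"].astype(bool)

    bad_mask = quality.isin(["bad", "no_match"]).to_numpy()
    neg_mask = (~bad_mask) & is_neg.to_numpy()

    survivors = matrix.data.loc[~(bad_mask | neg_mask)]

    cutoff_row = cutoffs.cutoff.reindex(survivors.columns)
    if cutoff_row.isna().any():
        raise ValidationError("cutoffs missing for some samples")
    detected = survivors.gt(cutoff_row, axis=1)

    present_all_tp = pd.Series(True, index=survivors.index)
    for tp in TIMEPOINTS:
        cols = matrix.columns_for(timepoint=tp)
        if not cols:
            continue
        present_all_tp &= detected[cols].any(axis=1)

    out = survivors.loc[present_all_tp]
    report = PreprocessReport(
        n_input=len(row_ids),
        n_removed_quality=int(bad_mask.sum()),
        n_removed_negative_control=int(neg_mask.sum()),
        n_removed_undetected=int((~present_all_tp).sum()),
        n_output=out.shape[0],
    )
    desc = None if matrix.descriptions is None else matrix.descriptions.loc[out.index]
    return ExpressionMatrix(out.copy(), list(matrix.samples), desc), report


def collapse_to_genes(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    reference: ExpressionMatrix | None = None,
) -> ExpressionMatrix:
    """One row per gene symbol, keeping the probe with the highest median
    intensity across the first-timepoint replicates.

    The medians come from the control genotype of ``reference`` (default:
    the matrix itself) so both genotypes can be collapsed consistently.
    Ties keep the lexicographically smallest probe id; probes without a
    gene symbol are excluded with a warning.
    """
    ref = reference if reference is not None else matrix
    p1_cols = ref.columns_for(genotype="control", timepoint=TIMEPOINTS[0])
    if not p1_cols:
        p1_cols = ref.columns_for(timepoint=TIMEPOINTS[0])
    if not p1_cols:
        raise ValidationError("no P1 samples available for probe collapse")

    symbols = {}
    unmapped = []
    for probe in matrix.row_ids:
        symbol = annotation.gene_symbol(probe).strip()
        if symbol:
            symbols[probe] = symbol
        else:
            unmapped.append(probe)
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} probes without gene symbol excluded from collapse",
            stacklevel=2,
        )

    p1_median = ref.data.reindex(list(symbols)).loc[:, p1_cols].median(axis=1)

    chosen: dict[str, str] = {}
    for probe, symbol in symbols.items():
        current = chosen.get(symbol)
        if current is None:
            chosen[symbol] = probe
            continue
        m_new, m_cur = p1_median[probe], p1_median[current]
        if m_new > m_cur or (m_new == m_cur and probe < current):
            chosen[symbol] = probe

    gene_ids = sorted(chosen)
    probes = [chosen[g] for g in gene_ids]
    out = matrix.data.loc[probes].copy()
    out.index = gene_ids
    return ExpressionMatrix(out, list(matrix.samples))


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column to share the mean per-rank value distribution.

    Ties within a column receive the mean of the quantile values they
    span (the ``ties=TRUE`` convention).
    """
    values = matrix.data.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError("quantile normalization requires complete columns")
    n = values.shape[0]
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(n, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    frame = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(frame, list(matrix.samples), matrix.descriptions)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    if (matrix.data.to_numpy() <= 0).any():
        raise ValidationError("log2 transform requires strictly positive values")
    return ExpressionMatrix(
        np.log2(matrix.data), list(matrix.samples), matrix.descriptions
    )


def mds_coordinates(matrix: ExpressionMatrix, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples on Euclidean column distances."""
    n = len(matrix.samples)
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the sample count {n}")
    x = matrix.data.to_numpy(dtype=float).T  # samples x features
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = eigvec[:, :k] * np.sqrt(np.clip(eigval[:k], 0.0, None))
    # deterministic sign: largest-magnitude coordinate positive
    for axis in range(k):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return pd.DataFrame(
        coords,
        index=matrix.sample_ids,
        columns=[f"dim{i + 1}" for i in range(k)],
    )


def preprocess_pipeline(
    matrices: dict[str, ExpressionMatrix],
    annotation: ProbeAnnotation,
) -> tuple[dict[str, ExpressionMatrix], dict[str, PreprocessReport]]:
    """Filter each genotype independently, intersect surviving probes,
    collapse to genes (control P1 medians) and quantile-normalize the
    combined data.

    Returns per-genotype normalized (unlogged) gene-level matrices plus
    the per-genotype filter reports.
    """
    filtered: dict[str, ExpressionMatrix] = {}
    reports: dict[str, PreprocessReport] = {}
    for genotype, matrix in matrices.items():
        cutoffs = compute_cutoffs(matrix, annotation)
        filtered[genotype], reports[genotype] = filter_probes(matrix, annotation, cutoffs)

    shared = set.intersection(*(set(m.row_ids) for m in filtered.values()))
    order = [p for p in next(iter(filtered.values())).row_ids if p in shared]

    reference = filtered.get("control", next(iter(filtered.values()))).subset_rows(order)
    collapsed = {
        genotype: collapse_to_genes(m.subset_rows(order), annotation, reference=reference)
        for genotype, m in filtered.items()
    }

    # normalize all arrays together so genotypes share one distribution
    genotypes = list(collapsed)
    combined_data = pd.concat([collapsed[g].data for g in genotypes], axis=1)
    combined_samples = [s for g in genotypes for s in collapsed[g].samples]
    combined = quantile_normalize(ExpressionMatrix(combined_data, combined_samples))
    out = {
        genotype: ExpressionMatrix(
            combined.data[[s.sample_id for s in collapsed[genotype].samples]].copy(),
            list(collapsed[genotype].samples),
        )
        for genotype in genotypes
    }
    return out, reports
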
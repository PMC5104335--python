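"""Per-timepoint two-group differential expression with empirical-Bayes
variance moderation, BH FDR, fold-change calling, DE-hub intersection
and cross-age consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from somhub.coexpr_network import HubRanking
from somhub.io_formats import ExpressionMatrix, TIMEPOINTS, ValidationError


@dataclass
class EBayesFit:
    s2: np.ndarray  # per-gene residual variances
    df_residual: float
    prior_df: float  # d0; math.inf when fully shrunk
    prior_var: float  # s0^2
    s2_post: np.ndarray

    def __post_init__(self) -> None:
        lo = np.minimum(self.s2, self.prior_var)
        hi = np.maximum(self.s2, self.prior_var)
        if ((self.s2_post < lo - 1e-9) | (self.s2_post > hi + 1e-9)).any():
            raise ValidationError("posterior variances outside [s2, s0^2] envelope")


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 200) -> float:
    """Solve trigamma(y) = x for y > 0 by bisection."""
    if x <= 0:
        return math.inf
    lo, hi = 1e-8, 1e8
    if special.polygamma(1, lo) < x:
        return lo
    if special.polygamma(1, hi) > x:
        return hi
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)  # geometric mid: trigamma spans many decades
        if special.polygamma(1, mid) > x:
            lo = mid
        else:
            hi = mid
        if hi / lo - 1.0 < tol:
            break
    return math.sqrt(lo * hi)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log variances (scaled-F model).

    Uses the digamma/trigamma moment equations for log of a scaled F
    variate; returns (inf, geometric-center variance) when the observed
    spread of log s^2 is no larger than the sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    if (s2 <= 0).any():
        # guard: exactly-zero residual variance has no log
        s2 = np.maximum(s2, 1e-30)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1)) if n > 1 else 0.0
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return d0, s0_sq


def fit_moderated_t(
    matrix: ExpressionMatrix,
    timepoint: str,
    prior_df_override: float | None = None,
) -> tuple[EBayesFit, pd.DataFrame]:
    """Two-group (ko vs control) moderated t at one timepoint.

    Expects log2 expression.  Returns the empirical-Bayes fit and a
    per-gene table with log2 fold change (ko - control), linear fold
    change, moderated t, and two-sided p.  ``prior_df_override`` is a
    test hook pinning d0 (0 recovers the ordinary pooled t, ``inf`` the
    fixed-prior-variance statistic).
    """
    ctrl_cols = matrix.columns_for(genotype="control", timepoint=timepoint)
    ko_cols = matrix.columns_for(genotype="ko", timepoint=timepoint)
    n1, n2 = len(ctrl_cols), len(ko_cols)
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"need >= 2 replicates per genotype at {timepoint} (got {n1} control, {n2} ko)"
        )
    df = float(n1 + n2 - 2)
    ctrl = matrix.data[ctrl_cols].to_numpy(dtype=float)
    ko = matrix.data[ko_cols].to_numpy(dtype=float)
    mean_ctrl = ctrl.mean(axis=1)
    mean_ko = ko.mean(axis=1)
    ss = ((ctrl - mean_ctrl[:, None]) ** 2).sum(axis=1) + (
        (ko - mean_ko[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df

    if prior_df_override is not None:
        d0 = float(prior_df_override)
        _, s0_sq = estimate_prior(s2, df)
    else:
        d0, s0_sq = estimate_prior(s2, df)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    lfc = mean_ko - mean_ctrl
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    fit = EBayesFit(
        s2=s2, df_residual=df, prior_df=d0, prior_var=s0_sq, s2_post=s2_post
    )
    table = pd.DataFrame(
        {
            "log2_fc": lfc,
            "fold_change": 2.0**lfc,
            "t": t,
            "p": p,
        },
        index=pd.Index(matrix.row_ids, name="gene"),
    )
    return fit, table


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_de(
    stats_table: pd.DataFrame, fdr_max: float = 0.01, fc_min: float = 1.5
) -> pd.DataFrame:
    """Add BH q-values and an up/down/ns call at the FDR and fold-change
    thresholds (down counted as fold change <= 1/fc_min)."""
    table = stats_table.copy()
    table["q"] = bh_adjust(table["p"].to_numpy())
    fc = table["fold_change"].to_numpy()
    significant = table["q"].to_numpy() <= fdr_max
    call = np.where(
        significant & (fc >= fc_min),
        "up_in_ko",
        np.where(significant & (fc <= 1.0 / fc_min), "down_in_ko", "ns"),
    )
    table["call"] = call
    return table


def de_all_timepoints(
    matrix: ExpressionMatrix,
    fdr_max: float = 0.01,
    fc_min: float = 1.5,
    prior_df_override: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Independent two-group contrast (own BH family) per timepoint."""
    results = {}
    for tp in TIMEPOINTS:
        _, table = fit_moderated_t(matrix, tp, prior_df_override=prior_df_override)
        results[tp] = call_de(table, fdr_max=fdr_max, fc_min=fc_min)
    return results


def intersect_de_hubs(
    de: dict[str, pd.DataFrame],
    hubs: dict[int, HubRanking | None],
) -> pd.DataFrame:
    """Hub genes with at least one non-ns DE call, with the fold change
    at each significant timepoint."""
    cluster_of: dict[str, int] = {}
    for cluster, ranking in hubs.items():
        if ranking is None:
            continue
        for gene in ranking.hub_genes:
            cluster_of[gene] = cluster
    rows = []
    for gene in sorted(cluster_of):
        fcs = {}
        for tp, table in de.items():
            if gene in table.index and table.at[gene, "call"] != "ns":
                fcs[tp] = float(table.at[gene, "fold_change"])
        if fcs:
            row = {"gene": gene, "cluster": cluster_of[gene]}
            row.update({f"fc_{tp}": fcs.get(tp, np.nan) for tp in TIMEPOINTS})
            rows.append(row)
    columns = ["gene", "cluster"] + [f"fc_{tp}" for tp in TIMEPOINTS]
    return pd.DataFrame(rows, columns=columns)


def consistent_de(de: dict[str, pd.DataFrame]) -> tuple[list[str], list[str]]:
    """Genes with the same non-ns direction at every timepoint."""
    missing = [tp for tp in TIMEPOINTS if tp not in de]
    if missing:
        raise ValidationError(f"DE table missing timepoints {missing}")
    calls = pd.DataFrame({tp: de[tp]["call"] for tp in TIMEPOINTS})
    if calls.isna().any().any():
        raise ValidationError("gene sets differ across timepoint tables")
    up = calls.index[(calls == "up_in_ko").all(axis=1)]
    down = calls.index[(calls == "down_in_ko").all(axis=1)]
    return sorted(up), sorted(down)
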
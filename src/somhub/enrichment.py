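"""Gene-set overrepresentation and PWM-based promoter motif enrichment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from somhub.io_formats import GeneSetCollection, Pwm, ValidationError


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    score_threshold: float
    p: float
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if self.fg_hits > self.fg_total or self.bg_hits > self.bg_total:
            raise ValidationError("hit counts exceed totals")


def hypergeometric_enrichment(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of each gene set in
    the query, BH-adjusted across sets; rows with adjusted p <= p_max,
    sorted by p ascending.
    """
    universe_set = set(universe)
    query_set = set(query)
    outside = query_set - universe_set
    if outside:
        raise ValidationError(
            f"query genes outside universe, e.g. {sorted(outside)[:3]}"
        )
    n_universe = len(universe_set)
    n_query = len(query_set)
    rows = []
    for term_id, (term_name, members) in sets.sets.items():
        members_in = set(members) & universe_set
        big_k = len(members_in)
        if big_k == 0:
            continue
        k = len(members_in & query_set)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_query))
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "overlap": k,
                "set_size": big_k,
                "query_size": n_query,
                "universe_size": n_universe,
                "p": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "term_name", "overlap", "set_size",
                "query_size", "universe_size", "p", "adjusted_p",
            ]
        )
    table = pd.DataFrame(rows)
    from somhub.diff_expression import bh_adjust

    table["adjusted_p"] = bh_adjust(table["p"].to_numpy())
    table = table[table["adjusted_p"] <= p_max]
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _window_scores(sequence: str, log_odds: np.ndarray) -> np.ndarray:
    """Scores of all valid windows on one strand; windows containing N
    or lowercase (soft-masked) letters are skipped."""
    length = log_odds.shape[1]
    n_windows = len(sequence) - length + 1
    if n_windows <= 0:
        return np.empty(0)
    # encode: 0..3 for upper-case ACGT, -1 for anything masked/ambiguous
    codes = np.full(len(sequence), -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(sequence.encode(), dtype=np.uint8) == ord(base)] = idx
    starts = np.arange(n_windows)[:, None] + np.arange(length)[None, :]
    window_codes = codes[starts]
    valid = (window_codes >= 0).all(axis=1)
    if not valid.any():
        return np.empty(0)
    rows = window_codes[valid]
    return log_odds[rows, np.arange(length)[None, :]].sum(axis=1)


def pwm_best_score(sequence: str, pwm: Pwm) -> float | None:
    """Best log2-odds PWM score over all windows on both strands.

    Returns None (with a warning) when no window is free of masked or
    ambiguous bases.
    """
    with np.errstate(divide="ignore"):
        fwd = np.log2(pwm.probs / pwm.background[:, None])
        rc = pwm.reverse_complement()
        rev = np.log2(rc.probs / rc.background[:, None])
    scores = np.concatenate(
        [_window_scores(sequence, fwd), _window_scores(sequence, rev)]
    )
    if scores.size == 0:
        warnings.warn("sequence has no unmasked window of motif length", stacklevel=2)
        return None
    return float(scores.max())


def motif_enrichment(
    fg: Mapping[str, str],
    bg: Mapping[str, str],
    pwm: Pwm,
    score_quantile: float = 0.95,
) -> MotifEnrichmentResult:
    """Threshold-and-Fisher motif enrichment.

    The score threshold is the given quantile of best scores pooled over
    both groups; a sequence with best score >= threshold is a hit; the
    one-sided Fisher exact test asks whether hits are enriched in the
    foreground.
    """
    if len(fg) < 5 or len(bg) < 5:
        raise ValidationError("need >= 5 sequences per group")

    def best_scores(records: Mapping[str, str]) -> list[float]:
        scores = []
        for seq in records.values():
            s = pwm_best_score(seq, pwm)
            if s is not None:
                scores.append(s)
        if not scores:
            raise ValidationError("group empty after masking")
        return scores

    fg_scores = best_scores(fg)
    bg_scores = best_scores(bg)
    threshold = float(np.quantile(fg_scores + bg_scores, score_quantile))
    fg_hits = sum(s >= threshold for s in fg_scores)
    bg_hits = sum(s >= threshold for s in bg_scores)
    table = [
        [fg_hits, len(fg_scores) - fg_hits],
        [bg_hits, len(bg_scores) - bg_hits],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    return MotifEnrichmentResult(
        motif_id=pwm.motif_id,
        fg_hits=int(fg_hits),
        fg_total=len(fg_scores),
        bg_hits=int(bg_hits),
        bg_total=len(bg_scores),
        score_threshold=threshold,
        p=float(p),
    )


def motif_enrichment_many(
    fg: Mapping[str, str],
    bg: Mapping[str, str],
    pwms: Sequence[Pwm],
    score_quantile: float = 0.95,
) -> pd.DataFrame:
    """Run motif_enrichment per PWM and BH-adjust across motifs."""
    from somhub.diff_expression import bh_adjust

    results = [motif_enrichment(fg, bg, pwm, score_quantile) for pwm in pwms]
    adjusted = bh_adjust(np.array([r.p for r in results]))
    rows = []
    for result, adj in zip(results, adjusted):
        result.adjusted_p = float(adj)
        rows.append(
            {
                "motif_id": result.motif_id,
                "fg_hits": result.fg_hits,
                "fg_total": result.fg_total,
                "bg_hits": result.bg_hits,
                "bg_total": result.bg_total,
                "score_threshold": result.score_threshold,
                "p": result.p,
                "adjusted_p": result.adjusted_p,
            }
        )
    return pd.DataFrame(rows)
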
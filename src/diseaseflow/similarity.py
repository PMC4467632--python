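"""Disease-disease correlation: cosine of the angle between weight vectors.

Because weight vectors are entrywise nonnegative, the cosine lies in [0, 1];
it is scale invariant, so the unnormalized expected-visit vectors can be
compared directly. Ranked queries support either a lowest-acceptable-rank
cutoff (with tie expansion: every disease tying the boundary value is
returned) or a minimum-correlation cutoff. A correlation above the advisory
significance floor (default 1e-6) is annotated as significant; the floor never
filters results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UnknownIDError

DEFAULT_SIGNIFICANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class SimilarityResult:
    """Ranked similar-disease list for one query disease."""

    query: str
    hits: tuple  # of (disease_id, correlation, significant)
    cutoff_mode: str  # "rank" or "min_corr"
    significance_floor: float = DEFAULT_SIGNIFICANCE_FLOOR


def correlation(wa, wb):
    """Cosine similarity between two weight vectors (same protein ordering)."""
    va = np.asarray(wa.w if hasattr(wa, "w") else wa, dtype=float)
    vb = np.asarray(wb.w if hasattr(wb, "w") else wb, dtype=float)
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ParameterError("correlation undefined for a zero weight vector")
    return float(va @ vb / (na * nb))


def correlation_matrix(W):
    """All-pairs cosine matrix for a diseases x proteins weight matrix.

    The diagonal is exactly 1 and the result is exactly symmetric (computed
    once per unordered pair).
    """
    W = np.asarray(W, dtype=float)
    norms = np.linalg.norm(W, axis=1)
    if np.any(norms == 0.0):
        raise ParameterError("correlation_matrix requires nonzero rows")
    C = (W / norms[:, None]) @ (W / norms[:, None]).T
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, 0.0, 1.0)


def rank_cutoff(pairs, rank):
    """Keep the top ``rank`` of (id, score) pairs, expanding boundary ties.

    ``pairs`` must already be sorted by non-increasing score. Tie detection is
    exact float equality: the deterministic pipeline makes equal inputs yield
    bitwise-equal scores, and near-ties are deliberately not expanded.
    """
    if rank < 1:
        raise ParameterError(f"rank cutoff must be >= 1, got {rank}")
    if len(pairs) <= rank:
        return list(pairs)
    boundary = pairs[rank - 1][1]
    out = list(pairs[:rank])
    for item in pairs[rank:]:
        if item[1] == boundary:
            out.append(item)
        else:
            break
    return out


def _sorted_pairs(ids, scores):
    # sort by score desc, then ID asc for byte-stable output
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return [(ids[i], float(scores[i])) for i in order]


def query_similar(C, diseases, disease, rank=None, min_corr=None,
                  significance_floor=DEFAULT_SIGNIFICANCE_FLOOR):
    """Ranked similar-disease query against a precomputed correlation matrix.

    Exactly one of ``rank`` (lowest acceptable rank, tie-expanded) or
    ``min_corr`` (minimum correlation, inclusive) must be given.
    """
    if (rank is None) == (min_corr is None):
        raise ParameterError("provide exactly one of rank or min_corr")
    diseases = list(diseases)
    try:
        qi = diseases.index(disease)
    except ValueError:
        raise UnknownIDError("disease", disease) from None

    others = [d for d in diseases if d != disease]
    scores = [C[qi, diseases.index(d)] for d in others]
    pairs = _sorted_pairs(others, scores)

    if rank is not None:
        hits = rank_cutoff(pairs, rank)
        mode = "rank"
    else:
        if not 0.0 <= min_corr <= 1.0:
            raise ParameterError(f"min_corr must be in [0, 1], got {min_corr}")
        hits = [(d, c) for d, c in pairs if c >= min_corr]
        mode = "min_corr"

    annotated = tuple((d, c, c > significance_floor) for d, c in hits)
    return SimilarityResult(
        query=disease,
        hits=annotated,
        cutoff_mode=mode,
        significance_floor=significance_floor,
    )
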
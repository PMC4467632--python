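"""Overlapping probabilistic clustering of diseases in weight-vector space.

Diseases and clusters live in the same space: each cluster is itself a unit
weight vector over proteins, and a disease's membership in cluster k is
proportional to the (sharpened) cosine between the disease's normalized weight
vector and the cluster vector. Fitting alternates a soft assignment (E) step

    P[d, k] = C(w_hat(d), v_k)^gamma / sum_j C(w_hat(d), v_j)^gamma

with a spherical (M) step ``v_k = normalize(sum_d P[d, k] * w_hat(d))`` until
memberships stabilize. Clusters overlap by construction: each membership row
is a probability distribution over clusters, not a hard label. After
convergence, near-duplicate clusters (mutual cosine above a merge threshold)
are merged by summing memberships, followed by one final E step.

This module is a self-contained definition of the clustering contract: a soft
spherical (cosine) expectation-maximization with a sharpness exponent, chosen
to satisfy the stated requirements (overlapping clusters, clusters represented
by weight vectors, memberships derived from correlations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UnknownIDError
from .similarity import rank_cutoff, _sorted_pairs

logger = logging.getLogger(__name__)

DEFAULT_MERGE_THRESHOLD = 0.999
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500

#: Default sharpness. Weight vectors are nonnegative, so every pairwise
#: cosine is positive and usually carries a large shared background (hub
#: proteins); with gamma = 1 the E-step responsibilities are so diffuse that
#: the M-step contracts every center to the global barycenter and the fit
#: degenerates to one cluster. gamma = 4 gives well-separated responsibilities
#: while keeping memberships genuinely soft.
DEFAULT_GAMMA = 4.0


def default_k(n_diseases):
    """Default cluster count: ceil(sqrt(number of diseases))."""
    return int(np.ceil(np.sqrt(n_diseases)))


@dataclass
class ClusterModel:
    """Fitted overlapping clustering.

    ``V`` is K x proteins (unit rows); ``P`` is diseases x K with rows summing
    to 1; ``cluster_ids`` are "C1".."CK" after any merges.
    """

    diseases: tuple
    cluster_ids: tuple
    V: np.ndarray
    P: np.ndarray
    gamma: float
    converged: bool
    n_iter: int

    def membership_row(self, disease):
        try:
            i = self.diseases.index(disease)
        except ValueError:
            raise UnknownIDError("disease", disease) from None
        return self.P[i]


def _normalize_rows(M):
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return M / norms


def init_clusters(W, K, seed):
    """Greedy farthest-first seeding on cosine distance.

    The first center is the disease with the largest total weight; each
    subsequent center maximizes its minimum cosine distance to the centers
    chosen so far. The seed only breaks exact ties (via a random priority
    permutation), so the initialization is deterministic.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not 1 <= K <= n:
        raise ParameterError(f"K must be in [1, {n}], got {K}")
    Wn = _normalize_rows(W)
    rng = np.random.default_rng(seed)
    priority = rng.permutation(n)  # tie-break order

    totals = W.sum(axis=1)
    first = max(range(n), key=lambda i: (totals[i], priority[i]))
    chosen = [first]
    min_sim = Wn @ Wn[first]
    while len(chosen) < K:
        nxt = max(
            (i for i in range(n) if i not in chosen),
            key=lambda i: (-min_sim[i], priority[i]),
        )
        chosen.append(nxt)
        min_sim = np.maximum(min_sim, Wn @ Wn[nxt])
    return Wn[chosen].copy()


def _e_step(Wn, V, gamma):
    C = np.clip(Wn @ V.T, 0.0, 1.0)
    G = C ** gamma
    sums = G.sum(axis=1)
    P = np.empty_like(G)
    zero = sums == 0.0
    P[~zero] = G[~zero] / sums[~zero, None]
    P[zero] = 1.0 / V.shape[0]  # no signal: uniform membership
    return P


def fit(W, K=None, gamma=DEFAULT_GAMMA, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER,
        seed=0, diseases=None, merge_threshold=DEFAULT_MERGE_THRESHOLD):
    """Fit the overlapping clustering by cosine E/M alternation.

    Parameters
    ----------
    W : array, diseases x proteins
        Weight matrix (rows need not be normalized).
    K : int, optional
        Number of clusters before merging; defaults to ceil(sqrt(#diseases)).
    gamma : float
        Sharpness exponent >= 1; larger values harden assignments.
    tol : float
        Convergence threshold on the max absolute membership change.
    max_iter : int
        Iteration cap; non-convergence returns the model with
        ``converged=False`` and a logged warning.
    seed : int
        Tie-break seed for initialization.
    diseases : sequence of str, optional
        Row labels; defaults to D0..Dn-1.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if diseases is None:
        diseases = tuple(f"D{i}" for i in range(n))
    diseases = tuple(diseases)
    if K is None:
        K = default_k(n)
    if gamma < 1.0:
        raise ParameterError(f"gamma must be >= 1, got {gamma}")

    Wn = _normalize_rows(W)
    V = init_clusters(W, K, seed)
    P = _e_step(Wn, V, gamma)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        V = _normalize_rows(P.T @ Wn)
        P_new = _e_step(Wn, V, gamma)
        delta = np.abs(P_new - P).max()
        P = P_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("clustering did not converge in %d iterations", max_iter)

    V, P = _merge_duplicates(Wn, V, P, gamma, merge_threshold)
    cluster_ids = tuple(f"C{k + 1}" for k in range(V.shape[0]))
    return ClusterModel(
        diseases=diseases,
        cluster_ids=cluster_ids,
        V=V,
        P=P,
        gamma=gamma,
        converged=converged,
        n_iter=n_iter,
    )


def _merge_duplicates(Wn, V, P, gamma, threshold):
    """Merge cluster pairs with mutual cosine > threshold; memberships summed.

    Merged groups are found by union-find over the above-threshold pairs; the
    merged cluster vector is rebuilt from the summed memberships, and one
    final E step refreshes P.
    """
    K = V.shape[0]
    parent = list(range(K))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    S = V @ V.T
    for i in range(K):
        for j in range(i + 1, K):
            if S[i, j] > threshold:
                parent[find(j)] = find(i)

    groups = {}
    for k in range(K):
        groups.setdefault(find(k), []).append(k)
    if len(groups) == K:
        return V, _e_step(Wn, V, gamma)

    members = [groups[r] for r in sorted(groups)]
    P_merged = np.stack([P[:, g].sum(axis=1) for g in members], axis=1)
    V_merged = _normalize_rows(P_merged.T @ Wn)
    return V_merged, _e_step(Wn, V_merged, gamma)


def membership_query(model, disease, rank=None, min_prob=None):
    """Clusters containing a disease, ranked by membership probability.

    Cutoff semantics (rank with tie expansion, or minimum probability) mirror
    the similar-disease query.
    """
    if (rank is None) == (min_prob is None):
        raise ParameterError("provide exactly one of rank or min_prob")
    row = model.membership_row(disease)
    pairs = _sorted_pairs(list(model.cluster_ids), row)
    if rank is not None:
        return rank_cutoff(pairs, rank)
    if not 0.0 <= min_prob <= 1.0:
        raise ParameterError(f"min_prob must be in [0, 1], got {min_prob}")
    return [(c, p) for c, p in pairs if p >= min_prob]


def cluster_listing(model, cluster_id):
    """All diseases in a cluster, sorted by non-increasing membership."""
    try:
        k = model.cluster_ids.index(cluster_id)
    except ValueError:
        raise UnknownIDError("cluster", cluster_id) from None
    return _sorted_pairs(list(model.diseases), model.P[:, k])
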
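"""Random-walk information flow: expected visit counts per protein.

A walker starts at a disease node, steps to one of the disease's associated
proteins uniformly at random (forced by equal attachment weights), and then
performs a weighted random walk on the protein subgraph. Every disease node is
absorbing: at protein ``i`` with total incident weight ``s_i`` (PPI weight plus
``beta`` per attached disease) the walker moves to protein ``j`` with
probability ``w_ij / s_i`` and is absorbed with probability
``beta * n_attached(i) / s_i``. The *weight* of protein ``i`` for a disease is
the expected number of visits to ``i`` before absorption — the corresponding
row of the absorbing-chain fundamental matrix (I - Q)^-1 averaged over the
start distribution.

Exact vectors come from a sparse LU solve of (I - Q^T) x = s(d); an
independent Monte-Carlo simulator (:func:`simulate_walks`) exists purely as a
cross-check oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix, identity
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .errors import DiseaseFlowError, UnknownIDError

#: absolute tolerance for the row-stochasticity check Q·1 + a = 1
_ROW_SUM_TOL = 1e-12


@dataclass
class TransitionModel:
    """Sub-stochastic protein-walk model derived from a pruned network.

    Attributes
    ----------
    proteins, diseases : tuple of str
        Node orderings inherited from the network.
    Q : scipy.sparse.csr_matrix
        proteins x proteins transition matrix, ``Q[i, j] = w_ij / s_i``.
    a : numpy.ndarray
        Per-protein absorption probability ``beta * n_attached(i) / s_i``.
    strengths : numpy.ndarray
        Total incident weight ``s_i`` per protein.
    starts : dict of str -> numpy.ndarray
        Per-disease start distribution over proteins (uniform on the
        disease's associated proteins).
    beta : float
    """

    proteins: tuple
    diseases: tuple
    Q: object
    a: np.ndarray
    strengths: np.ndarray
    starts: dict
    beta: float
    _lu: object = field(default=None, repr=False, compare=False)

    def start_distribution(self, disease):
        try:
            return self.starts[disease]
        except KeyError:
            raise UnknownIDError("disease", disease) from None

    def solver(self):
        """Cached sparse LU factorization of (I - Q)^T."""
        if self._lu is None:
            n = len(self.proteins)
            M = (identity(n, format="csc") - self.Q.T).tocsc()
            self._lu = splu(csc_matrix(M))
        return self._lu


@dataclass(frozen=True)
class WeightVector:
    """Expected visit counts over the protein ordering for one disease."""

    disease: str
    w: np.ndarray


def build_transition_model(net):
    """Derive Q, absorption probabilities, and start distributions.

    Requires a pruned network: every PPI component must contain at least one
    disease-attached protein, otherwise the walk could never terminate there.
    """
    n = net.n_proteins
    adj = net.adjacency()
    counts = net.attachment_counts()

    if n:
        _, labels = connected_components(adj, directed=False)
        absorbed = np.zeros(labels.max() + 1, dtype=bool)
        for comp in labels[counts > 0]:
            absorbed[comp] = True
        if not absorbed.all():
            raise DiseaseFlowError(
                "network contains a component with no disease attachment; "
                "run prune_unreachable first"
            )

    strengths = np.asarray(adj.sum(axis=1)).ravel() + net.beta * counts
    inv_s = np.zeros(n)
    nz = strengths > 0
    inv_s[nz] = 1.0 / strengths[nz]
    Q = adj.multiply(inv_s[:, None]).tocsr()
    a = np.where(nz, net.beta * counts * inv_s, 0.0)

    starts = {}
    for disease in net.diseases:
        genes = net.associations[disease]
        s = np.zeros(n)
        for p in genes:
            s[net.protein_index(p)] = 1.0 / len(genes)
        starts[disease] = s

    row_sums = np.asarray(Q.sum(axis=1)).ravel() + a
    if n and np.abs(row_sums - 1.0).max() > _ROW_SUM_TOL:
        raise DiseaseFlowError("transition rows do not sum to 1")

    return TransitionModel(
        proteins=net.proteins,
        diseases=net.diseases,
        Q=Q,
        a=a,
        strengths=strengths,
        starts=starts,
        beta=net.beta,
    )


def compute_weight_vector(tm, disease):
    """Exact weight vector: solve (I - Q^T) x = s(d)."""
    s = tm.start_distribution(disease)
    w = tm.solver().solve(s)
    return WeightVector(disease=disease, w=w)


def compute_all_weight_vectors(tm):
    """diseases x proteins matrix of weight vectors (rows in disease order).

    One LU factorization is reused across all right-hand sides; rows agree
    with :func:`compute_weight_vector` bitwise.
    """
    n = len(tm.proteins)
    W = np.empty((len(tm.diseases), n))
    if n == 0:
        return W
    lu = tm.solver()
    for i, disease in enumerate(tm.diseases):
        W[i] = lu.solve(tm.starts[disease])
    return W


def expected_total_visits(tm):
    """Per-protein expected total visits for a walk started at that protein.

    Solves (I - Q) l = 1; ``l[i]`` is the expected number of protein visits
    (including the start) before absorption when starting at protein ``i``.
    Used by the perturbation error bounds.
    """
    n = len(tm.proteins)
    if n == 0:
        return np.empty(0)
    M = (identity(n, format="csc") - tm.Q).tocsc()
    return splu(M).solve(np.ones(n))


@dataclass(frozen=True)
class EmpiricalWeightVector:
    """Monte-Carlo estimate of a weight vector with per-entry standard errors."""

    disease: str
    w: np.ndarray
    se: np.ndarray
    n_walks: int
    n_truncated: int


def simulate_walks(net, disease, n_walks, seed, max_steps=10**6):
    """Independent Monte-Carlo oracle for :func:`compute_weight_vector`.

    Simulates ``n_walks`` absorbing walks (vectorized over walkers) and
    returns mean visit counts with standard errors. ``max_steps`` is a safety
    valve only; truncated walks are counted and reported.
    """
    tm = build_transition_model(net)
    n = len(tm.proteins)
    rng = np.random.default_rng(seed)
    if n_walks <= 0:
        import warnings

        warnings.warn("simulate_walks called with n_walks <= 0; returning zeros")
        return EmpiricalWeightVector(disease, np.zeros(n), np.zeros(n), 0, 0)

    # Padded per-node tables: cumulative move probabilities (absorption is the
    # implicit tail) and the neighbor index per slot.
    Q = tm.Q.tocsr()
    degs = np.diff(Q.indptr)
    max_deg = int(degs.max()) if n else 0
    cum = np.ones((n, max_deg + 1))
    nxt = np.zeros((n, max_deg + 1), dtype=np.int64)
    for i in range(n):
        lo, hi = Q.indptr[i], Q.indptr[i + 1]
        probs = Q.data[lo:hi]
        cum[i, : hi - lo] = np.cumsum(probs)
        cum[i, hi - lo :] = 1.0  # remaining mass = absorption
        nxt[i, : hi - lo] = Q.indices[lo:hi]

    start = tm.start_distribution(disease)
    support = np.flatnonzero(start)
    cur = rng.choice(support, size=n_walks, p=start[support])

    visits = np.zeros((n_walks, n), dtype=np.int32)
    walker = np.arange(n_walks)
    np.add.at(visits, (walker, cur), 1)

    active = np.ones(n_walks, dtype=bool)
    n_truncated = 0
    for _ in range(max_steps):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        pos = cur[idx]
        r = rng.random(idx.size)
        slot = (r[:, None] >= cum[pos]).sum(axis=1)
        absorbed = slot >= degs[pos]
        moved = ~absorbed
        cur[idx[moved]] = nxt[pos[moved], slot[moved]]
        np.add.at(visits, (idx[moved], cur[idx[moved]]), 1)
        active[idx[absorbed]] = False
    else:
        n_truncated = int(active.sum())

    mean = visits.mean(axis=0)
    if n_walks > 1:
        se = visits.std(axis=0, ddof=1) / np.sqrt(n_walks)
    else:
        se = np.zeros(n)
    return EmpiricalWeightVector(disease, mean, se, n_walks, n_truncated)
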
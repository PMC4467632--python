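"""What-if edits: approximate re-scoring with certified error bounds.

Replacing a disease's gene associations (or adding a new disease) changes the
network, and in principle every weight vector, correlation, and cluster with
it. Recomputing everything is exact but slow; this module instead computes
only the *edited* disease's weight vector exactly in the edited network,
freezes every other disease vector and all cluster vectors at their base
values, and attaches to each reported number a certified upper bound on the
error introduced by the freeze.

Error-bound derivation
----------------------
Let Q and Q' be the base and edited protein-transition matrices. They differ
only in the rows of the proteins A whose attachment count changed: each such
row is rescaled by s_p / s'_p (s_p = total incident weight of protein p). For
an unedited disease e with base visit vector w(e), the exact perturbation
identity

    w'(e) - w(e) = [w(e)^T (Q' - Q) (I - Q')^{-1}]^T

gives, with u^T = w(e)^T (Q' - Q) (a sparse, explicitly computable vector
supported on the neighbors of A) and l'_j = expected total visits of the
*edited* walk started at protein j (one extra linear solve),

    ||w'(e) - w(e)||_1  <=  Delta1(e) := sum_j |u_j| * l'_j ,

because (I - Q')^{-1} is entrywise nonnegative with row sums l'.
Interpretation: |u_j| is the probability mass diverted through the edited
proteins into j, and each unit of diverted mass changes subsequent expected
visits by at most the expected visit count of a walk restarted at j.

Downstream bounds follow from the normalization perturbation lemma
|| y/||y|| - y'/||y'|| || <= 2 ||y - y'|| / max(||y||, ||y'||):

* correlation with disease e:   delta(e) = min(1, 2 Delta1(e) / ||w(e)||_2);
* cluster-vector drift (responsibilities P frozen):
      delta_k = min(2, 2 (sum_d P[d,k] eta_d) / ||y_k||_2),
  where eta_d bounds each disease's normalized-vector drift and y_k is the
  unnormalized cluster sum;
* membership of the edited disease, with g_k = C_k^gamma, S = sum_j g_j,
  e_k = min(1, gamma * delta_k), DS = sum_k e_k:
      min(1, (e_k + P_k * DS) / (S - DS))   if S > DS, else 1.

The membership bound certifies the deterministic frozen-responsibility
re-score (cluster vectors rebuilt from exactly recomputed disease vectors
with the base membership matrix fixed, then one E step;
:func:`rescore_frozen`), not a full clustering refit: a refit is an EM
restart whose outcome is not a continuous function of the input. A no-op
edit (same gene set) is detected and returns the base answers with all
bounds exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import _normalize_rows
from .errors import ParameterError, UnknownIDError
from .model import FlowModel
from .network import DiseaseProteinNetwork, prune_unreachable
from .walk import build_transition_model, compute_weight_vector, expected_total_visits


@dataclass(frozen=True)
class WhatIfResult:
    """Approximate re-scored answers for one edited disease.

    ``approx_correlations`` holds (disease_id, correlation, error_bound)
    sorted by non-increasing correlation; ``approx_memberships`` holds
    (cluster_id, probability, error_bound) sorted likewise (empty when no
    clustering was fit). ``exact_available`` is True when the edit was a
    no-op, in which case the "approximation" is exact and all bounds are 0.
    """

    disease: str
    approx_correlations: tuple
    approx_memberships: tuple
    exact_available: bool


def apply_edit(net, disease, genes):
    """Replace a disease's gene associations (or add a new disease).

    Existing associations of ``disease`` are discarded and replaced by
    ``genes`` (the supplied list fully defines the disease). Unknown proteins
    are added as isolated nodes; the result is re-pruned.
    """
    genes = frozenset(genes)
    if not genes:
        raise ParameterError("what-if edit requires a nonempty gene list")

    associations = dict(net.associations)
    associations[disease] = genes
    proteins = set(net.proteins) | genes
    edited = DiseaseProteinNetwork(
        proteins=tuple(sorted(proteins)),
        diseases=tuple(sorted(associations)),
        ppi_edges=net.ppi_edges,
        associations=associations,
        beta=net.beta,
    )
    pruned, _ = prune_unreachable(edited)
    return pruned


class _EditFrame:
    """Shared geometry of a base model and an edited network.

    Everything is expressed over the *base* protein ordering plus the norm of
    the edited disease's full vector: unedited diseases have zero weight on
    proteins outside the base set (new proteins are PPI-isolated and pruned
    proteins lie in components those diseases never attach to), so base-space
    projections lose nothing except the edited disease's own new-protein
    mass, which is tracked through ``x_norm``.
    """

    def __init__(self, model, edited_net, disease):
        if disease not in edited_net.diseases:
            raise UnknownIDError("disease", disease)
        self.model = model
        self.edited_net = edited_net
        self.disease = disease
        self.base_index = {p: i for i, p in enumerate(model.net.proteins)}
        self.tm1 = build_transition_model(edited_net)
        x = compute_weight_vector(self.tm1, disease).w
        self.x_norm = float(np.linalg.norm(x))
        self.x_base = self._to_base(x)
        self.is_noop = (
            disease in model.net.associations
            and edited_net.associations[disease] == model.net.associations[disease]
        )

    def _to_base(self, vec):
        out = np.zeros(self.model.net.n_proteins)
        for i, p in enumerate(self.edited_net.proteins):
            j = self.base_index.get(p)
            if j is not None:
                out[j] = vec[i]
        return out

    def edited_unit_drift(self):
        """Exact ||x_hat - w0_hat(d*)||_2 over the union protein space
        (0 if the edited disease is new to the base model)."""
        if self.disease not in self.model.diseases:
            return 0.0
        if self.is_noop:
            return 0.0
        di = self.model.diseases.index(self.disease)
        w0n = self.model.W[di] / self.model.weight_norms()[di]
        base_part = self.x_base / self.x_norm - w0n
        new_mass_sq = max(self.x_norm**2 - float(self.x_base @ self.x_base), 0.0)
        return float(np.sqrt(base_part @ base_part + new_mass_sq / self.x_norm**2))


def _visit_delta_bounds(frame):
    """Per-base-disease Delta1 bound on ||w'(e) - w(e)||_1 (0 for the edited
    disease itself, whose vector is computed exactly)."""
    model, edited_net = frame.model, frame.edited_net
    n0 = model.net.n_proteins
    deltas = np.zeros(len(model.diseases))
    if frame.is_noop:
        return deltas

    old = model.net.associations.get(frame.disease, frozenset())
    changed = old ^ edited_net.associations[frame.disease]
    if not changed:
        return deltas

    s0 = model.tm.strengths
    s1 = frame.tm1.strengths
    idx1 = {p: i for i, p in enumerate(edited_net.proteins)}

    # Row rescale factors for changed proteins present in both networks;
    # changed proteins absent from one side carry zero weight for every
    # unedited disease and drop out of u.
    rows, factors = [], []
    for p in sorted(changed):
        i0 = frame.base_index.get(p)
        i1 = idx1.get(p)
        if i0 is None or i1 is None:
            continue
        rows.append(i0)
        factors.append(s0[i0] / s1[i1] - 1.0)
    if not rows:
        return deltas

    rows = np.asarray(rows)
    factors = np.asarray(factors)
    ell1 = frame._to_base(expected_total_visits(frame.tm1))

    Q0 = model.tm.Q
    for di, e in enumerate(model.diseases):
        if e == frame.disease:
            continue
        d = np.zeros(n0)
        d[rows] = model.W[di, rows] * factors
        u = Q0.T @ d  # u_j = sum_p w_p(e) (Q'_pj - Q_pj)
        deltas[di] = float(np.abs(u) @ ell1)
    return deltas


def approx_whatif(model, edited_net, disease):
    """Approximately re-score one edited disease against a frozen base model.

    Parameters
    ----------
    model : FlowModel
        Base model (network, weight matrix, optional fitted clustering).
    edited_net : DiseaseProteinNetwork
        Output of :func:`apply_edit` on the base network.
    disease : str
        The edited (or new) disease ID.
    """
    frame = _EditFrame(model, edited_net, disease)
    deltas = _visit_delta_bounds(frame)
    wnorms = model.weight_norms()

    # normalized-vector drift bound per base disease, for the cluster bounds
    eta = np.minimum(2.0, 2.0 * deltas / wnorms)
    if disease in model.diseases:
        eta[model.diseases.index(disease)] = frame.edited_unit_drift()

    corr_rows = []
    for di, e in enumerate(model.diseases):
        if e == disease:
            continue
        c = float(frame.x_base @ model.W[di] / (frame.x_norm * wnorms[di]))
        bound = 0.0 if frame.is_noop else min(1.0, 2.0 * deltas[di] / wnorms[di])
        corr_rows.append((e, min(c, 1.0), bound))
    corr_rows.sort(key=lambda t: (-t[1], t[0]))

    memb_rows = []
    if model.clusters is not None:
        memb_rows = _approx_memberships(frame, eta)

    return WhatIfResult(
        disease=disease,
        approx_correlations=tuple(corr_rows),
        approx_memberships=tuple(memb_rows),
        exact_available=frame.is_noop,
    )


def _approx_memberships(frame, eta):
    model = frame.model
    cm = model.clusters
    gamma = cm.gamma
    K = len(cm.cluster_ids)

    Wn = _normalize_rows(model.W)
    y = cm.P.T @ Wn  # unnormalized cluster sums
    y_norms = np.linalg.norm(y, axis=1)
    drift = cm.P.T @ eta
    # convergence residual: the fitted V differs from the M-step
    # reconstruction normalize(P^T W_hat) by up to the fit tolerance, and the
    # frozen-responsibility re-score starts from the reconstruction
    resid = np.linalg.norm(cm.V - _normalize_rows(y), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta_k = np.where(y_norms > 0, 2.0 * drift / y_norms, 2.0) + resid
    delta_k = np.minimum(delta_k, 2.0)

    C_k = np.clip((cm.V @ frame.x_base) / frame.x_norm, 0.0, 1.0)
    G = C_k ** gamma
    S = float(G.sum())
    if S == 0.0:
        probs = np.full(K, 1.0 / K)
        bounds = np.ones(K)
    else:
        probs = G / S
        if frame.is_noop:
            bounds = np.zeros(K)
        else:
            e_k = np.minimum(1.0, gamma * delta_k)
            DS = float(e_k.sum())
            if S > DS:
                bounds = np.minimum(1.0, (e_k + probs * DS) / (S - DS))
            else:
                bounds = np.ones(K)

    rows = [
        (cid, float(probs[k]), float(bounds[k]))
        for k, cid in enumerate(cm.cluster_ids)
    ]
    rows.sort(key=lambda t: (-t[1], t[0]))
    return rows


def exact_whatif(edited_net, K=None, gamma=None, seed=0):
    """Full recomputation on the edited network: all weight vectors plus a
    fresh clustering fit. The exact (but slow) counterpart of
    :func:`approx_whatif` and the oracle for its weight vectors and
    correlations."""
    model = FlowModel.from_network(edited_net)
    if K is not None:
        kwargs = {} if gamma is None else {"gamma": gamma}
        model.fit_clusters(K=K, seed=seed, **kwargs)
    return model


def rescore_frozen(model, edited_net, disease):
    """Exact re-score with frozen cluster responsibilities (test oracle).

    Recomputes every base disease's weight vector exactly in the edited
    network, rebuilds each cluster vector from those exact vectors using the
    *base* membership matrix, then evaluates the edited disease's exact
    correlations and one-E-step memberships. This is the quantity the
    approximate path's error bounds certify. Returns ``(corr, memb)`` dicts
    keyed by disease and cluster ID.
    """
    frame = _EditFrame(model, edited_net, disease)
    tm1 = frame.tm1

    # exact edited vectors, projected to base space (lossless for unedited
    # diseases; the edited disease's new-protein mass is carried via x_norm)
    W1 = np.zeros_like(model.W)
    full_norms = np.zeros(len(model.diseases))
    for di, e in enumerate(model.diseases):
        if e == disease:
            W1[di] = frame.x_base
            full_norms[di] = frame.x_norm
        else:
            w = compute_weight_vector(tm1, e).w
            W1[di] = frame._to_base(w)
            full_norms[di] = float(np.linalg.norm(w))

    corr = {}
    for di, e in enumerate(model.diseases):
        if e == disease:
            continue
        corr[e] = float(frame.x_base @ W1[di] / (frame.x_norm * full_norms[di]))

    memb = {}
    if model.clusters is not None:
        cm = model.clusters
        Wn1 = W1 / full_norms[:, None]
        # cluster sums live on the union space; the only coordinate outside
        # the base projection is the edited disease's new-protein mass, which
        # is orthogonal to x_base but not to x itself, so the E-step cosine
        # needs the cross term restored
        y_base = cm.P.T @ Wn1
        if disease in model.diseases:
            p_star = cm.P[model.diseases.index(disease)]
            new_mass = np.sqrt(
                max(frame.x_norm**2 - float(frame.x_base @ frame.x_base), 0.0)
            ) / frame.x_norm
        else:
            p_star = np.zeros(len(cm.cluster_ids))
            new_mass = 0.0
        extra = p_star * new_mass  # per-cluster coefficient on the new axis
        y_norms = np.sqrt(np.linalg.norm(y_base, axis=1) ** 2 + extra**2)
        dots = y_base @ frame.x_base / frame.x_norm + extra * new_mass
        C_k = np.clip(dots / np.where(y_norms > 0, y_norms, 1.0), 0.0, 1.0)
        G = C_k ** cm.gamma
        S = float(G.sum())
        if S == 0.0:
            probs = np.full(len(cm.cluster_ids), 1.0 / len(cm.cluster_ids))
        else:
            probs = G / S
        memb = {cid: float(probs[k]) for k, cid in enumerate(cm.cluster_ids)}
    return corr, memb
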
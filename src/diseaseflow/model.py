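"""Convenience bundle tying network, walk, similarity, and clustering together."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cluster as _cluster
from .network import prune_unreachable
from .similarity import correlation_matrix
from .walk import build_transition_model, compute_all_weight_vectors


@dataclass
class FlowModel:
    """A fully scored network: weight matrix, correlations, optional clustering.

    Construct with :meth:`from_network`; the input network is pruned, the
    transition model built, all weight vectors solved, and the all-pairs
    correlation matrix computed. Clustering is fit on demand.
    """

    net: object
    prune_report: list
    tm: object
    W: np.ndarray
    C: np.ndarray
    clusters: object = None
    _wnorms: np.ndarray = field(default=None, repr=False)

    @classmethod
    def from_network(cls, net):
        pruned, report = prune_unreachable(net)
        tm = build_transition_model(pruned)
        W = compute_all_weight_vectors(tm)
        C = correlation_matrix(W) if len(pruned.diseases) else np.empty((0, 0))
        return cls(net=pruned, prune_report=report, tm=tm, W=W, C=C)

    @property
    def diseases(self):
        return self.net.diseases

    @property
    def proteins(self):
        return self.net.proteins

    def weight_norms(self):
        if self._wnorms is None:
            self._wnorms = np.linalg.norm(self.W, axis=1)
        return self._wnorms

    def fit_clusters(self, K=None, gamma=_cluster.DEFAULT_GAMMA, tol=_cluster.DEFAULT_TOL,
                     max_iter=_cluster.DEFAULT_MAX_ITER, seed=0):
        self.clusters = _cluster.fit(
            self.W, K=K, gamma=gamma, tol=tol, max_iter=max_iter,
            seed=seed, diseases=self.diseases,
        )
        return self.clusters
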
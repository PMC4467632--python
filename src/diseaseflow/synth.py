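"""Synthetic disease-protein networks with planted modular structure.

The generator plants ``n_modules`` protein modules. Each module gets a random
spanning tree (guaranteeing within-module connectivity even at low edge
density) plus independent within-module edges at probability ``p_within``;
pairs of proteins in different modules are joined at probability
``p_between``. Each disease draws its genes without replacement from a single
module's proteins, and the module index is returned as a ground-truth label
for clustering-recovery tests. Everything is deterministic given the seed.

A small catalog of hand-analyzable networks (:func:`tiny_fixtures`) carries
closed-form expected weight vectors and correlations for exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .network import build_network, prune_unreachable


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-module network."""

    n_modules: int = 3
    proteins_per_module: int = 15
    p_within: float = 0.3
    p_between: float = 0.01
    diseases_per_module: int = 4
    genes_per_disease: int = 3
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.p_within > self.p_between >= 0:
            raise ParameterError("require p_within > p_between >= 0")
        if min(self.n_modules, self.proteins_per_module,
               self.diseases_per_module, self.genes_per_disease) < 1:
            raise ParameterError("all counts must be >= 1")
        if self.genes_per_disease > self.proteins_per_module:
            raise ParameterError("genes_per_disease exceeds proteins_per_module")


def generate(spec):
    """Generate ``(network, labels)`` for a :class:`FixtureSpec`.

    ``labels`` maps each disease ID to its planted module index.
    """
    rng = np.random.default_rng(spec.seed)
    modules = [
        [f"M{m}P{i:03d}" for i in range(spec.proteins_per_module)]
        for m in range(spec.n_modules)
    ]

    pairs = set()
    for prots in modules:
        # random spanning tree: attach each node to a random earlier node
        order = rng.permutation(len(prots))
        for k in range(1, len(prots)):
            j = rng.integers(0, k)
            a, b = prots[order[k]], prots[order[j]]
            pairs.add((a, b) if a < b else (b, a))
        for i in range(len(prots)):
            for j in range(i + 1, len(prots)):
                if rng.random() < spec.p_within:
                    a, b = prots[i], prots[j]
                    pairs.add((a, b) if a < b else (b, a))
    for m1 in range(spec.n_modules):
        for m2 in range(m1 + 1, spec.n_modules):
            for a in modules[m1]:
                for b in modules[m2]:
                    if rng.random() < spec.p_between:
                        pairs.add((a, b) if a < b else (b, a))

    assoc = {}
    labels = {}
    for m, prots in enumerate(modules):
        for j in range(spec.diseases_per_module):
            disease = f"M{m}D{j}"
            genes = rng.choice(
                len(prots), size=spec.genes_per_disease, replace=False
            )
            assoc[disease] = {prots[g] for g in genes}
            labels[disease] = m

    net = build_network(sorted(pairs), assoc, beta=spec.beta)
    return net, labels


def write_fixture_files(net, ppi_path, assoc_path):
    """Write a network back out as the standard PPI/association TSVs."""
    with open(ppi_path, "w", encoding="utf-8") as fh:
        fh.write("#protein_a\tprotein_b\n")
        for a, b in net.ppi_edges:
            fh.write(f"{a}\t{b}\n")
    with open(assoc_path, "w", encoding="utf-8") as fh:
        fh.write("#disease_id\tprotein_id\n")
        for d in net.diseases:
            for p in sorted(net.associations[d]):
                fh.write(f"{d}\t{p}\n")


def tiny_fixtures():
    """Catalog of hand-analyzable networks with closed-form expectations.

    path2
        D1-P1-P2-D2 with beta=1. Each protein has strength 2, so
        Q = [[0, 1/2], [1/2, 0]], a = (1/2, 1/2); solving (I - Q^T)x = s
        gives w(D1) = (4/3, 2/3), w(D2) = (2/3, 4/3), cosine 16/20 = 0.8.
    star
        Hub P0 joined to leaves P1, P2, P3; D1 on P1, D2 on P2. First-step
        analysis gives w(D1) = (3/2, 3/2, 1/2, 1/2) over (P0..P3), w(D2)
        its P1/P2 swap, cosine 4/5 = 0.8.
    two-components
        Two disjoint path2 copies (D1, D2 | D3, D4); cross-component
        correlations are exactly 0.
    """
    catalog = {}

    net = build_network([("P1", "P2")], {"D1": {"P1"}, "D2": {"P2"}})
    catalog["path2"] = {
        "network": net,
        "weights": {"D1": {"P1": 4 / 3, "P2": 2 / 3},
                    "D2": {"P1": 2 / 3, "P2": 4 / 3}},
        "correlations": {("D1", "D2"): 0.8},
    }

    net = build_network(
        [("P0", "P1"), ("P0", "P2"), ("P0", "P3")],
        {"D1": {"P1"}, "D2": {"P2"}},
    )
    catalog["star"] = {
        "network": net,
        "weights": {
            "D1": {"P0": 3 / 2, "P1": 3 / 2, "P2": 1 / 2, "P3": 1 / 2},
            "D2": {"P0": 3 / 2, "P1": 1 / 2, "P2": 3 / 2, "P3": 1 / 2},
        },
        "correlations": {("D1", "D2"): 0.8},
    }

    net = build_network(
        [("P1", "P2"), ("P3", "P4")],
        {"D1": {"P1"}, "D2": {"P2"}, "D3": {"P3"}, "D4": {"P4"}},
    )
    catalog["two-components"] = {
        "network": net,
        "weights": {
            "D1": {"P1": 4 / 3, "P2": 2 / 3},
            "D2": {"P1": 2 / 3, "P2": 4 / 3},
            "D3": {"P3": 4 / 3, "P4": 2 / 3},
            "D4": {"P3": 2 / 3, "P4": 4 / 3},
        },
        "correlations": {
            ("D1", "D2"): 0.8,
            ("D3", "D4"): 0.8,
            ("D1", "D3"): 0.0,
            ("D1", "D4"): 0.0,
            ("D2", "D3"): 0.0,
            ("D2", "D4"): 0.0,
        },
    }

    for entry in catalog.values():
        pruned, report = prune_unreachable(entry["network"])
        assert not report  # catalog networks are fully attached
        entry["network"] = pruned
    return catalog
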
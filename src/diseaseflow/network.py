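"""Heterogeneous disease-protein network: parsing, construction, pruning.

The network has two node kinds: proteins, joined by unweighted (weight 1.0)
undirected protein-protein interaction (PPI) edges, and diseases, each attached
to the proteins encoded by its associated genes via attachment edges of weight
``beta``. Proteins whose PPI component contains no disease-attached protein are
pruned so that a random walk started at any retained protein is absorbed with
probability 1.

Identifiers are opaque, case-sensitive strings; no namespace mapping between
gene and protein IDs is attempted. Input files are plain UTF-8 TSV with ``#``
comment lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ParameterError, ParseError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiseaseProteinNetwork:
    """Immutable disease-protein network.

    Attributes
    ----------
    proteins : tuple of str
        Protein IDs in lexicographic order; this ordering defines the index
        space of every vector and matrix downstream.
    diseases : tuple of str
        Disease IDs in lexicographic order.
    ppi_edges : tuple of (str, str)
        Unordered PPI pairs stored as sorted 2-tuples, each pair once, no
        self-loops; every edge has weight 1.0.
    associations : dict of str -> frozenset of str
        Disease ID -> nonempty set of attached protein IDs.
    beta : float
        Attachment-edge weight (> 0); default 1.0.
    """

    proteins: tuple
    diseases: tuple
    ppi_edges: tuple
    associations: dict
    beta: float = 1.0
    _pindex: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "_pindex", {p: i for i, p in enumerate(self.proteins)}
        )

    @property
    def n_proteins(self):
        return len(self.proteins)

    @property
    def n_diseases(self):
        return len(self.diseases)

    def protein_index(self, protein):
        return self._pindex[protein]

    def adjacency(self):
        """Symmetric sparse PPI adjacency over the protein ordering (CSR)."""
        n = self.n_proteins
        if not self.ppi_edges:
            return coo_matrix((n, n)).tocsr()
        rows, cols = [], []
        for a, b in self.ppi_edges:
            ia, ib = self._pindex[a], self._pindex[b]
            rows.extend((ia, ib))
            cols.extend((ib, ia))
        data = np.ones(len(rows))
        return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()

    def attachment_counts(self):
        """Number of disease attachments per protein, in protein order."""
        counts = np.zeros(self.n_proteins, dtype=np.int64)
        for genes in self.associations.values():
            for p in genes:
                counts[self._pindex[p]] += 1
        return counts


def _iter_tsv(path):
    """Yield (lineno, fields) for non-comment, non-blank lines of a TSV."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def load_ppi(path):
    """Read a 2+ column TSV of interacting protein pairs.

    Returns deduplicated unordered pairs (sorted 2-tuples, first-appearance
    order). Self-loops are dropped; duplicate and reversed-duplicate pairs are
    collapsed; counts of both are logged.
    """
    pairs = []
    seen = set()
    n_dups = n_loops = 0
    for lineno, fields in _iter_tsv(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, "expected >= 2 tab-separated fields")
        a, b = fields[0], fields[1]
        if a == b:
            n_loops += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in seen:
            n_dups += 1
            continue
        seen.add(key)
        pairs.append(key)
    if n_dups or n_loops:
        logger.info(
            "load_ppi(%s): dropped %d duplicate pair(s), %d self-loop(s)",
            path, n_dups, n_loops,
        )
    return pairs


def load_associations(path):
    """Read a 2+ column TSV of (disease ID, gene/protein ID) rows.

    Duplicate rows are collapsed; every distinct disease is preserved. Extra
    columns are ignored.
    """
    assoc = {}
    for lineno, fields in _iter_tsv(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, "expected >= 2 tab-separated fields")
        disease, protein = fields[0], fields[1]
        assoc.setdefault(disease, set()).add(protein)
    return assoc


def build_network(ppi, assoc, beta=1.0):
    """Assemble a :class:`DiseaseProteinNetwork` from edge and association lists.

    Associated proteins absent from the PPI node set are kept as isolated
    protein nodes: a disease pair sharing such a gene still obtains a nonzero
    correlation through the shared attachment, so pure gene sharing is a
    special case of the network similarity rather than being silently lost.

    Raises
    ------
    ParameterError
        If ``assoc`` is empty or ``beta <= 0``.
    """
    if beta <= 0:
        raise ParameterError(f"beta must be > 0, got {beta}")
    if not assoc:
        raise ParameterError("no diseases: association mapping is empty")

    pairs = []
    seen = set()
    for a, b in ppi:
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if key not in seen:
            seen.add(key)
            pairs.append(key)

    proteins = set()
    for a, b in pairs:
        proteins.add(a)
        proteins.add(b)
    associations = {}
    for disease, genes in assoc.items():
        genes = frozenset(genes)
        if not genes:
            raise ParameterError(f"disease {disease!r} has an empty gene set")
        proteins.update(genes)
        associations[disease] = genes

    return DiseaseProteinNetwork(
        proteins=tuple(sorted(proteins)),
        diseases=tuple(sorted(associations)),
        ppi_edges=tuple(sorted(pairs)),
        associations=associations,
        beta=float(beta),
    )


def prune_unreachable(net):
    """Remove proteins whose PPI component holds no disease-attached protein.

    After pruning, every retained protein can reach an absorbing (disease)
    attachment through PPI edges, so the random walk terminates with
    probability 1. Returns ``(pruned_network, report)`` where the report is a
    list of ``(protein_id, reason)`` rows for every removed protein.
    """
    n = net.n_proteins
    if n == 0:
        return net, []
    _, labels = connected_components(net.adjacency(), directed=False)
    attached = net.attachment_counts() > 0
    keep_component = np.zeros(labels.max() + 1, dtype=bool)
    for comp in labels[attached]:
        keep_component[comp] = True
    keep = keep_component[labels]
    if keep.all():
        return net, []

    kept = {p for p, k in zip(net.proteins, keep) if k}
    report = [(p, "unreachable") for p, k in zip(net.proteins, keep) if not k]
    pruned = DiseaseProteinNetwork(
        proteins=tuple(p for p in net.proteins if p in kept),
        diseases=net.diseases,
        ppi_edges=tuple(e for e in net.ppi_edges if e[0] in kept and e[1] in kept),
        associations=net.associations,
        beta=net.beta,
    )
    logger.info("prune_unreachable: removed %d protein(s)", len(report))
    return pruned, report
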
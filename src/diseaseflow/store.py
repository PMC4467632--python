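"""Deterministic on-disk artifacts for built models.

Everything is plain TSV/JSON with fixed float formatting ("%.17g" for values
that must round-trip exactly, so reloading a model reproduces the in-memory
arrays bit for bit). Artifacts are keyed by a sha256 content hash of the
input files plus build parameters; a rebuild with an unchanged hash is a
cache hit and leaves the artifacts untouched.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np

from .cluster import ClusterModel
from .errors import DiseaseFlowError
from .model import FlowModel
from .network import build_network, load_associations, load_ppi
from .synth import write_fixture_files

WEIGHT_FMT = "%.17g"
SCORE_FMT = "%.12g"


def content_hash(ppi_path, assoc_path, beta, K, gamma, tol, max_iter, seed):
    h = hashlib.sha256()
    for path in (ppi_path, assoc_path):
        with open(path, "rb") as fh:
            h.update(fh.read())
        h.update(b"\0")
    h.update(
        json.dumps(
            {"beta": beta, "K": K, "gamma": gamma, "tol": tol,
             "max_iter": max_iter, "seed": seed},
            sort_keys=True,
        ).encode()
    )
    return h.hexdigest()


def _write_sparse_tsv(path, header, rows):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def save_model(model, outdir, meta):
    os.makedirs(outdir, exist_ok=True)
    net = model.net

    write_fixture_files(
        net,
        os.path.join(outdir, "network_ppi.tsv"),
        os.path.join(outdir, "network_assoc.tsv"),
    )
    _write_sparse_tsv(
        os.path.join(outdir, "prune_report.tsv"),
        ("protein_id", "reason"),
        ((p, reason) for p, reason in model.prune_report),
    )
    _write_sparse_tsv(
        os.path.join(outdir, "weights.tsv"),
        ("disease_id", "protein_id", "weight"),
        (
            (d, net.proteins[j], WEIGHT_FMT % model.W[i, j])
            for i, d in enumerate(net.diseases)
            for j in np.flatnonzero(model.W[i])
        ),
    )
    if model.clusters is not None:
        cm = model.clusters
        _write_sparse_tsv(
            os.path.join(outdir, "cluster_vectors.tsv"),
            ("cluster_id", "protein_id", "weight"),
            (
                (cid, net.proteins[j], WEIGHT_FMT % cm.V[k, j])
                for k, cid in enumerate(cm.cluster_ids)
                for j in np.flatnonzero(cm.V[k])
            ),
        )
        _write_sparse_tsv(
            os.path.join(outdir, "memberships.tsv"),
            ("disease_id", "cluster_id", "probability"),
            (
                (d, cid, WEIGHT_FMT % cm.P[i, k])
                for i, d in enumerate(cm.diseases)
                for k, cid in enumerate(cm.cluster_ids)
            ),
        )
    with open(os.path.join(outdir, "meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_meta(outdir):
    path = os.path.join(outdir, "meta.json")
    if not os.path.exists(path):
        return None
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def load_model(outdir):
    """Reload a built model from its artifact directory."""
    meta = load_meta(outdir)
    if meta is None:
        raise DiseaseFlowError(f"no built model found in {outdir}")

    ppi = load_ppi(os.path.join(outdir, "network_ppi.tsv"))
    assoc = load_associations(os.path.join(outdir, "network_assoc.tsv"))
    net = build_network(ppi, assoc, beta=meta["beta"])
    model = FlowModel.from_network(net)

    # weight matrix from disk (bit-exact round trip via %.17g)
    pindex = {p: j for j, p in enumerate(net.proteins)}
    dindex = {d: i for i, d in enumerate(net.diseases)}
    W = np.zeros_like(model.W)
    with open(os.path.join(outdir, "weights.tsv"), encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            d, p, w = line.rstrip("\n").split("\t")
            W[dindex[d], pindex[p]] = float(w)
    model.W = W

    cv_path = os.path.join(outdir, "cluster_vectors.tsv")
    if os.path.exists(cv_path):
        cluster_ids = []
        entries = []
        with open(cv_path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                cid, p, w = line.rstrip("\n").split("\t")
                if cid not in cluster_ids:
                    cluster_ids.append(cid)
                entries.append((cid, p, float(w)))
        cindex = {c: k for k, c in enumerate(cluster_ids)}
        V = np.zeros((len(cluster_ids), net.n_proteins))
        for cid, p, w in entries:
            V[cindex[cid], pindex[p]] = w
        P = np.zeros((net.n_diseases, len(cluster_ids)))
        with open(os.path.join(outdir, "memberships.tsv"), encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                d, cid, prob = line.rstrip("\n").split("\t")
                P[dindex[d], cindex[cid]] = float(prob)
        model.clusters = ClusterModel(
            diseases=net.diseases,
            cluster_ids=tuple(cluster_ids),
            V=V,
            P=P,
            gamma=meta.get("gamma", 1.0),
            converged=meta.get("converged", True),
            n_iter=meta.get("n_iter", 0),
        )
    return model
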
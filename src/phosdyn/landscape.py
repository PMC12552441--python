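"""Shapemer embedding and clustering of conformational landscapes.

Structures are fragmented into overlapping sequence k-mers (k = 20) and
residue-centred spheres (radius 15 Å); each fragment is summarised by four
translation- and rotation-invariant geometric moments, discretised (signed
log1p rescaling, rounding at a resolution of 2) into a shapemer key, and
counted per structure.  PCA reduces the count matrix; density clustering on
the first two components (with a noise label) — or, as a robustness check,
hierarchical clustering with cosine distance and average linkage at the
silhouette-maximising cut — defines conformational clusters.  The
cluster-share summary asks whether phosphorylated structures sit in
clusters that also contain non-phosphorylated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .structures import StructureRecord

SHAPEMER_K = 20
SHAPEMER_RADIUS = 15.0
SHAPEMER_RESOLUTION = 2.0
MIN_STRUCTURES = 10
MIN_PHOSPHO = 4
NOISE = -1


def fragment_moment_invariants(fragment: np.ndarray) -> np.ndarray:
    """Four rotation/translation-invariant moments of a coordinate fragment.

    After centering: the second-moment trace and three higher-order radial /
    cross moments.  Invariant under rigid motion, deliberately sensitive to
    scale.
    """
    x = np.asarray(fragment, float)
    if x.ndim != 2 or len(x) == 0:
        raise ValueError("empty fragment")
    x = x - x.mean(axis=0)
    r2 = (x ** 2).sum(axis=1)
    n = len(x)
    i1 = r2.mean()                            # second-moment trace
    i2 = (r2 ** 1.5).mean()                   # third radial moment
    i3 = (r2 ** 2).mean()                     # fourth radial moment
    g = x @ x.T
    i4 = (g ** 3).mean()                      # third-order cross moment
    return np.array([i1, i2, i3, i4])


def _shapemer_key(inv: np.ndarray, resolution: float) -> Tuple[int, ...]:
    scaled = np.sign(inv) * np.log1p(np.abs(inv))
    return tuple(int(v) for v in np.round(scaled * resolution))


@dataclass
class ShapemerEmbedding:
    structure_ids: List[str]
    vocabulary: List[tuple]
    counts: np.ndarray       # (n_structures, n_shapemers), int

    def row(self, structure_id: str) -> np.ndarray:
        return self.counts[self.structure_ids.index(structure_id)]


def embed_shapemers(structures: Sequence[StructureRecord],
                    k: int = SHAPEMER_K,
                    radius: float = SHAPEMER_RADIUS,
                    resolution: float = SHAPEMER_RESOLUTION
                    ) -> ShapemerEmbedding:
    """Count shapemers (k-mer and sphere fragments) per structure."""
    per_structure: List[Dict[tuple, int]] = []
    vocab: Dict[tuple, int] = {}
    for rec in structures:
        cas = np.array([r.atoms["CA"] for r in rec.residues
                        if "CA" in r.atoms])
        counts: Dict[tuple, int] = {}

        def add(fragment, tag):
            key = (tag,) + _shapemer_key(
                fragment_moment_invariants(fragment), resolution)
            counts[key] = counts.get(key, 0) + 1
            vocab.setdefault(key, len(vocab))

        n = len(cas)
        if n >= k:
            for i in range(n - k + 1):
                add(cas[i:i + k], "k")
        d = np.linalg.norm(cas[:, None] - cas[None], axis=-1)
        for i in range(n):
            add(cas[d[i] <= radius], "s")
        per_structure.append(counts)

    keys = sorted(vocab, key=vocab.get)
    mat = np.zeros((len(structures), len(keys)), dtype=int)
    index = {key: c for c, key in enumerate(keys)}
    for row, counts in enumerate(per_structure):
        for key, v in counts.items():
            mat[row, index[key]] = v
    return ShapemerEmbedding([s.structure_id for s in structures], keys, mat)


def pca_reduce(embedding: ShapemerEmbedding, n_components: int = 2
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Centered PCA of the count matrix; sign-fixed deterministic components.

    Returns (coordinates, explained variance).  The sign of each component
    is fixed so its largest-magnitude loading is positive.
    """
    from sklearn.decomposition import PCA
    X = embedding.counts.astype(float)
    if len(X) < 2:
        raise ValueError("need >= 2 structures")
    n_components = min(n_components, len(X) - 1, X.shape[1])
    if np.allclose(X, X[0]):
        return np.zeros((len(X), n_components)), np.zeros(n_components)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for c in range(coords.shape[1]):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, c] *= -1
    return coords, pca.explained_variance_


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    method: str                       # "density2d" | "hierarchical_cosine"
    n_clusters: int
    quality: Optional[float] = None   # silhouette for hierarchical
    meta: dict = field(default_factory=dict)


def cluster_landscape(data: np.ndarray, method: str = "density2d",
                      min_cluster_size: int = 2,
                      min_samples: int = 5) -> ClusterAssignment:
    """Cluster structures in the landscape.

    ``density2d``: HDBSCAN on 2D PCA coordinates (Euclidean), noise label −1.
    ``hierarchical_cosine``: average-linkage hierarchical clustering of the
    full count matrix with cosine distance, cut at the silhouette-maximising
    number of clusters in 2..min(10, n−1).
    """
    X = np.asarray(data, float)
    n = len(X)
    if n < 3:
        return ClusterAssignment(np.zeros(n, dtype=int), method, 1,
                                 meta={"flag": "too few structures"})
    if method == "density2d":
        from sklearn.cluster import HDBSCAN
        ms = min(min_samples, n - 1)
        h = HDBSCAN(min_cluster_size=min_cluster_size, min_samples=ms,
                    copy=True).fit(X)
        labels = h.labels_
        n_clusters = len(set(labels) - {NOISE})
        return ClusterAssignment(labels, method, n_clusters,
                                 meta={"min_cluster_size": min_cluster_size,
                                       "min_samples": ms,
                                       "implementation": "sklearn-HDBSCAN"})
    if method == "hierarchical_cosine":
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist
        from sklearn.metrics import silhouette_score
        if np.allclose(X, X[0]):
            return ClusterAssignment(np.zeros(n, dtype=int), method, 1,
                                     quality=None, meta={"flag": "constant"})
        d = pdist(X, metric="cosine")
        d = np.clip(d, 0.0, None)
        Z = linkage(d, method="average")
        best = None
        from scipy.spatial.distance import squareform
        dm = squareform(d)
        for kk in range(2, min(10, n - 1) + 1):
            labels = fcluster(Z, kk, criterion="maxclust") - 1
            if len(set(labels)) < 2:
                continue
            score = silhouette_score(dm, labels, metric="precomputed")
            if best is None or score > best[0]:
                best = (score, labels, kk)
        if best is None:
            return ClusterAssignment(np.zeros(n, dtype=int), method, 1)
        score, labels, kk = best
        return ClusterAssignment(labels, method, kk, quality=float(score))
    raise ValueError(f"unknown method {method!r}")


def phospho_cluster_share(assignment: ClusterAssignment,
                          phospho_flags: Sequence[bool]
                          ) -> Dict[str, float]:
    """Fractions of phosphorylated structures sharing clusters with
    non-phosphorylated ones, in pure-phospho clusters, or unclustered."""
    flags = np.asarray(phospho_flags, bool)
    if len(flags) != len(assignment.labels):
        raise ValueError("flags must cover all structures")
    if not flags.any():
        raise ValueError("no phosphorylated structures")
    labels = assignment.labels
    shared = phospho_only = noise = 0
    for i in np.where(flags)[0]:
        if labels[i] == NOISE:
            noise += 1
        elif np.any(~flags[labels == labels[i]]):
            shared += 1
        else:
            phospho_only += 1
    total = flags.sum()
    return {"fraction_shared": shared / total,
            "fraction_phospho_only": phospho_only / total,
            "fraction_noise": noise / total}


def extract_domain(record: StructureRecord, start: int, end: int,
                   max_ca_only: float = 0.10) -> Optional[StructureRecord]:
    """Slice a domain by author residue numbers [start, end].

    Returns None when more than 10% of the domain's residues are Cα-only
    (insufficiently modelled for shapemer fragments).
    """
    models = []
    for model in record.models:
        models.append([r for r in model if start <= r.author_index <= end])
    if not models[0]:
        return None
    ca_only = sum(1 for r in models[0] if set(r.atoms) == {"CA"})
    if ca_only / len(models[0]) > max_ca_only:
        return None
    return StructureRecord(f"{record.structure_id}_dom{start}-{end}",
                           record.uniprot_id, models, record.method,
                           record.resolution, record.r_free,
                           record.last_author)


def embedding_gate(n_total: int, n_phospho: int,
                   min_structures: int = MIN_STRUCTURES,
                   min_phospho: int = MIN_PHOSPHO) -> bool:
    """Minimum-ensemble gate: ≥10 structures of which ≥4 phosphorylated."""
    return n_total >= min_structures and n_phospho >= min_phospho
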
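"""UMAP embedding and radius-graph clustering of SNP association maps.

SNPs whose association with a phenotype is significant at more than a
coverage threshold (default 1%) of cortical locations are embedded in 2D
with UMAP (15 neighbors, 2 components, min_dist 0.1, Euclidean) applied to
their raw (unstandardized) beta maps.  Clusters are the connected
components of the graph joining embedded points within a Euclidean radius.
The radius defaults to a reproducible percentile (10th) of the pairwise
embedding distances, replacing the visual-inspection choice with a rule a
user can override.  Stability is assessed by repeating the embedding over
consecutive seeds and averaging the pairwise Adjusted Rand Index between
the resulting partitions.

UMAP itself is an external dependency treated as a deterministic-given-seed
black box; its parameters are pinned in :class:`UMAPParams` and recorded in
every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.special import comb

from .association import AssociationTensor
from .types import ValidationError


@dataclass
class UMAPParams:
    n_neighbors: int = 15
    n_components: int = 2
    min_dist: float = 0.1
    metric: str = "euclidean"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EmbeddingRun:
    seed: int
    coordinates: np.ndarray      # (n_snps, n_components)
    params: UMAPParams


@dataclass
class ClusterReport:
    radius: float | str
    labels: np.ndarray                      # per selected SNP
    snp_ids: np.ndarray
    runs: list = field(default_factory=list)
    ari_matrix: np.ndarray | None = None
    mean_ari: float | None = None
    cluster_maps: dict | None = None


def select_snps(tensor: AssociationTensor, min_coverage: float = 0.01):
    """SNPs with significant association at strictly more than
    ``min_coverage`` (fraction) of locations, plus their raw beta maps."""
    frac = tensor.significant.sum(axis=1) / tensor.n_locations
    keep = frac > min_coverage
    if not keep.any():
        raise ValidationError(
            f"no SNP exceeds coverage {min_coverage:.3%}; lower --min-coverage"
        )
    return tensor.snp_ids[keep], tensor.beta[keep]


def embed(features: np.ndarray, params: UMAPParams | None = None,
          seed: int = 0) -> EmbeddingRun:
    """Seeded 2D UMAP embedding of the feature rows."""
    import umap  # deferred: numba compilation is slow at import

    if params is None:
        params = UMAPParams()
    features = np.asarray(features, dtype=np.float64)
    if len(features) < params.n_neighbors + 1:
        raise ValidationError(
            f"need at least n_neighbors+1={params.n_neighbors + 1} points, "
            f"got {len(features)}"
        )
    reducer = umap.UMAP(
        n_neighbors=params.n_neighbors,
        n_components=params.n_components,
        min_dist=params.min_dist,
        metric=params.metric,
        random_state=int(seed),
    )
    import warnings

    with warnings.catch_warnings():
        # seeded runs are single-threaded by design; silence the n_jobs note
        warnings.filterwarnings("ignore", message=".*n_jobs value.*random_state.*")
        coords = reducer.fit_transform(features)
    return EmbeddingRun(seed=int(seed), coordinates=np.asarray(coords, dtype=np.float64),
                        params=params)


def radius_cluster(run: EmbeddingRun | np.ndarray, radius: float) -> np.ndarray:
    """Connected components of the <=radius neighbor graph.

    Labels are canonicalized by order of first appearance, so they are
    invariant to point relabeling of the underlying graph structure.
    """
    coords = run.coordinates if isinstance(run, EmbeddingRun) else np.asarray(run)
    if radius <= 0:
        raise ValidationError("radius must be positive")
    n = len(coords)
    from scipy.spatial import cKDTree

    pairs = cKDTree(coords).query_pairs(r=radius, output_type="ndarray")
    data = np.ones(len(pairs), dtype=np.int8)
    adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return _canonical_labels(labels)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def default_radius(run: EmbeddingRun | np.ndarray, percentile: float = 10.0) -> float:
    """Percentile of the pairwise embedding-distance distribution."""
    coords = run.coordinates if isinstance(run, EmbeddingRun) else np.asarray(run)
    if len(coords) < 2:
        raise ValidationError("need at least 2 points")
    return float(np.percentile(pdist(coords), percentile))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions, in [-1, 1].

    Computed from the contingency table by pair counting.  When both
    partitions are trivial (the expected and maximal pair-agreement indices
    coincide, a 0/0 case) the value is defined as 1 if the partitions are
    identical up to relabeling.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("label vectors must be 1D and of equal length")
    if len(a) < 2:
        raise ValidationError("need at least 2 elements")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)
    sum_comb = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    total = comb(len(a), 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both partitions trivial (all-singletons or single-cluster)
        return 1.0 if np.array_equal(_canonical_labels(ai), _canonical_labels(bi)) else 0.0
    return float((sum_comb - expected) / (max_index - expected))


def stability(features: np.ndarray, params: UMAPParams | None = None,
              n_runs: int = 50, seed0: int = 0,
              radius: float | None = None,
              radius_percentile: float = 10.0) -> ClusterReport:
    """Cluster over ``n_runs`` embeddings with seeds seed0..seed0+n_runs-1.

    The radius is recomputed per run from the percentile rule unless a
    fixed value is given.  Mean ARI averages the off-diagonal entries of
    the pairwise ARI matrix.
    """
    if n_runs < 2:
        raise ValidationError("need n_runs >= 2")
    if params is None:
        params = UMAPParams()
    runs = []
    labelings = []
    for k in range(n_runs):
        run = embed(features, params, seed=seed0 + k)
        r = radius if radius is not None else default_radius(run, radius_percentile)
        labelings.append(radius_cluster(run, r))
        runs.append(run)
    ari = np.ones((n_runs, n_runs))
    for i in range(n_runs):
        for j in range(i + 1, n_runs):
            ari[i, j] = ari[j, i] = adjusted_rand_index(labelings[i], labelings[j])
    off = ari[~np.eye(n_runs, dtype=bool)]
    report = ClusterReport(
        radius=radius if radius is not None else f"p{radius_percentile:g}",
        labels=labelings[0],
        snp_ids=np.array([]),
        runs=runs,
        ari_matrix=ari,
        mean_ari=float(off.mean()),
    )
    return report


def cluster_maps(labels: np.ndarray, snp_ids: np.ndarray, zmap, tensor) -> dict:
    """Per-cluster averaged standardized maps (mean raw beta, then z-scored)."""
    from .gene_ranking import average_map

    out = {}
    for lab in np.unique(labels):
        members = [str(s) for s in np.asarray(snp_ids)[labels == lab]]
        out[int(lab)] = average_map(zmap, members, tensor)
    return out
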
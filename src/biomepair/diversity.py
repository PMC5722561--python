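"""Community diversity, dissimilarity, ordination and clustering.

Alpha diversity is summarized per sample by the Shannon index
H = -sum(p_i * log(p_i)) (natural log by default) and by richness, the bare
count of taxa present.  Beta diversity is summarized by Bray-Curtis
dissimilarity on abundances and by unweighted UniFrac (presence/absence on a
rooted phylogeny), followed by classical principal-coordinates analysis and
UPGMA dendrograms.

No rarefaction is applied before diversity: with strongly unequal tumor /
non-tumor depths, richness in particular is depth-sensitive — see the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .core import AbundanceTable, DistanceMatrix, ValidationError

_LOG_BASE = {"e": 1.0, "2": np.log(2.0), "10": np.log(10.0)}


def shannon_index(proportions: Sequence[float], base: str = "e") -> float:
    """Shannon diversity of a proportion vector (zero entries contribute 0)."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValidationError("negative proportions")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError(f"proportions sum to {p.sum():.6g}, not 1")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return h / _LOG_BASE[base]


def richness(counts: Sequence[float]) -> int:
    """Number of strictly positive entries (abundance-free)."""
    return int(np.sum(np.asarray(counts, dtype=float) > 0))


@dataclass
class DiversityResult:
    sample_ids: list[str]
    shannon: np.ndarray  # nats unless base overridden
    richness: np.ndarray
    rank: str


def sample_diversity(table: AbundanceTable, base: str = "e") -> DiversityResult:
    """Per-sample Shannon index and richness of an abundance table."""
    totals = table.counts.sum(axis=0)
    zero = [s for s, t in zip(table.samples, totals) if t <= 0]
    if zero:
        raise ValidationError(f"zero-total samples: {zero}")
    props = table.counts / totals
    h = np.array([shannon_index(props[:, j], base=base) for j in range(table.n_samples)])
    s = np.array([richness(table.counts[:, j]) for j in range(table.n_samples)])
    return DiversityResult(
        sample_ids=list(table.samples), shannon=h, richness=s, rank=table.rank
    )


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    BC(a, b) = 1 - 2 * sum_i min(a_i, b_i) / (sum_i a_i + sum_i b_i),
    bounded in [0, 1].
    """
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    totals = table.counts.sum(axis=0)
    zero = [s for s, t in zip(table.samples, totals) if t <= 0]
    if zero:
        raise ValidationError(f"zero-total samples: {zero}")
    d = squareform(pdist(table.counts.T, metric="braycurtis"))
    return DistanceMatrix(sample_ids=list(table.samples), d=d)


def unweighted_unifrac(table: AbundanceTable, tree) -> DistanceMatrix:
    """Unweighted UniFrac between all sample pairs.

    Presence/absence only: the distance between two samples is the branch
    length observed in exactly one of them divided by the branch length
    observed in either, on the supplied rooted ``skbio.TreeNode``.  Every
    table taxon must be a tree leaf.
    """
    from skbio.diversity import beta_diversity

    leaves = {leaf.name for leaf in tree.tips()}
    taxa = [t.taxon_id for t in table.taxa]
    missing = sorted(set(taxa) - leaves)
    if missing:
        raise ValidationError(f"taxa missing from tree: {missing}")
    dm = beta_diversity(
        "unweighted_unifrac",
        table.counts.T.astype(int) if not table.is_relative else (table.counts.T > 0).astype(int),
        ids=list(table.samples),
        taxa=taxa,
        tree=tree,
        validate=True,
    )
    return DistanceMatrix(sample_ids=list(dm.ids), d=np.asarray(dm.data, dtype=float))


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # n_samples x k
    eigenvalues: np.ndarray  # all n eigenvalues, non-increasing (negatives kept)
    proportion_explained: np.ndarray  # per retained axis

    def axis(self, i: int) -> np.ndarray:
        return self.coordinates[:, i]


def pcoa(
    dm: DistanceMatrix, k: int = 2, *, negative_in_denominator: bool = False
) -> OrdinationResult:
    """Classical-scaling principal coordinates analysis.

    Double-centers -D^2/2 and eigendecomposes.  All eigenvalues are reported,
    including negatives from non-Euclidean input; by default the
    variance-explained denominator sums only the positive ones.
    """
    n = len(dm.sample_ids)
    if not 1 <= k <= n - 1:
        raise ValidationError(f"k={k} must be in [1, {n - 1}]")
    d2 = dm.d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lam = np.clip(eigval[:k], 0.0, None)
    coords = eigvec[:, :k] * np.sqrt(lam)
    denom = eigval.sum() if negative_in_denominator else eigval[eigval > 0].sum()
    prop = eigval[:k] / denom if denom > 0 else np.zeros(k)
    return OrdinationResult(
        sample_ids=list(dm.sample_ids),
        coordinates=coords,
        eigenvalues=eigval,
        proportion_explained=prop,
    )


def upgma_dendrogram(dm: DistanceMatrix, *, method: str = "average") -> tuple[str, np.ndarray]:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    Returns ``(newick, linkage)`` where the newick carries ultrametric node
    heights (merge height = linkage distance / 2, so two samples at distance
    0.4 merge at height 0.2).  Samples are pre-sorted lexicographically so
    tied merges resolve deterministically.  ``method='complete'`` is
    available as an alternative.
    """
    if len(dm.sample_ids) < 2:
        raise ValidationError("need at least 2 samples")
    order = np.argsort(np.asarray(dm.sample_ids, dtype=object))
    ids = [dm.sample_ids[i] for i in order]
    d = dm.d[np.ix_(order, order)]
    z = hierarchy.linkage(squareform(d, checks=False), method=method)
    n = len(ids)
    # height of each node above the leaves (ultrametric: linkage dist / 2)
    heights = np.zeros(2 * n - 1)
    newicks = {i: ids[i] for i in range(n)}
    for step, (a, b, dist, _) in enumerate(z):
        a, b = int(a), int(b)
        node = n + step
        h = dist / 2.0
        heights[node] = h
        la = h - heights[a]
        lb = h - heights[b]
        newicks[node] = f"({newicks[a]}:{la:.10g},{newicks[b]}:{lb:.10g})"
    return f"{newicks[2 * n - 2]};", z
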
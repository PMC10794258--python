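"""Pairwise kinship, IBS distance, classical MDS and relatedness clustering.

Kinship uses the Manichaikul (KING-robust) within-pair estimator computed
from genotype-category counts over pairwise-complete loci:

    phi_ij = (N_AaAa - 2 * N_AAaa) / (N_Aa(i) + N_Aa(j))

where N_AaAa counts loci at which both samples are heterozygous, N_AAaa
counts opposing homozygotes, and N_Aa(i) counts heterozygous loci of sample
i among the loci also called in j.  The estimator needs no allele
frequencies; its expectation is the pedigree kinship coefficient (0.5 self,
0.25 full sibs or parent-offspring, 0.125 half sibs, 0 unrelated within one
population).

IBS distance between two genotype vectors is the mean over pairwise-complete
loci of 1 - (shared alleles)/2, i.e. ``mean(|g_i - g_j|) / 2``.  Classical
(Torgerson) MDS embeds that distance matrix by eigendecomposition of the
double-centred squared-distance matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genotype_io import MISSING, GenotypeMatrix, SampleMetadata, samples_by_nest

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """Pairwise Manichaikul kinship and the category counts behind it.

    ``phi`` is NaN for pairs with an undefined estimate (no pairwise-complete
    loci, or no heterozygote in either sample).
    """

    sample_ids: list[str]
    phi: np.ndarray
    n_both_het: np.ndarray
    n_opposing_hom: np.ndarray
    n_het_in_pair: np.ndarray  # [i, j] = het loci of i among loci called in both
    n_complete: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    distances: np.ndarray
    n_complete: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.distances, index=self.sample_ids, columns=self.sample_ids
        )


@dataclass
class MDSResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    explained: np.ndarray  # positive-eigenvalue variance share per kept axis
    negative_variance_share: float = 0.0
    chosen_samples: list[str] | None = None


@dataclass
class ClusterTree:
    sample_ids: list[str]
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str
    linkage_method: str = "average"


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def manichaikul_kinship(matrix: GenotypeMatrix) -> KinshipMatrix:
    """Manichaikul within-pair kinship over pairwise-complete loci.

    Category counts are accumulated with 0/1 indicator matrix products, so
    the cost is a handful of (n x L)(L x n) multiplications.
    """
    g = matrix.genotypes
    called = (g != MISSING).astype(np.float64)
    het = (g == 1).astype(np.float64)
    hom_ref = (g == 0).astype(np.float64)
    hom_alt = (g == 2).astype(np.float64)

    n_both_het = het @ het.T
    n_opposing = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    n_het_in_pair = het @ called.T  # [i, j]: i het & j called
    n_complete = called @ called.T

    denom = n_het_in_pair + n_het_in_pair.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_both_het - 2.0 * n_opposing) / denom, np.nan)
    if np.isnan(phi[np.triu_indices_from(phi)]).any():
        logger.warning(
            "some sample pairs have undefined kinship "
            "(no pairwise-complete heterozygous loci)"
        )
    return KinshipMatrix(
        sample_ids=list(matrix.sample_ids),
        phi=phi,
        n_both_het=n_both_het.astype(np.int64),
        n_opposing_hom=n_opposing.astype(np.int64),
        n_het_in_pair=n_het_in_pair.astype(np.int64),
        n_complete=n_complete.astype(np.int64),
    )


def nest_relatedness_summary(
    kinship: KinshipMatrix, samples: list[SampleMetadata]
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-nest mean within-nest kinship, plus the full pair table.

    The per-nest mean is over unordered within-nest pairs, excluding the
    self diagonal; single-sample nests get NaN.  The pair table lists every
    unordered sample pair with its nest labels and phi, for heatmaps and
    cross-nest comparisons.
    """
    grouped = samples_by_nest(samples)
    nest_of = {s.sample_id: s.nest_id for s in samples}
    ids = kinship.sample_ids
    idx = {s: i for i, s in enumerate(ids)}

    means = {}
    for nest_id, members in grouped.items():
        pairs = [
            kinship.phi[idx[a], idx[b]]
            for k, a in enumerate(members)
            for b in members[k + 1:]
        ]
        pairs = [p for p in pairs if not np.isnan(p)]
        means[nest_id] = float(np.mean(pairs)) if pairs else np.nan

    rows = []
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            rows.append(
                {
                    "sample_i": a,
                    "sample_j": b,
                    "nest_i": nest_of.get(a),
                    "nest_j": nest_of.get(b),
                    "phi": kinship.phi[i, j],
                    "within_nest": nest_of.get(a) == nest_of.get(b),
                }
            )
    return pd.Series(means, name="mean_phi"), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IBS distance
# ---------------------------------------------------------------------------

def ibs_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """1 - mean fraction of alleles shared, over pairwise-complete loci."""
    g = matrix.genotypes
    called = (g != MISSING).astype(np.float64)

    # sum over complete loci of |g_i - g_j| via one-hot channels:
    # |a-b| = sum_{x,y} |x-y| 1[g_i=x] 1[g_j=y]
    channels = [(g == k).astype(np.float64) for k in (0, 1, 2)]
    abs_sum = np.zeros((matrix.n_samples, matrix.n_samples))
    for x in range(3):
        for y in range(3):
            if x == y:
                continue
            abs_sum += abs(x - y) * (channels[x] @ channels[y].T)
    n_complete = called @ called.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(n_complete > 0, abs_sum / (2.0 * n_complete), np.nan)
    np.fill_diagonal(dist, 0.0)
    if np.isnan(dist).any():
        logger.warning("some sample pairs share no complete loci (distance absent)")
    return DistanceMatrix(list(matrix.sample_ids), dist, n_complete.astype(np.int64))


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------

def classical_mds(distance: DistanceMatrix, k: int = 3) -> MDSResult:
    """Torgerson scaling of a distance matrix.

    Double-centre ``-0.5 * D**2``, eigendecompose, and scale the top-``k``
    positive-eigenvalue eigenvectors by the square root of their
    eigenvalues.  Negative eigenvalues (non-Euclidean distances) are
    discarded and their absolute variance share reported.  Axis signs are
    fixed so the largest-magnitude loading on each axis is positive.
    """
    d = np.asarray(distance.distances, dtype=np.float64)
    if np.isnan(d).any():
        raise ValueError("distance matrix has absent entries; MDS needs all pairs")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(abs(eigval[0]), 1.0) * 1e-12
    positive = eigval > tol
    n_pos = int(positive.sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {k_eff} axes",
            stacklevel=2,
        )
    coords = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])
    for axis in range(k_eff):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col

    pos_sum = eigval[positive].sum()
    explained = eigval[:k_eff] / pos_sum if pos_sum > 0 else np.zeros(k_eff)
    neg_share = float(-eigval[eigval < -tol].sum() / pos_sum) if pos_sum > 0 else 0.0
    return MDSResult(
        sample_ids=list(distance.sample_ids),
        coordinates=coords,
        eigenvalues=eigval,
        explained=explained,
        negative_variance_share=neg_share,
    )


def one_per_nest_mds(
    matrix: GenotypeMatrix,
    samples: list[SampleMetadata],
    seed: int,
    k: int = 3,
) -> MDSResult:
    """MDS on one randomly chosen hatchling per nest.

    Collapsing each nest to a single representative avoids the artificial
    clustering that uneven family sizes induce in an all-sample MDS.  The
    chosen sample ids are recorded in the result.
    """
    rng = np.random.default_rng(seed)
    grouped = samples_by_nest(samples)
    chosen = [
        members[rng.integers(len(members))] for members in grouped.values()
    ]
    subset = matrix.subset_samples(chosen)
    result = classical_mds(ibs_distance(subset), k=k)
    result.chosen_samples = chosen
    return result


# ---------------------------------------------------------------------------
# Relatedness dendrogram
# ---------------------------------------------------------------------------

def _linkage_to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _linkage_to_newick(node.left, labels)
    right = _linkage_to_newick(node.right, labels)
    dl = node.dist - node.left.dist
    dr = node.dist - node.right.dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def relatedness_dendrogram(kinship: KinshipMatrix) -> ClusterTree:
    """Average-linkage (UPGMA) clustering on ``max(phi) - phi``.

    The dissimilarity is the kinship range-reversal with a zero diagonal;
    UPGMA makes the merge heights ultrametric.  Leaf order is exported for
    heatmap row ordering and the tree as a Newick string.
    """
    phi = kinship.phi.copy()
    if np.isnan(phi).any():
        raise ValueError("kinship matrix has absent entries; cannot cluster")
    dissim = np.nanmax(phi) - phi
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip(dissim, 0.0, None)
    if len(kinship.sample_ids) == 1:
        return ClusterTree(
            kinship.sample_ids, np.empty((0, 4)), list(kinship.sample_ids),
            kinship.sample_ids[0] + ";",
        )
    z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    leaf_order = [kinship.sample_ids[i] for i in hierarchy.leaves_list(z)]
    root = hierarchy.to_tree(z)
    newick = _linkage_to_newick(root, kinship.sample_ids) + ";"
    return ClusterTree(list(kinship.sample_ids), z, leaf_order, newick)
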
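"""Community dissimilarity matrices and principal coordinates analysis.

Jaccard works on presence/absence; unweighted/weighted UniFrac additionally
use an OTU phylogeny (weighted UniFrac defaults to the raw, unnormalized
form). Distances are returned as :class:`skbio.DistanceMatrix`, which also
provides the labeled square TSV (lsmat) serialization used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .otu import OtuTable

logger = logging.getLogger(__name__)


def jaccard_matrix(table: OtuTable) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity, 1 - |intersection| / |union| of
    presence sets. A pair of empty samples gets distance 0 with a warning."""
    pres = table.presence().to_numpy()
    empty = ~pres.any(axis=1)
    if empty.any():
        logger.warning(
            "samples with no OTUs present: %s; Jaccard to other empty "
            "samples defined as 0",
            list(np.asarray(table.sample_ids)[empty]),
        )
    d = squareform(pdist(pres, metric="jaccard"))
    d = np.nan_to_num(d, nan=0.0)  # empty-vs-empty pairs
    return DistanceMatrix(d, ids=table.sample_ids)


def _check_tree(table: OtuTable, tree: TreeNode) -> TreeNode:
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(table.otu_ids) - tips)
    if missing:
        raise ValueError(
            f"{len(missing)} table OTUs missing from tree "
            f"(e.g. {missing[:5]})"
        )
    extra = tips - set(table.otu_ids)
    if extra:
        tree = tree.shear(set(table.otu_ids))
    return tree


def unweighted_unifrac(table: OtuTable, otu_tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: the fraction of branch length leading only to
    taxa present in exactly one of the two samples."""
    tree = _check_tree(table, otu_tree)
    return beta_diversity(
        "unweighted_unifrac",
        table.counts.to_numpy(),
        ids=table.sample_ids,
        tree=tree,
        taxa=table.otu_ids,
    )


def weighted_unifrac(
    table: OtuTable, otu_tree: TreeNode, normalized: bool = False
) -> DistanceMatrix:
    """Weighted UniFrac, sum_b l_b |p_A(b) - p_B(b)|; raw (unnormalized)
    by default, with the standard normalization behind ``normalized``."""
    tree = _check_tree(table, otu_tree)
    return beta_diversity(
        "weighted_unifrac",
        table.counts.to_numpy(),
        ids=table.sample_ids,
        tree=tree,
        taxa=table.otu_ids,
        normalized=normalized,
    )


@dataclass
class PcoaResult:
    """Classical-scaling ordination.

    ``coordinates`` keeps only positive-eigenvalue axes; ``eigenvalues``
    retains the full spectrum (negatives included, descending) and
    ``proportion_explained`` is relative to the positive inertia.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Principal coordinates (classical MDS) of a distance matrix.

    The doubly centered ``-d^2/2`` matrix is eigendecomposed; coordinates
    use positive axes only, ordered by eigenvalue descending, with signs
    canonicalized so each axis's first nonzero loading is positive.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    b = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ b @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals).max(), 1.0) * 1e-12
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):  # deterministic sign convention
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > tol)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    pos_sum = evals[pos].sum()
    prop = evals[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
    )
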
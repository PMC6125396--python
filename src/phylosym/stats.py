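"""Permutation tests on distance matrices and one-way ANOVA.

Mantel correlates the upper triangles of two aligned distance matrices
(Pearson by default) and permutes the rows/columns of one of them jointly;
ANOSIM contrasts the mean rank of between-group vs within-group distances.
Both report the plain permutation proportion k/N by default (the add-one
(k+1)/(N+1) variant is behind a flag), and both are bit-reproducible given
(seed, n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from skbio import DistanceMatrix


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: object
    tail: str
    method: str
    add_one: bool = False

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "tail": self.tail,
            "p_convention": "(k+1)/(N+1)" if self.add_one else "k/N",
        }


@dataclass
class AnovaResult:
    statistic: float
    p_value: float
    df_between: int
    df_within: int

    def to_dict(self) -> dict:
        return {
            "method": "one_way_anova",
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": [self.df_between, self.df_within],
        }


def _aligned(dm1: DistanceMatrix, dm2: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    if set(dm1.ids) != set(dm2.ids):
        raise ValueError(
            "distance matrices have different labels: "
            f"{sorted(set(dm1.ids) ^ set(dm2.ids))}"
        )
    d2 = dm2.filter(dm1.ids)  # align order to dm1
    return np.asarray(dm1.data, float), np.asarray(d2.data, float)


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 9999,
    seed=None,
    method: str = "pearson",
    add_one: bool = False,
) -> PermutationTestResult:
    """Mantel test of matrix association.

    The statistic is the Pearson (or, with ``method='spearman'``, Spearman)
    correlation over upper-triangle entries; the null is built by jointly
    permuting rows and columns of the second matrix; the p-value is
    one-sided for positive association.
    """
    x, y = _aligned(dm1, dm2)
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    xv = x[iu]
    if method == "spearman":
        xv = sps.rankdata(xv)

    def corr_with(mat: np.ndarray) -> float:
        yv = mat[iu]
        if method == "spearman":
            yv = sps.rankdata(yv)
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            raise ValueError("zero variance in distance-matrix upper triangle")
        return float(np.corrcoef(xv, yv)[0, 1])

    r_obs = corr_with(y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(y[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1) if add_one else hits / n_perm
    return PermutationTestResult(
        statistic=r_obs,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        tail="one_sided_greater",
        method=f"mantel_{method}",
        add_one=add_one,
    )


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = len(ranks)  # n(n-1)/2 pairs
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return float((r_b - r_w) / (m / 2.0))


def anosim(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed=None,
    add_one: bool = False,
) -> PermutationTestResult:
    """Analysis of Similarity (Clarke's R) with a label-permutation null.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise distances ranked with average ranks for ties;
    R is in [-1, 1] and the p-value is one-sided for R >= observed.
    ``groups`` maps each matrix label to its group.
    """
    labels = list(dm.ids)
    missing = [l for l in labels if l not in groups]
    if missing:
        raise ValueError(f"labels without group assignment: {missing}")
    g = np.asarray([groups[l] for l in labels])
    uniq, counts = np.unique(g, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    singles = uniq[counts < 2]
    if len(singles):
        raise ValueError(f"groups with a single member: {list(singles)}")
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = sps.rankdata(np.asarray(dm.data, float)[iu])
    gi, gj = g[iu[0]], g[iu[1]]
    r_obs = _anosim_r(ranks, gi == gj)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        gp = g[rng.permutation(n)]
        if _anosim_r(ranks, gp[iu[0]] == gp[iu[1]]) >= r_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1) if add_one else hits / n_perm
    return PermutationTestResult(
        statistic=r_obs,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        tail="one_sided_greater",
        method="anosim",
        add_one=add_one,
    )


def one_way_anova(samples_by_group: dict) -> AnovaResult:
    """Classical one-way ANOVA across groups; p from the F distribution."""
    groups = [np.asarray(v, float) for v in samples_by_group.values()]
    if len(groups) < 2 or any(len(v) < 2 for v in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(v) == 0 for v in groups):
        raise ValueError("zero within-group variance everywhere; F undefined")
    f, p = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(len(v) for v in groups)
    return AnovaResult(
        statistic=float(f), p_value=float(p), df_between=k - 1, df_within=n - k
    )
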
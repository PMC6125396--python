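"""Alpha diversity, coverage curves, core-OTU accounting and co-occurrence.

Conventions follow the legacy-QIIME toolchain: Shannon and equitability in
base 2, Simpson reported as ``1 - sum(p_i^2)``, Chao1 in its bias-corrected
form ``S_obs + F1(F1-1)/(2(F2+1))`` (defined even when there are no
doubletons), Good's coverage ``1 - F1/N``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio.diversity import alpha as skalpha

from .otu import OtuTable, aggregate_by_rank


@dataclass
class AlphaDiversityRecord:
    sample_id: str
    observed_otus: int
    chao1: float
    shannon: float
    simpson: float
    equitability: float
    goods_coverage: float


def _alpha_one(counts: np.ndarray) -> dict:
    counts = counts[counts > 0]
    if counts.size == 0:
        return dict(
            observed_otus=0, chao1=math.nan, shannon=math.nan,
            simpson=math.nan, equitability=math.nan, goods_coverage=math.nan,
        )
    s_obs = int(counts.size)
    h = float(skalpha.shannon(counts, base=2))
    return dict(
        observed_otus=s_obs,
        chao1=float(skalpha.chao1(counts, bias_corrected=True)),
        shannon=h,
        simpson=float(skalpha.simpson(counts)),
        equitability=h / math.log2(s_obs) if s_obs > 1 else math.nan,
        goods_coverage=float(skalpha.goods_coverage(counts)),
    )


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample alpha diversity (one row per sample).

    Columns: observed_otus, chao1, shannon (bits), simpson (1 - D),
    equitability (H / log2 S_obs), goods_coverage. Indices that are
    undefined for an empty sample are reported as NaN, never as zero.
    """
    rows = {
        sid: _alpha_one(table.counts.loc[sid].to_numpy())
        for sid in table.sample_ids
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def rarefaction_curve(
    table: OtuTable, depths, reps: int = 10, seed=None
) -> pd.DataFrame:
    """Mean Good's coverage per sample at each rarefaction depth.

    ``depths`` must be strictly increasing and no larger than every
    sample's total; the mean is over ``reps`` independent subsamples.
    Returns a DataFrame indexed by sample with one column per depth.
    """
    depths = list(depths)
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths must be strictly increasing")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_sums()
    if depths and depths[-1] > totals.min():
        raise ValueError(
            f"max depth {depths[-1]} exceeds smallest sample total {totals.min()}"
        )
    cov = np.zeros((len(table.sample_ids), len(depths)))
    counts = table.counts.to_numpy()
    for i, row in enumerate(counts):
        for j, d in enumerate(depths):
            acc = 0.0
            for _ in range(reps):
                sub = rng.multivariate_hypergeometric(row, d)
                acc += skalpha.goods_coverage(sub[sub > 0])
            cov[i, j] = acc / reps
    return pd.DataFrame(cov, index=table.sample_ids, columns=depths)


# -- core / shared OTUs --------------------------------------------------------


@dataclass
class CoreSummary:
    """Core OTUs of one host-species group.

    ``core_otu_ids`` are OTUs present in every replicate of the group;
    ``shared_otu_fraction`` is their percentage of the group's distinct
    OTUs; ``shared_seq_fraction_*`` summarize the percentage of each
    sample's reads that fall in core OTUs (mean and SD across replicates).
    """

    group: str
    core_otu_ids: frozenset = field(repr=False)
    n_core: int = 0
    n_total_otus: int = 0
    shared_otu_fraction: float = 0.0
    shared_seq_fraction_mean: float = 0.0
    shared_seq_fraction_sd: float = 0.0


def core_otus(table: OtuTable, group_by: str = "host_species") -> list[CoreSummary]:
    """Per-group core-OTU summary (presence in 100% of the group's samples)."""
    presence = table.presence()
    out = []
    for group, meta in table.metadata.groupby(group_by, sort=True):
        samples = list(meta.index)
        sub = presence.loc[samples]
        union = sub.any(axis=0)
        core = sub.all(axis=0) & union
        core_ids = frozenset(sub.columns[core])
        counts = table.counts.loc[samples]
        seq_frac = (
            100.0
            * counts.loc[:, list(core_ids)].sum(axis=1)
            / counts.sum(axis=1)
        )
        n_union = int(union.sum())
        out.append(
            CoreSummary(
                group=str(group),
                core_otu_ids=core_ids,
                n_core=len(core_ids),
                n_total_otus=n_union,
                shared_otu_fraction=100.0 * len(core_ids) / n_union if n_union else 0.0,
                shared_seq_fraction_mean=float(seq_frac.mean()),
                shared_seq_fraction_sd=float(seq_frac.std(ddof=1))
                if len(samples) > 1
                else 0.0,
            )
        )
    return out


def core_summary_frame(summaries: list[CoreSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [s.group for s in summaries],
            "n_core_otus": [s.n_core for s in summaries],
            "n_total_otus": [s.n_total_otus for s in summaries],
            "shared_otus_pct": [s.shared_otu_fraction for s in summaries],
            "shared_seqs_pct_mean": [s.shared_seq_fraction_mean for s in summaries],
            "shared_seqs_pct_sd": [s.shared_seq_fraction_sd for s in summaries],
        }
    ).set_index("group")


def intersection_counts(groups: dict[str, set]) -> pd.DataFrame:
    """Exclusive intersection sizes for every non-empty subset of groups.

    This is the matrix behind an UpSet plot: for each subset signature the
    count of elements present in exactly those groups. Counts over all
    signatures partition the union of the input sets.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = sorted(groups)
    sets = {k: set(v) for k, v in groups.items()}
    universe = set().union(*sets.values())
    membership = {}
    for el in universe:
        sig = frozenset(k for k in names if el in sets[k])
        membership[sig] = membership.get(sig, 0) + 1
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            sig = frozenset(combo)
            rows.append(
                {**{n: int(n in sig) for n in names},
                 "count": membership.get(sig, 0)}
            )
    return pd.DataFrame(rows)


# -- co-occurrence -------------------------------------------------------------

_EXACT_SPEARMAN_N = 9


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact p by full enumeration of pairings (n <= 9)."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    return hits / total


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rho with two-sided p: exact permutation enumeration for
    n <= 9, t-approximation otherwise. Undefined (NaN) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rho, p_t = sps.spearmanr(x, y)
    if len(x) <= _EXACT_SPEARMAN_N:
        return float(rho), _spearman_exact_p(x, y, float(rho))
    return float(rho), float(p_t)


def cooccurrence_spearman(
    table: OtuTable, genera: list[str], group_by: str = "host_species"
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Per-group Spearman co-occurrence among genus-level abundances.

    For each host-species group, genus-aggregated relative abundances
    across that group's samples are correlated pairwise (average ranks for
    ties). Returns ``{group: (rho_matrix, p_matrix)}``; pairs involving a
    constant abundance vector are NaN.
    """
    genus_table = aggregate_by_rank(table, "genus")
    missing = [g for g in genera if g not in genus_table.columns]
    if missing:
        raise ValueError(f"genera not resolvable from taxonomy: {missing}")
    out = {}
    for group, meta in table.metadata.groupby(group_by, sort=True):
        sub = genus_table.loc[list(meta.index), genera]
        k = len(genera)
        rho = np.eye(k)
        pval = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                r, p = spearman_with_p(sub.iloc[:, i], sub.iloc[:, j])
                rho[i, j] = rho[j, i] = r
                pval[i, j] = pval[j, i] = p
        out[str(group)] = (
            pd.DataFrame(rho, index=genera, columns=genera),
            pd.DataFrame(pval, index=genera, columns=genera),
        )
    return out
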
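"""End-to-end phylosymbiosis analysis.

``run_analysis`` drives the full workflow on an OTU table, sample metadata
and a rooted host phylogeny (plus an optional OTU phylogeny for UniFrac):
singleton filtering and rarefaction; alpha diversity with one-way ANOVA
across host species; core/shared-OTU accounting and UpSet-style
intersection counts; phylum/family composition; Jaccard distances; a
species-level UPGMA dendrogram scored against the host tree (RF and MC
with a random-topology null); a Mantel test of host distance vs community
dissimilarity; and, when an OTU tree is given, unweighted/weighted UniFrac
with PCoA and ANOSIM at species, genus and tribe levels.

Everything is written as a directory of TSV / newick / JSON files plus a
human-readable summary. A single config seed fans out to per-stage seeds
(stage-name hashed) so each stochastic stage is independently
reproducible and the machine-readable report is byte-identical across
reruns with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix

from . import __version__
from .beta import jaccard_matrix, pcoa, unweighted_unifrac, weighted_unifrac
from .diversity import (
    alpha_diversity,
    core_otus,
    core_summary_frame,
    intersection_counts,
)
from .otu import OtuTable, aggregate_by_rank, filter_singletons, rarefy, read_otu_table
from .stats import anosim, mantel, one_way_anova
from .trees import congruence_test, cophenetic_matrix, read_tree, upgma, write_tree

logger = logging.getLogger(__name__)

DEFAULTS = {
    "depth": 9683,
    "mantel_permutations": 9999,
    "anosim_permutations": 999,
    "congruence_draws": 80000,
    "congruence_mode": "auto",
    "profile_method": "mean",
    "prune_after_rarefaction": True,
    "seed": 0,
}


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the config seed and the stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return {**DEFAULTS, **cfg}


def species_profile(table: OtuTable, method: str = "mean") -> OtuTable:
    """Collapse replicates into one profile per host species.

    ``pooled`` sums raw counts. ``mean`` averages relative abundances and
    re-scales to integer pseudo-counts at the mean sample depth; any OTU
    with nonzero mean abundance keeps at least one count, so presence is
    identical under both methods when no replicate dropout occurred.
    """
    if method not in ("mean", "pooled"):
        raise ValueError(f"unknown profile method {method!r}")
    groups = table.metadata.groupby("host_species", sort=True)
    rows, meta_rows, species = [], [], []
    for sp, meta in groups:
        sub = table.counts.loc[list(meta.index)]
        if method == "pooled":
            prof = sub.sum(axis=0).to_numpy()
        else:
            rel = sub.div(sub.sum(axis=1).replace(0, 1), axis=0).mean(axis=0)
            scale = float(sub.sum(axis=1).mean())
            prof = np.maximum(
                np.rint(rel.to_numpy() * scale), (rel.to_numpy() > 0)
            ).astype(np.int64)
        rows.append(prof)
        species.append(str(sp))
        rec = meta.iloc[0].to_dict()
        rec["replicate"] = "*"
        meta_rows.append(rec)
    counts = pd.DataFrame(
        np.array(rows, dtype=np.int64), index=species, columns=table.counts.columns
    )
    return OtuTable(
        counts=counts,
        taxonomy=table.taxonomy,
        metadata=pd.DataFrame(meta_rows, index=species),
    )


def _write_dm(dm: DistanceMatrix, path: Path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def _species_map(dm: DistanceMatrix, meta: pd.DataFrame, column: str) -> dict:
    return {sid: meta.loc[sid, column] for sid in dm.ids}


def run_analysis(config, out_dir) -> dict:
    """Run the full analysis; returns the machine-readable report dict.

    ``config`` is a dict or a YAML path. Required keys: ``otu_table``,
    ``metadata``, ``host_tree``. Optional: ``otu_tree`` (enables UniFrac /
    PCoA / ANOSIM; skipped with a logged notice otherwise),
    ``host_distances`` (labeled square TSV; defaults to the host tree's
    cophenetic distances), plus the parameter keys in ``DEFAULTS``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = {**DEFAULTS, **config}
    for key in ("otu_table", "metadata", "host_tree"):
        if key not in config:
            raise ValueError(f"config is missing required key {key!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    report: dict = {
        "provenance": {
            "phylosym_version": __version__,
            "config": {k: str(v) for k, v in sorted(config.items())},
            "config_hash": hashlib.sha256(
                json.dumps(
                    {k: str(v) for k, v in config.items()}, sort_keys=True
                ).encode()
            ).hexdigest(),
            "stage_seeds": {
                s: stage_seed(seed, s) for s in ("rarefy", "congruence", "mantel", "anosim")
            },
        }
    }

    table = read_otu_table(config["otu_table"], config["metadata"])
    host = read_tree(config["host_tree"])
    table = filter_singletons(table)
    table = rarefy(
        table,
        int(config["depth"]),
        seed=stage_seed(seed, "rarefy"),
        prune=bool(config["prune_after_rarefaction"]),
    )
    report["n_samples"], report["n_otus"] = table.shape

    # keep the host tree in sync with species surviving rarefaction
    species = set(table.metadata["host_species"])
    host_leaves = {t.name for t in host.tips()}
    if species - host_leaves:
        raise ValueError(
            f"species missing from host tree: {sorted(species - host_leaves)}"
        )
    if host_leaves - species:
        logger.warning(
            "pruning host tree to %d species present in the table", len(species)
        )
        host = host.shear(species)

    # alpha diversity + ANOVA across host species
    alpha = alpha_diversity(table)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    anova = {}
    for index_name in alpha.columns:
        by_group = {
            sp: alpha.loc[list(m.index), index_name].dropna().to_list()
            for sp, m in table.metadata.groupby("host_species")
        }
        try:
            anova[index_name] = one_way_anova(by_group).to_dict()
        except ValueError as exc:
            anova[index_name] = {"error": str(exc)}
    report["anova"] = anova

    # core OTUs and intersections
    cores = core_otus(table, group_by="host_species")
    core_summary_frame(cores).to_csv(out / "core_summary.tsv", sep="\t")
    inter = intersection_counts({c.group: set(c.core_otu_ids) for c in cores})
    inter.to_csv(out / "intersection_counts.tsv", sep="\t", index=False)
    report["core"] = {
        c.group: {
            "n_core_otus": c.n_core,
            "shared_otus_pct": c.shared_otu_fraction,
            "shared_seqs_pct_mean": c.shared_seq_fraction_mean,
            "shared_seqs_pct_sd": c.shared_seq_fraction_sd,
        }
        for c in cores
    }

    # taxonomic composition
    for rank in ("phylum", "family"):
        aggregate_by_rank(table, rank).to_csv(out / f"composition_{rank}.tsv", sep="\t")

    # Jaccard: per sample and per species profile
    jac_samples = jaccard_matrix(table)
    _write_dm(jac_samples, out / "jaccard_samples.tsv")
    profile = species_profile(table, method=str(config["profile_method"]))
    jac_species = jaccard_matrix(profile)
    _write_dm(jac_species, out / "jaccard_species.tsv")

    # dendrogram vs host tree
    dendrogram = upgma(jac_species)
    write_tree(dendrogram, out / "dendrogram.nwk")
    write_tree(host, out / "host_tree.nwk")
    congruence = {}
    for metric in ("rf", "mc"):
        res = congruence_test(
            host,
            dendrogram,
            metric=metric,
            n_random=int(config["congruence_draws"]),
            mode=str(config["congruence_mode"]),
            seed=stage_seed(seed, "congruence"),
        )
        congruence[metric] = res.to_dict()
    report["congruence"] = congruence

    # Mantel: host genetic distances vs species-level Jaccard
    if config.get("host_distances"):
        host_dm = read_distance_matrix(config["host_distances"])
    else:
        host_dm = cophenetic_matrix(host)
    res = mantel(
        host_dm,
        jac_species,
        n_perm=int(config["mantel_permutations"]),
        seed=stage_seed(seed, "mantel"),
    )
    report["mantel"] = res.to_dict()

    # UniFrac / PCoA / ANOSIM (needs an OTU phylogeny)
    if config.get("otu_tree"):
        otu_tree = read_tree(config["otu_tree"])
        uu = unweighted_unifrac(table, otu_tree)
        wu = weighted_unifrac(table, otu_tree)
        _write_dm(uu, out / "unweighted_unifrac.tsv")
        _write_dm(wu, out / "weighted_unifrac.tsv")
        for name, dm in (("unweighted_unifrac", uu), ("weighted_unifrac", wu)):
            ordination = pcoa(dm)
            coords = ordination.coordinates.copy()
            coords.to_csv(out / f"pcoa_{name}.tsv", sep="\t")
        anosim_results = {}
        for level in ("host_species", "genus", "tribe"):
            if level not in table.metadata.columns:
                continue
            grouping = _species_map(uu, table.metadata, level)
            if pd.Series(grouping).nunique() < 2:
                continue
            res = anosim(
                uu,
                grouping,
                n_perm=int(config["anosim_permutations"]),
                seed=stage_seed(seed, "anosim"),
            )
            anosim_results[level] = res.to_dict()
        report["anosim"] = anosim_results
    else:
        logger.info("no OTU tree given; skipping UniFrac, PCoA and ANOSIM")
        report["anosim"] = None

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")
    _write_summary(report, out / "summary.txt")
    return report


def _write_summary(report: dict, path: Path) -> None:
    lines = ["phylosym analysis summary", "=" * 25, ""]
    lines.append(
        f"samples: {report['n_samples']}  OTUs (post-rarefaction): {report['n_otus']}"
    )
    for metric, res in report["congruence"].items():
        lines.append(
            f"congruence {metric.upper()}: raw={res['observed']} "
            f"n{metric.upper()}={res['normalized']:.4g} p={res['p_value']:.4g} "
            f"({res['mode']}, null={res['null_size']})"
        )
    m = report["mantel"]
    lines.append(
        f"mantel (host distance vs Jaccard): r={m['statistic']:.4f} "
        f"p={m['p_value']:.4g} ({m['n_permutations']} permutations)"
    )
    if report.get("anosim"):
        for level, res in report["anosim"].items():
            lines.append(
                f"anosim [{level}]: R={res['statistic']:.4f} p={res['p_value']:.4g}"
            )
    else:
        lines.append("anosim/UniFrac: skipped (no OTU tree)")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
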
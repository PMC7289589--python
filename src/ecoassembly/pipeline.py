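"""Orchestration: run every analysis stage per depth-layer group.

`run_all` is a pure function of (inputs, config): the same RunConfig and
input files always produce identical outputs. Each stage writes TSV outputs
to the run directory and failures are recorded in the manifest without
stopping independent stages.
"""

from __future__ import annotations

import json
import traceback
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .community_io import (CommunityTable, SampleTable, alpha_diversity,
                           env_variation, prevalence_filter, read_community,
                           read_tree)
from .neutral import fit_sloan, levins_breadth
from .network import build_network, or_ratio, topology
from .nullmodels import assembly_profile, beta_null_deviation

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Inputs, thresholds and seed for a full run.

    ``community``/``samples``/``tree`` may be file paths (TSV/TSV/Newick) or
    already-loaded objects.
    """

    community: object
    samples: object
    tree: object = None
    outdir: str = "ecoassembly_run"
    reps: int = 999
    permutations: int = 1000
    bnti_cut: float = 2.0
    rc_cut: float = 0.95
    r_cut: float = 0.6
    p_cut: float = 0.01
    prevalence: float = 0.75
    pool: str = "metacommunity"
    seed: int = 0
    run_networks: bool = True
    run_beta_null: bool = True

    def __post_init__(self) -> None:
        if self.reps < 100:
            raise ValueError("reps must be >= 100")
        for name in ("bnti_cut", "rc_cut", "r_cut", "p_cut", "prevalence"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _load(config: RunConfig):
    table = config.community
    if not isinstance(table, CommunityTable):
        table = read_community(table)
    samples = config.samples
    if not isinstance(samples, SampleTable):
        samples = SampleTable(pd.read_csv(samples, sep="\t", index_col=0))
    tree = config.tree
    if tree is not None and isinstance(tree, (str, Path)):
        tree = read_tree(tree)
    if tree is None:
        raise ValueError("phylogenetic stages require a tree")
    missing = set(table.sample_ids) ^ set(samples.sample_ids)
    if missing:
        raise ValueError(f"sample ids disagree between table and metadata: {sorted(missing)[:5]}")
    return table, samples, tree


def run_all(config: RunConfig) -> dict:
    """Run every stage per layer; returns the manifest dict.

    Outputs written under ``config.outdir``: assembly pair table and
    process fractions, β-null deviations (both metrics), per-layer neutral
    fits and niche breadth, per-layer networks with topology/PNC/OR tables,
    alpha diversity, and environmental variation.
    """
    table, samples, tree = _load(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups = samples.groups()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "pool": config.pool,
        "config": {k: v for k, v in asdict(config).items()
                   if isinstance(v, (int, float, str, bool))},
        "stages": {},
    }

    def stage(name, fn):
        try:
            fn()
            manifest["stages"][name] = "ok"
        except Exception as exc:  # record, keep going
            manifest["stages"][name] = f"failed: {exc}"
            warnings.warn(f"stage {name} failed: {exc}\n{traceback.format_exc()}")

    def _alpha():
        alpha_diversity(table).to_csv(outdir / "alpha_diversity.tsv", sep="\t")

    def _env():
        res = env_variation(samples)
        rows = [{"layer": lay, "dispersion": v["dispersion"]} for lay, v in res.items()]
        pd.DataFrame(rows).to_csv(outdir / "env_variation.tsv", sep="\t", index=False)
        cv = pd.DataFrame({lay: v["cv"] for lay, v in res.items()})
        cv.to_csv(outdir / "env_cv.tsv", sep="\t")

    def _assembly():
        pairs, frac = assembly_profile(
            table, tree, groups, reps=config.reps, seed=config.seed,
            pool=config.pool, bnti_cut=config.bnti_cut, rc_cut=config.rc_cut)
        pairs.to_csv(outdir / "assembly_pairs.tsv", sep="\t", index=False)
        frac.to_csv(outdir / "assembly_fractions.tsv", sep="\t")

    def _betanull():
        frames = [
            beta_null_deviation(table, metric=metric, tree=tree, groups=groups,
                                reps=config.reps, seed=config.seed)
            for metric in ("bray_curtis", "weighted_unifrac")
        ]
        pd.concat(frames).to_csv(outdir / "beta_null_deviations.tsv",
                                 sep="\t", index=False)

    def _neutral():
        fits, breadths = [], []
        for layer, sids in groups.items():
            sub = table.subset_samples(sids).drop_empty_taxa()
            fit = fit_sloan(sub)
            fits.append({"group": layer, "m": fit.m, "N": fit.N,
                         "r_squared": fit.r_squared,
                         "frac_within_ci": fit.frac_within_ci})
            nb = levins_breadth(table, group=sids)
            breadths.append(nb.B_com.rename("B_com").to_frame().assign(group=layer))
        pd.DataFrame(fits).to_csv(outdir / "neutral_fits.tsv", sep="\t", index=False)
        pd.concat(breadths).to_csv(outdir / "niche_breadth.tsv", sep="\t")

    def _networks():
        topo_rows, or_frames = [], []
        for layer, sids in groups.items():
            filtered = prevalence_filter(table, sids, config.prevalence)
            net = build_network(filtered, r_cut=config.r_cut, p_cut=config.p_cut,
                                B=config.permutations, seed=config.seed)
            net.edges.to_csv(outdir / f"network_edges_{layer}.tsv",
                             sep="\t", index=False)
            topo = topology(net)
            topo["group"] = layer
            topo_rows.append(topo)
            if net.graph.number_of_edges() > 0 and table.taxonomy is not None:
                orr = or_ratio(net, labels=table.taxonomy)
                orr["group"] = layer
                or_frames.append(orr)
        pd.DataFrame(topo_rows).to_csv(outdir / "network_topology.tsv",
                                       sep="\t", index=False)
        if or_frames:
            pd.concat(or_frames).to_csv(outdir / "or_ratio.tsv", sep="\t",
                                        index=False)

    stage("alpha_diversity", _alpha)
    stage("env_variation", _env)
    stage("assembly", _assembly)
    if config.run_beta_null:
        stage("beta_null_deviation", _betanull)
    stage("neutral_niche", _neutral)
    if config.run_networks:
        stage("networks", _networks)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
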
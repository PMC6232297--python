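"""End-to-end orchestration: config -> preprocess -> diversity -> resemblance
suite -> network suite -> report bundle.

The config is a YAML file with either an ``inputs`` section (paths to OTU,
environmental and metadata tables) or a ``synthetic`` section (parameters of
:class:`~reservoirnet.simulate.SyntheticConfig`).  All randomness flows from
one root seed split per analysis stage, and a run manifest records every
parameter, seed and input checksum so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, network, preprocess
from .containers import EnvTable, OTUTable, align_samples
from .diversity import diversity_table
from .resemblance import (
    anosim,
    bioenv_best,
    bray_curtis,
    distlm_forward,
    distlm_marginal,
    euclidean,
    nmds,
    permanova,
    relate,
    simper,
)
from .simulate import SyntheticConfig, generate_dataset

logger = logging.getLogger("reservoirnet")

_FLOAT_FMT = "%.8g"

STAGES = ("simulate", "diversity", "nmds", "permanova", "anosim", "simper",
          "distlm", "relate", "best", "network")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters; every seed explicit."""

    output_dir: Path
    inputs: dict | None = None
    synthetic: dict | None = None
    split_by: str | None = "reservoir"
    group_by: str = "site"
    filter_params: dict = field(default_factory=lambda: {
        "min_samples": 5, "min_sample_frac": 0.2, "min_abundance": 0.01})
    alpha: float = 0.05
    n_perm: int = 999
    nmds_restarts: int = 20
    max_best_subset: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "PipelineConfig":
        if "inputs" not in raw and "synthetic" not in raw:
            raise ValueError(
                "config must contain an 'inputs' or a 'synthetic' section"
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known - {"filter"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: v for k, v in raw.items() if k in known}
        if "filter" in raw:
            kwargs["filter_params"] = dict(raw["filter"])
        kwargs["output_dir"] = base / raw.get("output_dir", "reservoirnet-out")
        return cls(**kwargs)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed split from the root seed (< 2^31)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        syn = SyntheticConfig(**{**config.synthetic,
                                 "seed": config.synthetic.get(
                                     "seed", config.stage_seed("simulate"))})
        otus, env, truth = generate_dataset(syn)
        return otus, env, {"synthetic": True, "synthetic_seed": syn.seed}
    paths = config.inputs
    meta = (io.read_metadata(paths["metadata"])
            if paths.get("metadata") else None)
    otus = io.read_otu_table(paths["otu_table"],
                             dialect=paths.get("dialect", "wide-tsv"),
                             metadata=meta)
    env = io.read_env_table(paths["env_table"])
    checks = {key: _checksum(paths[key])
              for key in ("otu_table", "env_table", "metadata")
              if paths.get(key)}
    return otus, env, {"synthetic": False, "checksums": checks}


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _run_block(tag: str, otus: OTUTable, env: EnvTable,
               config: PipelineConfig, outdir: Path) -> dict:
    """Run the full analysis suite on one reservoir block."""
    summary: dict = {"n_samples": len(otus.sample_ids)}
    otus, env, align_report = align_samples(otus, env)
    if align_report["dropped_otu_samples"] or align_report["dropped_env_samples"]:
        logger.info("block %s: dropped samples %s", tag, align_report)
    summary["alignment"] = align_report

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            raise PipelineError(name, str(exc)) from exc

    # diversity on counts
    div = stage("diversity", lambda: diversity_table(otus))
    _write(div, outdir / f"{tag}.diversity.tsv")

    # resemblance suite on sqrt relative abundances / normalized env
    rel = preprocess.relative_abundance(otus)
    rel_sqrt = preprocess.sqrt_transform(rel)
    env_z = stage("distlm", lambda: preprocess.zscore_env(env))
    bc = stage("nmds", lambda: bray_curtis(rel_sqrt))
    ord_res = stage("nmds", lambda: nmds(
        bc, n_restarts=config.nmds_restarts, seed=config.stage_seed("nmds")))
    _write(ord_res.coordinates, outdir / f"{tag}.nmds.tsv")
    summary["nmds_stress"] = ord_res.stress

    groups = None
    if otus.metadata is not None and config.group_by in otus.metadata.columns:
        groups = otus.metadata[config.group_by].to_numpy()
    if groups is not None and len(pd.unique(groups)) >= 2:
        perm = stage("permanova", lambda: permanova(
            bc, groups, n_perm=config.n_perm,
            seed=config.stage_seed("permanova")))
        ano = stage("anosim", lambda: anosim(
            bc, groups, n_perm=config.n_perm, seed=config.stage_seed("anosim")))
        summary["permanova"] = {"pseudo_F": perm.statistic, "p": perm.p_perm}
        summary["anosim"] = {"R": ano.statistic, "p": ano.p_perm}
        if len(pd.unique(groups)) == 2:
            simp = stage("simper", lambda: simper(rel_sqrt, groups))
            _write(simp, outdir / f"{tag}.simper.tsv")
    else:
        logger.info("block %s: <2 levels of %r; skipping group tests",
                    tag, config.group_by)

    marg = stage("distlm", lambda: distlm_marginal(
        bc, env_z, n_perm=config.n_perm, seed=config.stage_seed("distlm")))
    _write(marg, outdir / f"{tag}.distlm_marginal.tsv")
    fwd = stage("distlm", lambda: distlm_forward(
        bc, env_z, entry_alpha=config.alpha, n_perm=config.n_perm,
        seed=config.stage_seed("distlm")))
    _write(fwd.steps.set_index("variable") if len(fwd.steps) else fwd.steps,
           outdir / f"{tag}.distlm_forward.tsv")
    summary["distlm_selected"] = fwd.selected

    env_complete = env_z.values.dropna(axis=0)
    if len(env_complete) >= 3:
        env_cc = EnvTable(env_complete, zscored=True)
        bc_cc = bray_curtis(rel_sqrt.subset_samples(list(env_complete.index)))
        dist_env = stage("relate", lambda: euclidean(env_cc))
        rel_test = stage("relate", lambda: relate(
            bc_cc, dist_env, n_perm=config.n_perm,
            seed=config.stage_seed("relate")))
        summary["relate"] = {"rho": rel_test.statistic, "p": rel_test.p_perm}
        best = stage("best", lambda: bioenv_best(
            bc_cc, env_cc, max_subset=config.max_best_subset))
        summary["best"] = {"subset": list(best.selected), "rho": best.rho}

    # network suite on unaltered relative abundances of the abundant OTUs
    filtered = stage("network", lambda: preprocess.filter_network_otus(
        rel, **config.filter_params))
    summary["n_otus_filtered"] = len(filtered.otu_ids)
    corr = stage("network", lambda: network.pairwise_correlations(
        filtered, env_z))
    corr.to_csv(outdir / f"{tag}.correlations.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT)
    pos, neg = network.build_networks(corr, alpha=config.alpha)
    report = network.network_report(corr, pos, neg)
    module_frames = []
    for sign_tag, g in (("cooccurrence", pos), ("coexclusion", neg)):
        if g.number_of_edges() == 0:
            continue
        part = network.detect_modules(g, seed=config.stage_seed("network"))
        metrics = network.betweenness(g)
        layout = network.fr_layout(g, iterations=200,
                                   seed=config.stage_seed("network"))
        for node in g.nodes:
            g.nodes[node]["module"] = int(part.assignments[node])
            g.nodes[node]["betweenness"] = float(
                metrics.loc[node, "betweenness"])
            g.nodes[node]["x"], g.nodes[node]["y"] = layout[node]
        kinds = {n: g.nodes[n].get("kind", "OTU") for n in g.nodes}
        msum = network.module_summary(part, kinds)
        msum.insert(0, "network", sign_tag)
        module_frames.append(msum)
        report[f"{sign_tag}_modularity_q"] = part.modularity_q
    io.write_network(pos, neg, outdir / f"{tag}.network", fmt="graphml")
    io.write_network(pos, neg, outdir / f"{tag}.network", fmt="edge-tsv")
    if module_frames:
        _write(pd.concat(module_frames), outdir / f"{tag}.modules.tsv")
    summary["network"] = report
    return summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict (also written)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    otus, env, input_info = _load_inputs(config)

    blocks: dict = {}
    if (config.split_by and otus.metadata is not None
            and config.split_by in otus.metadata.columns):
        for level in pd.unique(otus.metadata[config.split_by]):
            ids = list(otus.metadata.index[otus.metadata[config.split_by] == level])
            blocks[str(level)] = (otus.subset_samples(ids),
                                  env.subset_samples(
                                      [s for s in ids if s in set(env.sample_ids)]))
    else:
        blocks["all"] = (otus, env)

    summaries = {}
    for tag, (otu_block, env_block) in blocks.items():
        logger.info("analyzing block %s (%d samples)", tag,
                    len(otu_block.sample_ids))
        summaries[tag] = _run_block(tag, otu_block, env_block, config, outdir)

    manifest = {
        "package_version": __version__,
        "inputs": input_info,
        "parameters": {
            "split_by": config.split_by,
            "group_by": config.group_by,
            "filter": config.filter_params,
            "alpha": config.alpha,
            "n_perm": config.n_perm,
            "nmds_restarts": config.nmds_restarts,
            "max_best_subset": config.max_best_subset,
        },
        "root_seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "blocks": summaries,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
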
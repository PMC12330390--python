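"""End-to-end orchestration of the analysis stages.

Stages run in dependency order — generate -> profile -> biogeo / ani ->
transition — from a single YAML configuration and a global seed.  Every
output table is TSV with '#'-prefixed metadata comments (tool version,
stage, config hash, seed), and a run manifest records every file a stage
produced together with the parameters that produced it.  For a fixed
configuration and seed the outputs are byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import ani_divergence as ani_mod
from . import biogeography_stats as bio
from . import community_profiling as prof
from . import mk_transition as mk
from . import synthetic_data as synth
from .errors import DependencyError, InvalidArgumentError
from .trees import read_newick, write_newick

__all__ = ["PipelineConfig", "run_pipeline", "read_newick", "write_newick"]

STAGES = ("generate", "profile", "biogeo", "ani", "transition")


@dataclass
class PipelineConfig:
    """Validated pipeline settings (paths, stage toggles, per-stage params)."""

    outdir: Path
    seed: int = 0
    stages: tuple = STAGES
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # explicit input paths per table

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise InvalidArgumentError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = dict(
            outdir=raw.get("outdir", "sodalake_out"),
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", STAGES)),
            params={s: raw.get(s, {}) for s in STAGES},
            inputs=raw.get("inputs", {}),
        )
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**cfg)

    def config_hash(self, stage: str | None = None) -> str:
        """Hash of the settings that determine outputs.

        With ``stage`` given, only that stage's parameters (plus the seed)
        enter the hash, so one stage's outputs do not change when an
        unrelated stage is toggled or reconfigured.
        """
        if stage is None:
            payload = {"seed": self.seed, "stages": list(self.stages),
                       "params": self.params,
                       "inputs": {k: str(v) for k, v in self.inputs.items()}}
        else:
            keys = [stage] + (["generate_ani"] if stage == "generate" else [])
            payload = {"seed": self.seed,
                       "params": {k: self.params.get(k, {}) for k in keys}}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


# ----------------------------------------------------------------- io helpers

def _header(stage: str, cfg: PipelineConfig) -> str:
    return (f"sodalake v{__version__}\nstage: {stage}\n"
            f"config: {cfg.config_hash(stage)}\nseed: {cfg.seed}")


def write_tsv(df: pd.DataFrame, path: Path, stage: str, cfg: PipelineConfig,
              index: bool = False, index_label=None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header(stage, cfg).splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ----------------------------------------------------------------- stages

def _stage_generate(cfg: PipelineConfig, outputs: dict) -> list:
    p = dict(cfg.params.get("generate", {}))
    mk_params = p.pop("mk", {})
    sim = synth.SimConfig(seed=cfg.seed, **p)
    community = synth.generate_abundance_inputs(sim)
    outdir = cfg.outdir
    files = []

    def emit(df, name):
        path = outdir / name
        write_tsv(df, path, "generate", cfg)
        files.append(path)
        return path

    outputs["mapping_summaries"] = emit(community.mapping_summaries, "mapping_summaries.tsv")
    outputs["sample_metadata"] = emit(community.sample_metadata, "sample_metadata.tsv")
    outputs["truth"] = emit(community.truth, "occupancy_truth.tsv")

    ani_df = synth.generate_ani_pairs(seed=cfg.seed + 1, regions=sim.regions,
                                      **cfg.params.get("generate_ani", {}))
    outputs["ani_pairs"] = emit(ani_df, "ani_pairs.tsv")

    mk_defaults = {"n_tips": 100, "birth_rate": 1.0,
                   "true_rates": {"Asia->NorthAmerica": 0.5, "NorthAmerica->Asia": 0.5,
                                  "Africa->Asia": 0.05, "Asia->Africa": 0.05,
                                  "Africa->NorthAmerica": 0.05, "NorthAmerica->Africa": 0.05},
                   "state_names": ["Africa", "Asia", "NorthAmerica"]}
    mk_defaults.update(mk_params)
    names = list(mk_defaults["state_names"])
    idx = {nm: i for i, nm in enumerate(names)}
    rates = {}
    for key, val in mk_defaults["true_rates"].items():
        a, b = key.split("->")
        rates[(idx[a], idx[b])] = float(val)
    mk_cfg = synth.MkSimConfig(
        n_tips=int(mk_defaults["n_tips"]), birth_rate=float(mk_defaults["birth_rate"]),
        true_rates=rates, root_frequencies=tuple([1.0 / len(names)] * len(names)),
        state_names=tuple(names), seed=cfg.seed + 2)
    tree = synth.generate_tree(mk_cfg.n_tips, mk_cfg.birth_rate, seed=cfg.seed + 2)
    tips = synth.simulate_tip_states(tree, mk_cfg)
    tree_path = outdir / "species_tree.nwk"
    write_newick(tree, tree_path, header=_header("generate", cfg))
    files.append(tree_path)
    outputs["tree"] = tree_path
    outputs["tip_abundance"] = emit(
        tips.to_frame().rename_axis("species_id").reset_index(), "tip_abundance.tsv")
    return files


def _stage_profile(cfg: PipelineConfig, outputs: dict) -> list:
    summaries = _require(cfg, outputs, "mapping_summaries", "profile")
    metadata = _require(cfg, outputs, "sample_metadata", "profile")
    table = prof.abundance_table(read_tsv(summaries), read_tsv(metadata))
    threshold = float(cfg.params.get("profile", {}).get("presence_threshold", 0.0))
    profiles = prof.classify_occupancy(table, threshold)
    files = []
    for df, name, kw in (
        (table.matrix, "abundance_tpm.tsv", {"index": True, "index_label": "species_id"}),
        (profiles, "occupancy_profiles.tsv", {}),
        (prof.occupancy_summary(profiles), "occupancy_summary.tsv", {}),
        (prof.range_size_table(table), "range_size.tsv", {}),
    ):
        path = cfg.outdir / name
        write_tsv(df, path, "profile", cfg, **kw)
        files.append(path)
    outputs["abundance"] = cfg.outdir / "abundance_tpm.tsv"
    return files


def _load_abundance(cfg: PipelineConfig, outputs: dict, stage: str) -> prof.AbundanceTable:
    abundance = _require(cfg, outputs, "abundance", stage)
    metadata = _require(cfg, outputs, "sample_metadata", stage)
    matrix = read_tsv(abundance, index_col="species_id")
    return prof.AbundanceTable(matrix=matrix, metadata=read_tsv(metadata))


def _stage_biogeo(cfg: PipelineConfig, outputs: dict) -> list:
    table = _load_abundance(cfg, outputs, "biogeo")
    p = cfg.params.get("biogeo", {})
    metric = p.get("metric", "braycurtis")
    n_perm = int(p.get("permutations", 999))
    pairs = bio.distance_pairs(table, metric=metric)
    fit = bio.ddr_fit(pairs, metric=metric)
    D = bio._dissimilarity_matrix(table, metric)
    f, r2, pval = bio.permanova(D, table.region_of().to_numpy(), n_perm, seed=cfg.seed)
    files = []
    for df, name in (
        (pairs, "distance_pairs.tsv"),
        (pd.DataFrame([vars(fit)]), "ddr_fit.tsv"),
        (pd.DataFrame([{"pseudo_F": f, "R2": r2, "p_value": pval,
                        "n_permutations": n_perm, "metric": metric}]),
         "permanova.tsv"),
    ):
        path = cfg.outdir / name
        write_tsv(df, path, "biogeo", cfg)
        files.append(path)
    return files


def _stage_ani(cfg: PipelineConfig, outputs: dict) -> list:
    records = read_tsv(_require(cfg, outputs, "ani_pairs", "ani"))
    metadata = read_tsv(_require(cfg, outputs, "sample_metadata", "ani"))
    files = []
    contrast_rows = []
    for tier in ("species", "strain"):
        tier_records = ani_mod.tier_filter(records, tier)
        for region in sorted(set(records["region_a"]) | set(records["region_b"])):
            try:
                c = ani_mod.within_between_contrast(tier_records, region)
            except Exception:
                continue  # regions with an empty side are reported absent
            contrast_rows.append({"tier": tier, "region": region, **vars(c)})
    contrasts = pd.DataFrame(contrast_rows)
    if not contrasts.empty:
        contrasts["p_adjusted"] = bio.bh_adjust(contrasts["p_value"].to_numpy())
    summaries, pair_contrasts = ani_mod.region_pair_ordering(records, metadata)
    for df, name in ((contrasts, "ani_within_between.tsv"),
                     (summaries, "ani_region_pairs.tsv"),
                     (pair_contrasts, "ani_pair_contrasts.tsv")):
        path = cfg.outdir / name
        write_tsv(df, path, "ani", cfg)
        files.append(path)
    return files


def _stage_transition(cfg: PipelineConfig, outputs: dict) -> list:
    tree_path = _require(cfg, outputs, "tree", "transition")
    tips_path = _require(cfg, outputs, "tip_abundance", "transition")
    p = cfg.params.get("transition", {})
    tree = mk.scale_tree(read_newick(tree_path), float(p.get("target_mean", 0.1)))
    abundance = read_tsv(tips_path, index_col="species_id")
    tips = mk.encode_tip_states(abundance, float(p.get("ambiguity_threshold", 0.05)))
    model = mk.RateModel(n_states=tips.n_states, state_names=tips.state_names)
    prior = mk.PriorSpec(family=p.get("prior", "hyper-gamma"))
    if p.get("paper_mode", False):
        config = mk.McmcConfig.paper_mode(seed=cfg.seed)
    else:
        config = mk.McmcConfig(iterations=int(p.get("iterations", 20000)),
                               burn_in=int(p.get("burn_in", 2000)),
                               thinning=int(p.get("thinning", 10)),
                               n_chains=int(p.get("chains", 3)), seed=cfg.seed)
    traces = [mk.mcmc_sample(tree, tips, model, prior,
                             mk.McmcConfig(iterations=config.iterations,
                                           burn_in=config.burn_in,
                                           thinning=config.thinning,
                                           seed=cfg.seed + 100 + c))
              for c in range(config.n_chains)]
    congruence = mk.run_congruence(traces) if len(traces) > 1 else None
    combined = mk.McmcTrace(
        free=np.vstack([t.free for t in traces]),
        log_likelihood=np.concatenate([t.log_likelihood for t in traces]),
        pair_labels=traces[0].pair_labels)
    files = []
    for df, name in ((traces[0].rates_frame(model), "transition_trace.tsv"),
                     (combined.summary(model), "transition_posterior.tsv")):
        path = cfg.outdir / name
        write_tsv(df, path, "transition", cfg)
        files.append(path)
    if congruence is not None:
        path = cfg.outdir / "transition_congruence.tsv"
        write_tsv(congruence, path, "transition", cfg)
        files.append(path)
    if p.get("stepping_stone", False):
        ss = mk.stepping_stone_logml(
            tree, tips, model, prior,
            n_stones=int(p.get("stones", 100)),
            iterations_per_stone=int(p.get("iterations_per_stone", 1000)),
            seed=cfg.seed)
        path = cfg.outdir / "transition_logml.tsv"
        write_tsv(pd.DataFrame([{
            "log_marginal_likelihood": ss.log_marginal_likelihood,
            "n_stones": ss.n_stones,
            "iterations_per_stone": ss.iterations_per_stone,
            "failed": ss.failed}]), path, "transition", cfg)
        files.append(path)
    return files


def _require(cfg: PipelineConfig, outputs: dict, key: str, stage: str) -> Path:
    if key in cfg.inputs:
        path = Path(cfg.inputs[key])
    elif key in outputs:
        path = Path(outputs[key])
    else:
        raise DependencyError(
            f"stage {stage!r} needs input {key!r}: enable the producing stage "
            f"or set inputs.{key} in the config")
    if not path.exists():
        raise DependencyError(f"stage {stage!r}: input {key!r} not found at {path}")
    return path


_RUNNERS = {"generate": _stage_generate, "profile": _stage_profile,
            "biogeo": _stage_biogeo, "ani": _stage_ani,
            "transition": _stage_transition}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the run manifest."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": config.config_hash(), "stages": {}}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        files = _RUNNERS[stage](config, outputs)
        manifest["stages"][stage] = {
            "outputs": [str(f) for f in files],
            "params": config.params.get(stage, {}),
            "seed": config.seed,
        }
    manifest_path = config.outdir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
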
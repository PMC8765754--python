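"""End-to-end pipeline: simulate -> fit -> kinetic stats -> psi -> decay -> set stats.

A plain-file pipeline with content hashing: each stage records the SHA-256 of
its inputs and outputs in ``manifest.json``; on rerun, a stage is skipped when
its inputs and outputs are unchanged, and rerun (with its descendants) when
anything upstream changed.  The serialized config plus seed fully determine
every stochastic output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decay as decay_mod
from . import psi as psi_mod
from . import setstats
from .genome import read_annotation, intron_features
from .kinetics import RateSet, cleavage_before_splicing_prob, time_to_transcribe
from .ratefit import fit_rates, fits_to_frame
from .simulate import ConditionEffect, SimConfig, write_fixture_bundle
from . import io as swio

logger = logging.getLogger("splicewave.pipeline")

STAGES = ("simulate", "fit", "kinetic_stats", "psi", "decay", "set_stats")


@dataclass
class RunConfig:
    outdir: str = "splicewave_run"
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    n_fit_genes: int = 3
    fit_restarts: int = 2
    fit_quad_step: float = 0.1
    fdr_threshold: float = 0.05
    subsample_reps: int = 200
    log_level: str = "INFO"

    _KNOWN = None

    def __post_init__(self) -> None:
        known = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(self.sim) - known
        if bad:
            raise ValueError(f"unknown sim config keys: {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.sim)
        if "conditions" in kwargs:
            kwargs["conditions"] = {
                name: ConditionEffect(**eff) for name, eff in kwargs["conditions"].items()
            }
        kwargs["seed"] = self.seed
        return SimConfig(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_files(outdir: Path, names: list[str]) -> dict[str, str]:
    return {n: _sha256(outdir / n) for n in names if (outdir / n).exists()}


def _stage_fresh(manifest: dict, stage: str, outdir: Path, inputs: dict[str, str]) -> bool:
    rec = manifest.get("stages", {}).get(stage)
    if rec is None or rec.get("inputs") != inputs:
        return False
    for name, digest in rec.get("outputs", {}).items():
        p = outdir / name
        if not p.exists() or _sha256(p) != digest:
            return False
    return True


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_config = config.sim_config()
    manifest_path = outdir / "manifest.json"
    manifest = {}
    if manifest_path.exists() and not force:
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") != _config_hash(config):
            logger.info("config changed; rerunning all stages")
            manifest = {}
    manifest.setdefault("config", config.to_dict())
    manifest["config_hash"] = _config_hash(config)
    manifest["seed"] = config.seed
    manifest.setdefault("stages", {})

    def record(stage: str, inputs: dict[str, str], outputs: list[str], elapsed: float) -> None:
        # elapsed time is logged, not stored: the manifest must be
        # byte-identical across reruns of the same config + seed
        logger.info("stage %s finished in %.2fs", stage, elapsed)
        manifest["stages"][stage] = {
            "inputs": inputs,
            "outputs": _hash_files(outdir, outputs),
        }
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))

    upstream_ok = True
    for stage in STAGES:
        fn = _STAGE_FNS[stage]
        inputs = fn.input_hasher(outdir, config)
        if upstream_ok and not force and _stage_fresh(manifest, stage, outdir, inputs):
            logger.info("stage %s up to date; skipped", stage)
            continue
        upstream_ok = False  # once one stage reran, descendants rerun too
        logger.info("stage %s running (seed=%d)", stage, config.seed)
        t0 = time.monotonic()
        try:
            outputs = fn(outdir, config, sim_config)
        except Exception as exc:
            logger.error("stage %s failed: %s (inputs: %s)", stage, exc, inputs)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        record(stage, inputs, outputs, time.monotonic() - t0)
    return manifest


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _stage(input_names):
    """Decorator attaching an input-hash function to a stage function."""

    def deco(fn):
        def hasher(outdir: Path, config: RunConfig) -> dict[str, str]:
            return _hash_files(outdir, input_names)

        fn.input_hasher = hasher
        return fn

    return deco


@_stage([])
def _run_simulate(outdir: Path, config: RunConfig, sim_config: SimConfig) -> list[str]:
    sim_dir = outdir / "sim"
    bundle = write_fixture_bundle(sim_dir, sim_config)
    names = []
    for v in bundle["files"].values():
        names.extend([f"sim/{n}" for n in (v if isinstance(v, list) else [v])])
    names.append("sim/manifest.json")
    return names


def _load_sim(outdir: Path, sim_config: SimConfig):
    models = read_annotation(outdir / "sim" / "genes.gtf", format="GTF")
    cov_paths = sorted((outdir / "sim").glob("coverage_control_t*.bedGraph"),
                       key=lambda p: float(p.stem.split("_t")[-1]))
    times = [float(p.stem.split("_t")[-1]) for p in cov_paths]
    tcs = swio.read_timecourses(cov_paths, times, sim_config.bin_size) if cov_paths else {}
    return models, tcs


@_stage(["sim/genes.gtf"])
def _run_fit(outdir: Path, config: RunConfig, sim_config: SimConfig) -> list[str]:
    models, tcs = _load_sim(outdir, sim_config)
    fits = []
    for m in models[: config.n_fit_genes]:
        if m.gene_id not in tcs:
            continue
        try:
            fits.append(fit_rates(tcs[m.gene_id], m, n_restarts=config.fit_restarts,
                                  seed=config.seed, quad_step=config.fit_quad_step))
        except ValueError as exc:
            logger.warning("fit skipped for %s: %s", m.gene_id, exc)
    fits_to_frame(fits).to_csv(outdir / "rates_fit.tsv", sep="\t", index=False)
    return ["rates_fit.tsv"]


@_stage(["sim/genes.gtf", "sim/truth_rates.tsv"])
def _run_kinetic_stats(outdir: Path, config: RunConfig, sim_config: SimConfig) -> list[str]:
    models = read_annotation(outdir / "sim" / "genes.gtf", format="GTF")
    rates = pd.read_csv(outdir / "sim" / "truth_rates.tsv", sep="\t")
    feats = intron_features(models)
    by_gene = {m.gene_id: m for m in models}
    rows = []
    for _, rec in rates.iterrows():
        m = by_gene[rec["gene_id"]]
        rs = RateSet(sigma=rec["sigma"], v=rec["v"],
                     s=np.array([float(x) for x in str(rec["s"]).split(",")]), c=rec["c"])
        for intr in m.introns:
            rows.append({
                "intron_id": f"{m.gene_id}:{intr.index}",
                "condition": rec["condition"],
                "time_to_transcribe_min": time_to_transcribe(intr, rs),
                "p_cleave_before_splice": cleavage_before_splicing_prob(intr, rs),
            })
    stats_df = pd.DataFrame(rows)
    feats.to_csv(outdir / "intron_features.tsv", sep="\t", index=False)
    stats_df.to_csv(outdir / "kinetic_stats.tsv", sep="\t", index=False)
    return ["intron_features.tsv", "kinetic_stats.tsv"]


@_stage(["sim/polya_counts.tsv"])
def _run_psi(outdir: Path, config: RunConfig, sim_config: SimConfig) -> list[str]:
    table = pd.read_csv(outdir / "sim" / "polya_counts.tsv", sep="\t")
    outputs = []
    for trt in [c for c in table["condition"].unique() if c != "control"]:
        res = psi_mod.delta_psi_test(table, "control", trt)
        res.to_csv(outdir / f"psi_{trt}.tsv", sep="\t")
        ri = psi_mod.call_ri(res, config.fdr_threshold)
        ri.to_csv(outdir / f"ri_{trt}.tsv", sep="\t")
        outputs += [f"psi_{trt}.tsv", f"ri_{trt}.tsv"]
    return outputs


@_stage(["sim/actd_counts.tsv"])
def _run_decay(outdir: Path, config: RunConfig, sim_config: SimConfig) -> list[str]:
    counts = pd.read_csv(outdir / "sim" / "actd_counts.tsv", sep="\t")
    table = decay_mod.decay_table(counts)
    deltas = table.pivot(index="intron_id", columns="condition", values="delta")
    medians, pairwise = decay_mod.compare_decay(deltas)
    table.to_csv(outdir / "decay.tsv", sep="\t", index=False)
    pairwise.assign(
        median_overall=np.nan
    ).to_csv(outdir / "decay_compare.tsv", sep="\t", index=False)
    medians.rename("median_delta").to_csv(outdir / "decay_medians.tsv", sep="\t")
    return ["decay.tsv", "decay_compare.tsv", "decay_medians.tsv"]


@_stage(["sim/polya_counts.tsv", "intron_features.tsv"])
def _run_set_stats(outdir: Path, config: RunConfig, sim_config: SimConfig) -> list[str]:
    table = pd.read_csv(outdir / "sim" / "polya_counts.tsv", sep="\t")
    feats = pd.read_csv(outdir / "intron_features.tsv", sep="\t")
    treatments = [c for c in table["condition"].unique() if c != "control"]
    ri_sets, dpsi = {}, {}
    universe = set(table["event_id"].unique())
    for trt in treatments:
        res = psi_mod.delta_psi_test(table, "control", trt)
        ri_sets[trt] = set(psi_mod.call_ri(res, config.fdr_threshold).index)
        dpsi[trt] = res["delta_psi"]
    out: dict = {}
    if len(treatments) >= 2:
        a, b = treatments[:2]
        ov = setstats.overlap_or(ri_sets[a], ri_sets[b], universe)
        out["overlap"] = {"pair": f"{a}|{b}", "odds_ratio": ov.odds_ratio,
                          "log2_odds_ratio": ov.log2_odds_ratio, "p": ov.p,
                          "n_both": ov.n_both}
        common = dpsi[a].dropna().index.intersection(dpsi[b].dropna().index)
        if len(common) >= 10:
            out["concordance"] = setstats.delta_psi_concordance(dpsi[a], dpsi[b])
    feats = feats.set_index("intron_id")
    ri_union = set().union(*ri_sets.values()) if ri_sets else set()
    ri_feats = feats.loc[feats.index.intersection(ri_union), "dist_to_tes_nt"]
    if len(ri_feats) >= 3:
        med_p, _ = setstats.subsampled_wilcoxon(
            ri_feats.to_numpy(), feats["dist_to_tes_nt"].to_numpy(),
            n_rep=config.subsample_reps, seed=config.seed,
        )
        out["ri_dist_to_tes_subsampled_median_p"] = med_p
    (outdir / "set_stats.json").write_text(json.dumps(out, indent=1, default=float))
    return ["set_stats.json"]


_STAGE_FNS = {
    "simulate": _run_simulate,
    "fit": _run_fit,
    "kinetic_stats": _run_kinetic_stats,
    "psi": _run_psi,
    "decay": _run_decay,
    "set_stats": _run_set_stats,
}
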
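"""End-to-end orchestration with a YAML config, logging, and a manifest.

All randomness flows from a single global seed via named sub-streams, so
an identical config yields byte-identical numeric outputs.  Every stage
writes tabular/JSON files into the run directory and is recorded in
``manifest.json`` with a checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bb_scan import scan_genome
from .convergence import convergence_scan
from .heterozygosity import het_trend
from .hidden import hidden_variation_report
from .parallelism import TargetCriteria, loo_parallelism
from .pca import fit_pc_lmm, run_pca
from .simulate import SimConfig, simulate_experiment
from .snp_io import filter_snps, frequencies, read_snp_table, write_snp_table

logger = logging.getLogger(__name__)

_ALL_STAGES = ("simulate", "filter", "pca", "bb_scan", "het", "hidden",
               "converge", "loo")


@dataclass
class PipelineConfig:
    """Run configuration; paths are optional when simulate is enabled."""

    out_dir: str = "evoltraj_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(_ALL_STAGES))
    snp_table: str | None = None
    design: str | None = None
    deep_table: str | None = None
    deep_design: str | None = None
    focal_sample: str = "FA1"
    sim: dict = field(default_factory=dict)
    min_cov: int = 20
    min_maf: float = 0.02
    alpha: float = 0.05
    hidden_alpha: float = 0.005
    pseudocount: int = 1
    n_pcs: int = 10
    pc_alpha: float = 0.005
    fdr: float = 0.05
    min_dp: float = 0.02
    n_perm: int = 10000
    deep_min_cov: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def validate(self) -> None:
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if "simulate" not in self.stages:
            for name in ("snp_table", "design"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"stage inputs missing: {name}={p}")
            if "hidden" in self.stages and (
                self.deep_table is None or not Path(self.deep_table).exists()
            ):
                raise ValueError("hidden stage enabled but deep_table missing")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {k: v for k, v in config.__dict__.items() if k != "sim"},
        "sim": dict(config.sim),
        "outputs": {},
        "summaries": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(out)), "sha256": _sha256(path)
        }

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage = "setup"
    try:
        table = deep = truth = None
        if "simulate" in config.stages:
            stage = "simulate"
            t0 = time.time()
            sim_kwargs = dict(config.sim)
            sim_kwargs.setdefault("seed", int(seeds[0].generate_state(1)[0] % (2**31)))
            sim = simulate_experiment(SimConfig(**sim_kwargs))
            table, deep, truth = sim.table, sim.deep, sim.truth
            write_snp_table(table, out / "snp_table.tsv", out / "design.tsv")
            write_snp_table(deep, out / "deep_table.tsv", out / "deep_design.tsv")
            truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
            for f in ("snp_table.tsv", "design.tsv", "deep_table.tsv",
                      "deep_design.tsv", "truth.tsv"):
                record(f, out / f)
            logger.info("simulate: %d loci in %.1fs", table.n_loci, time.time() - t0)
        else:
            table = read_snp_table(config.snp_table, config.design)
            if config.deep_table is not None:
                deep = read_snp_table(
                    config.deep_table, config.deep_design or config.design
                )

        if "filter" in config.stages:
            stage = "filter"
            n0 = table.n_loci
            table = filter_snps(table, config.min_cov, config.min_maf)
            manifest["summaries"]["filter"] = {
                "n_input": n0, "n_retained": table.n_loci
            }
            write_snp_table(
                table, out / "snp_table.filtered.tsv", out / "design.filtered.tsv"
            )
            record("snp_table.filtered.tsv", out / "snp_table.filtered.tsv")
            record("design.filtered.tsv", out / "design.filtered.tsv")

        traj = table.select_samples(group={"A2C", "C2A"})

        if "pca" in config.stages:
            stage = "pca"
            freqs = frequencies(table, pseudocount=config.pseudocount)
            pca = run_pca(freqs, [s.group for s in table.samples])
            scores = pd.DataFrame(
                pca.scores[:, : config.n_pcs],
                columns=[f"PC{i+1}" for i in range(min(config.n_pcs, pca.scores.shape[1]))],
            )
            scores.insert(0, "sample_id", [s.sample_id for s in table.samples])
            scores.to_csv(out / "pca_scores.tsv", sep="\t", index=False)
            record("pca_scores.tsv", out / "pca_scores.tsv")
            is_traj = [s.group in ("A2C", "C2A") for s in table.samples]
            design = pd.DataFrame(
                {
                    "T": [0 if s.group == "A2C" else 1 for s in traj.samples],
                    "G": [s.generation for s in traj.samples],
                    "population": [f"{s.group}_{s.replicate}" for s in traj.samples],
                }
            )
            lmm = fit_pc_lmm(
                pca.scores[np.asarray(is_traj)], design,
                n_pcs=config.n_pcs, alpha=config.pc_alpha,
            )
            lmm.frame.to_csv(out / "pca_lmm.tsv", sep="\t", index=False)
            record("pca_lmm.tsv", out / "pca_lmm.tsv")
            manifest["summaries"]["pca"] = {
                "variance_explained": pca.variance_explained[: config.n_pcs].tolist()
            }

        scan = None
        if "bb_scan" in config.stages:
            stage = "bb_scan"
            t0 = time.time()
            scan = scan_genome(traj, alpha=config.alpha)
            scan.frame.to_csv(out / "bb_scan.tsv", sep="\t", index=False)
            record("bb_scan.tsv", out / "bb_scan.tsv")
            manifest["summaries"]["bb_scan"] = {
                "n_tested": scan.n_tested,
                "class_counts": {
                    "+".join(k): v for k, v in scan.class_counts().items()
                },
                "runtime_s": round(time.time() - t0, 1),
            }

        if "het" in config.stages:
            stage = "het"
            het = het_trend(table.select_samples(group={"A2C", "C2A"}))
            het.per_sample.to_csv(out / "het_per_sample.tsv", sep="\t", index=False)
            het.tests.to_csv(out / "het_tests.tsv", sep="\t", index=False)
            record("het_per_sample.tsv", out / "het_per_sample.tsv")
            record("het_tests.tsv", out / "het_tests.tsv")
            manifest["summaries"]["het"] = het.tests.to_dict("records")

        if "hidden" in config.stages:
            stage = "hidden"
            if deep is None:
                raise ValueError("hidden stage requires a deep table")
            if scan is not None:
                sig = scan.frame.index[
                    scan.frame["padj_interaction"] < config.hidden_alpha
                ].to_numpy()
            else:
                sig = np.arange(table.n_loci)
            rep = hidden_variation_report(
                table, deep, config.focal_sample, sig,
                deep_min_cov=config.deep_min_cov, n_perm=config.n_perm,
                seed=int(seeds[1].generate_state(1)[0] % (2**31)),
            )
            summary = {
                "n_sites": int(len(rep.sites)),
                "observed_mean_maf": rep.observed_mean,
                "null_mean": rep.null_mean,
                "null_sd": rep.null_sd,
                "z": rep.z,
                "p_empirical": rep.p_empirical,
                "n_permutations": rep.n_permutations,
            }
            with open(out / "hidden.json", "w") as fh:
                json.dump(summary, fh, indent=2)
            record("hidden.json", out / "hidden.json")
            manifest["summaries"]["hidden"] = summary

        if "converge" in config.stages:
            stage = "converge"
            conv_summary = {}
            for contrast in ("C2A-vs-FOUNDER_A", "A2C-vs-FOUNDER_C"):
                res = convergence_scan(table, contrast, alpha=config.alpha)
                fname = f"convergence_{contrast}.tsv"
                res.frame.to_csv(out / fname, sep="\t", index=False)
                record(fname, out / fname)
                conv_summary[contrast] = {
                    "n_tested": int(res.frame["ok"].sum()),
                    "n_differentiated": res.n_differentiated,
                }
            manifest["summaries"]["converge"] = conv_summary

        if "loo" in config.stages:
            stage = "loo"
            loo_summary = {}
            crit = TargetCriteria(fdr_threshold=config.fdr, min_abs_dp=config.min_dp)
            for t_i, trajectory in enumerate(("A2C", "C2A")):
                loo = loo_parallelism(
                    table, crit, trajectory=trajectory,
                    seed=int(seeds[2].generate_state(4)[t_i] % (2**31)),
                )
                fname = f"loo_{trajectory}.tsv"
                loo.per_iteration.to_csv(out / fname, sep="\t", index=False)
                record(fname, out / fname)
                gw = loo.tests[loo.tests["region"] == "genome"].iloc[0]
                med = loo.per_iteration.query("region == 'genome'")
                loo_summary[trajectory] = {
                    "target_median": float(np.nanmedian(med["target_median"])),
                    "control_median": float(np.nanmedian(med["control_median"])),
                    "t": None if np.isnan(gw["statistic"]) else float(gw["statistic"]),
                    "p": None if np.isnan(gw["p"]) else float(gw["p"]),
                }
            manifest["summaries"]["loo"] = loo_summary
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
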
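"""End-to-end orchestration: simulate/ingest -> QC -> TuRF -> rank -> interact.

A single declarative YAML config drives all stages; every stage writes its
artifacts into the output directory and the run is summarised in a manifest
with SHA-256 checksums, stage timings and record counts, so two runs with the
same config and seed are byte-identical and verifiably so.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ensemble, infogain, qc, relief
from .genotype import read_genotypes, write_genotypes
from .simulate import SimConfig, parity3_penetrance, xor_penetrance
from .simulate import simulate as run_simulation

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline"]

log = logging.getLogger("epigain")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and partial outputs remain."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative run description; see ``from_yaml`` for the file layout.

    Exactly one input source: either ``input_path``/``input_format`` for real
    data or ``sim`` for a simulated cohort.  Sub-configs default to the
    standard analysis settings (10-fold CV x 10 repeats, 1,000 permutations,
    mean+3SD TuRF cut); the default simulation profile is desk-scale.
    """

    out_dir: str = "epigain_run"
    seed: int = 0
    input_path: str | None = None
    input_format: str = "tsv"
    sim: SimConfig | None = None
    qc_params: qc.QCParams = field(default_factory=qc.QCParams)
    relief_params: relief.ReliefParams = field(default_factory=relief.ReliefParams)
    rf_params: dict = field(default_factory=lambda: {"mtry": 100, "ntree": 500})
    gbm_params: dict = field(
        default_factory=lambda: {"n_trees": 500, "interaction_depth": 10, "shrinkage": 0.1}
    )
    cv_folds: int = 10
    cv_repeats: int = 10
    consensus_rule: str = "top_k"
    consensus_t: float = 1.0
    consensus_fraction: float = 0.05
    n_permutations: int = 1000
    interaction_order: int = 2

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("config must name exactly one input source "
                             "(input_path or sim)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "sim" in kwargs and kwargs["sim"] is not None:
            sim_raw = dict(kwargs["sim"])
            models = []
            for m in sim_raw.pop("models", []):
                kind = m.get("kind", "xor")
                loci = tuple(m["loci"])
                h = float(m.get("h", 0.25))
                if kind == "xor":
                    models.append(xor_penetrance(h, loci))
                elif kind == "parity3":
                    models.append(parity3_penetrance(h, loci))
                else:
                    raise ValueError(f"unknown model kind {kind!r}")
            if "maf_range" in sim_raw:
                sim_raw["maf_range"] = tuple(sim_raw["maf_range"])
            kwargs["sim"] = SimConfig(models=models, **sim_raw)
        if "qc_params" in kwargs and kwargs["qc_params"] is not None:
            kwargs["qc_params"] = qc.QCParams(**kwargs["qc_params"])
        if "relief_params" in kwargs and kwargs["relief_params"] is not None:
            kwargs["relief_params"] = relief.ReliefParams(**kwargs["relief_params"])
        return cls(**{k: v for k, v in kwargs.items() if v is not None})


@dataclass
class RunManifest:
    """What a run produced: files + checksums, timings, per-stage counts."""

    stages: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    failed_stage: str | None = None

    def record_file(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.checksums[path.name] = digest

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stages\t" + ",".join(self.stages) + "\n")
            if self.failed_stage:
                fh.write(f"failed_stage\t{self.failed_stage}\n")
            for k, v in self.timings.items():
                fh.write(f"time.{k}\t{v:.3f}\n")
            for k, v in self.counts.items():
                fh.write(f"count.{k}\t{v}\n")
            for k, v in sorted(self.checksums.items()):
                fh.write(f"sha256.{k}\t{v}\n")


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute all stages in order, writing artifacts and a manifest to out_dir.

    Deterministic for a fixed config and seed.  On stage failure a
    :class:`PipelineError` naming the stage is raised after the manifest
    (with partial results) is written.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    stage = "input"
    try:
        t0 = time.time()
        if cfg.sim is not None:
            g, phen, truth = run_simulation(cfg.sim)
            truth.write(out / "truth.tsv")
            manifest.record_file(out / "truth.tsv")
        else:
            g, phen = read_genotypes(cfg.input_path, format=cfg.input_format)
        write_genotypes(g, phen, out / "input.tsv", format="tsv")
        manifest.record_file(out / "input.tsv")
        manifest.counts["input.samples"] = g.n_samples
        manifest.counts["input.snps"] = g.n_snps
        manifest.stages.append(stage)
        manifest.timings[stage] = time.time() - t0

        stage = "qc"
        t0 = time.time()
        g, phen, report = qc.run_qc(g, phen, cfg.qc_params)
        report.write(out / "qc_report.tsv")
        write_genotypes(g, phen, out / "clean.tsv", format="tsv")
        manifest.record_file(out / "qc_report.tsv")
        manifest.record_file(out / "clean.tsv")
        manifest.counts["qc.samples"] = g.n_samples
        manifest.counts["qc.snps"] = g.n_snps
        manifest.stages.append(stage)
        manifest.timings[stage] = time.time() - t0

        stage = "turf"
        t0 = time.time()
        table = relief.turf_scores(g, phen, cfg.relief_params)
        table.write(out / "turf_scores.tsv")
        manifest.record_file(out / "turf_scores.tsv")
        selected = relief.mean_sd_threshold(table, cfg.relief_params.sd_multiplier)
        if len(selected) < 2:
            # fall back to the TuRF survivors so downstream stages have input
            n_keep = max(2, int(np.ceil(0.05 * g.n_snps)))
            selected = set(table.ranking()[:n_keep])
            log.warning("mean+SD cut selected <2 SNPs; using top %d by TuRF", n_keep)
        sel_idx = [g.snp_ids.index(s) for s in sorted(selected)]
        g_sel = g.take_snps(sorted(sel_idx))
        manifest.counts["turf.selected"] = g_sel.n_snps
        manifest.stages.append(stage)
        manifest.timings[stage] = time.time() - t0

        stage = "rank"
        t0 = time.time()
        tables = {}
        for adapter, params in (
            (ensemble.RandomForestAdapter(), cfg.rf_params),
            (ensemble.GBMAdapter(), cfg.gbm_params),
        ):
            _, _, imps = ensemble.repeated_cv(
                g_sel, phen, adapter, params,
                k=cfg.cv_folds, repeats=cfg.cv_repeats, seed=cfg.seed,
            )
            tab = ensemble.aggregate_importance(imps, g_sel.snp_ids, adapter.name)
            tab.write(out / f"importance_{adapter.name}.tsv")
            manifest.record_file(out / f"importance_{adapter.name}.tsv")
            tables[adapter.name] = tab
        if cfg.consensus_rule == "top_k":
            k_sel = max(2, int(np.ceil(cfg.consensus_fraction * g_sel.n_snps)))
            consensus = ensemble.consensus_select(tables["rf"], tables["gbm"],
                                                  rule="top_k", k=k_sel)
        else:
            consensus = ensemble.consensus_select(tables["rf"], tables["gbm"],
                                                  rule="diagonal", t=cfg.consensus_t)
        if len(consensus) < cfg.interaction_order:
            raise RuntimeError("consensus selection too small for interaction analysis")
        with open(out / "consensus.txt", "w") as fh:
            fh.write("\n".join(sorted(consensus)) + "\n")
        manifest.record_file(out / "consensus.txt")
        manifest.counts["rank.consensus"] = len(consensus)
        manifest.stages.append(stage)
        manifest.timings[stage] = time.time() - t0

        stage = "interact"
        t0 = time.time()
        idx = sorted(g_sel.snp_ids.index(s) for s in consensus)
        g_int = g_sel.take_snps(idx)
        perm_cfg = infogain.PermutationConfig(cfg.n_permutations, cfg.seed)
        results = infogain.pairwise_scan(g_int, phen, perm_cfg)
        infogain.results_to_tsv(results, out / "interactions_pairs.tsv")
        manifest.record_file(out / "interactions_pairs.tsv")
        manifest.counts["interact.pairs"] = len(results)
        if cfg.interaction_order >= 3 and g_int.n_snps >= 3:
            results3 = infogain.threeway_scan(g_int, phen, perm_cfg)
            infogain.results_to_tsv(results3, out / "interactions_trios.tsv")
            manifest.record_file(out / "interactions_trios.tsv")
            manifest.counts["interact.trios"] = len(results3)
        manifest.stages.append(stage)
        manifest.timings[stage] = time.time() - t0
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.write(out / "manifest.tsv")
        raise PipelineError(stage, str(exc)) from exc

    manifest.write(out / "manifest.tsv")
    return manifest
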
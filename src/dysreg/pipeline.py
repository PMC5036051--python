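"""Stage orchestration: simulate -> de -> cis -> select -> compare -> downstream.

Each stage reads its inputs from (and writes its outputs to) a working
directory, so any stage can be re-run independently.  A single global seed
deterministically derives every stage- and gene-level seed via
``numpy.random.SeedSequence([global_seed, stage_index])`` (gene-level seeds
hash the gene identifier, so results are independent of scheduling).  A run
manifest records the configuration, seed and per-stage wall time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import cis_assoc, diff_expr, downstream, model_compare, omics_io, tf_select
from .bundle import GenePanel, OmicsBundle
from .errors import ConfigError, InputError
from .lasso import PathParams
from .synthetic import SyntheticConfig, generate_binding_annotation, generate_cohort, default_panel
from .tf_select import SelectionParams

log = logging.getLogger(__name__)

STAGES = ("simulate", "de", "cis", "select", "compare", "downstream")
_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

_STAGE_OUTPUTS = {
    "simulate": ["expression.tsv", "cna.tsv", "dm.tsv", "samples.tsv",
                 "panel.tsv", "tfs.txt", "truth.json", "peaks.bed", "tss.bed"],
    "de": ["de_results.tsv", "de_pathway_summary.tsv"],
    "cis": ["cis_cna.tsv", "cis_cna_top.tsv", "cis_cna_summary.json",
            "cis_dm.tsv", "cis_dm_top.tsv", "cis_dm_summary.json"],
    "select": ["tf_selections.tsv", "tf_profiles.json"],
    "compare": ["model_eval.tsv", "model_summary.tsv"],
    "downstream": ["regulator_ranking.tsv", "regulator_network.graphml",
                   "binding_support.tsv"],
}


@dataclass
class PipelineConfig:
    """All stage settings; defaults follow the published procedure
    (FDR < 0.05, 100 lambda draws, 100 subsamples of 2/3, 100 kb, top 10)."""

    outdir: str = "dysreg_out"
    seed: int = 0
    de_fdr_threshold: float = 0.05
    lasso_runs: int = 100
    lasso_folds: int = 10
    lasso_path_ratio: float = 1e-3
    lasso_path_points: int = 100
    lambda_rule: str = "1se"
    cutoff_splits: int = 100
    compare_repeats: int = 100
    train_fraction: float = 2.0 / 3.0
    support_threshold_bp: int = 100_000
    top_k: int = 10
    min_stratum_size: int = 10
    strata_column: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    supported_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.de_fdr_threshold < 1:
            raise ConfigError("de_fdr_threshold must lie in (0, 1)")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.support_threshold_bp < 0 or self.top_k < 1:
            raise ConfigError("invalid support threshold or top_k")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        return cls(synthetic=syn, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, _STAGE_INDEX[stage]])
        return int(ss.generate_state(1)[0] % (2**31))

    def selection_params(self) -> SelectionParams:
        return SelectionParams(
            runs=self.lasso_runs,
            splits=self.cutoff_splits,
            train_fraction=self.train_fraction,
            seed=self.stage_seed("select"),
            path=PathParams(
                ratio=self.lasso_path_ratio,
                n_points=self.lasso_path_points,
                folds=self.lasso_folds,
                rule=self.lambda_rule,
            ),
        )


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise InputError(f"stage '{stage}' needs missing input {path}")
    return path


class PipelineRun:
    """Filesystem-backed pipeline state for one output directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.timings: dict[str, float] = {}

    # -- stage inputs ---------------------------------------------------
    def load_panel(self) -> GenePanel:
        return omics_io.read_panel(
            _require(self.outdir / "panel.tsv", "load"),
            _require(self.outdir / "tfs.txt", "load"),
        )

    def load_bundle(self) -> OmicsBundle:
        paths = omics_io.BundlePaths.under(self.outdir)
        _require(paths.expression, "load")
        bundle, _ = omics_io.load_bundle(paths, self.load_panel())
        return bundle

    # -- stages ---------------------------------------------------------
    def simulate(self) -> None:
        cfg = dataclasses.replace(
            self.config.synthetic, seed=self.config.stage_seed("simulate")
        )
        bundle, truth = generate_cohort(cfg)
        peaks, tss = generate_binding_annotation(
            truth,
            supported_fraction=self.config.supported_fraction,
            threshold_bp=self.config.support_threshold_bp,
            seed=self.config.stage_seed("simulate") + 1,
        )
        omics_io.write_bundle(bundle, self.outdir)
        omics_io.write_panel(
            default_panel(cfg), self.outdir / "panel.tsv", self.outdir / "tfs.txt"
        )
        omics_io.write_truth(truth, self.outdir / "truth.json")
        omics_io.write_bed(peaks, self.outdir / "peaks.bed")
        omics_io.write_bed(
            tss.rename(columns={"gene": "name"}), self.outdir / "tss.bed"
        )

    def de(self) -> None:
        bundle = self.load_bundle()
        res = diff_expr.differential_expression(
            bundle, fdr_threshold=self.config.de_fdr_threshold
        )
        res.insert(0, "pathways", [
            ";".join(sorted(bundle.gene_pathways.get(g, set()))) for g in res.index
        ])
        res.to_csv(self.outdir / "de_results.tsv", sep="\t")
        summary = diff_expr.pathway_summary(res, self.load_panel())
        summary.to_csv(self.outdir / "de_pathway_summary.tsv", sep="\t")

    def _de_genes(self) -> list[str]:
        path = _require(self.outdir / "de_results.tsv", "cis/select")
        res = pd.read_csv(path, sep="\t", index_col=0)
        return diff_expr.de_genes(res)

    def cis(self) -> None:
        bundle = self.load_bundle()
        genes = self._de_genes()
        for layer in (cis_assoc.CNA_LAYER, cis_assoc.DM_LAYER):
            result = cis_assoc.cis_table(
                bundle, layer, genes,
                strata_column=self.config.strata_column,
                min_stratum_size=self.config.min_stratum_size,
                top_k=self.config.top_k,
            )
            tag = layer.lower()
            result.table.to_csv(self.outdir / f"cis_{tag}.tsv", sep="\t", index=False)
            result.top.to_csv(self.outdir / f"cis_{tag}_top.tsv", sep="\t", index=False)
            result.pathway_summary.to_json(self.outdir / f"cis_{tag}_summary.json")

    def select(self) -> None:
        bundle = self.load_bundle()
        genes = self._de_genes()
        params = self.config.selection_params()
        profiles = tf_select.select_tfs(bundle, genes, params)
        tf_select.selections_table(profiles).to_csv(
            self.outdir / "tf_selections.tsv", sep="\t"
        )
        payload = {g: p.to_dict() for g, p in profiles.items()}
        (self.outdir / "tf_profiles.json").write_text(json.dumps(payload, indent=1))

    def _selections(self) -> dict[str, set[str]]:
        path = _require(self.outdir / "tf_selections.tsv", "compare/downstream")
        df = pd.read_csv(path, sep="\t", index_col=0).fillna({"selected_tfs": ""})
        return {
            g: set(filter(None, str(r.selected_tfs).split(";")))
            for g, r in df.iterrows()
        }

    def compare(self) -> None:
        bundle = self.load_bundle()
        selections = {g: s for g, s in self._selections().items() if s}
        rows = model_compare.evaluate_all(
            bundle, selections,
            repeats=self.config.compare_repeats,
            train_fraction=self.config.train_fraction,
            seed=self.config.stage_seed("compare"),
        )
        rows.to_csv(self.outdir / "model_eval.tsv", sep="\t", index=False)
        model_compare.summarize_table(rows).to_csv(
            self.outdir / "model_summary.tsv", sep="\t"
        )

    def downstream(self) -> None:
        panel = self.load_panel()
        selections = self._selections()
        ranking = downstream.rank_regulators(selections, panel, top_k=self.config.top_k)
        ranking.drop(columns=["targets_by_pathway"]).to_csv(
            self.outdir / "regulator_ranking.tsv", sep="\t"
        )
        nx.write_graphml(
            downstream.regulator_graph(selections, panel),
            self.outdir / "regulator_network.graphml",
        )
        peaks = omics_io.read_bed_intervals(_require(self.outdir / "peaks.bed", "downstream"))
        tss = omics_io.read_tss_table(_require(self.outdir / "tss.bed", "downstream"))
        table = downstream.support_table(
            selections, peaks, tss, threshold_bp=self.config.support_threshold_bp
        )
        table.to_csv(self.outdir / "binding_support.tsv", sep="\t")

    # -- driver ---------------------------------------------------------
    def run(self, stages: list[str]) -> None:
        for stage in stages:
            if stage not in STAGES:
                raise ConfigError(f"unknown stage {stage!r}")
            t0 = time.perf_counter()
            try:
                getattr(self, stage)()
            except Exception:
                # do not leave partial stage outputs behind
                for name in _STAGE_OUTPUTS.get(stage, []):
                    (self.outdir / name).unlink(missing_ok=True)
                raise
            self.timings[stage] = time.perf_counter() - t0
            log.info("stage %s finished in %.1fs", stage, self.timings[stage])
        self._write_manifest(stages)

    def run_all(self) -> None:
        self.run(list(STAGES))

    def _write_manifest(self, stages: list[str]) -> None:
        cfg = self.config.to_dict()
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()
        manifest = {
            "config": cfg,
            "config_sha256": digest,
            "seed": self.config.seed,
            "stages": stages,
            "wall_time_s": {k: round(v, 3) for k, v in self.timings.items()},
        }
        (self.outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def run(stage: str, config: PipelineConfig) -> PipelineRun:
    """Run one stage (or ``all``) under the given configuration."""
    pr = PipelineRun(config)
    if stage == "all":
        pr.run_all()
    else:
        pr.run([stage])
    return pr
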
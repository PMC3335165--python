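"""End-to-end pipeline orchestration with stage caching and provenance.

Stages run in analysis order: simulate (optional) -> segment -> call ->
integrate -> candidates -> report.  Each stage writes plain TSV outputs into
the run directory plus a manifest recording a content hash of its inputs and
parameters; a re-run with unchanged inputs reuses the cached outputs, and a
re-run into a fresh directory with the same seeds is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import calling, candidates as cand_mod, integration, io, plots, segmentation
from .calling import Thresholds
from .simulate import SimulationConfig, simulate_all, truth_table

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "cnax_run"
    # inputs; every path may be None when the simulate block provides data
    acgh_matrix: str | None = None
    acgh_map: str | None = None
    expr_matrix: str | None = None
    expr_map: str | None = None
    clinical: str | None = None
    de_list: str | None = None
    normals: str | None = None
    simulate: dict | None = None  # SimulationConfig fields
    # thresholds (used when no normals file is given)
    gain_threshold: float = 0.225
    amp_threshold: float = 0.8
    homdel_threshold: float = -0.7
    sd_multiplier: float = 3.0
    # segmentation
    alpha: float = 0.01
    cbs_n_perm: int = 1000
    merge_tol: float = 0.05
    outlier_k: int = 2
    outlier_z: float = 4.0
    # integration
    corr_n_perm: int = 1000
    r_cut: float = 0.29
    q_cut: float = 0.01
    window_bp: float = 1_000_000
    min_n: int = 10
    bin_bp: float = 20_000_000
    # candidates
    min_imbalance: int = 5
    stratify_feature: str | None = "stage"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def simulation_config(self) -> SimulationConfig:
        block = dict(self.simulate or {})
        block.setdefault("seed", self.seed)
        return SimulationConfig(**block)

    def thresholds(self) -> Thresholds:
        return Thresholds(
            gain=self.gain_threshold, loss=-self.gain_threshold,
            amp=self.amp_threshold, homdel=self.homdel_threshold,
            sd_multiplier=self.sd_multiplier,
        )


def _hash_inputs(params: dict, files: list[Path]) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(params, sort_keys=True, default=str).encode())
    for f in files:
        h.update(str(f).encode())
        if f is not None and Path(f).exists():
            h.update(Path(f).read_bytes())
    return h.hexdigest()


def _stage_cached(outdir: Path, stage: str, digest: str, outputs: list[Path]) -> bool:
    manifest = outdir / f"{stage}.manifest.json"
    if not manifest.exists():
        return False
    try:
        recorded = json.loads(manifest.read_text())
    except json.JSONDecodeError:
        return False
    return recorded.get("digest") == digest and all(Path(o).exists() for o in outputs)


def _record_stage(outdir: Path, stage: str, digest: str, outputs: list[Path]) -> None:
    (outdir / f"{stage}.manifest.json").write_text(
        json.dumps({"stage": stage, "digest": digest, "outputs": [str(o) for o in outputs]},
                   indent=1)
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of output paths per stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.to_yaml(outdir / "resolved_config.yaml")
    outputs: dict = {}

    # ---------------------------------------------------------------- simulate
    if config.simulate is not None:
        stage = "simulate"
        sim_cfg = config.simulation_config()
        sim_files = {
            "acgh_map": outdir / "acgh_map.tsv",
            "acgh_matrix": outdir / "acgh_matrix.tsv",
            "expr_map": outdir / "expr_map.tsv",
            "expr_matrix": outdir / "expr_matrix.tsv",
            "clinical": outdir / "clinical.tsv",
            "de_list": outdir / "de_list.tsv",
            "truth": outdir / "truth.tsv",
        }
        digest = _hash_inputs(dataclasses.asdict(sim_cfg), [])
        if not _stage_cached(outdir, stage, digest, list(sim_files.values())):
            try:
                acgh_map, acgh, expr_map, expr, clinical, de, truth = simulate_all(sim_cfg)
            except Exception as exc:  # noqa: BLE001
                raise StageError(stage, str(exc)) from exc
            io.write_clone_map(acgh_map, sim_files["acgh_map"])
            io.write_ratio_matrix(acgh, sim_files["acgh_matrix"])
            expr_map_out = expr_map.rename(columns={"clone_id": "clone_id"})
            expr_map_out[["clone_id", "chromosome", "start", "end", "arm", "gene_symbol"]].to_csv(
                sim_files["expr_map"], sep="\t", index=False
            )
            io.write_ratio_matrix(expr, sim_files["expr_matrix"])
            io.write_clinical(clinical, sim_files["clinical"])
            io.write_de_list(de, sim_files["de_list"])
            truth_table(truth).to_csv(sim_files["truth"], sep="\t", index=False)
            _record_stage(outdir, stage, digest, list(sim_files.values()))
        outputs[stage] = {k: str(v) for k, v in sim_files.items()}
        config = dataclasses.replace(
            config,
            acgh_map=str(sim_files["acgh_map"]), acgh_matrix=str(sim_files["acgh_matrix"]),
            expr_map=str(sim_files["expr_map"]), expr_matrix=str(sim_files["expr_matrix"]),
            clinical=str(sim_files["clinical"]), de_list=str(sim_files["de_list"]),
        )

    if config.acgh_matrix is None or config.acgh_map is None:
        raise StageError("segment", "no aCGH matrix/map provided and no simulate block")

    acgh_map = io.read_clone_map(config.acgh_map)
    acgh = io.read_ratio_matrix(config.acgh_matrix, acgh_map)

    # ----------------------------------------------------------------- segment
    stage = "segment"
    seg_files = {"segments": outdir / "segments.tsv", "smoothed": outdir / "smoothed.tsv"}
    seg_params = {k: getattr(config, k) for k in
                  ("alpha", "cbs_n_perm", "merge_tol", "outlier_k", "outlier_z", "seed")}
    digest = _hash_inputs(seg_params, [Path(config.acgh_matrix), Path(config.acgh_map)])
    if not _stage_cached(outdir, stage, digest, list(seg_files.values())):
        try:
            result = segmentation.segment_matrix(
                acgh, acgh_map, alpha=config.alpha, n_perm=config.cbs_n_perm,
                seed=config.seed, merge_tol=config.merge_tol,
                outlier_k=config.outlier_k, outlier_z=config.outlier_z,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, str(exc)) from exc
        result.segments.to_csv(seg_files["segments"], sep="\t", index=False, float_format="%.9g")
        io.write_ratio_matrix(result.smoothed, seg_files["smoothed"])
        _record_stage(outdir, stage, digest, list(seg_files.values()))
    outputs[stage] = {k: str(v) for k, v in seg_files.items()}
    smoothed = io.read_ratio_matrix(seg_files["smoothed"], acgh_map)

    # -------------------------------------------------------------------- call
    stage = "call"
    call_files = {
        "calls": outdir / "calls.tsv", "arm_calls": outdir / "arm_calls.tsv",
        "frequency": outdir / "frequency.tsv", "events_bed": outdir / "events.bed",
        "recurrent_bed": outdir / "recurrent.bed",
    }
    if config.clinical and config.stratify_feature:
        call_files["stratified"] = outdir / "stratified_frequency.tsv"
    call_params = {"gain": config.gain_threshold, "amp": config.amp_threshold,
                   "homdel": config.homdel_threshold, "sd_multiplier": config.sd_multiplier,
                   "stratify": config.stratify_feature}
    digest = _hash_inputs(call_params, [Path(config.acgh_matrix), Path(config.acgh_map)]
                          + ([Path(config.normals)] if config.normals else [])
                          + ([Path(config.clinical)] if config.clinical else []))
    if not _stage_cached(outdir, stage, digest, list(call_files.values())):
        try:
            if config.normals:
                normals = io.read_ratio_matrix(config.normals)
                th = calling.derive_threshold(normals, config.sd_multiplier,
                                              amp=config.amp_threshold,
                                              homdel=config.homdel_threshold)
            else:
                th = config.thresholds()
            calls = calling.call_clones(acgh, th)
            arm_calls = calling.call_arms(acgh, acgh_map, th)
            freq = calling.frequency(calls)
            catalogue = calling.catalogue_events(calls, acgh_map)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, str(exc)) from exc
        io.write_ratio_matrix(calls, call_files["calls"])
        io.write_ratio_matrix(arm_calls, call_files["arm_calls"])
        freq.to_csv(call_files["frequency"], sep="\t", float_format="%.9g")
        per_sample = catalogue.events.assign(n_samples=1)[
            ["chromosome", "start", "end", "class", "n_samples"]
        ]
        io.write_regions_bed(per_sample, call_files["events_bed"])
        io.write_regions_bed(catalogue.recurrent, call_files["recurrent_bed"])
        if "stratified" in call_files:
            clinical = io.read_clinical(config.clinical)
            strat = calling.stratified_frequency(arm_calls, clinical, config.stratify_feature)
            strat.to_csv(call_files["stratified"], sep="\t", index=False, float_format="%.9g")
        _record_stage(outdir, stage, digest, list(call_files.values()))
    outputs[stage] = {k: str(v) for k, v in call_files.items()}
    calls = io.read_ratio_matrix(call_files["calls"], acgh_map)

    # --------------------------------------------------------------- integrate
    if config.expr_matrix and config.expr_map:
        stage = "integrate"
        expr_map = pd.read_csv(config.expr_map, sep="\t")
        expr_map["position"] = (expr_map["start"] + expr_map["end"]) / 2.0
        expr = io.read_ratio_matrix(config.expr_matrix)
        int_files = {
            "records": outdir / "correlation_records.tsv",
            "selected": outdir / "selected_records.tsv",
            "binned": outdir / "binned_correlation.tsv",
            "summary": outdir / "integration_summary.json",
        }
        int_params = {k: getattr(config, k) for k in
                      ("corr_n_perm", "r_cut", "q_cut", "window_bp", "min_n", "bin_bp", "seed")}
        digest = _hash_inputs(int_params, [Path(config.expr_matrix), Path(config.expr_map),
                                           Path(seg_files["smoothed"])])
        if not _stage_cached(outdir, stage, digest, list(int_files.values())):
            try:
                records = integration.map_expression_to_bac(
                    expr, expr_map, smoothed, acgh_map,
                    window_bp=config.window_bp, min_n=config.min_n,
                )
                records = integration.permutation_pvalues(
                    records, expr, smoothed, n_perm=config.corr_n_perm,
                    seed=config.seed, min_n=config.min_n,
                )
                records["q"] = integration.bh_adjust(records["p_perm"].to_numpy())
                selected, achieved = integration.select_correlated(
                    records, r_cut=config.r_cut, q_cut=config.q_cut
                )
                binned = integration.binned_diagonal_analysis(
                    expr, expr_map, smoothed, acgh_map, bin_bp=config.bin_bp
                )
            except Exception as exc:  # noqa: BLE001
                raise StageError(stage, str(exc)) from exc
            records.to_csv(int_files["records"], sep="\t", index=False, float_format="%.9g")
            selected.to_csv(int_files["selected"], sep="\t", index=False, float_format="%.9g")
            binned.matrix.to_csv(int_files["binned"], sep="\t", na_rep="NA", float_format="%.9g")
            summary = {
                "n_records": int(len(records)),
                "n_mapped": int(records["mapped"].sum()),
                "n_selected": int(len(selected)),
                "fraction_selected_of_mapped": float(len(selected) / max(records["mapped"].sum(), 1)),
                "achieved_fdr": None if pd.isna(achieved) else float(achieved),
                "median_diagonal_r": binned.median_diagonal,
                "median_offdiagonal_r": binned.median_offdiagonal,
            }
            Path(int_files["summary"]).write_text(json.dumps(summary, indent=1, sort_keys=True))
            _record_stage(outdir, stage, digest, list(int_files.values()))
        outputs[stage] = {k: str(v) for k, v in int_files.items()}

        # ------------------------------------------------------------ candidates
        if config.de_list:
            stage = "candidates"
            cand_files = {
                "candidates": outdir / "candidates.tsv",
                "discordant": outdir / "discordant.tsv",
                "gene_rollup": outdir / "gene_rollup.tsv",
                "gene_conflicts": outdir / "gene_conflicts.tsv",
                "cdt": outdir / "candidates_clustered.cdt",
            }
            digest = _hash_inputs({"min_imbalance": config.min_imbalance},
                                  [Path(int_files["selected"]), Path(call_files["calls"]),
                                   Path(config.de_list)])
            if not _stage_cached(outdir, stage, digest, list(cand_files.values())):
                try:
                    selected = pd.read_csv(int_files["selected"], sep="\t")
                    de = io.read_de_list(config.de_list)
                    nom = cand_mod.nominate(selected, calls, de,
                                            min_imbalance=config.min_imbalance)
                except Exception as exc:  # noqa: BLE001
                    raise StageError(stage, str(exc)) from exc
                nom.candidates.to_csv(cand_files["candidates"], sep="\t", index=False,
                                      float_format="%.9g")
                nom.discordant.to_csv(cand_files["discordant"], sep="\t", index=False,
                                      float_format="%.9g")
                nom.gene_rollup.to_csv(cand_files["gene_rollup"], sep="\t", index=False,
                                       float_format="%.9g")
                nom.gene_conflicts.to_csv(cand_files["gene_conflicts"], sep="\t", index=False)
                if len(nom.candidates) >= 2:
                    sub = expr.reindex(nom.candidates["expr_clone_id"])
                    clust = cand_mod.cluster_candidates(sub)
                    cand_mod.export_cdt(clust, cand_files["cdt"])
                else:
                    Path(cand_files["cdt"]).write_text("CLONE\n")
                _record_stage(outdir, stage, digest, list(cand_files.values()))
            outputs[stage] = {k: str(v) for k, v in cand_files.items()}
        else:
            logger.warning("no DE list configured; candidates stage skipped")
            outputs["candidates"] = {"skipped": "no DE list configured"}
    else:
        logger.warning("no expression inputs configured; integrate/candidates skipped")

    # ------------------------------------------------------------------ report
    stage = "report"
    fig_files = {"frequency_plot": outdir / "frequency.png",
                 "call_heatmap": outdir / "call_heatmap.png"}
    try:
        freq = pd.read_csv(call_files["frequency"], sep="\t", index_col=0)
        plots.frequency_plot(freq, acgh_map, fig_files["frequency_plot"])
        plots.call_heatmap(calls, fig_files["call_heatmap"])
        if "integrate" in outputs:
            binned_df = pd.read_csv(outputs["integrate"]["binned"], sep="\t", index_col=0)
            fig_files["binned_heatmap"] = outdir / "binned_correlation.png"
            plots.binned_correlation_heatmap(binned_df, fig_files["binned_heatmap"])
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc
    outputs[stage] = {k: str(v) for k, v in fig_files.items()}
    return outputs
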
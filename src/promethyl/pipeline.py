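"""End-to-end orchestration of the analysis stages from a single config.

``run_pipeline`` executes annotate -> normalize -> methylation ->
[chromatin] -> [expression] in order, writes every intermediate table
under the output directory and records a run manifest (parameter values,
input checksums, seed, stage versions). Outputs are pure functions of
(inputs, config): re-running with the same config reproduces byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from promethyl import __version__
from promethyl.annotation import (
    WindowSpec,
    assign_probes_to_windows,
    read_peaks_bed,
    read_probes,
    read_promoters,
    write_probes,
    write_promoters,
)
from promethyl.chromatin import (
    annotate_with_peaks,
    compose_states,
    score_chip_promoters,
    zscore_matrix,
)
from promethyl import expression as xpr
from promethyl.methylation import (
    MethylationConfig,
    aggregate_promoter_scores,
    call_differential,
    classify_trajectories,
    trajectory_heatmap_matrix,
)
from promethyl.normalization import loess_normalize, mad_scale
from promethyl.simulate import (
    GroundTruth,
    SimulationConfig,
    generate_annotation,
    generate_ground_truth,
    simulate_expression_arrays,
    simulate_map_arrays,
)

log = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "cutoff": 1.0,
    "min_probes": 3,
    "reference": "parent",
    "theta_chip": 1.0,
    "span": 0.3,
    "loess_iterations": 4,
    "fold": 3.0,
    "fdr": 0.05,
    "detection_percentile": 25.0,
    "window_core": [-500, 500],
    "window_upstream": [-1500, -500],
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config", "config must be a YAML mapping")
    return cfg


def default_config() -> dict:
    return {"seed": 0, "outdir": "promethyl_out", "params": dict(DEFAULT_PARAMS)}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def normalize_two_color(
    tables: dict[str, pd.DataFrame], params: dict, seed: int
) -> dict:
    rng = np.random.default_rng(seed)
    arrays = [
        loess_normalize(tbl, span=params["span"],
                        iterations=params["loess_iterations"], label=s, rng=rng)
        for s, tbl in tables.items()
    ]
    return {a.label: a for a in mad_scale(arrays)}


def stage_methylation(
    promoters: pd.DataFrame,
    probes: pd.DataFrame,
    map_tables: dict[str, pd.DataFrame],
    params: dict,
    seed: int,
) -> dict:
    spec = WindowSpec(tuple(params["window_core"]), tuple(params["window_upstream"]))
    assignment = assign_probes_to_windows(promoters, probes, spec)
    normalized = normalize_two_color(map_tables, params, seed)
    mcfg = MethylationConfig(
        cutoff=params["cutoff"], min_probes=params["min_probes"],
        reference=params["reference"],
    )
    scores = aggregate_promoter_scores(
        normalized, assignment, mcfg, promoter_order=list(promoters["gene_id"])
    )
    calls = call_differential(scores.core, mcfg)
    traj = classify_trajectories(calls, mcfg, scores=scores.core)
    heatmap = trajectory_heatmap_matrix(traj, calls)
    return {
        "assignment": assignment,
        "scores": scores,
        "calls": calls,
        "trajectories": traj,
        "heatmap": heatmap,
    }


def stage_chromatin(
    promoters: pd.DataFrame,
    probes: pd.DataFrame,
    chip_tables: dict[str, pd.DataFrame],
    peaks: dict[str, pd.DataFrame],
    de_novo_set: set,
    params: dict,
    seed: int,
) -> dict:
    spec = WindowSpec(tuple(params["window_core"]), tuple(params["window_upstream"]))
    out: dict = {}
    profile = None
    if chip_tables:
        assignment = assign_probes_to_windows(promoters, probes, spec)
        normalized = normalize_two_color(chip_tables, params, seed)
        profile = score_chip_promoters(
            normalized, assignment, theta_chip=params["theta_chip"],
            min_probes=params["min_probes"],
            promoter_order=list(promoters["gene_id"]),
        )
    if peaks:
        presence = annotate_with_peaks(promoters, peaks, spec)
        if profile is not None:
            profile.presence = presence
        out["presence"] = presence
    if profile is not None:
        out["profile"] = profile
        if de_novo_set and {"H3K27me3", "H3ac"} <= set(profile.marked.columns):
            out["composition"] = compose_states(de_novo_set, profile)
        zcols = profile.scores
        if "presence" in out:
            zcols = zcols.join(out["presence"].astype(float), how="left")
        out["zmatrix"] = zscore_matrix(zcols.fillna(0.0))
    return out


def stage_expression(
    probe_values: pd.DataFrame,
    conditions: pd.Series,
    probe_tx: pd.Series,
    params: dict,
) -> dict:
    matrix = xpr.summarize_transcripts(probe_values, probe_tx, conditions)
    stats_ = xpr.fit_contrasts(matrix)
    labels = xpr.assign_groups(
        stats_, matrix, fold_threshold=params["fold"],
        fdr_threshold=params["fdr"],
        detection_percentile=params["detection_percentile"],
    )
    return {"matrix": matrix, "stats": stats_, "groups": labels}


# ---------------------------------------------------------------------------
# runner
# ---------------------------------------------------------------------------

def _simulate_inputs(cfg: dict, outdir: Path, seed: int) -> dict:
    sim_opts = dict(cfg.get("simulate") or {})
    sim_opts.setdefault("seed", seed)
    scfg = SimulationConfig(**sim_opts)
    promoters, probes = generate_annotation(scfg)
    truth = generate_ground_truth(promoters, scfg)
    map_tables = simulate_map_arrays(probes, truth, scfg)

    # parental ChIP arrays for two modifications, marks independent of
    # methylation truth
    rng = np.random.default_rng(scfg.seed + 7)
    chip_tables = {}
    for i, mod in enumerate(("H3ac", "H3K27me3")):
        marked = rng.random(len(promoters)) < 0.15
        t = GroundTruth(
            promoters=pd.DataFrame(index=promoters["gene_id"]),
            true_scores=pd.DataFrame(
                {"parent": np.where(marked, scfg.effect_log2, 0.0)},
                index=promoters["gene_id"],
            ),
        )
        one = replace(scfg, samples=("parent",), seed=scfg.seed + 100 + i)
        chip_tables[mod] = simulate_map_arrays(probes, t, one)["parent"]

    arrays, sheet, probe_tx, expr_truth = simulate_expression_arrays(scfg)
    probe_values = pd.DataFrame(
        {row["array"]: arrays[row["array"]].set_index("probe_id")["intensity"]
         for _, row in sheet.iterrows()}
    )
    conditions = pd.Series(sheet["condition"].to_numpy(), index=sheet["array"].to_numpy())

    inputs_dir = outdir / "inputs"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    write_promoters(promoters, inputs_dir / "promoters.bed")
    write_probes(probes, inputs_dir / "probes.tsv")
    _write(truth.promoters, inputs_dir / "ground_truth_promoters.tsv")
    _write(expr_truth, inputs_dir / "ground_truth_transcripts.tsv")
    for s, tbl in map_tables.items():
        _write(tbl, inputs_dir / f"map_{s}.tsv", index=False)
    _write(sheet, inputs_dir / "expression_samples.tsv", index=False)

    return {
        "promoters": promoters,
        "probes": probes,
        "map_tables": map_tables,
        "chip_tables": chip_tables,
        "peaks": {},
        "probe_values": probe_values,
        "conditions": conditions,
        "probe_tx": probe_tx,
        "truth": truth,
    }


def _load_inputs(cfg: dict) -> dict:
    inputs: dict = {"chip_tables": {}, "peaks": {}, "map_tables": {}}
    inputs["promoters"] = read_promoters(cfg["annotation"])
    inputs["probes"] = read_probes(cfg["probes"])
    for s, path in (cfg.get("map_arrays") or {}).items():
        inputs["map_tables"][s] = pd.read_csv(path, sep="\t")
    for mod, path in (cfg.get("chip_arrays") or {}).items():
        inputs["chip_tables"][mod] = pd.read_csv(path, sep="\t")
    for mod, path in (cfg.get("peaks") or {}).items():
        inputs["peaks"][mod] = read_peaks_bed(path)
    if cfg.get("expression_arrays"):
        sheet = pd.read_csv(cfg["expression_sample_sheet"], sep="\t")
        tx_map = pd.read_csv(cfg["probe_to_transcript"], sep="\t")
        inputs["probe_tx"] = pd.Series(
            tx_map["transcript_id"].to_numpy(), index=tx_map["probe_id"].to_numpy()
        )
        cols = {}
        for _, row in sheet.iterrows():
            path = Path(cfg["expression_arrays"]) / f"{row['array']}.tsv"
            cols[row["array"]] = pd.read_csv(path, sep="\t").set_index("probe_id")["intensity"]
        inputs["probe_values"] = pd.DataFrame(cols)
        inputs["conditions"] = pd.Series(
            sheet["condition"].to_numpy(), index=sheet["array"].to_numpy()
        )
    return inputs


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages; returns the in-memory result bundle
    and writes all tables plus ``run_manifest.json`` under ``outdir``."""
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    params = {**DEFAULT_PARAMS, **(cfg.get("params") or {})}
    seed = int(cfg.get("seed", 0))
    outdir = Path(cfg.get("outdir", "promethyl_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    input_files = [
        cfg.get(k) for k in ("annotation", "probes", "expression_sample_sheet",
                             "probe_to_transcript")
        if cfg.get(k)
    ]
    for group in ("map_arrays", "chip_arrays", "peaks"):
        input_files.extend((cfg.get(group) or {}).values())
    for f in input_files:
        if not Path(f).exists():
            raise PipelineError("config", f"input file {f} does not exist")

    if cfg.get("simulate") is not None:
        inputs = _simulate_inputs(cfg, outdir, seed)
    else:
        try:
            inputs = _load_inputs(cfg)
        except KeyError as exc:
            raise PipelineError("annotate", f"missing config key {exc}") from exc

    results: dict = {}
    if inputs.get("map_tables"):
        try:
            meth = stage_methylation(
                inputs["promoters"], inputs["probes"], inputs["map_tables"],
                params, seed,
            )
        except Exception as exc:
            raise PipelineError("methylation", str(exc)) from exc
        results["methylation"] = meth
        _write(meth["scores"].core, outdir / "promoter_scores_core.tsv")
        _write(meth["scores"].upstream, outdir / "promoter_scores_upstream.tsv")
        _write(meth["calls"].calls, outdir / "differential_calls.tsv")
        _write(meth["trajectories"].table, outdir / "trajectories.tsv")
        _write(meth["heatmap"], outdir / "heatmap_matrix.tsv")

    if inputs.get("chip_tables") or inputs.get("peaks"):
        de_novo = (
            results["methylation"]["trajectories"].de_novo["union"]
            if "methylation" in results else set()
        )
        try:
            chrom = stage_chromatin(
                inputs["promoters"], inputs["probes"], inputs["chip_tables"],
                inputs["peaks"], de_novo, params, seed + 1,
            )
        except Exception as exc:
            raise PipelineError("chromatin", str(exc)) from exc
        results["chromatin"] = chrom
        if "profile" in chrom:
            _write(chrom["profile"].scores, outdir / "chip_scores.tsv")
        if "zmatrix" in chrom:
            _write(chrom["zmatrix"], outdir / "chromatin_zscores.tsv")
        if "composition" in chrom:
            comp = chrom["composition"]
            _write(
                pd.DataFrame(
                    {"count": comp.counts, "percentage": comp.percentages}
                ),
                outdir / "chromatin_composition.tsv",
            )
    else:
        log.info("chromatin stage skipped: no ChIP arrays or peak manifest configured")

    if inputs.get("probe_values") is not None and "probe_values" in inputs:
        try:
            expr = stage_expression(
                inputs["probe_values"], inputs["conditions"], inputs["probe_tx"], params
            )
        except Exception as exc:
            raise PipelineError("expression", str(exc)) from exc
        results["expression"] = expr
        _write(expr["matrix"].values, outdir / "expression_matrix.tsv")
        _write(expr["stats"].coef, outdir / "expression_coefficients.tsv")
        _write(expr["stats"].padj, outdir / "expression_fdr.tsv")
        _write(expr["groups"].rename("group").to_frame(), outdir / "expression_groups.tsv")

    manifest = {
        "version": __version__,
        "seed": seed,
        "params": params,
        "inputs": {str(f): _sha256(Path(f)) for f in input_files},
        "outputs": {
            p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
        },
        "stages": sorted(results.keys()),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
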
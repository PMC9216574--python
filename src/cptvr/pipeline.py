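"""End-to-end benchmark pipeline: simulate -> detect -> track -> retrack ->
evaluate -> invert, with all method variants run on the same image pair.

The three displacement-tracking variants compared throughout are

* ``cptv_filtered``  — strict cPTV followed by vector-median filtering,
  no retracking (the conventional baseline);
* ``cptvr_median``   — retracking with the plain median model vector;
* ``cptvr_ef``       — retracking continued with the adaptive
  enlargement factor.

The EF run resumes from the median run's fixed point (its initial
EF = 1 phase *is* the median algorithm), so the two share work.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .benchmark import Benchmark, BenchmarkConfig, make_benchmark
from .detection import detect_beads, detections_to_array
from .inversion import RegularizationSpec, interpolate_to_grid, reconstruct_traction
from .metrics import evaluate_truth_at, field_metrics, points_in_region
from .retracking import RetrackConfig, retrack_field, retrack_with_enlargement
from .tracking import TrackConfig, track_cptv, vector_median_filter

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_single_seed",
    "run_benchmark_suite",
    "pipeline_config_from_mapping",
]

METHODS = ("cptv_filtered", "cptvr_median", "cptvr_ef")


@dataclass
class PipelineConfig:
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    tracking: TrackConfig = field(default_factory=TrackConfig)
    retracking: RetrackConfig = field(default_factory=RetrackConfig)
    inversion_grid: int = 64
    inversion_lambda: float | None = None  # None -> L-curve selection
    missing_policy: str = "zero"
    run_inversion: bool = True
    output_dir: Path | None = None


@dataclass
class RunReport:
    seed: int
    displacement_metrics: dict  # method -> region -> metric dict
    traction_metrics: dict  # method -> region -> metric dict
    counts: dict  # method -> status counts
    iterations: dict
    wall_clock: float
    fields: dict | None = None  # method -> DisplacementField (in-memory only)
    benchmark: Benchmark | None = None


def _metric_dict(m) -> dict:
    return {"msd": m.msd, "accuracy": m.accuracy, "n": m.n_vectors}


def run_single_seed(config: PipelineConfig, seed: int) -> RunReport:
    """Run the full method comparison for one benchmark realization."""
    t0 = time.perf_counter()
    bench_cfg = BenchmarkConfig(**{**vars(config.benchmark), "seed": seed})
    bench = make_benchmark(bench_cfg)
    dets = detections_to_array(
        detect_beads(bench.ref_image, psf_sigma=bench_cfg.bead_sigma)
    )
    raw = track_cptv(bench.ref_image, bench.def_image, dets, config.tracking)
    filtered = vector_median_filter(
        raw,
        config.tracking.filter_radius,
        config.tracking.filter_threshold,
        config.tracking.filter_eps,
    )
    retrack_log: list = []
    median = retrack_field(
        bench.ref_image,
        bench.def_image,
        filtered,
        config.retracking,
        log=retrack_log,
    )
    ef = retrack_with_enlargement(
        bench.ref_image,
        bench.def_image,
        median,
        config.retracking,
        log=retrack_log,
        start_field_is_median_result=True,
    )
    fields = {"cptv_filtered": filtered, "cptvr_median": median, "cptvr_ef": ef}

    truth = evaluate_truth_at(bench, dets)
    disp_metrics: dict = {}
    for name, f in fields.items():
        disp_metrics[name] = {}
        for region in ("whole_field", "large_force", "small_force"):
            mask = bench.regions[region]
            if not points_in_region(f.origins, mask).any():
                continue
            m = field_metrics(
                f, truth, mask, config.missing_policy, region_label=region
            )
            disp_metrics[name][region] = _metric_dict(m)

    traction_metrics: dict = {}
    if config.run_inversion:
        traction_metrics = _traction_comparison(config, bench, fields)

    counts = {name: f.counts() for name, f in fields.items()}
    iterations = {
        "retrack_events": len(retrack_log),
        "median_sweeps": median.provenance.get("retrack", {}).get("sweeps"),
        "ef_escalations": ef.provenance.get("enlargement", {}).get("ef_escalations"),
        "final_ef": ef.provenance.get("enlargement", {}).get("final_ef"),
    }
    return RunReport(
        seed=seed,
        displacement_metrics=disp_metrics,
        traction_metrics=traction_metrics,
        counts=counts,
        iterations=iterations,
        wall_clock=time.perf_counter() - t0,
        fields=fields,
        benchmark=bench,
    )


def _traction_comparison(
    config: PipelineConfig, bench: Benchmark, fields: dict
) -> dict:
    """Reconstruct tractions from every variant and score them against the
    ground-truth traction on the inversion grid."""
    g = config.inversion_grid
    h, w = bench.config.shape
    stride = h // g
    # ground truth block-averaged onto the inversion grid
    truth_tx = bench.traction.tx.reshape(g, stride, g, stride).mean(axis=(1, 3))
    truth_ty = bench.traction.ty.reshape(g, stride, g, stride).mean(axis=(1, 3))
    truth_vec = np.column_stack([truth_tx.ravel(), truth_ty.ravel()])
    regions = {
        name: mask.reshape(g, stride, g, stride).any(axis=(1, 3)).ravel()
        for name, mask in bench.regions.items()
    }
    out: dict = {}
    for name, f in fields.items():
        ug, vg, spacing = interpolate_to_grid(f, (g, g), bench.config.shape)
        if config.inversion_lambda is None:
            reg = RegularizationSpec(selection="l_curve")
        else:
            reg = RegularizationSpec(lam=config.inversion_lambda)
        rec = reconstruct_traction(
            ug, vg, spacing, bench.config.material, reg, solver="fourier"
        )
        rec_vec = np.column_stack([rec.tx.ravel(), rec.ty.ravel()])
        out[name] = {}
        for region, rmask in regions.items():
            vg_r = truth_vec[rmask]
            vm_r = rec_vec[rmask]
            denom = np.hypot(vg_r[:, 0], vg_r[:, 1]).sum()
            if denom == 0:
                continue
            dev = np.hypot(vm_r[:, 0] - vg_r[:, 0], vm_r[:, 1] - vg_r[:, 1])
            gmean = np.hypot(vg_r[:, 0], vg_r[:, 1]).mean()
            out[name][region] = {
                "msd": float(dev.sum() / denom),
                "accuracy": float(np.mean(1.0 - dev / gmean)),
                "n": int(rmask.sum()),
            }
    return out


def pipeline_config_from_mapping(raw: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a parsed JSON/YAML mapping,
    validating keys with actionable error messages (e.g. a benchmark
    section without a Young's modulus reports ``benchmark.E``)."""
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = {"benchmark", "tracking", "retracking", "inversion_grid",
             "inversion_lambda", "missing_policy", "run_inversion"}
    for key in raw:
        if key not in known:
            raise ValueError(f"unknown config section '{key}' (expected {sorted(known)})")
    cfg = PipelineConfig()
    if "benchmark" in raw:
        section = dict(raw["benchmark"])
        allowed = set(vars(cfg.benchmark))
        for key in section:
            if key not in allowed:
                raise ValueError(f"unknown key 'benchmark.{key}'")
        for required in ("E", "nu"):
            if required not in section:
                raise ValueError(f"missing required key 'benchmark.{required}'")
        if "shape" in section:
            section["shape"] = tuple(section["shape"])
        cfg.benchmark = BenchmarkConfig(**section)
    for name, cls in (("tracking", TrackConfig), ("retracking", RetrackConfig)):
        if name in raw:
            section = dict(raw[name])
            allowed = set(vars(cls()))
            for key in section:
                if key not in allowed:
                    raise ValueError(f"unknown key '{name}.{key}'")
            setattr(cfg, name, cls(**section))
    for key in ("inversion_grid", "inversion_lambda", "missing_policy", "run_inversion"):
        if key in raw:
            setattr(cfg, key, raw[key])
    return cfg


def run_benchmark_suite(
    config: PipelineConfig | None = None,
    seeds: tuple[int, ...] = (0, 1, 2),
) -> dict:
    """Run the comparison over several benchmark seeds and aggregate.

    Returns a report dict with per-seed metrics and across-seed means of
    the large-force-region accuracies of the three variants."""
    cfg = config if config is not None else PipelineConfig()
    reports = [run_single_seed(cfg, s) for s in seeds]
    summary: dict = {"seeds": list(seeds), "per_seed": [], "mean_accuracy": {}}
    for rep in reports:
        summary["per_seed"].append(
            {
                "seed": rep.seed,
                "displacement": rep.displacement_metrics,
                "traction": rep.traction_metrics,
                "counts": rep.counts,
                "iterations": rep.iterations,
                "wall_clock": rep.wall_clock,
            }
        )
    for method in METHODS:
        accs = [
            rep.displacement_metrics[method]["large_force"]["accuracy"]
            for rep in reports
            if "large_force" in rep.displacement_metrics.get(method, {})
        ]
        if accs:
            summary["mean_accuracy"][method] = float(np.mean(accs))
    if cfg.output_dir is not None:
        _write_outputs(cfg, reports, summary)
    return summary


def _write_outputs(config: PipelineConfig, reports, summary) -> None:
    from . import io as cio

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_metrics(out / "summary.json", summary)
    for rep in reports:
        d = out / f"seed_{rep.seed}"
        d.mkdir(exist_ok=True)
        if rep.benchmark is not None:
            cio.write_image(d / "ref.tif", rep.benchmark.ref_image.astype(np.float32))
            cio.write_image(d / "def.tif", rep.benchmark.def_image.astype(np.float32))
        if rep.fields:
            for name, f in rep.fields.items():
                cio.write_field(d / f"{name}.csv", f)
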
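"""End-to-end benchmark experiments: simulate -> filter -> localize -> evaluate.

The experiment runner sweeps a grid of simulation parameters (brightness,
blinking rates, replicate seeds), builds one synthetic-background movie per
grid point, and evaluates single-molecule detection without filtering, after
temporal Fourier filtering at each requested threshold, and optionally after
sliding-median background subtraction.  Per-pixel background noise is tied to
the signal brightness through ``sd_ratio`` (per-pixel temporal SD =
``b_mean / sd_ratio``), matching the regime where the mean brightness exceeds
the background SD several-fold.

Detection thresholds are re-tuned for every filtering threshold: the frame
statistics of a filtered stack differ drastically from the raw movie, so a
single constant would serve neither regime.  The documented policy measures
TPR and FDR for a fixed grid of thresholds on a leading block of frames of
the (filtered) movie against its own ground truth -- the simulation-study
analogue of adjusting localizer settings per threshold -- picks the most
sensitive threshold that reaches the low-FDR regime (FDR <= 0.5) or, when
none does, the most sensitive threshold overall, and then scores the full
movie with the selected value.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import (
    DEFAULT_MATCH_RADIUS_NM,
    EvaluationCounts,
    compute_fdr,
    compute_tpr,
    localization_errors,
    match_tables,
)
from .filtering import FilterConfig, highpass_filter_stack, median_filter_subtract
from .localize import DetectorParams, localize_stack
from .simulate import SimulationParams, generate_synthetic_background, simulate_movie
from .stack import ImageStack, ParameterError

__all__ = [
    "ExperimentConfig",
    "select_threshold_k",
    "run_grid_point",
    "run_experiment",
    "compare_median_baseline",
    "benchmark_config",
    "dim_limit_config",
]

log = logging.getLogger(__name__)

#: Candidate detection thresholds for the per-threshold tuning policy.
DEFAULT_K_GRID = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 7.0, 8.0, 10.0)
#: The low-FDR regime is adopted only if it keeps at least this fraction of
#: the sensitivity attainable on the movie; beyond that cut an acquisition
#: would have to be impractically long to accumulate a reconstruction.
MIN_SENSITIVITY_FRACTION = 1 / 3


@dataclass
class ExperimentConfig:
    """Parameter grid and policies for one benchmark experiment."""

    b_mean_grid: tuple = (500.0, 750.0, 1000.0)
    tau_on_grid: tuple = (3.0, 11.0)
    tau_off_multiplier: float = 60.0
    density: float = 2.0
    omega_grid: tuple = (0.0, 60.0, 80.0, 90.0)
    methods: tuple = ("fourier",)
    n_frames: int = 2000
    shape: tuple = (64, 64)
    pixel_size: float = 160.0
    sigma_psf: float = 160.0
    seeds: tuple = (1, 2, 3)
    sd_ratio: float = 4.0
    mean_level_factor: float = 8.0
    bleach_tau: float = 50_000.0
    median_window: int = 2000
    radius: float = DEFAULT_MATCH_RADIUS_NM
    k_grid: tuple = DEFAULT_K_GRID
    tune_frames: int = 120
    detector: DetectorParams = field(default_factory=DetectorParams)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.b_mean_grid or not self.tau_on_grid or not self.omega_grid:
            raise ParameterError("all parameter grids must be non-empty")
        if not self.seeds:
            raise ParameterError("need at least one seed")
        for m in self.methods:
            if m not in ("fourier", "median"):
                raise ParameterError(f"unknown method {m!r}")

    @classmethod
    def from_yaml_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        det = raw.pop("detector", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if det:
            cfg = replace(cfg, detector=DetectorParams(**det))
        return cfg


def _rates(counts: EvaluationCounts) -> tuple[float, float]:
    tpr = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    fdr = counts.fp / (counts.tp + counts.fp) if counts.tp + counts.fp else 1.0
    return tpr, fdr


def _choose_threshold(rows: list[tuple[float, float, float]]) -> float:
    """Threshold-selection rule over measured ``(k, tpr, fdr)`` rows.

    Preferred regime: FDR <= 0.5 (detections mostly real -- the regime a
    practitioner actually operates in).  The most sensitive threshold in that
    regime wins.  When no threshold reaches it, the analysis is
    false-positive-bound no matter what (the typical situation without
    temporal filtering) and the most sensitive threshold overall wins.  Ties
    break toward the higher threshold (fewer spurious fits for the same
    sensitivity).  A low-FDR operating point only counts if it retains at
    least ``MIN_SENSITIVITY_FRACTION`` of the best sensitivity any threshold
    achieves on this movie: a "clean" setting that sacrifices most of the
    localization yield would need an impractically long acquisition to build
    a reconstruction, so no practitioner would choose it.
    """
    best_tpr = max(r[1] for r in rows)
    feasible = [
        r for r in rows
        if r[2] <= 0.5 and r[1] >= MIN_SENSITIVITY_FRACTION * best_tpr and r[1] > 0
    ]
    if feasible:
        return max(feasible, key=lambda r: (r[1], r[0]))[0]
    return max(rows, key=lambda r: (r[1], r[0]))[0]


def select_threshold_k(
    stack: ImageStack,
    truth: pd.DataFrame,
    detector: DetectorParams,
    k_grid=DEFAULT_K_GRID,
    tune_frames: int = 120,
    radius: float = DEFAULT_MATCH_RADIUS_NM,
) -> float:
    """Pick ``threshold_k`` on a leading block of frames of a (filtered) movie.

    The block is localized once at the most permissive candidate threshold;
    higher thresholds are evaluated by discarding localizations whose recorded
    ``peak_snr`` falls below them (the detection criterion is exactly a
    ``peak_snr`` cut, so this reproduces a per-threshold rerun up to the
    per-frame candidate cap).  The selection rule is documented in
    :func:`_choose_threshold`.  The stack passed in must already be filtered
    the way the full run will be.
    """
    n = min(tune_frames, stack.n_frames)
    block = stack.with_data(stack.data[:n])
    truth_block = truth[truth["frame"] < n]
    k_min = min(k_grid)
    locs = localize_stack(block, replace(detector, threshold_k=k_min))
    rows = []
    for k in sorted(k_grid):
        subset = locs if k == k_min else locs[locs["peak_snr"] > k]
        tpr, fdr = _rates(match_tables(subset, truth_block, radius))
        rows.append((k, tpr, fdr))
    return _choose_threshold(rows)


def _evaluate_variant(
    stack: ImageStack,
    truth: pd.DataFrame,
    cfg: ExperimentConfig,
) -> dict:
    k = select_threshold_k(
        stack, truth, cfg.detector, cfg.k_grid, cfg.tune_frames, cfg.radius
    )
    locs = localize_stack(stack, replace(cfg.detector, threshold_k=k))
    counts = match_tables(locs, truth, cfg.radius)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tpr, fdr = compute_tpr(counts), compute_fdr(counts)
    err = localization_errors(counts)
    return {
        "tpr": tpr,
        "fdr": fdr,
        "mean_error_nm": err["mean_nm"],
        "median_error_nm": err["median_nm"],
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
        "n_truth": counts.tp + counts.fn,
        "n_locs": counts.tp + counts.fp,
        "threshold_k": k,
    }


def run_grid_point(
    cfg: ExperimentConfig, b_mean: float, tau_on: float, seed: int
):
    """Simulate the movie for one grid point; returns (movie, truth table).

    The RNG is seeded from (seed, grid coordinates) so every cell can be
    reproduced in isolation.
    """
    rng = np.random.default_rng(
        [int(seed), int(round(b_mean)), int(round(10 * tau_on))]
    )
    temporal_std = b_mean / cfg.sd_ratio
    background, roi = generate_synthetic_background(
        cfg.shape,
        cfg.n_frames,
        mean_level=cfg.mean_level_factor * temporal_std,
        temporal_std=temporal_std,
        bleach_tau=cfg.bleach_tau,
        rng=rng,
        pixel_size=cfg.pixel_size,
    )
    params = SimulationParams(
        b_mean=b_mean,
        tau_on=tau_on,
        tau_off=cfg.tau_off_multiplier * tau_on,
        density=cfg.density,
        sigma_psf=cfg.sigma_psf,
        n_frames=cfg.n_frames,
        pixel_size=cfg.pixel_size,
    )
    return simulate_movie(params, background, roi, rng)


def _variants(cfg: ExperimentConfig):
    if "fourier" in cfg.methods:
        for omega in cfg.omega_grid:
            yield ("fourier", float(omega))
    if "median" in cfg.methods:
        yield ("median", float("nan"))


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run the full grid; returns one tidy row per grid point x variant.

    A failure in one variant is recorded (``error`` column) and the run
    continues.  When ``cfg.out_dir`` is set, ``results.csv`` and
    ``summary.json`` are written there.
    """
    rows = []
    for b_mean, tau_on, seed in product(cfg.b_mean_grid, cfg.tau_on_grid, cfg.seeds):
        t0 = time.perf_counter()
        movie, truth = run_grid_point(cfg, b_mean, tau_on, seed)
        log.info(
            "simulated B=%g tau_on=%g seed=%d: %d truth rows (%.1fs)",
            b_mean, tau_on, seed, len(truth), time.perf_counter() - t0,
        )
        for method, omega in _variants(cfg):
            base = {
                "b_mean": b_mean,
                "tau_on": tau_on,
                "tau_off": cfg.tau_off_multiplier * tau_on,
                "density": cfg.density,
                "sd_ratio": cfg.sd_ratio,
                "seed": seed,
                "method": method,
                "omega_t": omega,
                "window": cfg.median_window if method == "median" else np.nan,
            }
            t0 = time.perf_counter()
            try:
                if method == "median":
                    stack = median_filter_subtract(movie, cfg.median_window)
                elif omega == 0:
                    stack = movie
                else:
                    stack = highpass_filter_stack(movie, FilterConfig(omega_t=omega))
                base.update(_evaluate_variant(stack, truth, cfg))
                base["error"] = ""
            except Exception as exc:  # keep sweeping the rest of the grid
                log.exception("grid point failed: %s", base)
                base["error"] = f"{type(exc).__name__}: {exc}"
            base["elapsed_s"] = time.perf_counter() - t0
            log.info(
                "%s omega=%s: TPR=%.3f FDR=%.3f k=%s (%.1fs)",
                method, omega, base.get("tpr", np.nan), base.get("fdr", np.nan),
                base.get("threshold_k"), base["elapsed_s"],
            )
            rows.append(base)
    results = pd.DataFrame(rows)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        summary = (
            results[results["error"] == ""]
            .groupby(["method", "omega_t"], dropna=False)[["tpr", "fdr", "mean_error_nm"]]
            .mean()
            .reset_index()
            .to_dict(orient="records")
        )
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return results


def compare_median_baseline(cfg: ExperimentConfig, omega_t: float = 80.0) -> pd.DataFrame:
    """Paired Fourier (at ``omega_t``) vs sliding-median comparison.

    Both methods see identical movies and seeds; returns the tidy table with
    one row per method per grid point.
    """
    paired = replace(cfg, methods=("fourier", "median"), omega_grid=(omega_t,))
    return run_experiment(paired)


def benchmark_config(seeds=(1, 2, 3), **overrides) -> ExperimentConfig:
    """The scaled-down threshold-sweep study configuration.

    64 x 64 px, 2000 frames, brightness grid 500-1000 counts with background
    SD = B/4, short and long on-times, off-times 60x the on-time, 2 emitters
    per um^2.
    """
    return ExperimentConfig(seeds=tuple(seeds), **overrides)


def dim_limit_config(seeds=(1, 2, 3), **overrides) -> ExperimentConfig:
    """The hardest tested setting: dim emitters on the noisiest background.

    B = 500 counts with background SD = B/3, brief blinks (tau_on = 3 frames)
    separated by very long dark times (tau_off = 100 tau_on); evaluated
    unfiltered and at the recommended threshold of 80%.
    """
    defaults = dict(
        b_mean_grid=(500.0,),
        tau_on_grid=(3.0,),
        tau_off_multiplier=100.0,
        sd_ratio=3.0,
        omega_grid=(0.0, 80.0),
        seeds=tuple(seeds),
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)
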
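"""Detection benchmarking against ground truth: TPR, FDR, positional accuracy.

A detected localization with a ground-truth counterpart within a matching
radius (default 160 nm) is a true positive; unmatched detections are false
positives and unmatched ground-truth entries false negatives.  Matching is
one-to-one and greedy in order of increasing distance -- the standard
assignment heuristic at SMLM densities, validated against a brute-force
maximum-cardinality oracle in the test suite.  Because true negatives are
undefined for point detection in images, performance is summarised by the
pair (TPR, FDR) rather than a conventional ROC:

    TPR = TP / (TP + FN)        FDR = FP / (FP + TP)

Ground truth is per frame: a molecule that is on for five frames contributes
five reference entries, and each frame is matched independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .filtering import FilterConfig, highpass_filter_stack
from .localize import DetectorParams, localize_stack
from .stack import ImageStack, ParameterError

__all__ = [
    "EvaluationCounts",
    "DEFAULT_MATCH_RADIUS_NM",
    "match_frame",
    "match_tables",
    "compute_tpr",
    "compute_fdr",
    "localization_errors",
    "omega_sweep",
]

#: Matching radius in nm (one PSF sigma).
DEFAULT_MATCH_RADIUS_NM = 160.0


@dataclass
class EvaluationCounts:
    """TP/FP/FN tallies with the distance of every matched pair (nm)."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    match_distances: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.match_distances = np.asarray(self.match_distances, dtype=np.float64)
        if min(self.tp, self.fp, self.fn) < 0:
            raise ParameterError("counts must be >= 0")
        if self.match_distances.size != self.tp:
            raise ParameterError("need exactly one match distance per TP")

    def __add__(self, other: "EvaluationCounts") -> "EvaluationCounts":
        return EvaluationCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            np.concatenate([self.match_distances, other.match_distances]),
        )


def match_frame(
    detections: np.ndarray,
    truth: np.ndarray,
    radius: float = DEFAULT_MATCH_RADIUS_NM,
) -> EvaluationCounts:
    """One-to-one matching of detections to ground truth within one frame.

    ``detections`` and ``truth`` are ``(n, 2)`` arrays of (x, y) positions in
    nm.  Candidate pairs within ``radius`` are matched greedily in order of
    increasing distance (ties broken by detection then truth index), each
    point used at most once.
    """
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    det = np.asarray(detections, dtype=np.float64).reshape(-1, 2)
    tru = np.asarray(truth, dtype=np.float64).reshape(-1, 2)
    if det.shape[0] == 0 or tru.shape[0] == 0:
        return EvaluationCounts(tp=0, fp=det.shape[0], fn=tru.shape[0])
    dist = cdist(det, tru)
    di, tj = np.nonzero(dist <= radius)
    order = np.lexsort((tj, di, dist[di, tj]))
    det_used = np.zeros(det.shape[0], dtype=bool)
    tru_used = np.zeros(tru.shape[0], dtype=bool)
    distances = []
    for k in order:
        i, j = di[k], tj[k]
        if det_used[i] or tru_used[j]:
            continue
        det_used[i] = True
        tru_used[j] = True
        distances.append(dist[i, j])
    tp = len(distances)
    return EvaluationCounts(
        tp=tp,
        fp=det.shape[0] - tp,
        fn=tru.shape[0] - tp,
        match_distances=np.asarray(distances),
    )


def match_tables(
    locs: pd.DataFrame,
    truth: pd.DataFrame,
    radius: float = DEFAULT_MATCH_RADIUS_NM,
) -> EvaluationCounts:
    """Aggregate :func:`match_frame` over all frames of two tables.

    Both tables need ``frame``, ``x_nm`` and ``y_nm`` columns; frames present
    in only one table contribute pure FPs or FNs.
    """
    total = EvaluationCounts()
    loc_groups = {f: g[["x_nm", "y_nm"]].to_numpy() for f, g in locs.groupby("frame")}
    tru_groups = {f: g[["x_nm", "y_nm"]].to_numpy() for f, g in truth.groupby("frame")}
    for f in sorted(set(loc_groups) | set(tru_groups)):
        total = total + match_frame(
            loc_groups.get(f, np.empty((0, 2))),
            tru_groups.get(f, np.empty((0, 2))),
            radius,
        )
    return total


def compute_tpr(counts: EvaluationCounts) -> float:
    """TP / (TP + FN); NaN (with a warning) when there is no ground truth."""
    denom = counts.tp + counts.fn
    if denom == 0:
        warnings.warn("TPR undefined: no ground-truth entries", stacklevel=2)
        return float("nan")
    return counts.tp / denom


def compute_fdr(counts: EvaluationCounts) -> float:
    """FP / (FP + TP); NaN (with a warning) when there are no detections."""
    denom = counts.tp + counts.fp
    if denom == 0:
        warnings.warn("FDR undefined: no detections", stacklevel=2)
        return float("nan")
    return counts.fp / denom


def localization_errors(counts: EvaluationCounts, bin_width_nm: float = 10.0) -> dict:
    """Summary of the matched-pair distances (positional accuracy, nm)."""
    d = counts.match_distances
    if d.size == 0:
        return {"n": 0, "mean_nm": float("nan"), "median_nm": float("nan"),
                "hist_counts": np.empty(0, dtype=int), "hist_edges_nm": np.empty(0)}
    edges = np.arange(0.0, d.max() + bin_width_nm, bin_width_nm)
    hist, edges = np.histogram(d, bins=edges if edges.size > 1 else 2)
    return {
        "n": int(d.size),
        "mean_nm": float(d.mean()),
        "median_nm": float(np.median(d)),
        "hist_counts": hist,
        "hist_edges_nm": edges,
    }


def omega_sweep(
    movie: ImageStack,
    truth: pd.DataFrame,
    omega_grid,
    detector: DetectorParams | None = None,
    *,
    detector_for_omega=None,
    radius: float = DEFAULT_MATCH_RADIUS_NM,
) -> pd.DataFrame:
    """Filter/localize/evaluate the same movie over a grid of thresholds.

    ``omega_t = 0`` is the unfiltered reference (no transform, no offset).
    ``detector_for_omega`` may be a mapping or callable giving a
    :class:`DetectorParams` per threshold; otherwise ``detector`` is used for
    every threshold.  Returns one row per threshold with TPR, FDR, mean match
    distance and the raw tallies.
    """
    if detector is None:
        detector = DetectorParams()
    rows = []
    for omega in omega_grid:
        if not (0 <= omega < 100):
            raise ParameterError(f"omega_t must be in [0, 100); got {omega}")
        if detector_for_omega is None:
            det_params = detector
        elif callable(detector_for_omega):
            det_params = detector_for_omega(omega)
        else:
            det_params = detector_for_omega.get(omega, detector)
        if omega == 0:
            filtered = movie
        else:
            filtered = highpass_filter_stack(movie, FilterConfig(omega_t=omega))
        locs = localize_stack(filtered, det_params)
        counts = match_tables(locs, truth, radius)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tpr, fdr = compute_tpr(counts), compute_fdr(counts)
        err = localization_errors(counts)
        rows.append(
            {
                "omega_t": float(omega),
                "tpr": tpr,
                "fdr": fdr,
                "mean_error_nm": err["mean_nm"],
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "n_locs": counts.tp + counts.fp,
                "threshold_k": det_params.threshold_k,
            }
        )
    return pd.DataFrame(rows)
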
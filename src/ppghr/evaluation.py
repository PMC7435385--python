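"""Agreement between estimated and reference heart rate.

MAE = (1/N) Σ |HR_est(n) − HR_ref(n)| and RMSE = √((1/N) Σ (HR_est − HR_ref)²)
over epochs on a common grid; RMSE is more sensitive to occasional large
errors. Overall accuracy is 100·(1 − mean relative absolute error).
Wavelet-order comparisons report per-segment MAE/RMSE per order with paired
two-sided Wilcoxon signed-rank tests across segments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ppghr.pulse import HRSeries
from ppghr.signal_io import BeatReference, SampledSignal

__all__ = [
    "EvalReport",
    "align_reference",
    "mae",
    "rmse",
    "accuracy",
    "evaluate",
    "compare_wavelets",
    "paired_pvalues",
    "epoch_mask_overlap",
]


@dataclass(frozen=True)
class EvalReport:
    """Summary of HR-estimation agreement against a reference."""

    mae: float  # bpm
    rmse: float  # bpm
    accuracy_pct: float
    per_epoch_errors: np.ndarray  # bpm, est - ref
    n_epochs: int

    def __post_init__(self) -> None:
        if not (self.mae >= 0 and self.rmse >= self.mae - 1e-12):
            raise ValueError("need rmse >= mae >= 0")
        if self.accuracy_pct > 100:
            raise ValueError("accuracy cannot exceed 100%")
        object.__setattr__(self, "per_epoch_errors", np.asarray(self.per_epoch_errors, dtype=float))

    def to_json(self) -> str:
        return json.dumps(
            {
                "mae_bpm": self.mae,
                "rmse_bpm": self.rmse,
                "accuracy_pct": self.accuracy_pct,
                "n_epochs": self.n_epochs,
                "per_epoch_errors_bpm": self.per_epoch_errors.tolist(),
            }
        )


def _check_grids(est: HRSeries, ref: HRSeries) -> None:
    if not est.same_grid(ref):
        raise ValueError("estimated and reference HR series are on different epoch grids")


def align_reference(
    ref: BeatReference,
    total_duration_s: float,
    window_s: float = 60.0,
    hop_s: float = 30.0,
    t0: float = 0.0,
) -> HRSeries:
    """Project a beat-time or HR reference onto the estimation epoch grid.

    Beat times are counted per half-open window exactly like the PPG
    estimate (count × 60/window_s); an HR series is linearly interpolated
    at the epoch centers. The reference must cover the epoch span.
    """
    n_epochs = int(np.floor((total_duration_s - window_s) / hop_s)) + 1
    if n_epochs < 1:
        raise ValueError("recording shorter than one window")
    starts = t0 + hop_s * np.arange(n_epochs)
    centers = starts + window_s / 2
    span_end = starts[-1] + window_s
    if ref.beat_times is not None:
        bt = ref.beat_times
        # coverage: allow a couple of seconds of slack for the final inter-beat gap
        if bt.size == 0 or bt[-1] < span_end - max(2.0, 0.1 * window_s):
            raise ValueError("beat reference ends before the epoch span")
        bpm = np.array(
            [np.count_nonzero((bt >= s) & (bt < s + window_s)) * 60.0 / window_s for s in starts]
        )
    else:
        ts, hr = ref.hr_series[:, 0], ref.hr_series[:, 1]
        if ts[-1] < centers[-1] or ts[0] > centers[0]:
            raise ValueError("HR reference series does not cover the epoch centers")
        bpm = np.interp(centers, ts, hr)
    return HRSeries(centers, bpm, window_s, hop_s)


def mae(hr_est: HRSeries, hr_ref: HRSeries) -> float:
    """Mean absolute per-epoch HR difference, bpm."""
    _check_grids(hr_est, hr_ref)
    return float(np.mean(np.abs(hr_est.bpm - hr_ref.bpm)))


def rmse(hr_est: HRSeries, hr_ref: HRSeries) -> float:
    """Root mean squared per-epoch HR difference, bpm."""
    _check_grids(hr_est, hr_ref)
    return float(np.sqrt(np.mean((hr_est.bpm - hr_ref.bpm) ** 2)))


def accuracy(hr_est: HRSeries, hr_ref: HRSeries, method: str = "relative") -> float:
    """Overall accuracy in percent.

    ``"relative"`` (default): 100 × (1 − mean(|est − ref| / ref)).
    ``"within5"``: percentage of epochs with |est − ref| ≤ 5 bpm.
    """
    _check_grids(hr_est, hr_ref)
    if method == "relative":
        if np.any(hr_ref.bpm <= 0):
            raise ValueError("reference bpm must be positive for relative accuracy")
        return float(100.0 * (1.0 - np.mean(np.abs(hr_est.bpm - hr_ref.bpm) / hr_ref.bpm)))
    if method == "within5":
        return float(100.0 * np.mean(np.abs(hr_est.bpm - hr_ref.bpm) <= 5.0))
    raise ValueError(f"unknown accuracy method {method!r}")


def evaluate(hr_est: HRSeries, hr_ref: HRSeries) -> EvalReport:
    """Full agreement report: MAE, RMSE, accuracy and per-epoch errors."""
    errors = hr_est.bpm - hr_ref.bpm
    return EvalReport(
        mae=mae(hr_est, hr_ref),
        rmse=rmse(hr_est, hr_ref),
        accuracy_pct=accuracy(hr_est, hr_ref),
        per_epoch_errors=errors,
        n_epochs=len(hr_est),
    )


def compare_wavelets(
    signal: SampledSignal,
    reference: BeatReference,
    orders=(2, 4, 6),
    segment_s: float = 60.0,
    config=None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-segment HR error by wavelet order, with paired significance tests.

    Runs the full estimation pipeline once per DOG order on each
    ``segment_s`` segment of the recording, computes segment-wise MAE and
    RMSE against the reference, and summarises mean ± sd per order. With at
    least 6 segments, pairwise two-sided Wilcoxon signed-rank tests across
    segments are reported; with fewer, the p-value table is None and a
    warning is raised.

    Returns ``(summary, pvalues)`` DataFrames.
    """
    from ppghr.pipeline import PipelineConfig, estimate_hr
    from ppghr.signal_io import segment_signal

    base = config or PipelineConfig()
    # epoch grid within a segment: windows shorter than the segment
    window_s = min(base.window_s, segment_s / 2)
    hop_s = window_s / 2
    segments = segment_signal(signal, segment_s)

    rows = []
    per_segment: dict[int, dict[str, list[float]]] = {m: {"mae": [], "rmse": []} for m in orders}
    for seg in segments:
        t0 = seg.signal.t0
        ref_hr = align_reference(reference, segment_s, window_s, hop_s, t0=t0)
        for m in orders:
            cfg = base.replace(wavelet_order=m, window_s=window_s, hop_s=hop_s)
            res = estimate_hr(seg.signal, cfg)
            per_segment[m]["mae"].append(mae(res.hr, ref_hr))
            per_segment[m]["rmse"].append(rmse(res.hr, ref_hr))
    for m in orders:
        rows.append(
            {
                "order": m,
                "mae_mean": np.mean(per_segment[m]["mae"]),
                "mae_sd": np.std(per_segment[m]["mae"], ddof=1) if len(segments) > 1 else 0.0,
                "rmse_mean": np.mean(per_segment[m]["rmse"]),
                "rmse_sd": np.std(per_segment[m]["rmse"], ddof=1) if len(segments) > 1 else 0.0,
                "n_segments": len(segments),
            }
        )
    summary = pd.DataFrame(rows).set_index("order")

    if len(segments) < 6:
        warnings.warn(
            f"only {len(segments)} segments: too few for paired tests, p-values omitted",
            stacklevel=2,
        )
        return summary, None
    return summary, paired_pvalues(per_segment, orders)


def paired_pvalues(per_segment: dict, orders=(2, 4, 6)) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon signed-rank tests on per-segment errors.

    ``per_segment`` maps each wavelet order to ``{"mae": [...], "rmse": [...]}``
    lists indexed by segment. Identical error vectors are reported as p = 1
    (no evidence of a difference; the signed-rank statistic is undefined
    when every pair ties).
    """
    pv_rows = []
    orders = list(orders)
    for i, m1 in enumerate(orders):
        for m2 in orders[i + 1 :]:
            for metric in ("mae", "rmse"):
                a = np.asarray(per_segment[m1][metric], dtype=float)
                b = np.asarray(per_segment[m2][metric], dtype=float)
                if np.allclose(a, b):
                    p = 1.0
                else:
                    p = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
                pv_rows.append({"order_a": m1, "order_b": m2, "metric": metric, "p_value": p})
    return pd.DataFrame(pv_rows)


def epoch_mask_overlap(
    mask: np.ndarray,
    fs: float,
    window_s: float = 60.0,
    hop_s: float = 30.0,
    t0: float = 0.0,
) -> np.ndarray:
    """Fraction of artifact-contaminated samples per sliding epoch.

    Projects a per-sample boolean artifact mask onto the HR epoch grid so
    estimation error can be stratified into clean (overlap 0) and
    contaminated epochs.
    """
    mask = np.asarray(mask, dtype=bool)
    total_duration_s = mask.size / fs
    n_epochs = int(np.floor((total_duration_s - window_s) / hop_s)) + 1
    if n_epochs < 1:
        raise ValueError("mask shorter than one window")
    out = np.empty(n_epochs)
    for j in range(n_epochs):
        i0 = int(round((j * hop_s) * fs))
        i1 = int(round((j * hop_s + window_s) * fs))
        out[j] = mask[i0:i1].mean()
    return out
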
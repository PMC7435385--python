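"""Per-segment PPG signal-quality indices.

Three indices assess how usable a PPG segment is for pulse extraction:

* Perfusion (PSQI): pulsatile range of the filtered signal relative to the
  raw signal's static (DC) level, in percent — the field's gold-standard
  quality measure.
* Skewness (SSQI): third standardised moment of the signal; clean pulse
  segments are near-symmetric while corrupted ones skew.
* Signal-to-noise (SNSQI): variance of the absolute signal over the noise
  variance, with the noise taken as the residual after cardiac
  reconstruction — the only noise reference the pipeline itself provides.

All moments use population (1/N) estimators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from ppghr.signal_io import SampledSignal

__all__ = ["SQIReport", "psqi", "ssqi", "snsqi", "estimate_noise"]


@dataclass(frozen=True)
class SQIReport:
    """Quality indices for one analysis segment."""

    segment_index: int
    psqi: float  # percent
    ssqi: float  # dimensionless
    snsqi: float  # variance ratio

    def __post_init__(self) -> None:
        if self.psqi < 0 or self.snsqi < 0:
            raise ValueError("psqi and snsqi must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def psqi(raw: SampledSignal, filtered: SampledSignal) -> float:
    """Perfusion index: [(Xmax − Xmin)/|x̄|] × 100.

    ``raw`` must be the PRE-normalisation signal — its mean is the static
    blood-flow level; ``filtered`` supplies the pulsatile range.
    """
    if len(raw) != len(filtered):
        raise ValueError("raw and filtered must have equal lengths")
    mean_raw = float(np.mean(raw.values))
    if abs(mean_raw) <= 1e-12:
        raise ValueError(
            "raw signal has (near-)zero mean; pass the un-normalised raw PPG, "
            "not a normalised or filtered one"
        )
    return float(np.ptp(filtered.values) / abs(mean_raw) * 100.0)


def ssqi(signal: SampledSignal) -> float:
    """Skewness index: (1/N) Σ [(xₙ − μ̂)/σ]³ with population moments."""
    x = signal.values
    if x.size < 3:
        raise ValueError("need at least 3 samples for skewness")
    if np.var(x) == 0:
        raise ValueError("degenerate signal: zero variance")
    return float(stats.skew(x, bias=True))


def snsqi(signal: SampledSignal, noise: SampledSignal) -> float:
    """Signal-to-noise index: σ²(|x|) / σ²(noise).

    The numerator is the variance of the absolute value of the (pulsatile)
    signal; the denominator the plain variance of the noise estimate.
    """
    var_noise = float(np.var(noise.values))
    if var_noise == 0:
        raise ValueError("noise estimate has zero variance")
    return float(np.var(np.abs(signal.values)) / var_noise)


def estimate_noise(filtered: SampledSignal, cardiac: SampledSignal) -> SampledSignal:
    """Noise estimate: residual of the filtered PPG after removing the
    reconstructed cardiac (pulsatile) component."""
    if len(filtered) != len(cardiac):
        raise ValueError("filtered and cardiac must have equal lengths")
    return filtered.with_values(filtered.values - cardiac.values)
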
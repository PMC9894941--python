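"""Rule-based LH pulse-peak detection.

Implements the three-criterion peak rule used for serial tail-tip LH
profiles sampled every 5 min for 2 h (a DynPeak-style rule set):

1. the peak value rises by more than ``rise_frac`` (default 20%) over at
   least one of the preceding ``lookback`` samples;
2. the peak value is followed by a decrease of more than ``fall_frac``
   (default 10%) in at least one of the next ``lookahead`` samples;
3. the pulse amplitude — peak value minus the preceding nadir, the lowest
   of the ``nadir_window`` (default 3) preceding values — is at least
   ``min_amplitude`` (default 0.320 ng/mL, the assay sensitivity).

Candidate peaks are interior local maxima; for plateaus of equal maxima
only the leftmost plateau sample is a candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "LHProfile",
    "DetectionParams",
    "PulsePeak",
    "PulseSummary",
    "find_candidate_peaks",
    "passes_rise",
    "passes_fall",
    "compute_nadir",
    "detect_pulses",
    "summarize_profile",
]


@dataclass(frozen=True)
class LHProfile:
    """One animal's serial LH measurements.

    times are minutes (strictly increasing), values are concentrations in
    ng/mL. Uniform 5-min spacing is expected but not required; non-uniform
    spacing triggers a warning only.
    """

    animal_id: str
    times: np.ndarray
    values: np.ndarray
    group: str = ""
    diet: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have the same length")
        if len(self.times) < 2:
            raise ValueError("a profile needs at least 2 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0]):
            warnings.warn(
                f"profile {self.animal_id!r}: non-uniform sampling interval",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Elapsed sampled time in minutes (last time minus first)."""
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds and window sizes of the three-criterion peak rule.

    window_mode selects how the percent criteria read their windows:
    "any" (default) accepts a rise/fall relative to *either* of the one-or-
    two neighbouring samples; "all" requires it against every sample in the
    window. The rule text is ambiguous on this point; "any" is the adopted
    reading.
    """

    rise_frac: float = 0.20
    fall_frac: float = 0.10
    min_amplitude: float = 0.320
    lookback: int = 2
    lookahead: int = 2
    nadir_window: int = 3
    window_mode: Literal["any", "all"] = "any"

    def __post_init__(self) -> None:
        if self.rise_frac <= 0 or self.fall_frac <= 0:
            raise ValueError("rise_frac and fall_frac must be > 0")
        if self.min_amplitude < 0:
            raise ValueError("min_amplitude must be >= 0")
        if min(self.lookback, self.lookahead, self.nadir_window) < 1:
            raise ValueError("window sizes must be >= 1")
        if self.window_mode not in ("any", "all"):
            raise ValueError("window_mode must be 'any' or 'all'")


@dataclass(frozen=True)
class PulsePeak:
    """A detected pulse peak with its preceding nadir and amplitude."""

    index: int
    time: float
    value: float
    nadir_index: int
    nadir_value: float
    amplitude: float


@dataclass(frozen=True)
class PulseSummary:
    """Per-profile pulsatility parameters.

    frequency_per_60min = n_peaks / duration_min * 60; mean_lh is the
    arithmetic mean of *all* samples over the sampling session;
    mean_amplitude is NaN when no peak was detected.
    """

    animal_id: str
    group: str
    diet: str
    n_peaks: int
    duration_min: float
    frequency_per_60min: float
    amplitudes: tuple[float, ...]
    mean_amplitude: float
    mean_lh: float


def _check_index(i: int, n: int) -> None:
    if not 0 <= i < n:
        raise IndexError(f"sample index {i} out of range for {n} samples")


def find_candidate_peaks(profile: LHProfile) -> list[int]:
    """Interior local maxima, leftmost sample of any plateau.

    Index i (1 <= i <= n-2) is a candidate iff values[i] > values[i-1]
    and values[i] >= values[i+1]; the strict left inequality makes the
    leftmost plateau sample the unique candidate of a flat-topped peak.
    """
    v = profile.values
    if len(v) < 3:
        raise ValueError("candidate detection needs at least 3 samples")
    return [
        i for i in range(1, len(v) - 1) if v[i] > v[i - 1] and v[i] >= v[i + 1]
    ]


def passes_rise(profile: LHProfile, i: int, params: DetectionParams) -> bool:
    """Criterion 1: >rise_frac increase over the previous one-or-two values."""
    v = profile.values
    _check_index(i, len(v))
    if i == 0:
        return False
    window = v[max(0, i - params.lookback) : i]
    ref = window.min() if params.window_mode == "any" else window.max()
    return bool(v[i] > (1.0 + params.rise_frac) * ref)


def passes_fall(profile: LHProfile, i: int, params: DetectionParams) -> bool:
    """Criterion 2: >fall_frac decrease in the subsequent one-or-two values."""
    v = profile.values
    _check_index(i, len(v))
    if i == len(v) - 1:
        return False
    window = v[i + 1 : i + 1 + params.lookahead]
    ref = window.min() if params.window_mode == "any" else window.max()
    return bool(ref < (1.0 - params.fall_frac) * v[i])


def compute_nadir(
    profile: LHProfile, i: int, params: DetectionParams
) -> tuple[int, float]:
    """Preceding nadir: minimum of the nadir_window values before i.

    Ties are broken by the earliest index. The window is clipped at the
    start of the profile.
    """
    v = profile.values
    _check_index(i, len(v))
    if i == 0:
        raise ValueError("no preceding values before index 0")
    lo = max(0, i - params.nadir_window)
    j = lo + int(np.argmin(v[lo:i]))  # argmin returns the first minimum
    return j, float(v[j])


def detect_pulses(
    profile: LHProfile, params: DetectionParams | None = None
) -> list[PulsePeak]:
    """Apply the three-criterion rule to every candidate peak.

    Returns the peaks, in time order, that satisfy rise, fall and
    amplitude criteria; each carries its nadir and amplitude.
    """
    if params is None:
        params = DetectionParams()
    v = profile.values
    if np.any(v < 0):
        raise ValueError("negative LH concentration in profile")
    peaks: list[PulsePeak] = []
    for i in find_candidate_peaks(profile):
        if not passes_rise(profile, i, params):
            continue
        if not passes_fall(profile, i, params):
            continue
        nadir_index, nadir_value = compute_nadir(profile, i, params)
        amplitude = float(v[i] - nadir_value)
        if amplitude < params.min_amplitude:
            continue
        peaks.append(
            PulsePeak(
                index=i,
                time=float(profile.times[i]),
                value=float(v[i]),
                nadir_index=nadir_index,
                nadir_value=nadir_value,
                amplitude=amplitude,
            )
        )
    return peaks


def summarize_profile(
    profile: LHProfile, peaks: Sequence[PulsePeak]
) -> PulseSummary:
    """Pulse frequency per 60 min, amplitudes, and overall mean LH.

    Frequency is computed over the elapsed sampled time, not a nominal
    session length, so truncated profiles are handled gracefully.
    """
    duration = profile.duration
    amplitudes = tuple(p.amplitude for p in peaks)
    return PulseSummary(
        animal_id=profile.animal_id,
        group=profile.group,
        diet=profile.diet,
        n_peaks=len(peaks),
        duration_min=duration,
        frequency_per_60min=len(peaks) / duration * 60.0,
        amplitudes=amplitudes,
        mean_amplitude=float(np.mean(amplitudes)) if amplitudes else float("nan"),
        mean_lh=float(np.mean(profile.values)),
    )
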
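"""Thermogram frame stacks -> corrected per-ROI temperature traces.

A tethered-flight assay is recorded with a thermal infrared camera; the
recording is a stack of per-frame temperature matrices (degC).  Three 3x3-pixel
regions of interest (ROIs) are placed on the thorax (metathoracic plate), the
third abdominal sternite and the nearby background.  The per-frame ROI value
is the *maximum* over the 3x3 window, which is robust to a leg sweeping
through the window (legs are cooler than the flight muscles).  Apparent
temperatures are converted to surface temperatures with a single-reflection
greybody model, and a flight is kept for analysis only if it contains at
least 40 s of continuous flight after take-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureTrace",
    "FlightWindow",
    "FrameStack",
    "ROISpec",
    "RadiometricParams",
    "extract_roi_trace",
    "correct_temperature",
    "estimate_emissivity",
    "detect_flight_window",
    "MIN_FLIGHT_SECONDS",
]

#: minimum continuous-flight duration (s) for an individual to be analysed
MIN_FLIGHT_SECONDS = 40.0

_ZERO_C_IN_K = 273.15


@dataclass(frozen=True)
class TemperatureTrace:
    """Time-indexed temperature series (degC) for one ROI of one individual."""

    roi_label: str
    times: np.ndarray
    values: np.ndarray
    corrected: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("empty trace")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite temperature values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, self.roi_label: self.values})


@dataclass(frozen=True)
class FlightWindow:
    """Continuous-flight interval; ``qualifies`` encodes the >=40 s filter."""

    takeoff_time: float
    end_time: float
    qualifies: bool
    min_duration: float = MIN_FLIGHT_SECONDS

    def __post_init__(self) -> None:
        if not self.end_time > self.takeoff_time:
            raise ValueError("end_time must exceed takeoff_time")
        if self.qualifies != (self.duration >= self.min_duration - 1e-9):
            raise ValueError(
                f"qualifies={self.qualifies} inconsistent with duration "
                f"{self.duration:.3f} s under the >= {self.min_duration:g} s rule")

    @property
    def duration(self) -> float:
        return self.end_time - self.takeoff_time

    def mask(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask of samples inside [takeoff, end]."""
        t = np.asarray(times, dtype=float)
        return (t >= self.takeoff_time - 1e-9) & (t <= self.end_time + 1e-9)


@dataclass(frozen=True)
class FrameStack:
    """Stack of 2-D temperature matrices (degC) with strictly increasing times."""

    frames: np.ndarray  # (n_frames, rows, cols)
    frame_times: np.ndarray  # seconds

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        t = np.asarray(self.frame_times, dtype=float)
        if f.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) array")
        if f.shape[0] == 0:
            raise ValueError("empty frame stack")
        if t.shape != (f.shape[0],):
            raise ValueError("frame_times must have one entry per frame")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame_times must be strictly increasing")
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "frame_times", t)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def to_tiff(self, path: str | Path, times_path: str | Path) -> None:
        """Write as multi-page float32 grayscale TIFF + frame-time CSV sidecar."""
        import tifffile

        tifffile.imwrite(str(path), self.frames.astype(np.float32))
        pd.DataFrame({"frame": np.arange(len(self.frame_times)),
                      "time_s": self.frame_times}).to_csv(times_path, index=False)

    @classmethod
    def from_tiff(cls, path: str | Path, times_path: str | Path) -> "FrameStack":
        import tifffile

        frames = np.asarray(tifffile.imread(str(path)), dtype=float)
        if frames.ndim == 2:  # single-page stack
            frames = frames[None, :, :]
        times = pd.read_csv(times_path)["time_s"].to_numpy(dtype=float)
        return cls(frames=frames, frame_times=times)


@dataclass(frozen=True)
class ROISpec:
    """A fixed 3x3-pixel region of interest, 0-based center row/col."""

    label: str
    center_row: int
    center_col: int
    size: int = 3

    def __post_init__(self) -> None:
        if self.size != 3:
            raise ValueError("ROI size is fixed at 3x3 pixels")

    @property
    def half(self) -> int:
        return self.size // 2

    def bounds(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1) half-open slice bounds of the window."""
        h = self.half
        return (self.center_row - h, self.center_row + h + 1,
                self.center_col - h, self.center_col + h + 1)

    def inside(self, shape: tuple[int, int]) -> bool:
        r0, r1, c0, c1 = self.bounds()
        return r0 >= 0 and c0 >= 0 and r1 <= shape[0] and c1 <= shape[1]

    def overlaps(self, other: "ROISpec") -> bool:
        a, b = self.bounds(), other.bounds()
        return not (a[1] <= b[0] or b[1] <= a[0] or a[3] <= b[2] or b[3] <= a[2])


@dataclass(frozen=True)
class RadiometricParams:
    """Parameters of the greybody radiance correction.

    emissivity:       surface emissivity in (0, 1]; 0.95 is the electrical-tape
                      reference commonly used to calibrate insect cuticle.
    reflected_temp:   apparent reflected (background) temperature, degC.
    air_temp:         air temperature along the optical path, degC.
    distance:         camera-to-object distance, m (0.5 m in the assay).
    relative_humidity: fraction in [0, 1].
    transmittance:    atmospheric transmittance in (0, 1]; at 0.5 m it is
                      indistinguishable from 1, the default.
    """

    emissivity: float
    reflected_temp: float = 25.0
    air_temp: float = 25.0
    distance: float = 0.5
    relative_humidity: float = 0.5
    transmittance: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.emissivity <= 1.0):
            raise ValueError("emissivity must be in (0, 1]")
        if not (0.0 < self.transmittance <= 1.0):
            raise ValueError("transmittance must be in (0, 1]")
        if not (0.0 <= self.relative_humidity <= 1.0):
            raise ValueError("relative_humidity must be in [0, 1]")


def _radiance(temp_c: np.ndarray | float) -> np.ndarray | float:
    """Blackbody-equivalent radiance, proportional to T^4 in Kelvin."""
    t_k = np.asarray(temp_c, dtype=float) + _ZERO_C_IN_K
    if np.any(t_k <= 0):
        raise ValueError("temperature below 0 K")
    return t_k ** 4


def _radiance_to_temp(w: np.ndarray | float) -> np.ndarray | float:
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("non-physical corrected radiance (below 0 K)")
    return w ** 0.25 - _ZERO_C_IN_K


def extract_roi_trace(stack: FrameStack, roi: ROISpec) -> TemperatureTrace:
    """Per-frame maximum temperature over the ROI's 3x3 window.

    The maximum (rather than the mean) is used because a leg moving through
    the window reads cooler than the body part of interest and would bias a
    mean downward.
    """
    if not roi.inside(stack.shape):
        raise ValueError(f"ROI {roi.label!r} falls outside the frame bounds")
    r0, r1, c0, c1 = roi.bounds()
    values = stack.frames[:, r0:r1, c0:c1].max(axis=(1, 2))
    return TemperatureTrace(roi_label=roi.label, times=stack.frame_times.copy(),
                            values=values, corrected=False)


def apparent_from_true(true_temp_c, params: RadiometricParams):
    """Forward greybody model: true surface temperature -> apparent reading.

    W_meas = eps*tau*W(T_obj) + (1-eps)*tau*W(T_refl) + (1-tau)*W(T_atm)
    """
    w_obj = _radiance(true_temp_c)
    w_refl = _radiance(params.reflected_temp)
    w_atm = _radiance(params.air_temp)
    eps, tau = params.emissivity, params.transmittance
    w_meas = eps * tau * w_obj + (1.0 - eps) * tau * w_refl + (1.0 - tau) * w_atm
    return _radiance_to_temp(w_meas)


def correct_temperature(apparent: TemperatureTrace,
                        params: RadiometricParams) -> TemperatureTrace:
    """Invert the greybody model: apparent reading -> surface temperature.

    W_obj = (W_meas - (1-eps)*tau*W_refl - (1-tau)*W_atm) / (eps*tau)

    Monotone increasing in the apparent value; the identity when eps=tau=1.
    """
    if apparent.corrected:
        raise ValueError("trace is already corrected")
    w_meas = _radiance(apparent.values)
    w_refl = _radiance(params.reflected_temp)
    w_atm = _radiance(params.air_temp)
    eps, tau = params.emissivity, params.transmittance
    w_obj = (w_meas - (1.0 - eps) * tau * w_refl - (1.0 - tau) * w_atm) / (eps * tau)
    return TemperatureTrace(roi_label=apparent.roi_label, times=apparent.times.copy(),
                            values=np.asarray(_radiance_to_temp(w_obj)),
                            corrected=True)


def estimate_emissivity(cuticle_apparent: Sequence[float],
                        reference_apparent: Sequence[float],
                        eps_ref: float = 0.95,
                        reflected_temp: float = 25.0) -> float:
    """Least-squares cuticle emissivity from paired apparent temperatures.

    Cuticle and a reference emitter of known emissivity ``eps_ref`` are held
    at the same (unknown) true temperature across several set points
    (typically 50-80 degC).  In the greybody model the apparent radiances obey

        W_app = eps * W(T_true) + (1 - eps) * W(T_refl)

    so W(T_true) is recovered from the reference at each set point and the
    cuticle emissivity is the no-intercept least-squares slope of
    (W_app_cut - W_refl) on (W_true - W_refl), clipped to (0, 1].
    """
    cut = np.asarray(cuticle_apparent, dtype=float)
    ref = np.asarray(reference_apparent, dtype=float)
    if cut.shape != ref.shape or cut.ndim != 1:
        raise ValueError("paired 1-D measurement arrays required")
    if cut.size < 2:
        raise ValueError("at least 2 paired measurements required")
    if not (0.0 < eps_ref <= 1.0):
        raise ValueError("eps_ref must be in (0, 1]")
    if np.ptp(ref) == 0.0:
        raise ValueError("zero-variance inputs: measurements at a single temperature")
    w_refl = _radiance(reflected_temp)
    w_true = (_radiance(ref) - (1.0 - eps_ref) * w_refl) / eps_ref
    x = w_true - w_refl
    y = _radiance(cut) - w_refl
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("degenerate measurements: reference indistinguishable from background")
    eps = float(np.dot(x, y) / denom)
    return float(np.clip(eps, np.finfo(float).tiny, 1.0))


def detect_flight_window(trace: TemperatureTrace,
                         takeoff_time: Optional[float] = None,
                         min_duration: float = MIN_FLIGHT_SECONDS) -> FlightWindow:
    """Locate the continuous-flight window and apply the >=40 s filter.

    If a take-off annotation is supplied it is used verbatim.  Otherwise
    take-off is taken at the largest forward difference of the (thorax)
    trace -- the warm-up/step signature of flight onset.  This heuristic is a
    stand-in for the manual annotation done on real recordings.
    """
    t = trace.times
    if takeoff_time is None:
        if len(trace) < 2:
            takeoff_time = float(t[0])
        else:
            takeoff_time = float(t[int(np.argmax(np.diff(trace.values)))])
    end_time = float(t[-1])
    if end_time <= takeoff_time:  # degenerate: annotation at/after last frame
        return FlightWindow(takeoff_time=float(t[0]),
                            end_time=max(end_time, float(t[0]) + 1e-9),
                            qualifies=False, min_duration=min_duration)
    qualifies = (end_time - takeoff_time) >= min_duration - 1e-9
    return FlightWindow(takeoff_time=takeoff_time, end_time=end_time,
                        qualifies=qualifies, min_duration=min_duration)
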
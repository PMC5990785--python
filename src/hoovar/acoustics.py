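"""Acoustic variable measurement from F0 contours and framewise spectra.

Implements the measurement definitions used for quiet chimpanzee hoos:
call duration from the visible F0 band, start/end F0 within the first/last
0.05 s, maximum F0 and its position, the F0 drop and its slope, and the
peak frequency located in the frame of maximum intensity.  Inputs are a
sampled F0 contour (sample spacing at most 0.01 s, matching a pitch-listing
export) and a spectrum time series (Gaussian-windowed frames, a fixed
frequency-bin grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "F0Contour",
    "SpectrumSeries",
    "SyntheticCall",
    "CallBout",
    "ContourError",
    "measure_call",
    "inter_call_intervals",
    "EDGE_WINDOW_S",
]

#: Width of the start/end F0 measurement window, seconds.
EDGE_WINDOW_S = 0.05

#: Maximum allowed F0 sample spacing, seconds.
MAX_CONTOUR_SPACING_S = 0.01


class ContourError(ValueError):
    """An F0 contour or bout violates its structural contract."""


@dataclass(frozen=True)
class F0Contour:
    """Sampled fundamental-frequency track of one call.

    times_s are strictly increasing with spacing at most 0.01 s; f0_hz are
    positive.  Times may be absolute (within a recording) — all measurements
    are invariant to uniform time translation.
    """

    times_s: np.ndarray
    f0_hz: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_s, float)
        f = np.asarray(self.f0_hz, float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "f0_hz", f)
        if t.ndim != 1 or f.shape != t.shape:
            raise ContourError("times_s and f0_hz must be 1-D and equal length")
        if len(t) < 2:
            raise ContourError("contour needs at least 2 samples")
        dt = np.diff(t)
        if not (dt > 0).all():
            raise ContourError("contour times must be strictly increasing")
        if dt.max() > MAX_CONTOUR_SPACING_S + 1e-12:
            raise ContourError(
                f"contour spacing {dt.max():.4f}s exceeds {MAX_CONTOUR_SPACING_S}s"
            )
        if not (f > 0).all():
            raise ContourError("f0_hz must be positive")

    @property
    def onset_s(self) -> float:
        return float(self.times_s[0])

    @property
    def offset_s(self) -> float:
        return float(self.times_s[-1])


@dataclass(frozen=True)
class SpectrumSeries:
    """Framewise amplitude spectra of one call.

    frame_times_s are frame centres; freqs_hz the (strictly increasing)
    frequency-bin grid of the analysis; amplitude is frames x bins; and
    intensity_db the per-frame total intensity.
    """

    frame_times_s: np.ndarray
    freqs_hz: np.ndarray
    amplitude: np.ndarray
    intensity_db: np.ndarray

    def __post_init__(self):
        ft = np.asarray(self.frame_times_s, float)
        fq = np.asarray(self.freqs_hz, float)
        a = np.asarray(self.amplitude, float)
        i = np.asarray(self.intensity_db, float)
        for name, arr in (("frame_times_s", ft), ("freqs_hz", fq), ("intensity_db", i)):
            if arr.ndim != 1:
                raise ContourError(f"{name} must be 1-D")
        if not (np.diff(fq) > 0).all():
            raise ContourError("freqs_hz must be strictly increasing")
        if a.shape != (len(ft), len(fq)):
            raise ContourError("amplitude must be frames x bins")
        if i.shape != ft.shape:
            raise ContourError("intensity_db must align with frames")
        object.__setattr__(self, "frame_times_s", ft)
        object.__setattr__(self, "freqs_hz", fq)
        object.__setattr__(self, "amplitude", a)
        object.__setattr__(self, "intensity_db", i)


@dataclass(frozen=True)
class SyntheticCall:
    """One call of a bout: its contour and spectra share an absolute time axis."""

    contour: F0Contour
    spectra: SpectrumSeries | None = None

    @property
    def onset_s(self) -> float:
        return self.contour.onset_s

    @property
    def offset_s(self) -> float:
        return self.contour.offset_s


@dataclass(frozen=True)
class CallBout:
    """Time-ordered, non-overlapping calls of one caller and one call type."""

    calls: tuple[SyntheticCall, ...]

    def __post_init__(self):
        calls = tuple(self.calls)
        object.__setattr__(self, "calls", calls)
        if not calls:
            raise ContourError("bout needs at least one call")
        for a, b in zip(calls, calls[1:]):
            if b.onset_s < a.offset_s:
                raise ContourError(
                    f"overlapping calls: offset {a.offset_s:.3f}s > onset {b.onset_s:.3f}s"
                )


def _edge_median(t: np.ndarray, f: np.ndarray, window: tuple[float, float]) -> float:
    lo, hi = window
    mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    return float(np.median(f[mask]))


def measure_call(contour: F0Contour, spectra: SpectrumSeries | None = None) -> dict:
    """Measure the acoustic variables of one call.

    Returns a dict keyed by call-table column names.  Start/end F0 are the
    median of contour samples within the first/last 0.05 s (robust to edge
    jitter); the time of maximum F0 is the earliest sample attaining the
    maximum; the slope of the F0 fall is 0 when the drop or the remaining
    time is 0; peak frequency is the maximum-amplitude bin within the frame
    nearest the time of maximum intensity.  Calls shorter than 0.1 s have
    their edge windows truncated at the call midpoint (with a warning).
    Spectral fields are NaN when ``spectra`` is None.
    """
    t = contour.times_s - contour.times_s[0]  # translation invariance
    f = contour.f0_hz
    duration = float(t[-1])
    half = duration / 2.0
    win = EDGE_WINDOW_S
    if duration < 2 * EDGE_WINDOW_S:
        warnings.warn(
            f"call of {duration:.3f}s is shorter than two edge windows; "
            "start/end windows truncated at the midpoint",
            stacklevel=2,
        )
        win = half

    f0_start = _edge_median(t, f, (0.0, win))
    f0_end = _edge_median(t, f, (duration - win, duration))
    i_max = int(np.argmax(f))  # argmax returns the earliest maximum
    f0_max = float(f[i_max])
    t_f0max = float(t[i_max])
    f0_drop = f0_max - f0_end
    dt_fall = duration - t_f0max
    slope = f0_drop / dt_fall if (f0_drop > 0 and dt_fall > 0) else 0.0

    peak_freq = float("nan")
    t_peak = float("nan")
    pos_peak = float("nan")
    if spectra is not None:
        ft = spectra.frame_times_s - contour.times_s[0]
        j = int(np.argmax(spectra.intensity_db))
        k = int(np.argmax(spectra.amplitude[j]))
        peak_freq = float(spectra.freqs_hz[k])
        t_peak = float(np.clip(ft[j], 0.0, duration))
        pos_peak = t_peak / duration

    return {
        "duration_s": duration,
        "f0_start_hz": f0_start,
        "f0_end_hz": f0_end,
        "f0_max_hz": f0_max,
        "f0_drop_hz": f0_drop,
        "slope_steepness_hz_per_s": slope,
        "peak_freq_hz": peak_freq,
        "t_f0max_s": t_f0max,
        "t_peakfreq_s": t_peak,
        "pos_f0max": t_f0max / duration,
        "pos_peakfreq": pos_peak,
    }


def contour_to_csv(contour: F0Contour, path) -> None:
    """Serialize a contour as two-column CSV (time_s, f0_hz) at 9 digits."""
    import pandas as pd

    pd.DataFrame({"time_s": contour.times_s, "f0_hz": contour.f0_hz}).to_csv(
        path, index=False, float_format="%.9g"
    )


def contour_from_csv(path) -> F0Contour:
    import pandas as pd

    df = pd.read_csv(path)
    return F0Contour(times_s=df["time_s"].to_numpy(float), f0_hz=df["f0_hz"].to_numpy(float))


def inter_call_intervals(bout: CallBout) -> list[float]:
    """Silent gaps within a bout: end of each call to the start of the next.

    A single-call bout yields an empty list.  Overlap is rejected by the
    CallBout constructor.
    """
    gaps = []
    for a, b in zip(bout.calls, bout.calls[1:]):
        gaps.append(float(b.onset_s - a.offset_s))
    return gaps
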
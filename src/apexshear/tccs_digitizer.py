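"""Spectral-Doppler spectrogram digitisation.

Transcranial colour-coded sonography exports the spectral display as a bitmap;
this module turns such an image back into a numeric velocity waveform and the
clinical indices read from it:

* Vps — peak systolic velocity (cycle maximum, cm/s),
* Ved — end-diastolic velocity (value at the cycle end, cm/s),
* Vm  — time-mean velocity over the cycle (trapezoid, cm/s).

Axis calibration (seconds and cm/s per pixel, baseline row) is supplied by the
user; on-screen axis auto-detection is device-specific and out of scope.  Only
antegrade flow (above the baseline) is digitised.

The maximal-velocity envelope per image column is the topmost pixel whose
intensity reaches ``intensity_threshold`` x (image max), required to start a
vertical run of at least ``min_run`` super-threshold pixels (a standard
despeckle guard), then median-smoothed across columns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.signal import find_peaks, medfilt

__all__ = [
    "Calibration",
    "SpectrogramImage",
    "Waveform",
    "load_spectrogram",
    "extract_envelope",
    "single_cycle",
    "waveform_indices",
    "export_inlet_profile",
    "read_inlet_profile",
]


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-physics mapping of a spectrogram image.

    seconds_per_px : horizontal time step per column (s)
    cm_s_per_px    : velocity per row (cm/s)
    baseline_row   : image row of zero velocity; smaller rows = higher velocity
    t0             : time of column 0 (s)
    """

    seconds_per_px: float
    cm_s_per_px: float
    baseline_row: int
    t0: float = 0.0

    def validate(self, shape: tuple[int, int]) -> None:
        if self.seconds_per_px <= 0 or self.cm_s_per_px <= 0:
            raise ValueError("calibration scale factors must be strictly positive")
        if not 0 <= self.baseline_row < shape[0]:
            raise ValueError("baseline row outside the image")


@dataclass
class SpectrogramImage:
    pixels: np.ndarray  # (rows, cols) grayscale intensities
    calibration: Calibration

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        self.calibration.validate(self.pixels.shape)


@dataclass
class Waveform:
    """Velocity-vs-time trace (cm/s); ``period`` is set once cycle-cropped."""

    times: np.ndarray
    velocities: np.ndarray
    period: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.times.shape != self.velocities.shape or self.times.ndim != 1:
            raise ValueError("times and velocities must be matching 1-D arrays")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocities must be finite")

    @property
    def is_cropped(self) -> bool:
        return self.period is not None


def load_spectrogram(path: str | Path, calibration: Calibration) -> SpectrogramImage:
    """Read a BMP/PNG spectrogram; colour images are converted by luminance."""
    if calibration is None:
        raise ValueError("calibration is required (axis auto-detection is not supported)")
    img = Image.open(path).convert("L")
    return SpectrogramImage(pixels=np.asarray(img, dtype=float), calibration=calibration)


def extract_envelope(img: SpectrogramImage, intensity_threshold: float = 0.2,
                     smooth_window: int = 5, min_run: int = 3) -> Waveform:
    """Maximal-velocity envelope of the spectrogram, one sample per column.

    Per column, the envelope row is the topmost (highest-velocity) pixel above
    the baseline that starts a vertical run of ``min_run`` pixels with
    intensity >= ``intensity_threshold`` x (image max).  Columns without any
    signal are linearly interpolated from their neighbours; the result is
    median-smoothed over ``smooth_window`` columns.
    """
    if not 0 < intensity_threshold <= 1:
        raise ValueError("intensity_threshold must be in (0, 1]")
    cal = img.calibration
    px = img.pixels
    thr = intensity_threshold * px.max()
    if px.max() <= 0:
        raise ValueError("blank image: no signal")
    above = px[: cal.baseline_row, :] >= thr  # rows above the baseline only
    n_rows, n_cols = above.shape
    if min_run > 1 and n_rows >= min_run:
        # a downward run of length k starts at row r <=> the k-window mean is 1
        from scipy.ndimage import uniform_filter1d

        window = uniform_filter1d(above.astype(float), size=min_run, axis=0,
                                  origin=-(min_run // 2), mode="constant")
        starts = window >= (1.0 - 1e-9)
    else:
        starts = above
    velocities = np.full(n_cols, np.nan)
    for col in range(n_cols):
        rows = np.flatnonzero(starts[:, col])
        if len(rows):
            top = rows[0]
            velocities[col] = (cal.baseline_row - top) * cal.cm_s_per_px
    good = np.isfinite(velocities)
    if not np.any(good):
        raise ValueError("blank image: no super-threshold pixels above the baseline")
    cols = np.arange(n_cols)
    velocities = np.interp(cols, cols[good], velocities[good])
    if smooth_window and smooth_window > 1:
        k = smooth_window if smooth_window % 2 == 1 else smooth_window + 1
        velocities = medfilt(velocities, kernel_size=min(k, n_cols - (n_cols + 1) % 2))
    times = cal.t0 + cols * cal.seconds_per_px
    return Waveform(times=times, velocities=velocities)


def single_cycle(w: Waveform, method: str = "autocorrelation",
                 markers: tuple[float, float] | None = None,
                 min_period: float | None = None) -> Waveform:
    """Crop a multi-beat waveform to one cardiac cycle starting at end-diastole.

    ``autocorrelation`` estimates the beat period from the first prominent
    autocorrelation peak of the mean-removed trace (needs >= 2 beats);
    ``markers`` crops to the supplied ``[t0, t1]`` interval directly.  The
    returned waveform carries the cycle duration in ``period``.
    """
    v, t = w.velocities, w.times
    if method == "markers" or markers is not None:
        if markers is None:
            raise ValueError("markers method requires (t0, t1)")
        t0, t1 = markers
        if not t0 < t1:
            raise ValueError("markers must satisfy t0 < t1")
        sel = (t >= t0) & (t <= t1 + 1e-12)
        if sel.sum() < 2:
            raise ValueError("markers select fewer than 2 samples")
        return Waveform(times=t[sel], velocities=v[sel], period=float(t[sel][-1] - t[sel][0]))
    if method != "autocorrelation":
        raise ValueError(f"unknown cycle-cropping method {method!r}")
    n = len(v)
    if n < 8:
        raise ValueError("waveform too short for period detection")
    x = v - v.mean()
    if np.allclose(x, 0):
        raise ValueError("constant waveform: no detectable periodicity")
    ac = np.correlate(x, x, mode="full")[n - 1:]
    ac = ac / ac[0]
    dt = float(np.median(np.diff(t)))
    min_lag = max(2, int(round((min_period or 0.25) / dt)))
    peaks, props = find_peaks(ac[: n // 2 + 1], height=0.2)
    peaks = peaks[peaks >= min_lag]
    if len(peaks) == 0:
        raise ValueError("no detectable periodicity in waveform")
    heights = ac[peaks]
    # fundamental = first peak comparable to the strongest one
    lag = int(peaks[heights >= 0.8 * heights.max()][0])
    i0 = int(np.argmin(v[:lag]))  # end-diastole: minimum within the first beat
    if i0 + lag >= n:
        i0 = n - 1 - lag
    sl = slice(i0, i0 + lag + 1)
    return Waveform(times=t[sl], velocities=v[sl], period=float(t[sl][-1] - t[sl][0]))


def waveform_indices(w: Waveform) -> tuple[float, float, float]:
    """(Vps, Ved, Vm) of a cycle-cropped waveform, cm/s.

    Vps is the cycle maximum, Ved the end-of-cycle (end-diastolic) value, and
    Vm the trapezoidal time average.
    """
    if not w.is_cropped:
        raise ValueError("waveform must be cycle-cropped first (see single_cycle)")
    vps = float(w.velocities.max())
    ved = float(w.velocities[-1])
    vm = float(np.trapezoid(w.velocities, w.times) / (w.times[-1] - w.times[0]))
    return vps, ved, vm


def export_inlet_profile(w: Waveform, path: str | Path) -> None:
    """Write a two-column ASCII inlet profile: time (s), velocity (m/s).

    Velocities are converted from cm/s.  Values are printed with 17
    significant digits so a re-import reproduces the stored doubles exactly.
    Header lines start with ``#``.
    """
    if not w.is_cropped:
        raise ValueError("export requires a cycle-cropped waveform")
    if len(w.times) == 0:
        raise ValueError("empty waveform")
    data = np.column_stack([w.times, w.velocities / 100.0])
    header = (
        "inlet velocity profile\n"
        "columns: time [s], velocity [m/s]\n"
        f"cycle duration T = {w.period:.17g} s"
    )
    np.savetxt(path, data, fmt="%.17e", header=header)


def read_inlet_profile(path: str | Path, to_cm_s: bool = True) -> Waveform:
    """Re-import an exported inlet profile.

    With ``to_cm_s`` the m/s column is scaled back to cm/s (exact up to one
    unit in the last place); pass ``False`` to keep the stored m/s doubles
    bit-exactly.
    """
    data = np.loadtxt(path)
    t, v = data[:, 0], data[:, 1]
    if to_cm_s:
        v = v * 100.0
    return Waveform(times=t, velocities=v, period=float(t[-1] - t[0]))
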
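"""Per-vertex haemodynamic wall parameters and their region summaries.

Given a time-resolved wall-shear vector field sampled over one cardiac cycle
of duration T, this module computes

* TAWSS, the time-averaged wall-shear magnitude
  ``(1/T) * integral_0^T |wss(t)| dt``  (Pa),
* OSI, the oscillatory shear index
  ``0.5 * (1 - |integral wss dt| / integral |wss| dt)`` in [0, 0.5]
  (0 for unidirectional shear, 0.5 for complete reversal),
* the signed wall-shear-stress gradient (WSSG): the tangential gradient of
  TAWSS decomposed in the local (p, q) frame, where p is the time-averaged
  WSS direction and q its in-plane perpendicular.  The magnitude is
  ``sqrt((dTAWSS/dp)^2 + (dTAWSS/dq)^2)`` (Pa/mm); the sign is the sign of
  the p-component — positive where the wall shear rises along the flow
  direction (acceleration zone), negative where it falls (recovery zone).

Region-level summaries (over the high-WSS subset of the apex patch) use
area-weighted vertex averages by default and report the subject-level
WSS / WSSG / absWSSG / OSI / dirWSSG quintet.

All time integrals are trapezoidal on the provided (possibly non-uniform)
sample times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import ApexPatch, SurfaceMesh, tangent_gradient_field, vertex_areas

__all__ = [
    "TimeResolvedWallField",
    "WSSFrame",
    "WSSGField",
    "RegionMetrics",
    "time_averaged_wss",
    "time_averaged_wss_vector",
    "osi",
    "wss_frame",
    "wssg_field",
    "high_wss_region",
    "region_metrics",
    "select_branch",
]


@dataclass
class TimeResolvedWallField:
    """Per-vertex wall-shear vectors (Pa) at sample times spanning one cycle.

    ``vectors`` has shape ``(n_vertices, n_times, 3)``; ``times`` (s) must be
    strictly increasing and span the cycle ``[t0, t0 + T]``.
    """

    mesh: SurfaceMesh
    times: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least 2 time samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        expected = (self.mesh.n_vertices, len(self.times), 3)
        if self.vectors.shape != expected:
            raise ValueError(f"vectors must have shape {expected}, got {self.vectors.shape}")
        if self.period <= 0:
            raise ValueError("cycle duration must be positive")

    @property
    def period(self) -> float:
        """Cardiac-cycle duration T (s) covered by the samples."""
        return float(self.times[-1] - self.times[0])

    def max_tangency_angle(self) -> float:
        """Worst angle (deg) between any sampled vector and its tangent plane."""
        n = self.mesh.vertex_normals[:, None, :]
        mags = np.linalg.norm(self.vectors, axis=2)
        normal_comp = np.abs(np.sum(self.vectors * n, axis=2))
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(mags > 0, normal_comp / np.maximum(mags, 1e-300), 0.0)
        return float(np.degrees(np.arcsin(np.clip(s, 0, 1)).max()))


@dataclass
class WSSFrame:
    """Local (p, q) surface frame: p along the time-averaged WSS, q = n x p."""

    p_dir: np.ndarray
    q_dir: np.ndarray
    defined: np.ndarray


@dataclass
class WSSGField:
    """Signed tangential gradient of TAWSS decomposed in the (p, q) frame."""

    d_tau_dp: np.ndarray  # Pa/mm
    d_tau_dq: np.ndarray  # Pa/mm
    magnitude: np.ndarray  # Pa/mm
    sign: np.ndarray  # +1 / -1 where defined
    defined: np.ndarray


@dataclass
class RegionMetrics:
    """Area-weighted summary of a vertex region (one subject's outcome row)."""

    wss: float  # Pa
    wssg_signed: float  # Pa/mm
    abs_wssg: float  # Pa/mm
    osi: float
    dir_wssg: str  # "positive" | "negative"
    region_size: int
    region_area: float  # mm^2

    def to_row(self, subject_id: str, group: str) -> dict:
        """Cohort-CSV row; dirWSSG encoded 1 (positive) / 0 (negative)."""
        return {
            "subject_id": subject_id,
            "group": group,
            "WSS": self.wss,
            "WSSG": self.wssg_signed,
            "absWSSG": self.abs_wssg,
            "OSI": self.osi,
            "dirWSSG": 1 if self.dir_wssg == "positive" else 0,
        }


def _trapz(y: np.ndarray, x: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.trapezoid(y, x, axis=axis)


def time_averaged_wss(field: TimeResolvedWallField) -> np.ndarray:
    """TAWSS (Pa): cycle average of the wall-shear magnitude per vertex."""
    mags = np.linalg.norm(field.vectors, axis=2)
    return _trapz(mags, field.times, axis=1) / field.period


def time_averaged_wss_vector(field: TimeResolvedWallField) -> np.ndarray:
    """Component-wise cycle mean of the wall-shear vector (Pa), per vertex."""
    return _trapz(field.vectors, field.times[None, :, None], axis=1) / field.period


def osi(field: TimeResolvedWallField) -> tuple[np.ndarray, np.ndarray]:
    """Oscillatory shear index per vertex, with a defined-mask.

    Vertices whose shear trajectory is identically (numerically) zero carry no
    direction information and are flagged undefined (NaN).
    """
    mean_mag = _trapz(np.linalg.norm(field.vectors, axis=2), field.times, axis=1)
    mean_vec = _trapz(field.vectors, field.times[None, :, None], axis=1)
    defined = mean_mag > 1e-300
    out = np.full(field.mesh.n_vertices, np.nan)
    num = np.linalg.norm(mean_vec, axis=1)
    out[defined] = 0.5 * (1.0 - num[defined] / mean_mag[defined])
    # the triangle inequality bounds OSI in [0, 0.5]; clip quadrature jitter
    out[defined] = np.clip(out[defined], 0.0, 0.5)
    return out, defined


def wss_frame(field: TimeResolvedWallField, mean_threshold: float = 1e-9) -> WSSFrame:
    """Per-vertex (p, q) frame from the time-averaged WSS direction.

    p is the cycle-mean wall-shear vector projected into the tangent plane and
    normalised; q = normal x p.  Vertices whose projected mean magnitude falls
    below ``mean_threshold`` (Pa) — e.g. perfectly reversing shear — are
    flagged undefined.
    """
    mean_vec = time_averaged_wss_vector(field)
    n = field.mesh.vertex_normals
    tang = mean_vec - np.sum(mean_vec * n, axis=1, keepdims=True) * n
    mag = np.linalg.norm(tang, axis=1)
    defined = mag > mean_threshold
    p = np.full_like(tang, np.nan)
    q = np.full_like(tang, np.nan)
    p[defined] = tang[defined] / mag[defined, None]
    q[defined] = np.cross(n[defined], p[defined])
    qn = np.linalg.norm(q[defined], axis=1)
    q[defined] /= qn[:, None]
    return WSSFrame(p_dir=p, q_dir=q, defined=defined)


def wssg_field(tawss: np.ndarray, frame: WSSFrame, mesh: SurfaceMesh) -> WSSGField:
    """Signed WSSG field: TAWSS tangent gradient resolved onto (p, q).

    sign = sign of the p-component: +1 where the TAWSS gradient points along
    the local WSS direction, -1 where it opposes it.  The q-component
    contributes to the magnitude only.
    """
    tawss = np.asarray(tawss, dtype=float)
    grads, grad_ok = tangent_gradient_field(mesh, tawss)
    defined = grad_ok & frame.defined
    dp = np.full(mesh.n_vertices, np.nan)
    dq = np.full(mesh.n_vertices, np.nan)
    dp[defined] = np.sum(grads[defined] * frame.p_dir[defined], axis=1)
    dq[defined] = np.sum(grads[defined] * frame.q_dir[defined], axis=1)
    mag = np.hypot(dp, dq)
    sign = np.where(dp >= 0, 1.0, -1.0)
    sign[~defined] = np.nan
    return WSSGField(d_tau_dp=dp, d_tau_dq=dq, magnitude=mag, sign=sign, defined=defined)


def high_wss_region(tawss: np.ndarray, patch: ApexPatch, percentile: float = 98.0,
                    threshold_vertices: np.ndarray | None = None) -> np.ndarray:
    """Patch vertices whose TAWSS reaches the given percentile.

    The threshold is the linear-interpolation percentile of TAWSS over the
    patch (or over ``threshold_vertices`` when the percentile scope should be
    wider, e.g. the whole model); the region is the set of patch vertices at
    or above it.
    """
    if len(patch) == 0:
        raise ValueError("empty patch")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    tawss = np.asarray(tawss, dtype=float)
    scope = patch.vertex_indices if threshold_vertices is None else np.asarray(threshold_vertices)
    vals = tawss[scope]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no finite TAWSS values in percentile scope")
    thr = np.percentile(vals, percentile, method="linear")
    member = patch.vertex_indices[tawss[patch.vertex_indices] >= thr]
    return member


def region_metrics(region: np.ndarray, tawss: np.ndarray, wssg: WSSGField,
                   osi_field: np.ndarray, areas: np.ndarray,
                   area_weighted: bool = True) -> RegionMetrics:
    """Area-weighted averages of the wall parameters over a vertex region.

    Vertices with an undefined WSSG frame or OSI are excluded from the
    corresponding average (not zero-filled).  ``dir_wssg`` is "positive" iff
    the signed WSSG average is > 0.
    """
    region = np.asarray(region, dtype=np.int64)
    if len(region) == 0:
        raise ValueError("empty region")
    w = areas[region].astype(float) if area_weighted else np.ones(len(region))

    def _avg(values: np.ndarray, ok: np.ndarray) -> float:
        ok = ok & np.isfinite(values)
        if not np.any(ok):
            raise ValueError("region has no defined vertices for a requested field")
        return float(np.sum(values[ok] * w[ok]) / np.sum(w[ok]))

    t_r = tawss[region]
    signed_r = (wssg.sign * wssg.magnitude)[region]
    mag_r = wssg.magnitude[region]
    osi_r = osi_field[region]
    ok_wssg = wssg.defined[region]
    mean_wss = _avg(t_r, np.ones(len(region), bool))
    mean_signed = _avg(signed_r, ok_wssg)
    mean_abs = _avg(mag_r, ok_wssg)
    mean_osi = _avg(osi_r, np.isfinite(osi_r))
    return RegionMetrics(
        wss=mean_wss,
        wssg_signed=mean_signed,
        abs_wssg=mean_abs,
        osi=mean_osi,
        dir_wssg="positive" if mean_signed > 0 else "negative",
        region_size=int(len(region)),
        region_area=float(np.sum(areas[region])),
    )


def select_branch(mesh: SurfaceMesh, tawss: np.ndarray, patch: ApexPatch) -> str:
    """The daughter branch attaining the higher maximum TAWSS within the patch.

    Measurements are then restricted to that branch.  Exact ties break
    deterministically to ``branch1`` (with a warning).
    """
    if mesh.branch_labels is None:
        raise ValueError("mesh has no branch labels; cannot select a branch")
    tawss = np.asarray(tawss, dtype=float)
    peaks = {}
    for label in ("branch1", "branch2"):
        members = patch.vertex_indices[mesh.branch_labels[patch.vertex_indices] == label]
        peaks[label] = float(np.nanmax(tawss[members])) if len(members) else -np.inf
    if peaks["branch1"] == peaks["branch2"]:
        warnings.warn("equal peak TAWSS on both branches; tie broken to branch1")
        return "branch1"
    return max(peaks, key=peaks.get)
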
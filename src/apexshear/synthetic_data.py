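"""Synthetic inputs for every pipeline stage.

The package analyses wall-shear fields that would normally come from a
patient-specific CFD solve.  This module replaces the solver and the clinical
recordings with controlled, seeded generators:

* :func:`womersley_wall_shear` — the exact wall shear of pulsatile laminar
  flow in a rigid cylinder (Poiseuille + Womersley harmonics), used as an
  analytic oracle for the time-integration operators;
* :func:`make_bifurcation_mesh` — a parametric Y-shaped bifurcation surface
  (trunk + two branches) with a labelled apex at the flow divider;
* :func:`make_zonal_wss_field` — a time-resolved wall-shear field whose TAWSS
  rises from an impingement value at the apex to a peak along each branch and
  decays beyond it, reproducing the impingement / acceleration / recovery
  zone structure of bifurcation flow;
* :func:`make_pulse_waveform` / :func:`render_spectrogram` — a cardiac-cycle
  velocity waveform with prescribed Vps/Ved/Vm and its rendering as a
  spectral-Doppler-like image for digitiser round trips;
* :func:`make_cohort` — a seeded case-control table whose per-group medians,
  IQRs, dirWSSG proportions and intercorrelations are calibrated to the study
  conditions the statistics pipeline expects.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import optimize, special, stats

from .geometry import SurfaceMesh, geodesic_distances
from .tccs_digitizer import Calibration, Waveform
from .wall_metrics import TimeResolvedWallField

__all__ = [
    "BloodProperties",
    "ZonalFieldParams",
    "CohortParams",
    "womersley_wall_shear",
    "make_bifurcation_mesh",
    "make_zonal_wss_field",
    "make_pulse_waveform",
    "render_spectrogram",
    "make_cohort",
    "case_like_params",
    "control_like_params",
    "load_preset",
]


# ---------------------------------------------------------------------------
# blood properties and the Womersley oracle


@dataclass(frozen=True)
class BloodProperties:
    """Newtonian blood model: density (kg/m^3) and dynamic viscosity (Pa s)."""

    density: float = 1056.0
    viscosity: float = 0.0035

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("blood density and viscosity must be strictly positive")


def womersley_wall_shear(radius: float, props: BloodProperties,
                         pressure_harmonics: list[tuple[float, float]],
                         period: float, times: np.ndarray) -> np.ndarray:
    """Wall shear (Pa) of pulsatile flow in a rigid cylinder of radius R (m).

    ``pressure_harmonics[k]`` is ``(amplitude G_k in Pa/m, phase rad)`` of the
    driving pressure-gradient harmonic at frequency k/period; the k = 0 entry
    is the steady term (phase ignored) which contributes the Poiseuille wall
    shear ``G0 * R / 2``.  Each oscillatory harmonic contributes

        tau_k(t) = Re[ G_k R/2 * 2 J1(L) / (L J0(L)) * e^{i(k w t + phi_k)} ]

    with ``L = alpha_k e^{i 3 pi / 4}`` and Womersley number
    ``alpha_k = R sqrt(k w rho / mu)``.  In the low-alpha limit each harmonic
    approaches the quasi-steady value ``G_k R/2 cos(k w t + phi_k)``.
    """
    if radius <= 0 or period <= 0:
        raise ValueError("radius and period must be strictly positive")
    times = np.asarray(times, dtype=float)
    omega = 2.0 * math.pi / period
    tau = np.zeros_like(times)
    for k, (amp, phase) in enumerate(pressure_harmonics):
        if k == 0:
            tau = tau + amp * radius / 2.0
            continue
        alpha = radius * math.sqrt(k * omega * props.density / props.viscosity)
        lam = alpha * np.exp(1j * 3.0 * math.pi / 4.0)
        coef = (amp * radius / 2.0) * (2.0 * special.jv(1, lam) / (lam * special.jv(0, lam)))
        tau = tau + np.real(coef * np.exp(1j * (k * omega * times + phase)))
    return tau


# ---------------------------------------------------------------------------
# parametric bifurcation surface


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(points - closest, axis=1)


def make_bifurcation_mesh(trunk_radius: float = 2.5,
                          branch_radii: tuple[float, float] = (2.0, 1.8),
                          bifurcation_angle: float = 90.0,
                          edge_length: float = 0.3,
                          trunk_length: float = 8.0,
                          branch_length: float = 10.0,
                          blend: float = 0.4) -> SurfaceMesh:
    """Y-shaped bifurcation surface with apex vertex and branch labels.

    The surface is the zero level set of a smooth-min union of three capsule
    distance fields (trunk along -x into the origin; branches splayed by
    ``bifurcation_angle`` degrees about +x), triangulated by marching cubes at
    a voxel pitch of ``edge_length`` (mm).  Every vertex is labelled by its
    nearest centreline; the apex is the surface vertex at the flow-divider
    crotch between the two branches.
    """
    if trunk_radius <= 0 or min(branch_radii) <= 0:
        raise ValueError("radii must be positive")
    if not 0 < bifurcation_angle < 180:
        raise ValueError("bifurcation angle must lie in (0, 180) degrees")
    if edge_length <= 0:
        raise ValueError("edge length must be positive")
    from skimage.measure import marching_cubes

    half = math.radians(bifurcation_angle) / 2.0
    d1 = np.array([math.cos(half), math.sin(half), 0.0])
    d2 = np.array([math.cos(half), -math.sin(half), 0.0])
    segments = [
        (np.array([-trunk_length, 0.0, 0.0]), np.zeros(3), trunk_radius, "trunk"),
        (np.zeros(3), branch_length * d1, branch_radii[0], "branch1"),
        (np.zeros(3), branch_length * d2, branch_radii[1], "branch2"),
    ]
    rmax = max(trunk_radius, *branch_radii)
    pad = rmax + 3 * edge_length
    lo = np.array([-trunk_length - pad,
                   -branch_length * math.sin(half) - pad, -rmax - pad])
    hi = np.array([branch_length * math.cos(half) + pad,
                   branch_length * math.sin(half) + pad, rmax + pad])
    nx, ny, nz = [max(8, int(math.ceil((h - l) / edge_length)) + 1) for l, h in zip(lo, hi)]
    xs = np.linspace(lo[0], hi[0], nx)
    ys = np.linspace(lo[1], hi[1], ny)
    zs = np.linspace(lo[2], hi[2], nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    dists = np.stack([_segment_distance(pts, a, b) - r for a, b, r, _ in segments])
    # smooth min: negative inside the union, blended at the crotch
    k = blend
    sdf = -k * special.logsumexp(-dists / k, axis=0)
    vol = sdf.reshape(X.shape)
    spacing = (xs[1] - xs[0], ys[1] - ys[0], zs[1] - zs[0])
    verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=spacing)
    verts = verts + lo
    import trimesh

    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    tm.update_faces(tm.nondegenerate_faces(height=1e-9))
    tm.remove_unreferenced_vertices()
    verts = np.asarray(tm.vertices, float)
    faces = np.asarray(tm.faces, np.int64)
    # label by nearest centreline (surface offset by each capsule radius)
    vd = np.stack([_segment_distance(verts, a, b) - r for a, b, r, _ in segments])
    labels = np.array([segments[i][3] for i in np.argmin(vd, axis=0)])
    apex = _find_apex(verts, vd[1], vd[2], edge_length)
    return SurfaceMesh(vertices=verts, triangles=faces, apex_vertex=apex,
                       branch_labels=labels)


def _find_apex(verts: np.ndarray, d_branch1: np.ndarray, d_branch2: np.ndarray,
               edge_length: float) -> int:
    """Surface vertex at the flow-divider crotch.

    The crotch is the point of the inter-branch ridge lying in the bifurcation
    plane (z = 0): among in-plane vertices ahead of the bifurcation (x > 0) it
    uniquely minimises the larger of the two distances to the branch surfaces.
    """
    band = 1.6 * edge_length
    cand = (verts[:, 0] > 0) & (np.abs(verts[:, 2]) <= band)
    while not np.any(cand):
        band *= 2.0
        cand = (verts[:, 0] > 0) & (np.abs(verts[:, 2]) <= band)
    idx = np.flatnonzero(cand)
    score = np.maximum(d_branch1[idx], d_branch2[idx])
    return int(idx[np.argmin(score)])


# ---------------------------------------------------------------------------
# zonal wall-shear fields


@dataclass
class ZonalFieldParams:
    """Arclength TAWSS profile of the impingement/acceleration/recovery zones.

    ``tau_impingement`` (Pa) is the TAWSS at the apex (flow impingement);
    the profile rises linearly to ``tau_peak`` at ``peak_distance`` (mm of
    geodesic arclength) — the acceleration zone — then decays exponentially
    with ``decay_length`` (mm) — the recovery zone.  ``pulsatility`` modulates
    the instantaneous magnitude over the cycle and ``reversal_fraction`` flips
    the shear direction for that fraction of the cycle (raising OSI above 0).
    """

    tau_impingement: float = 25.0
    tau_peak: float = 100.0
    peak_distance: float = 7.0
    decay_length: float = 5.0
    pulsatility: float = 0.4
    reversal_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau_peak > self.tau_impingement >= 0:
            raise ValueError("need tau_peak > tau_impingement >= 0")
        if self.peak_distance <= 0 or self.decay_length <= 0:
            raise ValueError("peak_distance and decay_length must be positive")
        if not (0 <= self.pulsatility <= 1 and 0 <= self.reversal_fraction <= 1):
            raise ValueError("pulsatility and reversal_fraction must lie in [0, 1]")


def case_like_params() -> ZonalFieldParams:
    """Acceleration-zone preset: the TAWSS peak lies beyond the apex patch, so
    the high-WSS region sits on the rising limb (positive dirWSSG)."""
    return ZonalFieldParams(tau_impingement=25.0, tau_peak=100.0, peak_distance=7.0,
                            decay_length=5.0, pulsatility=0.4, reversal_fraction=0.08)


def control_like_params() -> ZonalFieldParams:
    """Recovery-zone preset: the TAWSS peak sits just off the apex, so the
    high-WSS region lies on the decaying limb (negative dirWSSG)."""
    return ZonalFieldParams(tau_impingement=85.0, tau_peak=90.0, peak_distance=1.0,
                            decay_length=4.0, pulsatility=0.4, reversal_fraction=0.1)


def _zonal_profile(s: np.ndarray, p: ZonalFieldParams) -> np.ndarray:
    rising = p.tau_impingement + (p.tau_peak - p.tau_impingement) * (s / p.peak_distance)
    decaying = p.tau_peak * np.exp(-(s - p.peak_distance) / p.decay_length)
    return np.where(s <= p.peak_distance, rising, decaying)


def make_zonal_wss_field(mesh: SurfaceMesh, params: ZonalFieldParams,
                         period: float = 0.9, n_times: int = 24,
                         seed: int | None = None, jitter: float = 0.0
                         ) -> TimeResolvedWallField:
    """Time-resolved wall-shear field with the zonal TAWSS profile.

    The shear direction at each vertex is its branch (or trunk) axis projected
    into the tangent plane; the magnitude follows the arclength profile from
    the apex, modulated over the cycle by ``1 + pulsatility * sin(2 pi t/T)``
    and flipped for the trailing ``reversal_fraction`` of the cycle.  Two
    cycles are generated and the first discarded (a pipeline convention for
    solver transients), so the returned times span exactly one cycle.
    ``jitter`` adds seeded multiplicative magnitude noise.
    """
    if mesh.apex_vertex is None or mesh.branch_labels is None:
        raise ValueError("mesh needs an apex vertex and branch labels")
    if n_times < 8:
        raise ValueError("need at least 8 time samples per cycle")
    s = geodesic_distances(mesh, mesh.apex_vertex)
    base = _zonal_profile(s, params)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        base = base * (1.0 + jitter * rng.standard_normal(len(base)))
        base = np.clip(base, 0.0, None)
    # per-vertex direction: local downstream direction away from the apex,
    # i.e. the tangent-plane gradient of the arclength field; branch-axis
    # projection as the fallback where that is degenerate (caps, apex point)
    from .geometry import tangent_gradient_field

    grad_s, grad_ok = tangent_gradient_field(mesh, s)
    dirs = np.where(grad_ok[:, None], grad_s, 0.0)
    mag = np.linalg.norm(np.nan_to_num(dirs), axis=1)
    dirs = np.nan_to_num(dirs)
    bad = mag < 1e-6
    if np.any(bad):
        axes = {"trunk": np.array([1.0, 0.0, 0.0])}
        for label in ("branch1", "branch2"):
            pts = mesh.vertices[mesh.branch_labels == label]
            axes[label] = _principal_direction(pts) if len(pts) else np.array([1.0, 0, 0])
        fallback = np.stack([axes[label] for label in mesh.branch_labels[bad]])
        n_bad = mesh.vertex_normals[bad]
        fallback = fallback - np.sum(fallback * n_bad, axis=1, keepdims=True) * n_bad
        fb_mag = np.linalg.norm(fallback, axis=1)
        fallback[fb_mag < 1e-8] = [1.0, 0.0, 0.0]
        dirs[bad] = fallback
        mag[bad] = np.linalg.norm(dirs[bad], axis=1)
    dirs = dirs / mag[:, None]
    # second of two generated cycles, remapped to [0, T]
    times = np.linspace(0.0, period, n_times)
    modulation = 1.0 + params.pulsatility * np.sin(2.0 * math.pi * times / period)
    if params.reversal_fraction > 0:
        flip = np.where(times / period >= 1.0 - params.reversal_fraction - 1e-12, -1.0, 1.0)
    else:
        flip = np.ones_like(times)
    vectors = base[:, None, None] * (modulation * flip)[None, :, None] * dirs[:, None, :]
    return TimeResolvedWallField(mesh=mesh, times=times, vectors=vectors)


def _principal_direction(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    d = vt[0]
    # orient away from the origin (apex side) so flow runs down the branch
    if d @ points.mean(axis=0) < 0:
        d = -d
    return d / np.linalg.norm(d)


# ---------------------------------------------------------------------------
# waveforms and spectrogram rendering


def make_pulse_waveform(vps: float = 97.4, ved: float = 44.0, vm: float = 66.4,
                        period: float = 0.9, n_samples: int = 256,
                        n_cycles: int = 1, skew: float = 0.5) -> Waveform:
    """Cardiac-cycle velocity waveform with prescribed Vps / Ved / Vm (cm/s).

    The pulse shape is ``sin(pi * u^skew)^beta`` on u in [0, 1] (skew < 1
    moves the systolic peak earlier in the cycle); ``beta`` is solved so the
    cycle mean equals ``vm`` exactly.  The waveform starts and ends at
    end-diastole (``ved``).  With ``n_cycles > 1`` the beat is tiled, for
    period-detection and digitiser tests; the result is cycle-cropped
    (``period`` set) only when a single cycle is requested.
    """
    if not ved < vm < vps:
        raise ValueError("need Ved < Vm < Vps")
    target = (vm - ved) / (vps - ved)
    u = np.linspace(0.0, 1.0, n_samples, endpoint=False)

    def mean_shape(beta: float) -> float:
        uu = np.linspace(0.0, 1.0, 4096)
        return float(np.trapezoid(np.sin(math.pi * uu**skew) ** beta, uu))

    beta = optimize.brentq(lambda b: mean_shape(b) - target, 1e-3, 50.0)
    one = ved + (vps - ved) * np.sin(math.pi * u**skew) ** beta
    v = np.tile(one, n_cycles)
    v = np.append(v, ved)  # close the final cycle at end-diastole
    t = np.linspace(0.0, n_cycles * period, len(v))
    return Waveform(times=t, velocities=v,
                    period=period if n_cycles == 1 else None)


def render_spectrogram(w: Waveform, size: tuple[int, int] = (300, 500),
                       calibration: Calibration | None = None,
                       noise_level: float = 0.0, seed: int | None = None,
                       path: str | Path | None = None
                       ) -> tuple[np.ndarray, Calibration]:
    """Render a waveform as a spectral-Doppler-like grayscale image.

    Per column the band from the baseline up to the waveform velocity is
    bright (with mild multiplicative speckle texture); ``noise_level`` adds
    seeded additive background noise of that fraction of full scale.  Returns
    the pixel array and the calibration used; optionally writes a PNG/BMP.
    Raises if the waveform exceeds the calibrated velocity axis.
    """
    rows, cols = size
    if calibration is None:
        baseline = rows - max(10, rows // 15)
        vmax = 1.15 * float(w.velocities.max())
        calibration = Calibration(
            seconds_per_px=float(w.times[-1] - w.times[0]) / (cols - 1),
            cm_s_per_px=float(vmax / baseline),
            baseline_row=int(baseline),
            t0=float(w.times[0]),
        )
    cal = calibration
    col_times = cal.t0 + np.arange(cols) * cal.seconds_per_px
    v = np.interp(col_times, w.times, w.velocities)
    top_rows = cal.baseline_row - v / cal.cm_s_per_px
    if np.any(top_rows < 0):
        raise ValueError("waveform exceeds the calibrated velocity axis")
    rng = np.random.default_rng(seed)
    img = np.zeros((rows, cols))
    rr = np.arange(rows)[:, None]
    band = (rr >= np.round(top_rows)[None, :]) & (rr <= cal.baseline_row)
    texture = rng.uniform(0.75, 1.0, size=img.shape)
    img[band] = 230.0 * texture[band]
    if noise_level > 0:
        img += np.abs(rng.normal(0.0, noise_level * 255.0, size=img.shape))
    img = np.clip(img, 0.0, 255.0)
    if path is not None:
        Image.fromarray(img.astype(np.uint8), mode="L").save(path)
    return img, cal


# ---------------------------------------------------------------------------
# cohort generator

_Z75 = stats.norm.ppf(0.75)

#: per-group (median, q25, q75) calibration targets of the study conditions
DEFAULT_TARGETS = {
    "case": {
        "WSS": (69.36, 59.27, 89.96),
        "WSSG": (11.05, -14.88, 28.06),
        "absWSSG": (23.63, 12.29, 56.13),
        "OSI": (0.175, 0.069, 0.319),
    },
    "control": {
        "WSS": (76.59, 61.92, 125.27),
        "WSSG": (-14.76, -64.49, 18.14),
        "absWSSG": (35.07, 15.29, 74.86),
        "OSI": (0.185, 0.0, 0.353),
    },
}

#: Spearman intercorrelations reproduced by the Gaussian copula
DEFAULT_SPEARMAN = {("WSS", "absWSSG"): 0.488, ("absWSSG", "OSI"): -0.309}


@dataclass
class CohortParams:
    """Study conditions of the synthetic case-control cohort."""

    n_case: int = 38
    n_control: int = 39
    p_dir_pos_case: float = 23.0 / 38.0
    p_dir_pos_control: float = 14.0 / 39.0
    targets: dict = field(default_factory=lambda: DEFAULT_TARGETS)
    spearman: dict = field(default_factory=lambda: DEFAULT_SPEARMAN)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("group sizes must be >= 1")
        for p in (self.p_dir_pos_case, self.p_dir_pos_control):
            if not 0 <= p <= 1:
                raise ValueError("dirWSSG probabilities must lie in [0, 1]")
        for group, metrics in self.targets.items():
            for name, (med, q25, q75) in metrics.items():
                if not q25 <= med <= q75 or q75 - q25 <= 0:
                    raise ValueError(f"infeasible target for {group}/{name}: IQR must be positive")


def _lognormal_from_quartiles(med: float, q25: float, q75: float) -> tuple[float, float]:
    if q25 <= 0:
        raise ValueError("log-normal calibration needs positive quartiles")
    mu = math.log(med)
    sigma = math.log(q75 / q25) / (2.0 * _Z75)
    return mu, sigma


def _beta_from_quantiles(med: float, q25: float, q75: float,
                         scale: float = 0.5) -> tuple[float, float, float]:
    """Scaled-beta on [0, scale] through the three quartiles.

    When q25 = 0 (a point mass at zero in the source summaries) the
    distribution is zero-inflated: P(X = 0) = pi0 slightly above 0.25 and the
    continuous part is a beta fitted to the remaining conditional quantiles.
    Returns (a, b, pi0).
    """
    pi0 = 0.0
    qs = np.array([0.25, 0.5, 0.75])
    targets = np.array([q25, med, q75]) / scale
    weights = np.array([1.0, 5.0, 1.0])  # the median target matters most
    if q25 <= 0:
        pi0 = 0.26
        qs = (np.array([0.5, 0.75]) - pi0) / (1.0 - pi0)
        targets = np.array([med, q75]) / scale
        weights = np.array([5.0, 1.0])

    def resid(logab: np.ndarray) -> np.ndarray:
        a, b = np.exp(logab)
        return weights * (stats.beta.ppf(qs, a, b) - targets)

    sol = optimize.least_squares(resid, x0=np.log([2.0, 4.0]), method="lm")
    a, b = np.exp(sol.x)
    return float(a), float(b), pi0


def _signed_quantile_fn(med: float, q25: float, q75: float, p_pos: float):
    """Monotone piecewise-linear quantile function through the quartiles and
    the zero crossing at u = 1 - p_pos, with logarithmic tails."""
    anchors = [(0.25, q25), (0.5, med), (0.75, q75)]
    u0 = 1.0 - p_pos
    if 0.0 < u0 < 1.0:
        anchors.append((u0, 0.0))
    anchors.sort()
    us = np.array([a[0] for a in anchors])
    vs = np.array([a[1] for a in anchors])
    if np.any(np.diff(us) <= 0) or np.any(np.diff(vs) < 0):
        raise ValueError("signed-metric targets inconsistent with the sign probability")
    s_lo = max((med - q25) / math.log(2.0), 1e-9)
    s_hi = max((q75 - med) / math.log(2.0), 1e-9)

    def q(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        out = np.interp(u, us, vs)
        lo = u < us[0]
        hi = u > us[-1]
        out[lo] = vs[0] - s_lo * np.log(us[0] / u[lo])
        out[hi] = vs[-1] + s_hi * np.log((1.0 - us[-1]) / (1.0 - u[hi]))
        return out

    return q


def _median_sharpen(u: np.ndarray, fixed: tuple[float, ...] = (),
                    slope: float = 0.1, half_width: float = 0.05) -> np.ndarray:
    """Monotone probability map that preserves 0, the quartiles, 1 and any
    extra ``fixed`` points while compressing ``[0.5 - hw, 0.5 + hw]`` towards
    the median (central slope ``slope``).

    Composing a quantile function with this map leaves all quartile anchors
    exact but concentrates probability mass at the median, so finite-sample
    medians converge tightly to the calibration target.
    """
    hw = half_width
    for f in fixed:
        if 0.0 < f < 1.0:
            hw = min(hw, abs(f - 0.5) * 0.9) if abs(f - 0.5) < hw else hw
    eps = slope * hw
    xs = sorted({0.0, 0.25, 0.75, 1.0, 0.5 - hw, 0.5 + hw, *[f for f in fixed if 0 < f < 1]})
    ys = [0.5 - eps if abs(x - (0.5 - hw)) < 1e-12 else
          0.5 + eps if abs(x - (0.5 + hw)) < 1e-12 else x for x in xs]
    return np.interp(u, xs, ys)


def make_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Seeded synthetic case-control table (one row per subject).

    Columns: subject_id, group ("case"/"control"), WSS (Pa), WSSG (Pa/mm),
    absWSSG (Pa/mm), OSI, dirWSSG (1 positive / 0 negative).

    WSS and absWSSG are log-normal with median/IQR solved in closed form from
    the group targets; OSI is a (zero-inflated where needed) scaled beta on
    [0, 0.5]; the signed WSSG is drawn from a quantile function anchored at
    the group quartiles and at a zero crossing at u = 1 - p_dir_pos, which
    makes dirWSSG = [WSSG > 0] exactly Bernoulli with the group proportion and
    always sign-consistent with WSSG.  All quantile functions are composed
    with a quartile-preserving, median-concentrating probability map (see
    :func:`_median_sharpen`) so sample medians calibrate tightly at finite n.
    A Gaussian copula couples WSS, absWSSG and OSI at the configured Spearman
    correlations.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)
    frames = []
    for group, n, p_pos in (("case", params.n_case, params.p_dir_pos_case),
                            ("control", params.n_control, params.p_dir_pos_control)):
        tg = params.targets[group]
        # copula for (WSS, absWSSG, OSI)
        names = ["WSS", "absWSSG", "OSI"]
        corr = np.eye(3)
        for (a, b), rho_s in params.spearman.items():
            if a in names and b in names:
                i, j = names.index(a), names.index(b)
                r = 2.0 * math.sin(math.pi * rho_s / 6.0)  # Spearman -> Pearson
                corr[i, j] = corr[j, i] = r
        z = rng.multivariate_normal(np.zeros(3), corr, size=n, method="cholesky")
        u = _median_sharpen(stats.norm.cdf(z))
        mu_w, sg_w = _lognormal_from_quartiles(*tg["WSS"])
        wss = np.exp(mu_w + sg_w * stats.norm.ppf(u[:, 0]))
        mu_a, sg_a = _lognormal_from_quartiles(*tg["absWSSG"])
        abswssg = np.exp(mu_a + sg_a * stats.norm.ppf(u[:, 1]))
        a_b, b_b, pi0 = _beta_from_quantiles(*tg["OSI"])
        u_osi = u[:, 2]
        osi = np.where(u_osi < pi0, 0.0,
                       0.5 * stats.beta.ppf(np.clip((u_osi - pi0) / (1.0 - pi0), 0, 1), a_b, b_b))
        # signed WSSG; its zero crossing at u0 makes dirWSSG ~ Bernoulli(p_pos)
        u0 = 1.0 - p_pos
        qfn = _signed_quantile_fn(*tg["WSSG"], p_pos=p_pos)
        u_w = _median_sharpen(rng.uniform(size=n), fixed=(u0,))
        wssg = qfn(u_w)
        dir_pos = u_w > u0 if 0.0 < u0 < 1.0 else np.full(n, p_pos >= 0.5)
        if u0 <= 0.0:
            dir_pos = np.ones(n, dtype=bool)
        elif u0 >= 1.0:
            dir_pos = np.zeros(n, dtype=bool)
        prefix = "case" if group == "case" else "ctrl"
        frames.append(pd.DataFrame({
            "subject_id": [f"{prefix}_{i + 1:05d}" for i in range(n)],
            "group": group,
            "WSS": wss,
            "WSSG": wssg,
            "absWSSG": abswssg,
            "OSI": np.clip(osi, 0.0, 0.5),
            "dirWSSG": dir_pos.astype(int),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# presets

_PRESET_DIR = Path(__file__).parent / "presets"


def load_preset(name: str) -> dict:
    """Load a shipped YAML preset (``case_like``, ``control_like``,
    ``cohort_default``) or a path to a user YAML file."""
    import yaml

    p = Path(name)
    if not p.exists():
        p = _PRESET_DIR / f"{name}.yaml"
    if not p.exists():
        raise FileNotFoundError(f"no preset or file named {name!r}")
    return yaml.safe_load(p.read_text())
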
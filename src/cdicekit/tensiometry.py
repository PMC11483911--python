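"""Pendant-drop tensiometry: Young--Laplace profiles, fits and tensiograms.

A pendant drop hanging from a needle deforms away from a sphere by an
amount set by the shape parameter ``beta = drho g b^2 / gamma``, where
``b`` is the radius of curvature at the drop apex.  In the arc-length
(Bashforth--Adams) form, with lengths scaled by ``b`` and the turning
angle ``phi`` measured from the apex::

    dX/dS = cos(phi)
    dZ/dS = sin(phi)
    dphi/dS = 2 - beta Z - sin(phi)/X

(Z increases from the apex toward the needle; at the apex both principal
curvatures equal 1/b, so dphi/dS -> 1 as S -> 0.)  Fitting this forward
model to a measured silhouette by least squares yields the interfacial
tension — the core of drop-shape analysis.

The tensiogram side implements the time-series conventions used when
tracking lipid/protein adsorption at a water--oil interface: a 1 s rolling
mean, truncation at drop detachment, and discarding runs whose tension
collapses abnormally fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "DropContour",
    "PendantFit",
    "Tensiogram",
    "NEEDLE_DIAMETER",
    "DROP_VOLUME",
    "STANDARD_GRAVITY",
    "young_laplace_profile",
    "fit_tension",
    "contour_volume",
    "tensiogram_pipeline",
    "synthetic_tensiogram",
    "TENSIOGRAM_PRESETS",
]

#: Dosing-needle diameter (m) and final drop volume (m^3) of the
#: instrument protocol the fixtures emulate.
NEEDLE_DIAMETER = 0.313e-3
DROP_VOLUME = 8e-9
STANDARD_GRAVITY = 9.81


@dataclass(frozen=True)
class DropContour:
    """Silhouette of a pendant drop.

    ``points`` is an (N, 2) array of (x, z) coordinates in metres with the
    symmetry axis at x = 0 and z increasing from the apex toward the
    needle.  Both sides of the silhouette may be present (x of either
    sign).
    """

    points: np.ndarray
    needle_diameter: float = NEEDLE_DIAMETER
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 20:
            raise ValueError("contour needs >= 20 (x, z) points")
        object.__setattr__(self, "points", pts)

    def asymmetry(self) -> float:
        """Relative mismatch between left and right silhouette radii.

        Returns 0 for one-sided contours.
        """
        x, z = self.points[:, 0], self.points[:, 1]
        left, right = x < 0, x > 0
        if left.sum() < 2 or right.sum() < 2:
            return 0.0
        zs = np.linspace(
            max(z[left].min(), z[right].min()), min(z[left].max(), z[right].max()), 50
        )
        rl = np.interp(zs, z[left][np.argsort(z[left])], -x[left][np.argsort(z[left])])
        rr = np.interp(zs, z[right][np.argsort(z[right])], x[right][np.argsort(z[right])])
        scale = max(np.abs(x).max(), 1e-30)
        return float(np.max(np.abs(rl - rr)) / scale)


@dataclass(frozen=True)
class PendantFit:
    """Result of fitting the Young--Laplace model to one contour."""

    tension: float  # N/m
    apex_radius: float  # m
    apex_position: tuple[float, float]  # (x, z) m
    residual_rms: float  # m
    converged: bool
    volume: float | None = None  # m^3
    timestamp: float = 0.0
    message: str = ""


def _integrate_profile(beta: float, rn_over_b: float | None, s_max: float = 6.0):
    """Integrate the nondimensional Bashforth--Adams system from the apex.

    Returns ``(S, X, Z, phi, V, reason)`` sampled densely along the arc,
    where V is the running solid-of-revolution volume (nondimensional,
    scaled by b^3).  Integration terminates at the first of:

    * ``needle`` — the silhouette radius comes back down to ``rn_over_b``
      (attachment of the drop to the dosing needle),
    * ``neck`` — the turning angle falls back through pi/2 (the neck
      reopens; no equilibrium drop continues past its narrowest point),
    * ``overturn`` — phi reaches pi (the profile closes, spherical limit),
    * ``s_max`` — arc-length budget exhausted.
    """

    def rhs(s, y):
        x, z, phi, v = y
        sinphi = math.sin(phi)
        curv = sinphi / x if x > 1e-12 else 1.0  # apex limit sin(phi)/x -> dphi/ds
        return [math.cos(phi), sinphi, 2.0 - beta * z - curv, math.pi * x * x * sinphi]

    def needle(s, y):
        return y[0] - (rn_over_b if rn_over_b is not None else -1.0)

    needle.terminal = True
    needle.direction = -1

    def neck(s, y):  # phi falling back through pi/2: neck reopening
        return y[2] - math.pi / 2.0

    neck.terminal = True
    neck.direction = -1

    def overturn(s, y):
        return y[2] - math.pi

    overturn.terminal = True
    overturn.direction = 1

    s0 = 1e-6
    y0 = [s0, s0 * s0 / 2.0, s0, 0.0]
    sol = solve_ivp(
        rhs,
        (s0, s_max),
        y0,
        events=[needle, neck, overturn],
        rtol=1e-10,
        atol=1e-12,
        dense_output=True,
        max_step=0.05,
    )
    if not sol.success:
        raise RuntimeError(f"Young-Laplace integration failed: {sol.message}")
    s_end, reason = sol.t[-1], "s_max"
    for idx, name in ((0, "needle"), (1, "neck"), (2, "overturn")):
        if sol.t_events[idx].size:
            s_end, reason = sol.t_events[idx][0], name
            break
    s_samples = np.linspace(s0, s_end, 2000)
    x, z, phi, v = sol.sol(s_samples)
    return s_samples, x, z, phi, v, reason


def young_laplace_profile(
    apex_radius: float,
    tension: float,
    delta_density: float,
    gravity: float = STANDARD_GRAVITY,
    needle_diameter: float = NEEDLE_DIAMETER,
    n_points: int = 200,
    two_sided: bool = True,
    timestamp: float = 0.0,
    require_attachment: bool = False,
) -> DropContour:
    """Generate the axisymmetric pendant-drop silhouette.

    Integrates the Bashforth--Adams system with apex curvature
    ``2/apex_radius`` and hydrostatic term ``drho g z / gamma`` until the
    profile returns to the needle radius, or — for drops whose neck never
    narrows to the needle — until the neck's narrowest point.
    ``delta_density = 0`` gives the spherical (zero-Bond) limit.

    With ``require_attachment=True`` a profile that cannot attach to the
    needle (tension too low, or the needle too thin, for the drop to
    hang) raises a diagnostic ``RuntimeError`` instead of truncating.

    Returns a :class:`DropContour` with ``n_points`` per side, ordered
    from needle (left side) around the apex back to the needle.
    """
    if apex_radius <= 0 or tension <= 0 or gravity < 0 or delta_density < 0:
        raise ValueError("apex_radius and tension must be > 0; drho, g >= 0")
    b = apex_radius
    beta = delta_density * gravity * b * b / tension
    rn_over_b = (needle_diameter / 2.0) / b
    s, x, z, phi, _, reason = _integrate_profile(beta, rn_over_b)
    if require_attachment and reason != "needle":
        raise RuntimeError(
            f"profile terminated by {reason!r} before reaching the needle radius: "
            "the tension is too low (or the needle too thin) for this drop to hang"
        )
    idx = np.linspace(0, len(s) - 1, n_points).round().astype(int)
    xr = x[idx] * b
    zr = z[idx] * b
    if two_sided:
        pts = np.concatenate(
            [np.column_stack([-xr[::-1], zr[::-1]]), np.column_stack([xr, zr])]
        )
    else:
        pts = np.column_stack([xr, zr])
    return DropContour(pts, needle_diameter=needle_diameter, timestamp=timestamp)


def contour_volume(contour: DropContour) -> float:
    """Drop volume (m^3) by solid of revolution of the silhouette."""
    x, z = np.abs(contour.points[:, 0]), contour.points[:, 1]
    order = np.argsort(z)
    z, x = z[order], x[order]
    keep = np.concatenate([[True], np.diff(z) > 0])
    return float(np.trapezoid(math.pi * x[keep] ** 2, z[keep]))


def _initial_guess(points: np.ndarray, delta_density: float, gravity: float):
    """Shape-factor starting point for (gamma, b, x0, z0).

    A coarse grid of shape parameters is screened: for each candidate
    ``beta`` the nondimensional profile is integrated once and scaled so
    its maximum silhouette radius matches the data; the candidate with the
    smallest radial misfit wins.  This is the classical diameter-ratio
    idea (drop elongation encodes ``beta``) made numerical.
    """
    x, z = points[:, 0], points[:, 1]
    z0 = float(z.min())
    x0 = float(np.mean(x[z <= z0 + 0.05 * (z.max() - z0 + 1e-30)]))
    r_data = np.abs(x - x0)
    r_max = r_data.max()
    best = None
    for beta0 in (0.02, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6):
        try:
            _, xp, zp, _, _, _ = _integrate_profile(beta0, None)
        except RuntimeError:
            continue
        b0 = r_max / xp.max()
        pred = np.interp(z - z0, zp * b0, xp * b0)
        cost = float(np.mean((r_data - pred) ** 2))
        if best is None or cost < best[0]:
            best = (cost, beta0, b0)
    _, beta0, b0 = best
    gamma0 = delta_density * gravity * b0 * b0 / beta0 if delta_density > 0 else 1e-3
    return gamma0, float(b0), x0, z0


def fit_tension(
    contour: DropContour,
    delta_density: float,
    gravity: float = STANDARD_GRAVITY,
    initial_guess: tuple[float, float] | None = None,
) -> PendantFit:
    """Fit (tension, apex radius, apex position) to a measured contour.

    Least-squares on radial residuals: for each contour point the
    predicted silhouette radius at its height, interpolated on the densely
    integrated profile (z is monotone along the arc for a hanging drop, so
    the silhouette radius is single-valued in z).  Convergence follows the
    optimizer's parameter/residual tolerances (1e-10); non-convergence is
    reported in the returned object, never silently.

    Parameters
    ----------
    initial_guess : (gamma, b), optional
        Overrides the automatic apex-circle starting point.
    """
    if delta_density <= 0:
        raise ValueError("delta_density must be > 0 for a fit")
    pts = contour.points
    gamma0, b0, x00, z00 = _initial_guess(pts, delta_density, gravity)
    if initial_guess is not None:
        gamma0, b0 = initial_guess

    def residuals(theta):
        lg, lb, x0, z0 = theta
        gamma, b = math.exp(lg), math.exp(lb)
        beta = delta_density * gravity * b * b / gamma
        try:
            _, x, z, _, _, _ = _integrate_profile(min(beta, 50.0), None)
        except RuntimeError:
            return np.full(pts.shape[0], 1e3 * b0)
        z_prof = z * b + z0
        x_prof = x * b
        r = np.abs(pts[:, 0] - x0)
        pred = np.interp(pts[:, 1], z_prof, x_prof)
        # penalise data above the integrated profile end
        overshoot = np.clip(pts[:, 1] - z_prof[-1], 0.0, None)
        return (r - pred) + overshoot

    theta0 = np.array([math.log(gamma0), math.log(b0), x00, z00])
    scale = max(np.abs(pts[:, 0]).max(), 1e-9)
    result = least_squares(
        residuals,
        theta0,
        method="lm",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=400,
    )
    gamma, b = math.exp(result.x[0]), math.exp(result.x[1])
    rms = float(np.sqrt(np.mean(result.fun**2)))
    converged = bool(result.success and rms < 0.05 * scale)
    volume = contour_volume(contour) if converged else None
    return PendantFit(
        tension=gamma,
        apex_radius=b,
        apex_position=(float(result.x[2]), float(result.x[3])),
        residual_rms=rms,
        converged=converged,
        volume=volume,
        timestamp=contour.timestamp,
        message=str(result.message),
    )


# ---------------------------------------------------------------------------
# Tensiograms
# ---------------------------------------------------------------------------


@dataclass
class Tensiogram:
    """Interfacial-tension time series after smoothing and truncation."""

    times: np.ndarray  # s
    tension_raw: np.ndarray  # N/m
    tension_smoothed: np.ndarray  # N/m
    detachment_time: float | None = None
    discarded: bool = False
    discard_reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "tension_raw_n_per_m": self.tension_raw,
                "tension_smoothed_n_per_m": self.tension_smoothed,
            }
        )


def tensiogram_pipeline(
    fits: list[PendantFit],
    sampling_rate: float,
    min_duration: float | None = None,
    nominal_duration: float | None = None,
    consecutive_failures: int = 3,
    volume_drop_fraction: float = 0.5,
    smoothing_window_s: float = 1.0,
) -> Tensiogram:
    """Assemble per-frame fits into a smoothed, truncated tensiogram.

    Smoothing is a centred rolling mean of ``smoothing_window_s`` seconds
    (``sampling_rate`` points per second).  Detachment is declared at the
    first of ``consecutive_failures`` consecutive non-converged fits or at
    a frame whose drop volume fell by more than ``volume_drop_fraction``
    relative to the previous frame; all samples at or after that time are
    removed.  Runs detaching before ``min_duration`` (default 10% of the
    nominal duration) are flagged as discarded — the signature of an
    abnormally fast tension collapse.
    """
    if not fits:
        raise ValueError("empty fit series")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    times = np.array([f.timestamp for f in fits], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("fit timestamps must be monotone")
    tension = np.array([f.tension for f in fits], dtype=float)

    detach_idx: int | None = None
    bad_run = 0
    prev_volume = None
    for i, f in enumerate(fits):
        if not f.converged:
            bad_run += 1
            if bad_run >= consecutive_failures:
                detach_idx = i - consecutive_failures + 1
                break
        else:
            bad_run = 0
        if f.volume is not None and prev_volume is not None:
            if f.volume < (1.0 - volume_drop_fraction) * prev_volume:
                detach_idx = i
                break
        if f.volume is not None:
            prev_volume = f.volume

    detachment_time = None
    if detach_idx is not None:
        detachment_time = float(times[detach_idx])
        keep = times < detachment_time
        times, tension = times[keep], tension[keep]

    window = max(1, int(round(smoothing_window_s * sampling_rate)))
    smoothed = (
        pd.Series(tension).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )

    if nominal_duration is None:
        nominal_duration = float(np.array([f.timestamp for f in fits]).max()) or 1.0
    if min_duration is None:
        min_duration = 0.1 * nominal_duration
    discarded = False
    reason = ""
    if detachment_time is not None and detachment_time < min_duration:
        discarded = True
        reason = (
            f"detachment at {detachment_time:.3g} s, before the minimum duration "
            f"{min_duration:.3g} s (abnormally fast tension decrease)"
        )
    return Tensiogram(times, tension, smoothed, detachment_time, discarded, reason)


#: Qualitative adsorption-kinetics presets: solutions combining protein and
#: lipids equilibrate faster (smaller tau) than lipid-only dispersions.
TENSIOGRAM_PRESETS: dict[str, dict] = {
    "lipid_only": dict(gamma_start=25e-3, gamma_end=4e-3, timescale=120.0),
    "protein_only": dict(gamma_start=25e-3, gamma_end=8e-3, timescale=100.0),
    "protein_lipid": dict(gamma_start=25e-3, gamma_end=2e-3, timescale=40.0),
}


def synthetic_tensiogram(
    gamma_start: float,
    gamma_end: float,
    timescale: float,
    noise: float = 0.0,
    duration: float = 300.0,
    sampling_rate: float = 5.0,
    seed: int | None = None,
    detachment_time: float | None = None,
) -> list[PendantFit]:
    """Generate a fit series with exponential adsorption kinetics.

    ``gamma(t) = gamma_end + (gamma_start - gamma_end) exp(-t / tau)``
    plus additive Gaussian noise (absolute, N/m).  If ``detachment_time``
    is given, fits at or after that time are marked non-converged with
    collapsed volume, emulating the drop falling off the needle.
    """
    if not gamma_start >= gamma_end > 0:
        raise ValueError("need gamma_start >= gamma_end > 0")
    if timescale <= 0 or duration <= 0 or sampling_rate <= 0:
        raise ValueError("timescale, duration, sampling_rate must be > 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration, 1.0 / sampling_rate)
    gamma = gamma_end + (gamma_start - gamma_end) * np.exp(-times / timescale)
    if noise > 0:
        gamma = gamma + rng.normal(0.0, noise, size=times.size)
    fits = []
    for t, g in zip(times, gamma):
        detached = detachment_time is not None and t >= detachment_time
        fits.append(
            PendantFit(
                tension=float(max(g, 1e-8)),
                apex_radius=1e-3,
                apex_position=(0.0, 0.0),
                residual_rms=0.0 if not detached else 1.0,
                converged=not detached,
                volume=DROP_VOLUME if not detached else DROP_VOLUME * 0.01,
                timestamp=float(t),
            )
        )
    return fits
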
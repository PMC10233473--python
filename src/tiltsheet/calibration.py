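"""Light-sheet profile calibration.

Given a z-scan of direct-beam images of the sheet, fit a 1D Gaussian per
focal plane to get the stripe centre and FWHM, estimate the tilt angle from
the linear drift of the centre with z, fit the Gaussian-beam thickness
hyperbola to recover the waist and Rayleigh range, and compute the
effective field of view (eFOV).

Geometry: the sheet mid-plane obeys ``center(z) = z / tan(theta) + c`` so
the OLS slope of centre vs z gives the tilt.  A stripe imaged in a z-plane
is the oblique cut of the sheet, hence its lateral FWHM along x is the
perpendicular sheet thickness divided by ``sin(theta)``; the hyperbola is
fitted to the perpendicular thickness against the in-plane propagation
coordinate ``s = z / sin(theta)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ProfileFit",
    "WaistFit",
    "ProfileCalibration",
    "CalibrationError",
    "fit_profile_1d",
    "calibrate_stack",
    "estimate_tilt",
    "estimate_waist",
    "compute_efov",
]


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ProfileFit:
    center: float
    fwhm: float
    amplitude: float
    baseline: float
    ok: bool = True


@dataclass(frozen=True)
class WaistFit:
    waist_fwhm_um: float
    rayleigh_um: float
    focus_z_um: float
    degenerate: bool = False


@dataclass
class ProfileCalibration:
    """Per-z stripe fits plus the derived sheet parameters."""

    z_um: np.ndarray
    center_um: np.ndarray
    fwhm_um: np.ndarray           # perpendicular sheet thickness per z
    fwhm_lateral_um: np.ndarray   # stripe FWHM as measured along x
    tilt_deg: float
    waist_fwhm_um: float
    rayleigh_um: float
    focus_z_um: float
    efov_um: float
    flags: dict = field(default_factory=dict)


_FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def _gauss(x, amp, center, sigma, baseline):
    return baseline + amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def fit_profile_1d(profile: np.ndarray, axis: np.ndarray | None = None) -> ProfileFit:
    """Nonlinear least-squares Gaussian + constant baseline fit of a 1D profile.

    ``axis`` gives the coordinate of each sample (defaults to the sample
    index); centre and FWHM are returned in those units.  A flat profile
    raises; a degenerate/non-converging fit returns ``ok=False`` so callers
    can drop it.
    """
    profile = np.asarray(profile, float)
    if profile.ndim != 1 or profile.size < 7:
        raise ValueError("profile must be 1D with at least 7 samples")
    if not np.all(np.isfinite(profile)):
        raise ValueError("profile contains non-finite values")
    x = np.arange(profile.size, dtype=float) if axis is None else np.asarray(axis, float)

    baseline0 = float(np.percentile(profile, 10))
    amp0 = float(profile.max() - baseline0)
    if amp0 <= 0 or np.ptp(profile) < 1e-12 * max(1.0, abs(profile.max())):
        raise CalibrationError("flat profile: no peak to fit")
    center0 = float(x[int(np.argmax(profile))])
    weights = np.clip(profile - baseline0, 0.0, None)
    wsum = weights.sum()
    if wsum > 0:
        mu = float((weights * x).sum() / wsum)
        var = float((weights * (x - mu) ** 2).sum() / wsum)
        sigma0 = math.sqrt(max(var, (x[1] - x[0]) ** 2 / 12.0))
    else:  # pragma: no cover - guarded by the flat check
        sigma0 = (x[-1] - x[0]) / 6.0
    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            profile,
            p0=(amp0, center0, sigma0, baseline0),
            maxfev=5000,
        )
    except RuntimeError:
        return ProfileFit(np.nan, np.nan, np.nan, np.nan, ok=False)
    amp, center, sigma, baseline = popt
    sigma = abs(float(sigma))
    if amp <= 0 or not (x.min() - (x.max() - x.min()) <= center <= x.max() + (x.max() - x.min())):
        return ProfileFit(float(center), _FWHM_SIGMA * sigma, float(amp), float(baseline), ok=False)
    return ProfileFit(float(center), _FWHM_SIGMA * sigma, float(amp), float(baseline))


def estimate_tilt(center_um: np.ndarray, z_um: np.ndarray) -> float:
    """Tilt angle (degrees) from the drift of the stripe centre with z.

    OLS slope ``m = d(center)/dz``; the sheet plane satisfies
    ``center(z) = z / tan(theta) + c`` so ``theta = atan2(1, m)``.  A
    non-positive slope is an orientation ambiguity: warn and use |m|.
    """
    center = np.asarray(center_um, float)
    z = np.asarray(z_um, float)
    if center.size < 3 or center.size != z.size:
        raise ValueError("need at least 3 matched (z, center) points")
    m = float(np.polyfit(z, center, 1)[0])
    if m < 0:
        warnings.warn("negative centre-drift slope; using |slope| (orientation ambiguity)")
        m = -m
    return math.degrees(math.atan2(1.0, m))


def _hyperbola(s, f0, s0, sr):
    return f0 * np.sqrt(1.0 + ((s - s0) / sr) ** 2)


def estimate_waist(
    fwhm_um: np.ndarray, z_um: np.ndarray, tilt_deg: float
) -> WaistFit:
    """Fit the Gaussian-beam thickness hyperbola to FWHM(z).

    ``FWHM(s) = F0 * sqrt(1 + ((s - s0)/sR)^2)`` with ``s = z / sin(tilt)``
    the distance along the propagation axis.  Returns the waist FWHM,
    Rayleigh range and the z of the focus.  A monotone or constant series
    has no interior minimum: warn and return the boundary minimum flagged
    degenerate.
    """
    fwhm = np.asarray(fwhm_um, float)
    z = np.asarray(z_um, float)
    if fwhm.size < 5 or fwhm.size != z.size:
        raise ValueError("need at least 5 matched (z, fwhm) points")
    sin_t = math.sin(math.radians(tilt_deg))
    if sin_t <= 0:
        raise ValueError("tilt_deg must be in (0, 90]")
    s = z / sin_t

    i_min = int(np.argmin(fwhm))
    span = fwhm.max() - fwhm.min()
    interior = 0 < i_min < fwhm.size - 1
    if span < 1e-9 * max(1.0, fwhm.max()) or not interior:
        warnings.warn("FWHM series has no interior minimum; returning boundary value")
        return WaistFit(float(fwhm[i_min]), np.inf, float(z[i_min]), degenerate=True)

    p0 = (float(fwhm[i_min]), float(s[i_min]), max((s.max() - s.min()) / 4.0, 1e-6))
    try:
        popt, _ = curve_fit(_hyperbola, s, fwhm, p0=p0, maxfev=10000)
    except RuntimeError:
        warnings.warn("hyperbola fit failed; returning boundary minimum")
        return WaistFit(float(fwhm[i_min]), np.inf, float(z[i_min]), degenerate=True)
    f0, s0, sr = popt
    return WaistFit(float(abs(f0)), float(abs(sr)), float(s0 * sin_t))


def compute_efov(fwhm_um: float, tilt_deg: float) -> float:
    """Effective field of view: the lateral extent of the focal plane lying
    inside the sheet's FWHM thickness, ``fwhm / sin(tilt)``."""
    if fwhm_um <= 0:
        raise ValueError("fwhm_um must be positive")
    if not 0.0 < tilt_deg <= 90.0:
        raise ValueError("tilt_deg must be in (0, 90]")
    return fwhm_um / math.sin(math.radians(tilt_deg))


def _oblique_cut_model(p, x_um, z_um):
    """Collapsed-profile surface of a tilted Gaussian sheet imaged per z-plane.

    ``p = (theta_rad, w0, zR, x0, s1, A, B)``: the stripe seen at focal
    plane z is the oblique cut of the beam, so the thickness varies across
    the cut — the effect that biases naive per-z Gaussian widths for thick
    sheets at shallow tilt.
    """
    theta, w0, zr, x0, s1, amp, base = p
    dx = x_um[None, :] - x0
    z = z_um[:, None]
    d = z * math.cos(theta) - dx * math.sin(theta)
    s = dx * math.cos(theta) + z * math.sin(theta) - s1
    w = w0 * np.sqrt(1.0 + (s / zr) ** 2)
    return amp * (w0 / w) * np.exp(-2.0 * d**2 / w**2) + base


def _refine_joint_fit(profiles, x_um, z_um, tilt_deg, waist: WaistFit, center_at_focus):
    """Joint least-squares fit of every collapsed profile to the oblique-cut
    model, seeded by the two-step estimates."""
    theta0 = math.radians(tilt_deg)
    w0_0 = max(waist.waist_fwhm_um / _FWHM_SIGMA * 2.0, 0.05)  # FWHM -> w0
    zr0 = waist.rayleigh_um if np.isfinite(waist.rayleigh_um) else 10.0
    base0 = float(np.percentile(profiles, 10))
    amp0 = float(profiles.max() - base0)
    p0 = np.array([theta0, w0_0, zr0, center_at_focus, 0.0, amp0, base0])

    def residuals(p):
        return (_oblique_cut_model(p, x_um, z_um) - profiles).ravel()

    from scipy.optimize import least_squares

    res = least_squares(
        residuals,
        p0,
        bounds=(
            [math.radians(1), 1e-3, 1e-2, x_um.min() - 50, -50, 0, -np.inf],
            [math.radians(89.9), 50, 1e4, x_um.max() + 50, 50, np.inf, np.inf],
        ),
        max_nfev=400,
    )
    if not res.success and res.status <= 0:
        return None
    return res.x


def calibrate_stack(
    stack: np.ndarray,
    z_um: np.ndarray,
    pixel_um: float = 0.157,
    stripe_axis: int = 0,
    max_failed_fraction: float = 0.2,
    refine: bool = True,
) -> ProfileCalibration:
    """Full calibration of a profile z-scan.

    Collapses each per-z image along the stripe axis (mean), fits the 1D
    Gaussian per plane, then estimates tilt from centre drift, converts the
    lateral stripe FWHM to perpendicular sheet thickness (* sin(tilt)), fits
    the thickness hyperbola, and computes the eFOV at the waist.

    With ``refine`` (default) the two-step estimates seed a joint fit of
    all collapsed profiles to the oblique-cut beam model, which removes the
    across-the-cut broadening bias of the per-z widths; the per-z series
    are reported unchanged.
    """
    stack = np.asarray(stack, float)
    z_um = np.asarray(z_um, float)
    if stack.ndim != 3 or stack.shape[0] != z_um.size:
        raise ValueError("stack must be (n_z, H, W) matching z_um")
    centers = np.full(z_um.size, np.nan)
    fwhm_lat = np.full(z_um.size, np.nan)
    n_failed = 0
    for i in range(z_um.size):
        profile = stack[i].mean(axis=stripe_axis)
        axis = (np.arange(profile.size) + 0.5) * pixel_um
        try:
            fit = fit_profile_1d(profile, axis=axis)
        except CalibrationError:
            n_failed += 1
            continue
        if not fit.ok:
            n_failed += 1
            continue
        centers[i] = fit.center
        fwhm_lat[i] = fit.fwhm
    if n_failed > max_failed_fraction * z_um.size:
        raise CalibrationError(
            f"{n_failed}/{z_um.size} per-z Gaussian fits failed"
        )
    good = np.isfinite(centers)
    tilt = estimate_tilt(centers[good], z_um[good])
    sin_t = math.sin(math.radians(tilt))
    fwhm_perp = fwhm_lat * sin_t
    waist = estimate_waist(fwhm_perp[good], z_um[good], tilt)
    refined = False
    if refine and not waist.degenerate:
        profiles = np.stack(
            [stack[i].mean(axis=stripe_axis) for i in range(z_um.size)]
        )
        x_axis = (np.arange(profiles.shape[1]) + 0.5) * pixel_um
        i_focus = int(np.nanargmin(np.where(good, fwhm_perp, np.nan)))
        p = _refine_joint_fit(
            profiles, x_axis, z_um, tilt, waist, float(centers[i_focus])
        )
        if p is not None:
            theta, w0, zr, _x0, s1, _a, _b = p
            tilt = math.degrees(theta)
            waist = WaistFit(
                waist_fwhm_um=float(w0 * _FWHM_SIGMA / 2.0),
                rayleigh_um=float(zr),
                focus_z_um=float(s1 * math.sin(theta)),
            )
            refined = True
    efov = compute_efov(waist.waist_fwhm_um, tilt)
    return ProfileCalibration(
        z_um=z_um,
        center_um=centers,
        fwhm_um=fwhm_perp,
        fwhm_lateral_um=fwhm_lat,
        tilt_deg=tilt,
        waist_fwhm_um=waist.waist_fwhm_um,
        rayleigh_um=waist.rayleigh_um,
        focus_z_um=waist.focus_z_um,
        efov_um=efov,
        flags={
            "n_failed_fits": n_failed,
            "waist_degenerate": waist.degenerate,
            "refined": refined,
        },
    )
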
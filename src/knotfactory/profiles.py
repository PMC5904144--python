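"""Concentration-profile models and fits.

A nanochannel-confined DNA molecule imaged in fluorescence yields a 1-D
intensity profile along the channel axis.  In no-flow equilibrium the
underlying concentration is a uniform box of extension ``r_o`` and amplitude
``c_o``; under steady hydrodynamic compression against the slit barrier it is
a truncated linear ramp

    C(X) = C_b - alpha * X,    0 <= X <= R_c,

in normalized variables C = c/c_o and X = x/r_o.  Both shapes are observed
convolved with the microscope's Gaussian point-spread function (PSF).  This
module provides the closed-form convolved models, statsmodels-style model/fit
classes for both regimes, the local extension R(X) = 1/C(X), and log-log
power-law regression used to test the piston scaling laws
(C_b ~ sqrt(V), alpha ~ V, R_c ~ 1/sqrt(V), hence alpha ~ 1/R_b^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr
import lmfit
import statsmodels.api as sm

__all__ = [
    "IntensityProfile",
    "box_psf_model",
    "ramp_psf_model",
    "EquilibriumFit",
    "CompressedFit",
    "ScalingFit",
    "EquilibriumProfileModel",
    "CompressedProfileModel",
    "fit_equilibrium",
    "fit_compressed",
    "local_extension",
    "fit_scaling",
    "EmptyProfileError",
    "FitRejectedError",
]


class EmptyProfileError(ValueError):
    """Profile contains no above-background signal."""


class FitRejectedError(RuntimeError):
    """Fitted parameters violate physical constraints (C_b <= 0, R_c outside (0,1])."""


@dataclass
class IntensityProfile:
    """1-D fluorescence intensity along the channel axis.

    ``x`` must be strictly increasing and uniformly spaced (um); ``intensity``
    is in camera units.
    """

    x: np.ndarray
    intensity: np.ndarray
    pixel_size: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.intensity.shape:
            raise ValueError("x and intensity must be 1-D arrays of equal length")
        dx = np.diff(self.x)
        if not np.all(dx > 0):
            raise ValueError("x must be strictly increasing")
        if dx.size and not np.allclose(dx, dx[0], rtol=1e-6):
            raise ValueError("x must be uniformly spaced")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.pixel_size == 0.0 and dx.size:
            self.pixel_size = float(dx[0])

    @property
    def dx(self) -> float:
        return self.pixel_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x_um": self.x, "intensity": self.intensity})

    @classmethod
    def from_csv(cls, path) -> "IntensityProfile":
        df = pd.read_csv(path)
        return cls(df["x_um"].to_numpy(), df["intensity"].to_numpy())

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _gauss_pdf(t: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (t / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


def box_psf_model(x, left, width, amplitude, sigma_psf):
    """Uniform box on [left, left+width] convolved with a Gaussian PSF.

    For sigma_psf -> 0 this degenerates to the bare box (evaluated pointwise).
    """
    x = np.asarray(x, dtype=float)
    if width <= 0 or amplitude < 0:
        raise ValueError("width must be > 0 and amplitude >= 0")
    if sigma_psf <= 0:
        return np.where((x >= left) & (x < left + width), amplitude, 0.0)
    return amplitude * (ndtr((x - left) / sigma_psf) - ndtr((x - left - width) / sigma_psf))


def ramp_psf_model(x, C_b, alpha, R_c, sigma_psf):
    """Truncated linear ramp C_b - alpha*x on [0, R_c], convolved with a Gaussian.

    Closed form: with Phi the normal CDF and phi_s the normal density of width
    ``sigma_psf``,

        p(x) = (C_b - alpha x) [Phi(x/s) - Phi((x-R_c)/s)]
               + alpha s^2 [phi_s(x - R_c) - phi_s(x)].

    Convolution preserves the ramp area C_b*R_c - alpha*R_c^2/2.  Works in any
    consistent units (normalized X or absolute um).
    """
    x = np.asarray(x, dtype=float)
    if R_c <= 0:
        raise ValueError("R_c must be positive")
    if sigma_psf <= 0:
        ramp = C_b - alpha * x
        return np.where((x >= 0) & (x < R_c), ramp, 0.0)
    s = sigma_psf
    window = ndtr(x / s) - ndtr((x - R_c) / s)
    return (C_b - alpha * x) * window + alpha * s**2 * (_gauss_pdf(x - R_c, s) - _gauss_pdf(x, s))


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class EquilibriumFit:
    """Result of a box (x) Gaussian fit to an equilibrium profile."""

    r_o: float
    c_o: float
    sigma_psf: float
    left_edge: float
    residual_rms: float
    background: float
    lmfit_result: object = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Equilibrium profile fit (box convolved with Gaussian PSF)",
            f"  r_o (extension)      : {self.r_o:10.4f} um",
            f"  c_o (plateau)        : {self.c_o:10.4f} camera units",
            f"  sigma_psf            : {self.sigma_psf:10.4f} um",
            f"  background           : {self.background:10.4f}",
            f"  residual rms         : {self.residual_rms:10.4g}",
        ]
        return "\n".join(lines)


@dataclass
class CompressedFit:
    """Result of a ramp (x) Gaussian fit to a compressed profile.

    Parameters are in normalized units: C = c/c_o, X = x/r_o.  ``R_b = 1/C_b``
    is the barrier extension, the compression coordinate used throughout.
    """

    C_b: float
    alpha: float
    R_c: float
    residual_rms: float
    covariance: np.ndarray | None = None
    mass_defect: float = np.nan  # |C_b R_c - alpha R_c^2/2 - 1|, diagnostic only
    flipped: bool = False
    lmfit_result: object = field(repr=False, default=None)

    @property
    def R_b(self) -> float:
        return 1.0 / self.C_b

    def to_row(self) -> dict:
        """Flat dict for CSV assembly of many events."""
        return {"C_b": self.C_b, "alpha": self.alpha, "R_c": self.R_c,
                "R_b": self.R_b, "residual_rms": self.residual_rms,
                "mass_defect": self.mass_defect}

    def summary(self) -> str:
        lines = [
            "Compressed profile fit (linear ramp convolved with Gaussian PSF)",
            f"  C_b   (barrier conc.)   : {self.C_b:10.4f}",
            f"  alpha (ramp slope)      : {self.alpha:10.4f}",
            f"  R_c   (extension)       : {self.R_c:10.4f}",
            f"  R_b = 1/C_b             : {self.R_b:10.4f}",
            f"  mass defect |area - 1|  : {self.mass_defect:10.4g}",
            f"  residual rms            : {self.residual_rms:10.4g}",
        ]
        return "\n".join(lines)


@dataclass
class ScalingFit:
    """Power-law fit y = prefactor * x^exponent via OLS on logs."""

    exponent: float
    prefactor: float
    exponent_stderr: float
    n_points: int = 0

    def summary(self) -> str:
        return (
            f"Power-law fit on {self.n_points} points: "
            f"exponent = {self.exponent:.4f} +/- {self.exponent_stderr:.4f}, "
            f"prefactor = {self.prefactor:.4g}"
        )


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def _background_subtract(profile: IntensityProfile, frac: float = 0.10):
    """Median of the outermost ``frac`` pixels on each side, subtracted."""
    n = profile.x.size
    k = max(1, int(round(frac * n / 2)))
    edges = np.concatenate([profile.intensity[:k], profile.intensity[-k:]])
    bg = float(np.median(edges))
    return profile.intensity - bg, bg


class EquilibriumProfileModel:
    """Box-convolved-with-Gaussian model for a no-flow equilibrium profile.

    fit() estimates (r_o, c_o, sigma_psf, left edge) by least squares, with
    initial values taken from the thresholded support width and the plateau
    median.  Background is the median of the outermost 10% of pixels and is
    subtracted before fitting.
    """

    def __init__(self, profile: IntensityProfile, background_frac: float = 0.10):
        self.profile = profile
        self.signal, self.background = _background_subtract(profile, background_frac)

    def _initial_guess(self):
        sig = self.signal
        peak = float(np.max(sig)) if sig.size else 0.0
        noise = float(np.std(np.concatenate([sig[:5], sig[-5:]])))
        thr = max(0.5 * peak, 3.0 * noise)
        above = sig > thr
        if peak <= 0 or not np.any(above):
            raise EmptyProfileError("no above-background region in profile")
        idx = np.flatnonzero(above)
        x = self.profile.x
        left = x[idx[0]]
        width = x[idx[-1]] - x[idx[0]]
        if width <= 0:
            raise EmptyProfileError("above-background region too narrow to fit")
        plateau = float(np.median(sig[idx]))
        return left, width, plateau

    def fit(self, sigma_guess: float | None = None) -> EquilibriumFit:
        left0, width0, c0 = self._initial_guess()
        if sigma_guess is None:
            sigma_guess = max(2.0 * self.profile.dx, 0.02 * width0)
        params = lmfit.Parameters()
        params.add("left", value=left0 - sigma_guess, min=self.profile.x[0] - width0)
        params.add("width", value=width0, min=2 * self.profile.dx)
        params.add("amplitude", value=c0, min=0.0)
        params.add("sigma_psf", value=sigma_guess, min=0.1 * self.profile.dx)

        x = self.profile.x
        y = self.signal

        def resid(p):
            return box_psf_model(x, p["left"], p["width"], p["amplitude"], p["sigma_psf"]) - y

        out = lmfit.minimize(resid, params, method="leastsq")
        p = out.params
        rms = float(np.sqrt(np.mean(out.residual**2)))
        return EquilibriumFit(
            r_o=float(p["width"]),
            c_o=float(p["amplitude"]),
            sigma_psf=float(p["sigma_psf"]),
            left_edge=float(p["left"]),
            residual_rms=rms,
            background=self.background,
            lmfit_result=out,
        )


class CompressedProfileModel:
    """Ramp-convolved-with-Gaussian model for a flow-compressed profile.

    Requires an :class:`EquilibriumFit` supplying the normalization scales
    (c_o, r_o) and the PSF width, which is held fixed here: refitting sigma
    together with the steep barrier-side edge is strongly degenerate.

    The barrier side is identified as the steeper-edged side of the profile;
    the coordinate is flipped if necessary so the barrier sits at X = 0.  Mass
    conservation (unit ramp area) is *not* imposed; the deviation is reported
    as a diagnostic.
    """

    def __init__(self, profile: IntensityProfile, equilibrium: EquilibriumFit,
                 background_frac: float = 0.10):
        self.profile = profile
        self.equilibrium = equilibrium
        signal, self.background = _background_subtract(profile, background_frac)
        # normalized coordinates: C = c/c_o, X = x/r_o
        self.C = signal / equilibrium.c_o
        self.X = profile.x / equilibrium.r_o
        self.sigma_X = equilibrium.sigma_psf / equilibrium.r_o

    @staticmethod
    def _orient(X: np.ndarray, C: np.ndarray):
        """Flip so the steeper edge (the barrier) is on the low-X side."""
        peak = np.max(C)
        above = C > 0.5 * peak
        if not np.any(above):
            raise EmptyProfileError("no above-background region in profile")
        idx = np.flatnonzero(above)
        # compare |gradient| just outside each edge of the support
        grad = np.gradient(C, X)
        lo, hi = idx[0], idx[-1]
        left_steep = abs(grad[max(lo - 1, 0): lo + 2]).max()
        right_steep = abs(grad[hi - 1: min(hi + 2, len(X))]).max()
        flipped = right_steep > left_steep
        if flipped:
            X = X.max() - X[::-1]
            C = C[::-1].copy()
        # shift so the barrier edge is at X ~ 0
        above = C > 0.5 * peak
        idx = np.flatnonzero(above)
        X = X - X[idx[0]]
        return X, C, flipped

    def fit(self) -> CompressedFit:
        X, C, flipped = self._orient(self.X, self.C)
        peak = float(np.max(C))
        above = C > 0.5 * peak
        idx = np.flatnonzero(above)
        Rc0 = float(X[idx[-1]] - X[idx[0]]) + 2 * self.sigma_X
        Cb0 = peak
        a0 = max((peak - C[idx[-1]]) / max(Rc0, 1e-6), 0.0)

        params = lmfit.Parameters()
        params.add("C_b", value=Cb0, min=1e-6)
        params.add("alpha", value=a0, min=0.0)
        params.add("R_c", value=Rc0, min=2 * (X[1] - X[0]))
        # residual barrier-edge offset (the coarse orientation step aligns the
        # half-max crossing, not the true edge)
        params.add("X0", value=0.0, min=-0.05, max=0.05)

        sig = self.sigma_X

        def resid(p):
            return ramp_psf_model(X - p["X0"], p["C_b"], p["alpha"], p["R_c"], sig) - C

        out = lmfit.minimize(resid, params, method="leastsq")
        p = out.params
        C_b, alpha, R_c = float(p["C_b"]), float(p["alpha"]), float(p["R_c"])
        if C_b <= 0 or not (0 < R_c <= 1.0 + 5 * sig):
            raise FitRejectedError(
                f"fit rejected: C_b={C_b:.4g}, R_c={R_c:.4g} outside physical range"
            )
        cov = out.covar if out.covar is not None else None
        rms = float(np.sqrt(np.mean(out.residual**2)))
        mass = abs(C_b * R_c - alpha * R_c**2 / 2.0 - 1.0)
        return CompressedFit(
            C_b=C_b, alpha=alpha, R_c=R_c, residual_rms=rms,
            covariance=cov, mass_defect=mass, flipped=flipped, lmfit_result=out,
        )


def fit_equilibrium(profile: IntensityProfile) -> EquilibriumFit:
    """Fit a box (x) Gaussian model to an equilibrium profile."""
    return EquilibriumProfileModel(profile).fit()


def fit_compressed(profile: IntensityProfile, equilibrium: EquilibriumFit) -> CompressedFit:
    """Fit a ramp (x) Gaussian model to a compressed profile (normalized by
    the equilibrium fit, PSF width held fixed)."""
    return CompressedProfileModel(profile, equilibrium).fit()


def local_extension(fit: CompressedFit, X):
    """Local extension R(X) = 1/C(X) = 1/(C_b - alpha X) along the ramp.

    Measures how locally compressed the chain is relative to no-flow
    equilibrium (R = 1).  ``X`` must lie within the ramp support [0, R_c].
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0) or np.any(X > fit.R_c):
        raise ValueError("X outside ramp support [0, R_c]")
    C = fit.C_b - fit.alpha * X
    if np.any(C <= 0):
        raise ValueError("concentration non-positive at requested X")
    return 1.0 / C


def fit_scaling(x_values, y_values) -> ScalingFit:
    """Ordinary least squares of log(y) on log(x): y = prefactor * x^exponent."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a scaling fit")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("scaling fit requires strictly positive data")
    design = sm.add_constant(np.log(x))
    res = sm.OLS(np.log(y), design).fit()
    return ScalingFit(
        exponent=float(res.params[1]),
        prefactor=float(np.exp(res.params[0])),
        exponent_stderr=float(res.bse[1]),
        n_points=int(x.size),
    )
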
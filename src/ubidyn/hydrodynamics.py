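"""Translational diffusion from pulsed-field-gradient echo decays.

1D spectra are integrated over the aliphatic window (0.5-2.5 ppm by
convention) and the integrals fitted to the Stejskal-Tanner equation

    I(G) = I0 exp(-G^2 gamma^2 delta^2 D (Delta - delta/3))

The fit is performed as a weighted linear regression of ln(I) on the
diffusion weighting b(G) — exact for this model, with no initialization
question — with an optional nonlinear refinement.  Repeated gradient
strengths, when present, provide scatter-derived weights.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

from . import models
from .types import DecayCurve, Spectrum1D, ValidationError


def integrate_region(spec: Spectrum1D, lo: float, hi: float) -> float:
    """Trapezoidal integral of intensity over the ppm window [lo, hi].

    Orientation independent: descending ppm axes integrate to the same
    (positive-window) value.
    """
    if hi <= lo:
        raise ValidationError("window must satisfy lo < hi")
    ppm, inten = spec.ppm, spec.intensity
    if ppm[0] > ppm[-1]:
        ppm, inten = ppm[::-1], inten[::-1]
    if lo < ppm[0] or hi > ppm[-1]:
        raise ValidationError(
            f"window [{lo}, {hi}] outside spectrum range [{ppm[0]}, {ppm[-1]}]"
        )
    mask = (ppm >= lo) & (ppm <= hi)
    if mask.sum() < 2:
        raise ValidationError("window contains fewer than 2 points")
    x, y = ppm[mask], inten[mask]
    # Include exact window edges by linear interpolation.
    if x[0] > lo:
        x = np.concatenate([[lo], x])
        y = np.concatenate([[np.interp(lo, ppm, inten)], y])
    if x[-1] < hi:
        x = np.concatenate([x, [hi]])
        y = np.concatenate([y, [np.interp(hi, ppm, inten)]])
    return float(np.trapezoid(y, x))


@dataclasses.dataclass
class DiffusionFit:
    """Diffusion coefficient D (m^2/s) with the fixed acquisition constants."""

    d: float
    d_err: float
    i0: float
    i0_err: float
    gamma: float
    delta: float
    big_delta: float
    residual_norm: float
    flags: list[str] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def fit_diffusion(
    curve: DecayCurve,
    gamma: float = models.GAMMA_1H,
    delta: float = 0.006,
    big_delta: float = 0.100,
    refine: bool = False,
) -> DiffusionFit:
    """Fit I0 and D to a gradient-decay curve.

    ``gamma`` is the gyromagnetic ratio (rad/s/T, 1H by default), ``delta``
    the gradient pulse length and ``big_delta`` the diffusion time, both in
    seconds.  Replicated gradient strengths supply scatter-derived weights;
    otherwise the regression is unweighted and errors come from the
    covariance.  A decay that rises with G beyond its noise level is
    flagged.
    """
    if curve.kind != "diffusion":
        raise ValidationError(f"expected a diffusion curve, got {curve.kind!r}")
    if delta >= big_delta:
        raise ValidationError("gradient length delta must be below diffusion time Delta")
    if len(np.unique(curve.abscissa)) < 5:
        raise ValidationError("need at least 5 distinct gradient strengths")
    g, y = curve.abscissa, curve.intensity
    flags = []
    if np.any(y <= 0):
        raise ValidationError("non-positive echo intensities cannot be log-fitted")

    b = models.stejskal_tanner_b(g, gamma, delta, big_delta)
    ln_y = np.log(y)

    # Scatter-derived weights from replicate gradient strengths.
    scatter = None
    xs, counts = np.unique(g, return_counts=True)
    if np.any(counts > 1):
        sds = [
            float(np.std(ln_y[g == x], ddof=1)) for x, c in zip(xs, counts) if c > 1
        ]
        mean_sd = float(np.mean(sds))
        if mean_sd > 0:
            scatter = mean_sd
    w = np.ones_like(ln_y) if scatter is None else np.full_like(ln_y, 1.0 / scatter)

    # Weighted linear regression ln(I) = ln(I0) - b D.
    design = np.column_stack([np.ones_like(b), -b])
    wd = design * w[:, None]
    coef, *_ = np.linalg.lstsq(wd, ln_y * w, rcond=None)
    ln_i0, d = float(coef[0]), float(coef[1])
    resid = (design @ coef - ln_y) * w
    dof = len(y) - 2
    cov = None
    if dof > 0:
        s_sq = float(resid @ resid) / dof
        cov = np.linalg.pinv(wd.T @ wd) * s_sq
    if d <= 0:
        flags.append("non-monotone decay: non-positive D")
    i0 = float(np.exp(ln_i0))
    if cov is not None:
        d_err = float(np.sqrt(cov[1, 1]))
        i0_err = i0 * float(np.sqrt(cov[0, 0]))
    else:
        d_err = i0_err = np.nan

    if refine and d > 0:
        def f(p):
            return models.stejskal_tanner(g, p[0], p[1], gamma, delta, big_delta) - y

        res = least_squares(f, [i0, d], bounds=([0, 0], [np.inf, np.inf]),
                            xtol=1e-15, ftol=1e-15)
        i0, d = float(res.x[0]), float(res.x[1])
        resid = res.fun

    return DiffusionFit(
        d=d,
        d_err=d_err,
        i0=i0,
        i0_err=i0_err,
        gamma=gamma,
        delta=delta,
        big_delta=big_delta,
        residual_norm=float(np.linalg.norm(resid)),
        flags=flags,
    )


def gradient_decay_from_spectra(
    spectra: list[Spectrum1D],
    gradients,
    lo: float = 0.5,
    hi: float = 2.5,
) -> DecayCurve:
    """Integrate each spectrum over [lo, hi] ppm into a diffusion decay curve."""
    gradients = np.asarray(gradients, dtype=float)
    if len(spectra) != len(gradients):
        raise ValidationError("one gradient strength per spectrum required")
    integrals = np.array([integrate_region(s, lo, hi) for s in spectra])
    return DecayCurve(abscissa=gradients, intensity=integrals, kind="diffusion")
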
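"""Per-residue exchange and spin-relaxation fitting and classification.

Covers four observables of backbone dynamics:

* millisecond amide-proton exchange rate constants k_HX from the
  double-exponential build-up of the modified MEXICO experiment (water
  relaxation rate R1w held fixed at its separately measured value);
* 15N T1/T2 times from single-exponential intensity decays;
* the {1H}-15N steady-state heteronuclear NOE as the saturated/unsaturated
  intensity ratio;
* an empirical fast-timescale mobility classification from R2/R1 ratios
  against a 10% trimmed mean, flagging residues more than one standard
  deviation above (slowed, or exchange-affected when R2 is also high) or
  below (fast internal motion) the robust average.

Fits are weighted Levenberg-style least squares with inverse-variance
weights when point errors are available; non-convergence produces a flagged
result with diagnostics, never an exception.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

from . import models
from .types import DecayCurve, PeakList, ResidueKey, ResidueSeries, ValidationError


def _covariance(res) -> np.ndarray | None:
    """Parameter covariance from a scipy least_squares result (weighted residuals)."""
    n, p = res.fun.size, res.x.size
    if n <= p:
        return None
    try:
        jtj_inv = np.linalg.pinv(res.jac.T @ res.jac)
    except np.linalg.LinAlgError:
        return None
    s_sq = 2.0 * res.cost / (n - p)
    return jtj_inv * s_sq


@dataclasses.dataclass
class ExchangeFit:
    """k_HX and amide-proton R1 (1/s) from one exchange build-up curve."""

    k_hx: float
    k_hx_err: float
    r1: float
    r1_err: float
    r1w: float
    residual_norm: float
    covariance: np.ndarray | None
    flags: list[str] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def fit_mexico(
    curve: DecayCurve,
    r1w: float = models.R1W_DEFAULT,
    fit_r1w: bool = False,
) -> ExchangeFit:
    """Weighted fit of the exchange build-up model to a MEXICO curve.

    ``r1w`` is held fixed unless ``fit_r1w`` is requested.  The starting
    k_HX comes from the initial slope of the curve and R1 starts at 1/s; a
    best fit driven to the k_HX >= 0 bound is clipped and flagged.
    """
    if curve.kind != "mexico":
        raise ValidationError(f"expected a mexico curve, got {curve.kind!r}")
    if len(curve) < 5:
        raise ValidationError("need at least 5 points for an exchange fit")
    if r1w <= 0:
        raise ValidationError("r1w must be positive")
    t, y = curve.abscissa, curve.intensity
    w = 1.0 / curve.error if curve.error is not None and np.all(curve.error > 0) else None

    if np.allclose(y, 0.0, atol=1e-12):
        return ExchangeFit(0.0, 0.0, np.nan, np.nan, r1w, 0.0, None, ["unidentifiable: S == 0"])

    pos = t > 0
    slope = float(np.max(y[pos] / t[pos])) if pos.any() else 1.0
    k0 = max(slope, 1e-3)

    if fit_r1w:
        def resid(p):
            r = models.mexico_signal(t, p[0], p[1], p[2]) - y
            return r * w if w is not None else r

        x0, lb, ub = [k0, 1.0, r1w], [0.0, 1e-9, 1e-9], [np.inf] * 3
    else:
        def resid(p):
            r = models.mexico_signal(t, p[0], p[1], r1w) - y
            return r * w if w is not None else r

        x0, lb, ub = [k0, 1.0], [0.0, 1e-9], [np.inf] * 2

    res = least_squares(resid, x0, bounds=(lb, ub), method="trf", xtol=1e-14, ftol=1e-14)
    flags = []
    if not res.success:
        flags.append("non-convergence")
    if res.x[0] <= 1e-12:
        flags.append("k_hx at lower bound")
    cov = _covariance(res)
    errs = np.sqrt(np.diag(cov)) if cov is not None else np.full(res.x.size, np.nan)
    return ExchangeFit(
        k_hx=float(res.x[0]),
        k_hx_err=float(errs[0]),
        r1=float(res.x[1]),
        r1_err=float(errs[1]),
        r1w=float(res.x[2]) if fit_r1w else r1w,
        residual_norm=float(np.linalg.norm(res.fun)),
        covariance=cov,
        flags=flags,
    )


@dataclasses.dataclass
class RelaxFit:
    """I0 and relaxation time (s) from a single-exponential decay."""

    i0: float
    i0_err: float
    t_relax: float
    t_err: float
    kind: str
    residual_norm: float
    flags: list[str] = dataclasses.field(default_factory=list)

    @property
    def rate(self) -> float:
        """R1 = 1/T1 or R2 = 1/T2, in 1/s."""
        return 1.0 / self.t_relax

    @property
    def rate_err(self) -> float:
        return self.t_err / self.t_relax**2

    @property
    def ok(self) -> bool:
        return not self.flags


def replicate_scatter(curve: DecayCurve) -> float | None:
    """Mean standard deviation over groups of replicate abscissa values."""
    xs, counts = np.unique(curve.abscissa, return_counts=True)
    sds = [
        float(np.std(curve.intensity[curve.abscissa == x], ddof=1))
        for x, c in zip(xs, counts)
        if c > 1
    ]
    return float(np.mean(sds)) if sds else None


def fit_exp_decay(curve: DecayCurve) -> RelaxFit:
    """Weighted fit of I(t) = I0 exp(-t/T) to a T1 or T2 decay series.

    The start values come from a log-linear regression.  When the curve
    carries replicate delays, the mean replicate scatter supplies a uniform
    intensity error (the replicate-based error rule); explicit per-point
    errors take precedence.
    """
    if curve.kind not in ("t1", "t2"):
        raise ValidationError(f"expected a t1/t2 curve, got {curve.kind!r}")
    if len(curve) < 4:
        raise ValidationError("need at least 4 points for a relaxation fit")
    t, y = curve.abscissa, curve.intensity
    flags = []
    noise = float(np.std(y[-max(2, len(y) // 4):])) if len(y) >= 4 else 0.0
    if np.any(y < -5.0 * max(noise, 1e-12)):
        flags.append("negative intensities beyond noise floor")

    sigma = None
    if curve.error is not None and np.all(curve.error > 0):
        sigma = curve.error
    else:
        scatter = replicate_scatter(curve)
        if scatter and scatter > 0:
            sigma = np.full_like(y, scatter)

    pos = y > 0
    if pos.sum() >= 2:
        b, a = np.polyfit(t[pos], np.log(y[pos]), 1)
        i0_0 = float(np.exp(a))
        t0 = -1.0 / b if b < 0 else 10.0 * float(t.max())
    else:
        i0_0, t0 = float(np.max(np.abs(y))) or 1.0, float(t.max())
    t0 = min(max(t0, 1e-6), 1e6 * float(t.max()))

    def resid(p):
        r = models.exp_decay(t, p[0], p[1]) - y
        return r / sigma if sigma is not None else r

    res = least_squares(
        resid, [i0_0, t0], bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        method="trf", xtol=1e-14, ftol=1e-14,
    )
    if not res.success:
        flags.append("non-convergence")
    if res.x[1] > 100.0 * float(t.max()):
        flags.append("non-decaying: T beyond observable window")
    cov = _covariance(res)
    errs = np.sqrt(np.diag(cov)) if cov is not None else np.array([np.nan, np.nan])
    return RelaxFit(
        i0=float(res.x[0]),
        i0_err=float(errs[0]),
        t_relax=float(res.x[1]),
        t_err=float(errs[1]),
        kind=curve.kind,
        residual_norm=float(np.linalg.norm(res.fun)),
        flags=flags,
    )


def fit_decay_table(curves: dict[int, DecayCurve]) -> tuple[ResidueSeries, dict[int, RelaxFit]]:
    """Fit every residue's decay and collect rates into a ResidueSeries."""
    from .ubiquitin import UBIQUITIN_SEQUENCE

    values, fits = {}, {}
    for idx, curve in sorted(curves.items()):
        fit = fit_exp_decay(curve)
        fits[idx] = fit
        aa = UBIQUITIN_SEQUENCE[idx - 1] if 1 <= idx <= len(UBIQUITIN_SEQUENCE) else "X"
        if fit.ok:
            values[ResidueKey(idx, aa)] = (fit.rate, fit.rate_err if np.isfinite(fit.rate_err) else 0.0)
    unit = "1/s"
    return ResidueSeries(values=values, unit=unit, metadata="relaxation rates"), fits


def het_noe(
    sat: PeakList,
    unsat: PeakList,
    replicates: list[tuple[PeakList, PeakList]] | None = None,
) -> tuple[ResidueSeries, set[int]]:
    """Per-residue saturated/unsaturated intensity ratio (the hetNOE).

    With replicate pairs, each residue's error is the mean over residues of
    the replicate standard deviation; without replicates errors are 0 and
    the series metadata notes that no replicate error is available.
    Residues with zero unsaturated intensity are omitted and returned.
    """
    if not (sat.has_intensities() and unsat.has_intensities()):
        raise ValidationError("both peak lists must carry intensities")
    shared = sat.common_residues(unsat)
    s_ix, u_ix = sat.by_index(), unsat.by_index()
    omitted: set[int] = set()
    ratios: dict[ResidueKey, list[float]] = {}
    for key in shared:
        u = u_ix[key.index][1].intensity
        if u == 0:
            omitted.add(key.index)
            continue
        ratios[key] = [s_ix[key.index][1].intensity / u]
    if replicates:
        for rep_sat, rep_unsat in replicates:
            rs, ru = rep_sat.by_index(), rep_unsat.by_index()
            for key in list(ratios):
                if key.index in rs and key.index in ru and ru[key.index][1].intensity:
                    ratios[key].append(
                        rs[key.index][1].intensity / ru[key.index][1].intensity
                    )
    per_res_sd = {
        key: float(np.std(vals, ddof=1)) for key, vals in ratios.items() if len(vals) > 1
    }
    err = float(np.mean(list(per_res_sd.values()))) if per_res_sd else 0.0
    meta = "hetNOE" if per_res_sd else "hetNOE (no replicate error available)"
    values = {key: (float(np.mean(vals)), err) for key, vals in ratios.items()}
    return ResidueSeries(values=values, unit="", metadata=meta), omitted


def trimmed_mean_sd(values: np.ndarray, trim: float) -> tuple[float, float]:
    """Mean and SD after removing the ``trim`` fraction from each tail.

    The cut count is floor(trim * n) per tail, the standard definition of
    the symmetrically trimmed robust estimator.
    """
    if not 0 <= trim < 0.5:
        raise ValidationError("trim fraction must be in [0, 0.5)")
    v = np.sort(np.asarray(values, dtype=float))
    cut = int(np.floor(trim * len(v)))
    core = v[cut: len(v) - cut] if cut else v
    mean = float(core.mean())
    sd = float(core.std(ddof=1)) if len(core) > 1 else 0.0
    return mean, sd


@dataclasses.dataclass
class MobilityClass:
    """R2/R1-based empirical mobility classification.

    ``slow``: ratio more than one SD above the trimmed mean (motion slower
    than overall tumbling, or exchange); ``fast``: more than one SD below
    (fast internal motion); ``exchange_suspect``: high ratio combined with
    an R2 that is itself an outlier, the signature of microsecond-to-
    millisecond exchange contributions.
    """

    ratio: ResidueSeries
    trimmed_mean: float
    trimmed_sd: float
    slow: set[int]
    fast: set[int]
    exchange_suspect: set[int]


def classify_mobility(
    r1: ResidueSeries,
    r2: ResidueSeries,
    trim: float = 0.10,
    use_trimmed_sd: bool = True,
) -> MobilityClass:
    """Classify residues by their R2/R1 ratio against the 10% trimmed mean."""
    keys, v1, v2 = r1.aligned(r2)
    if len(keys) < 5:
        raise ValidationError("need at least 5 shared residues")
    if np.any(v1 == 0):
        raise ValidationError("zero R1 value")
    ratio = v2 / v1
    errs = np.zeros_like(ratio)
    ix1, ix2 = r1.by_index(), r2.by_index()
    for j, key in enumerate(keys):
        e1, e2 = ix1[key.index][1][1], ix2[key.index][1][1]
        errs[j] = abs(ratio[j]) * np.hypot(
            e1 / v1[j] if v1[j] else 0.0, e2 / v2[j] if v2[j] else 0.0
        )
    mean, t_sd = trimmed_mean_sd(ratio, trim)
    sd = t_sd if use_trimmed_sd else float(np.std(ratio, ddof=1))
    slow = {keys[j].index for j in range(len(keys)) if ratio[j] > mean + sd}
    fast = {keys[j].index for j in range(len(keys)) if ratio[j] < mean - sd}
    r2_mean, r2_sd = trimmed_mean_sd(v2, trim)
    suspects = {
        keys[j].index
        for j in range(len(keys))
        if keys[j].index in slow and v2[j] > r2_mean + r2_sd
    }
    series = ResidueSeries(
        values={keys[j]: (float(ratio[j]), float(errs[j])) for j in range(len(keys))},
        unit="",
        metadata="R2/R1",
    )
    return MobilityClass(
        ratio=series,
        trimmed_mean=mean,
        trimmed_sd=sd,
        slow=slow,
        fast=fast,
        exchange_suspect=suspects,
    )


def delta_khx(dimer: ResidueSeries, monomer: ResidueSeries) -> ResidueSeries:
    """k_HX(dimer) - k_HX(monomer) with errors propagated in quadrature.

    Negative values mean exchange is slowed in the dimer (protection by the
    distal unit).
    """
    keys, vd, vm = dimer.aligned(monomer)
    d_ix, m_ix = dimer.by_index(), monomer.by_index()
    values = {}
    for j, key in enumerate(keys):
        ed, em = d_ix[key.index][1][1], m_ix[key.index][1][1]
        values[key] = (float(vd[j] - vm[j]), float(np.hypot(ed, em)))
    return ResidueSeries(values=values, unit=dimer.unit or "1/s", metadata="delta k_HX")
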
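"""Dissociation-constant fitting from fast-exchange NMR titrations.

A titration series is an ordered set of peak lists with total protein and
ligand concentrations per point.  Observed shift changes relative to the
apo point follow the quadratic single-site isotherm (exact solution of the
1:n binding equilibrium under fast exchange):

    dw_obs = dw_max * (n P + L + K_D - sqrt((n P + L + K_D)^2 - 4 n P L))
             / (2 n P)

K_D is fitted either per residue (with the summary reported as the
inverse-variance-weighted mean of individual fits) or globally (one shared
K_D, per-residue dw_max, joint least squares).  The stoichiometry n is
fixed to 1 by default; fitting it is opt-in.  Residues attenuated beyond
the configured threshold are excluded from fits by default, as are
residues whose maximal shift change stays below a configurable floor.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

from . import models
from .chemshift import combined_shift
from .types import PeakList, ResidueKey, ResidueSeries, ValidationError


@dataclasses.dataclass
class TitrationSeries:
    """Ordered (peak list, [P]t, [L]t) points; the reference point is apo."""

    points: list[tuple[PeakList, float, float]]
    reference: int = 0

    def __post_init__(self) -> None:
        if not self.points:
            raise ValidationError("empty titration series")
        if not 0 <= self.reference < len(self.points):
            raise ValidationError("reference index out of range")
        if self.points[self.reference][2] != 0.0:
            raise ValidationError("reference point must have zero ligand")

    def __len__(self) -> int:
        return len(self.points)


@dataclasses.dataclass
class TitrationCSP:
    """Per-point shift changes relative to the apo reference."""

    delta_obs: list[ResidueSeries]
    attenuated: list[set[int]]
    l_total: np.ndarray
    p_total: np.ndarray


def titration_csp(
    series: TitrationSeries,
    attenuation_threshold: float = 0.75,
) -> TitrationCSP:
    """Shift change of every point versus the apo reference.

    Residues losing more than the threshold fraction of their reference
    intensity are flagged per point (and will be excluded from fitting by
    default).
    """
    ref_list = series.points[series.reference][0]
    ref_ix = ref_list.by_index()
    delta, attenuated = [], []
    for peaks, _p, _l in series.points:
        shared = ref_list.common_residues(peaks)
        ix = peaks.by_index()
        values: dict[ResidueKey, tuple[float, float]] = {}
        att: set[int] = set()
        for key in shared:
            pr, pt = ref_ix[key.index][1], ix[key.index][1]
            dw = float(combined_shift(pt.shift_h - pr.shift_h, pt.shift_n - pr.shift_n))
            values[key] = (dw, 0.0)
            if pr.intensity and pt.intensity is not None:
                if pt.intensity / pr.intensity < 1.0 - attenuation_threshold:
                    att.add(key.index)
        delta.append(ResidueSeries(values=values, unit="ppm", metadata="dw_obs"))
        attenuated.append(att)
    return TitrationCSP(
        delta_obs=delta,
        attenuated=attenuated,
        l_total=np.array([p[2] for p in series.points], dtype=float),
        p_total=np.array([p[1] for p in series.points], dtype=float),
    )


@dataclasses.dataclass
class BindingFit:
    """Fitted dissociation constant with per-residue detail.

    ``per_residue`` maps residue index to (K_D, error) for per-residue
    mode; ``dmax`` holds the fitted saturation shift changes in ppm.
    """

    k_d: float
    k_d_err: float
    n: float
    dmax: dict[int, float]
    per_residue: dict[int, tuple[float, float]]
    residues_used: set[int]
    mode: str
    flags: list[str] = dataclasses.field(default_factory=list)


def _fit_single_residue(l_t, p_t, dobs, n: float, kd0: float):
    """Least-squares (K_D, dw_max) for one residue's titration profile."""
    dmax0 = max(float(np.max(dobs)), 1e-6)

    def resid(x):
        return models.binding_isotherm(l_t, p_t, x[0], n, x[1]) - dobs

    res = least_squares(
        resid, [kd0, dmax0], bounds=([1e-9, 0.0], [1e9, np.inf]),
        method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    n_pts, n_par = len(dobs), 2
    cov = None
    if n_pts > n_par:
        s_sq = 2.0 * res.cost / (n_pts - n_par)
        cov = np.linalg.pinv(res.jac.T @ res.jac) * s_sq
    errs = np.sqrt(np.diag(cov)) if cov is not None else np.array([np.nan, np.nan])
    return res, errs


def fit_kd(
    series: TitrationSeries,
    mode: str = "per-residue",
    n_fixed: float | None = 1.0,
    min_dmax: float = 0.01,
    attenuation_threshold: float = 0.75,
    exclude_attenuated: bool = True,
) -> BindingFit:
    """Fit the single-site isotherm to a titration series.

    ``mode`` is ``per-residue`` (individual profiles, summary by
    inverse-variance-weighted mean) or ``global`` (joint fit: one K_D, one
    dw_max per residue).  ``n_fixed`` fixes the stoichiometry (pass None to
    fit it per residue alongside K_D and dw_max).  Residues whose maximal
    observed change is below ``min_dmax`` ppm, or that are attenuation-
    flagged, are excluded.
    """
    if mode not in ("per-residue", "global"):
        raise ValidationError(f"unknown mode {mode!r}")
    if len(series) < 4:
        raise ValidationError("need at least 4 titration points")
    tc = titration_csp(series, attenuation_threshold)
    l_t, p_t = tc.l_total, tc.p_total

    # Assemble per-residue profiles across points.
    profiles: dict[int, np.ndarray] = {}
    common = set(tc.delta_obs[0].indices())
    for s in tc.delta_obs[1:]:
        common &= set(s.indices())
    flagged_att = set().union(*tc.attenuated) if tc.attenuated else set()
    for idx in sorted(common):
        if exclude_attenuated and idx in flagged_att:
            continue
        prof = np.array([s.by_index()[idx][1][0] for s in tc.delta_obs])
        if float(prof.max()) < min_dmax:
            continue
        profiles[idx] = prof
    if not profiles:
        raise ValidationError("no usable residues after exclusion filters")

    n_val = 1.0 if n_fixed is None else float(n_fixed)
    kd0 = max(float(np.median(l_t[l_t > 0])), 1e-3) if np.any(l_t > 0) else 1.0
    flags: list[str] = []

    if mode == "global":
        if len(profiles) < 3:
            raise ValidationError("global mode needs at least 3 usable residues")
        indices = sorted(profiles)
        stacked = np.concatenate([profiles[i] for i in indices])
        m = len(indices)

        def resid(x):
            kd = x[0]
            preds = [
                models.binding_isotherm(l_t, p_t, kd, n_val, x[1 + j]) for j in range(m)
            ]
            return np.concatenate(preds) - stacked

        x0 = [kd0] + [max(float(profiles[i].max()), 1e-6) for i in indices]
        lb = [1e-9] + [0.0] * m
        ub = [1e9] + [np.inf] * m
        res = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        dof = stacked.size - res.x.size
        cov = np.linalg.pinv(res.jac.T @ res.jac) * (2.0 * res.cost / dof) if dof > 0 else None
        kd_err = float(np.sqrt(cov[0, 0])) if cov is not None else np.nan
        if res.x[0] <= 2e-9 or res.x[0] >= 9e8:
            flags.append("K_D driven to bound")
        return BindingFit(
            k_d=float(res.x[0]),
            k_d_err=kd_err,
            n=n_val,
            dmax={i: float(res.x[1 + j]) for j, i in enumerate(indices)},
            per_residue={},
            residues_used=set(indices),
            mode=mode,
            flags=flags,
        )

    per_residue: dict[int, tuple[float, float]] = {}
    dmax: dict[int, float] = {}
    for idx, prof in sorted(profiles.items()):
        res, errs = _fit_single_residue(l_t, p_t, prof, n_val, kd0)
        kd, kd_err = float(res.x[0]), float(errs[0])
        per_residue[idx] = (kd, kd_err)
        dmax[idx] = float(res.x[1])
        if kd <= 2e-9 or kd >= 9e8:
            flags.append(f"residue {idx}: K_D driven to bound")
        else:
            # Relative sensitivity of the profile to K_D; vanishing under
            # saturation, where K_D is unidentifiable however small the
            # covariance claims the error to be.
            sens = float(np.linalg.norm(res.jac[:, 0])) * kd
            scale = max(float(np.linalg.norm(prof)), 1e-12)
            if sens / scale < 1e-3 or (np.isfinite(kd_err) and kd_err > kd):
                flags.append(f"residue {idx}: K_D poorly determined")

    kds = np.array([v[0] for v in per_residue.values()])
    errs = np.array([v[1] for v in per_residue.values()])
    usable = np.isfinite(errs) & (errs > 0)
    if usable.all() and len(kds) > 1:
        w = 1.0 / errs**2
        kd_summary = float(np.sum(w * kds) / np.sum(w))
        kd_summary_err = float(np.sqrt(1.0 / np.sum(w)))
    else:
        # Noiseless or degenerate errors: plain mean with SD spread.
        kd_summary = float(np.mean(kds))
        kd_summary_err = float(np.std(kds, ddof=1)) if len(kds) > 1 else 0.0
    return BindingFit(
        k_d=kd_summary,
        k_d_err=kd_summary_err,
        n=n_val,
        dmax=dmax,
        per_residue=per_residue,
        residues_used=set(per_residue),
        mode=mode,
        flags=flags,
    )
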
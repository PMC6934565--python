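"""Closed-form observable models used by both the generators and the fitters.

* Amide-proton exchange (modified MEXICO): relative signal build-up
  ``S(t) = k_HX / (R1 + R1w) * (exp(-R1w t) - exp(-(R1 + k_HX) t))`` with the
  water-proton relaxation rate R1w held at an independently measured
  constant (0.31 1/s by default).
* Single-exponential relaxation decay ``I(t) = I0 exp(-t / T)`` for 15N T1
  and T2 series.
* Stejskal-Tanner pulsed-field-gradient echo attenuation
  ``I(G) = I0 exp(-G^2 gamma^2 delta^2 D (Delta - delta/3))``.
* Quadratic single-site binding isotherm for fast-exchange titrations,
  giving the observed shift change as a function of total protein and
  ligand concentrations, K_D and stoichiometry n.
"""

from __future__ import annotations

import numpy as np

#: Water-proton longitudinal relaxation rate constant, 1/s.
R1W_DEFAULT = 0.31

#: 1H gyromagnetic ratio, rad / (s T).
GAMMA_1H = 2.6752218744e8


def mexico_signal(t, k_hx: float, r1: float, r1w: float = R1W_DEFAULT):
    """Exchange build-up signal relative to the reference spectrum.

    S(0) = 0 for every parameter choice; S >= 0 whenever all rates are
    positive.  ``t`` is the exchange period in seconds.
    """
    t = np.asarray(t, dtype=float)
    return (k_hx / (r1 + r1w)) * (np.exp(-r1w * t) - np.exp(-(r1 + k_hx) * t))


def exp_decay(t, i0: float, t_relax: float):
    """Single-exponential intensity decay; ``t_relax`` is T1 or T2 in seconds."""
    t = np.asarray(t, dtype=float)
    return i0 * np.exp(-t / t_relax)


def stejskal_tanner_b(g, gamma: float, delta: float, big_delta: float):
    """The diffusion-weighting factor b(G) = G^2 gamma^2 delta^2 (Delta - delta/3)."""
    g = np.asarray(g, dtype=float)
    return g**2 * gamma**2 * delta**2 * (big_delta - delta / 3.0)


def stejskal_tanner(g, i0: float, d: float, gamma: float, delta: float, big_delta: float):
    """Echo intensity at gradient strength ``g`` (T/m) for diffusion coefficient ``d`` (m^2/s)."""
    return i0 * np.exp(-stejskal_tanner_b(g, gamma, delta, big_delta) * d)


def binding_isotherm(l_total, p_total, k_d: float, n: float, d_max):
    """Observed shift change for a single-site interaction in fast exchange.

    Parameters are total ligand and protein concentrations (same unit as
    ``k_d``), the dissociation constant, the stoichiometry ``n`` and the
    saturation shift change ``d_max``.  Returns 0 at zero ligand and
    approaches ``d_max`` at saturating ligand.
    """
    l_total = np.asarray(l_total, dtype=float)
    s = n * p_total + l_total + k_d
    frac = (s - np.sqrt(s**2 - 4.0 * n * p_total * l_total)) / (2.0 * n * p_total)
    return d_max * frac
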
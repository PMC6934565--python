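"""Chemical-shift perturbation (CSP) mapping between two states.

The combined perturbation per residue is

    dw = sqrt(((dH)^2 + (dN)^2 / 25) / 2)

i.e. the 15N dimension is down-weighted by a factor of 5 to account for its
wider shift range.  Significance is called against the mean (and mean plus
one standard deviation) of the observed perturbations, computed over
residues present in both states only — prolines and exchange-broadened
peaks never enter the statistics.  Peaks carrying intensities are
additionally screened for attenuation (default: >75% signal loss).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .types import PeakList, ResidueKey, ResidueSeries, ValidationError


def combined_shift(delta_h, delta_n) -> np.ndarray:
    """Weighted 1H/15N perturbation; symmetric in the two nuclei after 1/5 scaling."""
    delta_h = np.asarray(delta_h, dtype=float)
    delta_n = np.asarray(delta_n, dtype=float)
    return np.sqrt((delta_h**2 + delta_n**2 / 25.0) / 2.0)


@dataclasses.dataclass
class CSPResult:
    """Per-residue perturbations plus threshold calls.

    ``significant``: dw above the mean; ``strong``: dw above mean + SD
    (strong is a subset of significant); ``attenuated``: intensity ratio
    below 1 - threshold; ``appeared``/``vanished``: peaks observed in only
    one state (reported separately, never as dw values).
    """

    delta_omega: ResidueSeries
    mean: float
    sd: float
    significant: set[int]
    strong: set[int]
    attenuated: set[int]
    appeared: set[int]
    vanished: set[int]


def csp(
    state_a: PeakList,
    state_b: PeakList,
    attenuation_threshold: float = 0.75,
) -> CSPResult:
    """Perturbations of ``state_b`` relative to ``state_a`` on shared residues."""
    shared = state_a.common_residues(state_b)
    if not shared:
        raise ValidationError("peak lists share no residues")
    a_ix, b_ix = state_a.by_index(), state_b.by_index()
    values: dict[ResidueKey, tuple[float, float]] = {}
    attenuated: set[int] = set()
    both_intens = state_a.has_intensities() and state_b.has_intensities()
    for key in shared:
        pa, pb = a_ix[key.index][1], b_ix[key.index][1]
        dw = float(combined_shift(pb.shift_h - pa.shift_h, pb.shift_n - pa.shift_n))
        values[key] = (dw, 0.0)
        if both_intens and pa.intensity:
            if pb.intensity / pa.intensity < 1.0 - attenuation_threshold:
                attenuated.add(key.index)
    arr = np.array([values[k][0] for k in shared])
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    significant = {k.index for k in shared if values[k][0] > mean}
    strong = {k.index for k in shared if values[k][0] > mean + sd}
    series = ResidueSeries(
        values=values,
        unit="ppm",
        metadata=f"CSP {state_b.label} vs {state_a.label}",
    )
    only_a = {k.index for k in state_a.entries} - {k.index for k in state_b.entries}
    only_b = {k.index for k in state_b.entries} - {k.index for k in state_a.entries}
    return CSPResult(
        delta_omega=series,
        mean=mean,
        sd=sd,
        significant=significant,
        strong=strong,
        attenuated=attenuated,
        appeared=only_b,
        vanished=only_a,
    )


@dataclasses.dataclass
class ShiftTrajectory:
    """Ordered (1H, 15N) coordinates per residue across >= 3 states.

    ``collinearity`` is the maximum perpendicular distance (ppm, in raw
    shift space) of intermediate points from the chord joining the first
    and last state — zero for a perfectly linear route.
    """

    paths: dict[ResidueKey, np.ndarray]
    collinearity: ResidueSeries
    omitted: set[int]


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def csp_trajectory(states: list[PeakList]) -> ShiftTrajectory:
    """Trace per-residue peak routes across an ordered series of states.

    Residues absent from any state are omitted (and reported); the
    collinearity score diagnoses whether the route is a concerted linear
    walk or a multi-step path.
    """
    if len(states) < 3:
        raise ValidationError("need at least 3 states to trace a trajectory")
    index_maps = [s.by_index() for s in states]
    common = set(index_maps[0])
    for m in index_maps[1:]:
        common &= set(m)
    all_idx = set().union(*(set(m) for m in index_maps))
    omitted = all_idx - common
    paths: dict[ResidueKey, np.ndarray] = {}
    scores: dict[ResidueKey, tuple[float, float]] = {}
    for idx in sorted(common):
        key = index_maps[0][idx][0]
        pts = np.array(
            [[m[idx][1].shift_h, m[idx][1].shift_n] for m in index_maps]
        )
        paths[key] = pts
        score = max(
            _point_segment_distance(pts[j], pts[0], pts[-1]) for j in range(1, len(pts) - 1)
        )
        scores[key] = (score, 0.0)
    return ShiftTrajectory(
        paths=paths,
        collinearity=ResidueSeries(values=scores, unit="ppm", metadata="chord deviation"),
        omitted=omitted,
    )
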
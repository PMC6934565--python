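"""Synthetic-data generators for every input the pipeline consumes.

The generators emit perturbed amide peak lists (localized shift clusters
with optional intensity attenuation, emulating linkage-specific contact
footprints), decay curves shaped by the packaged forward models with
additive homoscedastic Gaussian noise, fast-exchange titration series, and
toy two-domain coordinate ensembles with controllable interface contacts
and conformational substates.

Toy domains are compact bead clusters, not real protein folds; a separate
helper builds a synthetic ubiquitin-like backbone for more realistic
surface-area tests.  With a fixed seed every generator is bit-reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import models
from .types import (
    AtomRecord,
    DecayCurve,
    Ensemble,
    Peak,
    PeakList,
    ResidueKey,
    ResidueSeries,
    ValidationError,
)
from .ubiquitin import PROLINE_POSITIONS, UBIQUITIN_SEQUENCE


@dataclasses.dataclass
class PerturbationProfile:
    """Target residues with per-residue displacement and attenuation.

    ``direction`` is a unit vector in raw (1H, 15N) ppm space; the peak of a
    targeted residue moves by ``amplitude`` ppm along it, and its intensity
    is scaled by ``1 - attenuation``.
    """

    amplitude: dict[int, float] = dataclasses.field(default_factory=dict)
    direction: dict[int, tuple[float, float]] = dataclasses.field(default_factory=dict)
    attenuation: dict[int, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for idx, a in self.amplitude.items():
            if a < 0:
                raise ValidationError(f"negative amplitude for residue {idx}")
        for idx, f in self.attenuation.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"attenuation for residue {idx} outside [0, 1]")

    @property
    def targets(self) -> set[int]:
        return set(self.amplitude) | set(self.attenuation)

    @classmethod
    def cluster(
        cls,
        residues,
        amplitude: float,
        seed: int = 0,
        attenuation: float = 0.0,
    ) -> "PerturbationProfile":
        """Uniform-amplitude cluster with random per-residue directions."""
        rng = np.random.default_rng(seed)
        amp, direc, att = {}, {}, {}
        for idx in residues:
            theta = rng.uniform(0, 2 * np.pi)
            amp[idx] = amplitude
            direc[idx] = (np.cos(theta), np.sin(theta))
            if attenuation:
                att[idx] = attenuation
        return cls(amplitude=amp, direction=direc, attenuation=att)


def gen_peaklists(
    reference: PeakList,
    profile: PerturbationProfile,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> PeakList:
    """Displace targeted peaks of ``reference`` along the profile directions.

    Untouched residues are copied verbatim.  Optional Gaussian noise
    (``noise_sd`` ppm, applied to both dimensions of every peak) emulates
    peak-position uncertainty.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    present = {k.index for k in reference.entries}
    bad = profile.targets - present
    if bad:
        missing_pro = sorted(b for b in bad if b in PROLINE_POSITIONS)
        if missing_pro:
            raise ValidationError(f"profile targets proline residues {missing_pro}")
        raise ValidationError(f"profile targets residues missing from reference: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    entries: dict[ResidueKey, Peak] = {}
    for key in reference:
        p = reference.entries[key]
        h, n, inten = p.shift_h, p.shift_n, p.intensity
        if key.index in profile.amplitude:
            a = profile.amplitude[key.index]
            dh, dn = profile.direction.get(key.index, (1.0, 0.0))
            norm = float(np.hypot(dh, dn))
            if norm == 0:
                raise ValidationError(f"zero direction vector for residue {key.index}")
            h += a * dh / norm
            n += a * dn / norm
        if key.index in profile.attenuation and inten is not None:
            inten = inten * (1.0 - profile.attenuation[key.index])
        if noise_sd > 0:
            h += rng.normal(0.0, noise_sd)
            n += rng.normal(0.0, noise_sd)
        entries[key] = Peak(h, n, inten)
    return PeakList(entries=entries, label=f"{reference.label}+perturbed")


_CURVE_PARAMS = {
    "mexico": ("k_hx", "r1", "r1w"),
    "t1": ("i0", "t_relax"),
    "t2": ("i0", "t_relax"),
    "diffusion": ("i0", "d", "gamma", "delta", "big_delta"),
}


def gen_curve(
    kind: str,
    params: dict,
    abscissa,
    noise_sd: float = 0.0,
    replicates=(),
    seed: int = 0,
) -> DecayCurve:
    """Forward-evaluate the model for ``kind`` and add Gaussian noise.

    ``replicates`` is a sequence of abscissa values appended to the design
    (each drawing fresh noise); replicate points carry the scatter used for
    error estimation downstream.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    missing = [p for p in _CURVE_PARAMS.get(kind, ()) if p not in params]
    if kind not in _CURVE_PARAMS:
        raise ValidationError(f"unknown curve kind {kind!r}")
    if missing:
        raise ValidationError(f"missing parameters for {kind}: {missing}")
    x = np.concatenate([np.asarray(abscissa, dtype=float), np.asarray(replicates, dtype=float)])
    if kind == "mexico":
        y = models.mexico_signal(x, params["k_hx"], params["r1"], params["r1w"])
    elif kind in ("t1", "t2"):
        y = models.exp_decay(x, params["i0"], params["t_relax"])
    else:
        y = models.stejskal_tanner(
            x, params["i0"], params["d"], params["gamma"], params["delta"], params["big_delta"]
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return DecayCurve(abscissa=x, intensity=y, kind=kind)


@dataclasses.dataclass
class TitrationScheme:
    """Explicit per-point total protein and ligand concentrations (µM)."""

    p_total: np.ndarray
    l_total: np.ndarray

    def __post_init__(self) -> None:
        self.p_total = np.asarray(self.p_total, dtype=float)
        self.l_total = np.asarray(self.l_total, dtype=float)
        if self.p_total.shape != self.l_total.shape or self.p_total.ndim != 1:
            raise ValidationError("p_total and l_total must be 1-D and equal length")
        if self.l_total[0] != 0.0:
            raise ValidationError("first titration point must have zero ligand")
        if np.any(np.diff(self.ratios()) < 0):
            raise ValidationError("molar ratios must be non-decreasing")
        if np.any(self.p_total <= 0):
            raise ValidationError("protein concentrations must be positive")

    def ratios(self, n: float = 1.0) -> np.ndarray:
        """Molar ratios [L]t / (n [P]t) per point."""
        return self.l_total / (n * self.p_total)

    @classmethod
    def from_ratios(cls, p_total: float, ratios, n: float = 1.0) -> "TitrationScheme":
        """Constant-protein scheme from a start concentration and molar ratios."""
        r = np.asarray(ratios, dtype=float)
        return cls(p_total=np.full_like(r, p_total), l_total=r * n * p_total)


def gen_titration(
    scheme: TitrationScheme,
    k_d: float,
    n: float,
    dmax: ResidueSeries,
    seed: int = 0,
    noise_sd: float = 0.0,
    attenuation: dict[int, float] | None = None,
    reference: PeakList | None = None,
):
    """Forward-evaluate the binding isotherm into a peak-list titration series.

    Per residue, the observed shift change at each point follows the
    quadratic single-site isotherm with that point's concentrations; the
    peak is displaced along a fixed per-residue direction chosen from
    ``seed`` so that the combined 1H/15N perturbation equals the predicted
    value.  ``attenuation`` maps residues to a final intensity-loss fraction
    reached linearly over the series.  Returns a
    :class:`~ubidyn.binding.TitrationSeries`.
    """
    from .binding import TitrationSeries
    from .types import reference_peaklist

    if k_d <= 0 or n <= 0:
        raise ValidationError("k_d and n must be positive")
    if reference is None:
        reference = reference_peaklist("apo")
    rng = np.random.default_rng(seed)
    # Fixed per-residue direction, parametrized so the weighted shift change
    # (Eq.-1-style combination) equals the isotherm value exactly.
    angles = {k.index: rng.uniform(0, 2 * np.pi) for k in reference}
    points = []
    n_pts = len(scheme.p_total)
    for j in range(n_pts):
        p_t, l_t = scheme.p_total[j], scheme.l_total[j]
        entries: dict[ResidueKey, Peak] = {}
        for key in reference:
            ref = reference.entries[key]
            d_obs = 0.0
            dm = dmax.by_index().get(key.index)
            if dm is not None and l_t > 0:
                d_obs = float(models.binding_isotherm(l_t, p_t, k_d, n, dm[1][0]))
            theta = angles[key.index]
            # dH = d*sqrt(2)cos(theta), dN = 5*sqrt(2)*d*sin(theta) gives a
            # combined perturbation of exactly d.
            dh = d_obs * np.sqrt(2.0) * np.cos(theta)
            dn = d_obs * 5.0 * np.sqrt(2.0) * np.sin(theta)
            h = ref.shift_h + dh + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            nn = ref.shift_n + dn + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            inten = ref.intensity
            if attenuation and key.index in attenuation and inten is not None:
                frac = attenuation[key.index] * (j / (n_pts - 1) if n_pts > 1 else 1.0)
                inten = inten * (1.0 - frac)
            entries[key] = Peak(h, nn, inten)
        points.append((PeakList(entries=entries, label=f"point{j}"), float(p_t), float(l_t)))
    return TitrationSeries(points=points, reference=0)


@dataclasses.dataclass
class ToyEnsembleSpec:
    """Recipe for a two-domain bead ensemble with discrete substates.

    Each domain is a compact cluster of ``beads_per_domain`` beads (element
    'X', 2.3 Angstrom radius, one bead per residue, atom name CA).  Substate
    ``k`` places the second domain in contact with the first along a
    distinct direction (angles equally spaced in the xy-plane) with an
    optional extra rotation, so interface contacts differ between substates.
    Frames add isotropic Gaussian jitter of ``jitter_sigma`` per coordinate.
    """

    beads_per_domain: int = 30
    n_substates: int = 2
    frames_per_substate: int = 10
    jitter_sigma: float = 0.3
    seed: int = 0
    bead_spacing: float = 4.0
    gap: float = 1.0
    rotations_deg: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_substates < 1:
            raise ValidationError("need at least one substate")
        if self.jitter_sigma < 0:
            raise ValidationError("jitter must be non-negative")
        if self.beads_per_domain < 2:
            raise ValidationError("need at least 2 beads per domain")


def _compact_cluster(n: int, spacing: float) -> np.ndarray:
    """The ``n`` cubic-lattice points closest to the origin (deterministic)."""
    m = 1
    while (2 * m + 1) ** 3 < 4 * n:
        m += 1
    axes = np.arange(-m, m + 1)
    grid = np.array(np.meshgrid(axes, axes, axes)).reshape(3, -1).T * spacing
    # Tiny symmetry-breaking tilt so the nearest-n selection is unambiguous.
    r2 = (grid**2).sum(axis=1) + 1e-6 * grid[:, 0] + 1e-9 * grid[:, 1]
    order = np.argsort(r2, kind="stable")
    return grid[order[:n]].astype(float)


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def gen_toy_ensemble(spec: ToyEnsembleSpec) -> Ensemble:
    """Build the multi-frame two-chain bead ensemble described by ``spec``.

    Ground truth is recorded in ``metadata``: per-frame substate labels and,
    per substate, the chain-A residues in contact with chain B (surface
    separation below one bead radius).
    """
    rng = np.random.default_rng(spec.seed)
    domain = _compact_cluster(spec.beads_per_domain, spec.bead_spacing)
    bead_r = 2.3

    base_frames = []
    labels = []
    contacts: dict[int, list[int]] = {}
    for k in range(spec.n_substates):
        phi = 2.0 * np.pi * k / max(spec.n_substates, 1)
        direction = np.array([np.cos(phi), np.sin(phi), 0.0])
        if spec.rotations_deg is not None:
            angle = np.deg2rad(spec.rotations_deg[k])
        else:
            angle = np.pi * k  # alternate 0 / 180 degree domain flips
        rot = _rotation_matrix(np.array([0.0, 0.0, 1.0]), angle)
        rotated = domain @ rot.T
        # Surface-to-surface gap along this substate's approach direction,
        # so every substate makes interface contact regardless of the
        # cluster's (non-spherical) shape.
        offset_len = (
            float((domain @ direction).max())
            + float((rotated @ -direction).max())
            + 2.0 * bead_r
            + spec.gap
        )
        domain_b = rotated + direction * offset_len
        coords = np.vstack([domain, domain_b])
        base_frames.append(coords)
        # Contact = close enough for mutual surface occlusion at the default
        # 1.4 Angstrom solvent probe (center distance < r_i + r_j + 2 probe).
        from scipy.spatial.distance import cdist

        dmat = cdist(domain, domain_b)
        cutoff = 2 * bead_r + 2 * 1.4
        contacts[k] = sorted(int(i) + 1 for i in np.unique(np.where(dmat < cutoff)[0]))
        labels.extend([k] * spec.frames_per_substate)

    frames = []
    for k in range(spec.n_substates):
        for _ in range(spec.frames_per_substate):
            jitter = (
                rng.normal(0.0, spec.jitter_sigma, size=base_frames[k].shape)
                if spec.jitter_sigma > 0
                else 0.0
            )
            frames.append(base_frames[k] + jitter)

    atoms = []
    for chain in ("A", "B"):
        for i in range(spec.beads_per_domain):
            atoms.append(
                AtomRecord(
                    name="CA", element="X", radius=bead_r,
                    res_index=i + 1, res_name="UNK", chain=chain,
                )
            )
    return Ensemble(
        coords=np.array(frames),
        atoms=atoms,
        metadata={
            "substate_labels": np.array(labels, dtype=int),
            "contacts": contacts,
            "base_frames": np.array(base_frames),
        },
    )


def isolated_domain(spec: ToyEnsembleSpec) -> Ensemble:
    """Chain A of the toy system alone, jittered with the same statistics."""
    rng = np.random.default_rng(spec.seed + 1)
    domain = _compact_cluster(spec.beads_per_domain, spec.bead_spacing)
    n_frames = spec.n_substates * spec.frames_per_substate
    frames = [
        domain
        + (rng.normal(0.0, spec.jitter_sigma, size=domain.shape) if spec.jitter_sigma > 0 else 0.0)
        for _ in range(n_frames)
    ]
    atoms = [
        AtomRecord(name="CA", element="X", radius=2.3, res_index=i + 1, res_name="UNK", chain="A")
        for i in range(spec.beads_per_domain)
    ]
    return Ensemble(coords=np.array(frames), atoms=atoms)


def ubiquitin_like_ensemble(n_frames: int = 1, jitter_sigma: float = 0.0, seed: int = 0) -> Ensemble:
    """A synthetic compact 76-residue backbone resembling ubiquitin in size.

    The backbone (N, CA, C, O per residue) follows a spherical spiral of
    ~12 Angstrom radius — a stand-in fold for surface-area and gyration
    tests, not a real ubiquitin structure.
    """
    n_res = len(UBIQUITIN_SEQUENCE)
    from .io import aa_three_letter

    t = np.linspace(-1.0 + 1.0 / n_res, 1.0 - 1.0 / n_res, n_res)
    theta = np.arccos(t)
    phi = np.sqrt(n_res * np.pi) * theta  # spiral winding
    r_sphere = 12.0
    ca = np.column_stack(
        [
            r_sphere * np.sin(theta) * np.cos(phi),
            r_sphere * np.sin(theta) * np.sin(phi),
            r_sphere * np.cos(theta),
        ]
    )
    atoms = []
    coords0 = []
    for i in range(n_res):
        direction = ca[i] / np.linalg.norm(ca[i])
        # Place N/C along the chain, O outward; bond lengths approximate.
        prev_vec = ca[i] - ca[i - 1] if i > 0 else ca[i + 1] - ca[i]
        prev_vec = prev_vec / np.linalg.norm(prev_vec)
        res3 = aa_three_letter(UBIQUITIN_SEQUENCE[i])
        for name, element, pos in (
            ("N", "N", ca[i] - 1.46 * prev_vec),
            ("CA", "C", ca[i]),
            ("C", "C", ca[i] + 1.52 * prev_vec),
            ("O", "O", ca[i] + 1.52 * prev_vec + 1.23 * direction),
        ):
            atoms.append(
                AtomRecord(
                    name=name, element=element,
                    radius={"N": 1.55, "C": 1.70, "O": 1.52}[element],
                    res_index=i + 1, res_name=res3, chain="A",
                )
            )
            coords0.append(pos)
    coords0 = np.array(coords0)
    rng = np.random.default_rng(seed)
    frames = [
        coords0
        + (rng.normal(0.0, jitter_sigma, size=coords0.shape) if jitter_sigma > 0 else 0.0)
        for _ in range(n_frames)
    ]
    return Ensemble(coords=np.array(frames), atoms=atoms)
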
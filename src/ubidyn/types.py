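"""Core containers shared by every analysis stage.

The universal result carrier is :class:`ResidueSeries` — per-residue values
with symmetric errors — which every fitting and ensemble operator returns.
Peak lists, decay curves, 1D spectra and coordinate ensembles are thin,
validated wrappers around numpy arrays and plain dicts.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterator, NamedTuple

import numpy as np

from .ubiquitin import UBIQUITIN_SEQUENCE, residue_letter


class ValidationError(ValueError):
    """An input violates a documented invariant (never silently repaired)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ResidueKey(NamedTuple):
    """1-based residue position plus one-letter amino-acid code."""

    index: int
    aa: str

    @classmethod
    def of_ubiquitin(cls, index: int) -> "ResidueKey":
        return cls(index, residue_letter(index))


class Peak(NamedTuple):
    shift_h: float
    shift_n: float
    intensity: float | None = None


@dataclasses.dataclass
class PeakList:
    """Assigned 2D (1H, 15N) peak positions for one species/state.

    At most one entry per residue; missing residues (prolines,
    exchange-broadened peaks) are simply absent.
    """

    entries: dict[ResidueKey, Peak]
    label: str = ""

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for key, peak in self.entries.items():
            if key.index < 1:
                raise ValidationError(f"residue index {key.index} < 1")
            if key.index in seen:
                raise ValidationError(f"duplicate residue {key.index}")
            seen.add(key.index)
            if not (np.isfinite(peak.shift_h) and np.isfinite(peak.shift_n)):
                raise ValidationError(f"non-finite shift for residue {key.index}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ResidueKey]:
        return iter(sorted(self.entries, key=lambda k: k.index))

    def by_index(self) -> dict[int, tuple[ResidueKey, Peak]]:
        return {k.index: (k, v) for k, v in self.entries.items()}

    def common_residues(self, other: "PeakList") -> list[ResidueKey]:
        """Keys shared by both lists, matched on residue index.

        A mismatching amino-acid code at a shared index is an error, not a
        silent exclusion.
        """
        mine, theirs = self.by_index(), other.by_index()
        shared = []
        for idx in sorted(set(mine) & set(theirs)):
            ka, kb = mine[idx][0], theirs[idx][0]
            if ka.aa != kb.aa:
                raise ValidationError(
                    f"residue {idx}: amino acid mismatch {ka.aa!r} vs {kb.aa!r}"
                )
            shared.append(ka)
        return shared

    def has_intensities(self) -> bool:
        return all(p.intensity is not None for p in self.entries.values())


@dataclasses.dataclass
class ResidueSeries:
    """Per-residue values with symmetric errors and a uniform unit."""

    values: dict[ResidueKey, tuple[float, float]]
    unit: str = ""
    metadata: str = ""

    def __post_init__(self) -> None:
        for key, (_, err) in self.values.items():
            if err < 0:
                raise ValidationError(f"negative error for residue {key.index}")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[ResidueKey]:
        return iter(sorted(self.values, key=lambda k: k.index))

    def by_index(self) -> dict[int, tuple[ResidueKey, tuple[float, float]]]:
        return {k.index: (k, v) for k, v in self.values.items()}

    def value(self, index: int) -> float:
        return self.by_index()[index][1][0]

    def error(self, index: int) -> float:
        return self.by_index()[index][1][1]

    def indices(self) -> list[int]:
        return sorted(k.index for k in self.values)

    def aligned(self, other: "ResidueSeries") -> tuple[list[ResidueKey], np.ndarray, np.ndarray]:
        """Shared residues and the two value arrays in matching order."""
        mine, theirs = self.by_index(), other.by_index()
        keys = [mine[i][0] for i in sorted(set(mine) & set(theirs))]
        a = np.array([mine[k.index][1][0] for k in keys])
        b = np.array([theirs[k.index][1][0] for k in keys])
        return keys, a, b


_CURVE_KINDS = ("mexico", "t1", "t2", "diffusion")


@dataclasses.dataclass
class DecayCurve:
    """(abscissa, intensity[, error]) triplets for exponential-model fitting.

    Abscissa units are seconds for delay-type curves and T/m for gradient
    ramps.  Replicate abscissa values are permitted (they carry the
    scatter-based error estimate).
    """

    abscissa: np.ndarray
    intensity: np.ndarray
    kind: str
    error: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.kind not in _CURVE_KINDS:
            raise ValidationError(f"unknown curve kind {self.kind!r}")
        if self.abscissa.shape != self.intensity.shape or self.abscissa.ndim != 1:
            raise ValidationError("abscissa and intensity must be 1-D and equal length")
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)
            if self.error.shape != self.abscissa.shape:
                raise ValidationError("error array length mismatch")
            if np.any(self.error < 0):
                raise ValidationError("negative error values")
        order = np.argsort(self.abscissa, kind="stable")
        self.abscissa = self.abscissa[order]
        self.intensity = self.intensity[order]
        if self.error is not None:
            self.error = self.error[order]

    def __len__(self) -> int:
        return len(self.abscissa)


@dataclasses.dataclass
class Spectrum1D:
    """A 1D spectrum as (ppm, intensity); ppm may run in either direction."""

    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValidationError("ppm and intensity must be 1-D and equal length")
        d = np.diff(self.ppm)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("ppm axis must be strictly monotone")


class AtomRecord(NamedTuple):
    """One topology atom: name, element, vdW radius (Angstrom), residue, chain."""

    name: str
    element: str
    radius: float
    res_index: int
    res_name: str
    chain: str


@dataclasses.dataclass
class Ensemble:
    """Multi-frame coordinate set sharing a single topology.

    Coordinates are in Angstrom, shaped ``(n_frames, n_atoms, 3)``.  Chain
    identifiers distinguish the proximal from the distal unit in dimers.
    ``metadata`` carries generator ground truth (e.g. substate labels).
    """

    coords: np.ndarray
    atoms: list[AtomRecord]
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValidationError(
                f"{self.coords.shape[1]} coordinate columns vs {len(self.atoms)} atoms"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def select(
        self,
        chain: str | None = None,
        names: set[str] | None = None,
        res_range: tuple[int, int] | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching all given filters."""
        idx = []
        for i, a in enumerate(self.atoms):
            if chain is not None and a.chain != chain:
                continue
            if names is not None and a.name not in names:
                continue
            if res_range is not None and not res_range[0] <= a.res_index <= res_range[1]:
                continue
            idx.append(i)
        return np.array(idx, dtype=int)

    def subset(self, indices: np.ndarray) -> "Ensemble":
        return Ensemble(
            coords=self.coords[:, indices, :].copy(),
            atoms=[self.atoms[i] for i in indices],
            metadata=dict(self.metadata),
        )

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])


@dataclasses.dataclass
class RunConfig:
    """Tunable parameters shared across pipeline stages.

    Lengths are Angstrom internally; ``from_json`` accepts ``*_nm`` keys and
    converts.  Defaults follow the analysis conventions for two-domain
    ubiquitin ensembles: 1.4 Angstrom solvent probe, 12 conformational
    clusters, 10% trimmed mean for R2/R1 classification, 75% signal
    attenuation flagging, 300 K for free-energy scaling.
    """

    attenuation_threshold: float = 0.75
    trim_fraction: float = 0.10
    probe_radius: float = 1.4
    sphere_points: int = 960
    rmsf_window: int = 100
    n_clusters: int = 12
    landscape_bins: int = 50
    temperature: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValidationError("probe radius must be positive")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValidationError("trim fraction must be in [0, 0.5)")
        if self.n_clusters < 1:
            raise ValidationError("cluster count must be >= 1")
        if not 0 <= self.attenuation_threshold <= 1:
            raise ValidationError("attenuation threshold must be in [0, 1]")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "probe_radius_nm" in raw:
            raw["probe_radius"] = raw.pop("probe_radius_nm") * 10.0
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def reference_peaklist(label: str = "reference") -> PeakList:
    """A deterministic, idealized amide peak list for the ubiquitin sequence.

    Shift values are a fixed synthetic dispersion (not measured shifts); the
    list covers every observable amide (prolines and Met1 excluded) and is
    the canonical starting point for the synthetic-data generators.
    """
    from .ubiquitin import amide_positions

    entries: dict[ResidueKey, Peak] = {}
    for i in amide_positions():
        # Deterministic pseudo-dispersion spanning typical amide ranges.
        h = 7.0 + 2.5 * ((i * 37) % 97) / 97.0
        n = 105.0 + 25.0 * ((i * 53) % 89) / 89.0
        entries[ResidueKey.of_ubiquitin(i)] = Peak(round(h, 4), round(n, 4), 1.0)
    return PeakList(entries=entries, label=label)


SEQUENCE_LENGTH = len(UBIQUITIN_SEQUENCE)
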
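"""Structure-ensemble operators for two-domain coordinate sets.

Implements the analyses used to connect simulated conformational ensembles
to per-residue NMR observables:

* Shrake-Rupley solvent-accessible surface area (SASA) with a 1.4 Angstrom
  probe, and residue-wise Delta-SASA of a dimer chain against the isolated
  monomer (positive = surface buried by the partner domain);
* windowed RMSF: backbone fluctuation about the window-average structure
  after Kabsch alignment, averaged across windows;
* mass-weighted radius of gyration per frame;
* pairwise backbone-RMSD matrices (Kabsch superposition) with Ward
  agglomerative clustering, cluster populations and centroid frames;
* inter-domain minimum-distance collective variables (one Calpha minimum
  distance per core residue of each chain; 144 components for two 72-residue
  cores) with a 2D principal-component embedding and the associated
  free-energy landscape F = -ln(rho/rho_max) in units of k_B T.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, squareform

from .types import Ensemble, ResidueKey, ResidueSeries, ValidationError
from .ubiquitin import CORE_RANGE

BACKBONE_NAMES = {"N", "CA", "C", "O"}

_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "X": 1.0,
}


# --- solvent accessible surface area -------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """``n`` nearly uniform unit-sphere points (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@dataclasses.dataclass
class SASAResult:
    """Per-atom and per-residue solvent-accessible areas in Angstrom^2."""

    per_atom: np.ndarray
    per_residue: dict[tuple[str, int], float]
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def sasa(
    ens: Ensemble,
    frame: int = 0,
    probe: float = 1.4,
    n_points: int = 960,
) -> SASAResult:
    """Shrake-Rupley SASA of one frame.

    Each atom is inflated by the probe radius and sampled with ``n_points``
    sphere points; the accessible fraction times the inflated-sphere area
    gives the atomic SASA.  Exactly overlapping atoms are computed as-is
    with a warning.
    """
    coords = ens.coords[frame]
    radii = ens.radii()
    if np.any(radii <= 0):
        raise ValidationError("all atoms need positive radii")
    inflated = radii + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = float(inflated.max())
    per_atom = np.zeros(len(coords))

    dup = tree.query_pairs(1e-9)
    if dup:
        warnings.warn(f"{len(dup)} pairs of overlapping identical atoms", stacklevel=2)

    for i in range(len(coords)):
        neighbors = [
            j for j in tree.query_ball_point(coords[i], inflated[i] + max_r) if j != i
        ]
        pts = coords[i] + inflated[i] * unit
        if neighbors:
            nb = np.asarray(neighbors, dtype=int)
            close = nb[np.linalg.norm(coords[nb] - coords[i], axis=1) < inflated[i] + inflated[nb]]
            if len(close):
                d2 = cdist(pts, coords[close], "sqeuclidean")
                buried = (d2 < (inflated[close] ** 2)[None, :]).any(axis=1)
                frac = 1.0 - buried.mean()
            else:
                frac = 1.0
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * inflated[i] ** 2

    per_residue: dict[tuple[str, int], float] = {}
    for i, atom in enumerate(ens.atoms):
        key = (atom.chain, atom.res_index)
        per_residue[key] = per_residue.get(key, 0.0) + float(per_atom[i])
    return SASAResult(per_atom=per_atom, per_residue=per_residue, probe=probe, n_points=n_points)


def sasa_mean(ens: Ensemble, probe: float = 1.4, n_points: int = 960) -> dict[tuple[str, int], float]:
    """Frame-averaged per-residue SASA over the whole ensemble."""
    acc: dict[tuple[str, int], float] = {}
    for f in range(ens.n_frames):
        res = sasa(ens, frame=f, probe=probe, n_points=n_points)
        for key, val in res.per_residue.items():
            acc[key] = acc.get(key, 0.0) + val
    return {k: v / ens.n_frames for k, v in acc.items()}


def delta_sasa(
    dimer: Ensemble,
    unit_chain: str,
    monomer: Ensemble,
    probe: float = 1.4,
    n_points: int = 960,
) -> ResidueSeries:
    """Residue-wise SASA loss of a dimer chain relative to the free monomer.

    Delta-SASA(res) = <SASA_monomer(res)> - <SASA_chain-in-dimer(res)>,
    frame-averaged on both sides; positive values mark surface buried by
    the partner domain.  The chain's residues must map one-to-one onto the
    monomer's.
    """
    if unit_chain not in dimer.chains():
        raise ValidationError(f"chain {unit_chain!r} not in dimer")
    mono_chains = monomer.chains()
    if len(mono_chains) != 1:
        raise ValidationError("monomer ensemble must contain exactly one chain")
    dimer_res = sorted({a.res_index for a in dimer.atoms if a.chain == unit_chain})
    mono_res = sorted({a.res_index for a in monomer.atoms})
    unmapped = sorted(set(dimer_res) ^ set(mono_res))
    if unmapped:
        raise ValidationError(f"residues without 1:1 mapping: {unmapped}")

    dimer_sasa = sasa_mean(dimer, probe=probe, n_points=n_points)
    mono_sasa = sasa_mean(monomer, probe=probe, n_points=n_points)
    mono_chain = mono_chains[0]
    res_names = {a.res_index: a.res_name for a in dimer.atoms if a.chain == unit_chain}
    from .io import aa_one_letter

    values = {
        ResidueKey(r, aa_one_letter(res_names[r])): (
            mono_sasa[(mono_chain, r)] - dimer_sasa[(unit_chain, r)],
            0.0,
        )
        for r in dimer_res
    }
    return ResidueSeries(values=values, unit="A^2", metadata=f"dSASA chain {unit_chain}")


# --- superposition, fluctuation, gyration --------------------------------

def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centered ``p`` onto centered ``q``."""
    h = p.T @ q
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigid-body superposition of ``mobile`` onto ``target`` (both (n, 3))."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    rot = kabsch_rotation(mc, tc)
    return mc @ rot.T + target.mean(axis=0)


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets after optimal superposition."""
    moved = superpose(p, q)
    return float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))


def rmsf(
    ens: Ensemble,
    window: int | None = None,
    selection: np.ndarray | None = None,
) -> ResidueSeries:
    """Windowed backbone RMSF, aggregated per residue.

    Frames are split into windows of ``window`` frames (one window spanning
    everything when omitted); within each window all frames are aligned to
    the window-average structure (Kabsch, iterated to self-consistency),
    per-atom RMS deviations from the average are computed, atoms are
    aggregated to residues as the RMS over atoms, and windows are averaged.
    A trailing partial window shorter than half the window length is
    dropped.
    """
    if selection is None:
        selection = ens.select(names=BACKBONE_NAMES)
    if len(selection) == 0:
        raise ValidationError("empty atom selection")
    coords = ens.coords[:, selection, :]
    n_frames = coords.shape[0]
    window = window or n_frames
    if window < 2:
        raise ValidationError("window must span at least 2 frames")

    starts = list(range(0, n_frames, window))
    per_window: list[np.ndarray] = []
    for s in starts:
        chunk = coords[s: s + window]
        if len(chunk) < max(2, window // 2):
            continue  # trailing partial window dropped
        aligned = chunk.copy()
        mean = aligned[0]
        for _ in range(3):  # alignment/average self-consistency iterations
            aligned = np.array([superpose(f, mean) for f in aligned])
            mean = aligned.mean(axis=0)
        msf = np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0)
        per_window.append(msf)
    if not per_window:
        raise ValidationError("no complete window available")
    atom_rmsf = np.mean([np.sqrt(m) for m in per_window], axis=0)

    from .io import aa_one_letter

    groups: dict[tuple[str, int, str], list[float]] = {}
    for local_i, atom_i in enumerate(selection):
        a = ens.atoms[atom_i]
        groups.setdefault((a.chain, a.res_index, a.res_name), []).append(atom_rmsf[local_i] ** 2)
    res_chains: dict[int, set[str]] = {}
    for chain, res, _ in groups:
        res_chains.setdefault(res, set()).add(chain)
    ambiguous = sorted(r for r, chs in res_chains.items() if len(chs) > 1)
    if ambiguous:
        raise ValidationError(
            f"residues {ambiguous} appear in multiple chains; restrict the "
            "selection to one chain"
        )
    values = {}
    for (_chain, res, res_name), sq in sorted(groups.items()):
        values[ResidueKey(res, aa_one_letter(res_name))] = (
            float(np.sqrt(np.mean(sq))),
            0.0,
        )
    return ResidueSeries(values=values, unit="A", metadata="windowed backbone RMSF")


@dataclasses.dataclass
class GyrationResult:
    per_frame: np.ndarray
    mean: float
    sd: float


def gyration(ens: Ensemble, selection: np.ndarray | None = None) -> GyrationResult:
    """Mass-weighted radius of gyration per frame, with mean and SD."""
    if selection is None:
        selection = np.arange(ens.n_atoms)
    coords = ens.coords[:, selection, :]
    masses = np.array([_MASSES.get(ens.atoms[i].element, 1.0) for i in selection])
    com = (coords * masses[None, :, None]).sum(axis=1) / masses.sum()
    d2 = np.sum((coords - com[:, None, :]) ** 2, axis=2)
    rg = np.sqrt((d2 * masses[None, :]).sum(axis=1) / masses.sum())
    return GyrationResult(
        per_frame=rg,
        mean=float(rg.mean()),
        sd=float(rg.std(ddof=1)) if len(rg) > 1 else 0.0,
    )


# --- clustering -----------------------------------------------------------

@dataclasses.dataclass
class ClusterResult:
    """Pairwise-RMSD Ward clustering of ensemble frames.

    ``labels`` are 0-based per (strided) frame; ``centroids`` maps cluster
    label to the member frame minimizing summed RMSD to its cluster;
    ``populations`` are fractions summing to 1, ``frame_indices`` the
    original frame numbers used.
    """

    rmsd_matrix: np.ndarray
    labels: np.ndarray
    k: int
    centroids: dict[int, int]
    populations: dict[int, float]
    frame_indices: np.ndarray

    def most_populated(self, top: int = 3) -> float:
        """Combined population fraction of the ``top`` largest clusters."""
        return float(sum(sorted(self.populations.values(), reverse=True)[:top]))


def rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """Symmetric pairwise Kabsch-RMSD matrix of a (frames, atoms, 3) stack."""
    n = len(coords)
    mat = np.zeros((n, n))
    centered = coords - coords.mean(axis=1, keepdims=True)
    for i in range(n):
        for j in range(i + 1, n):
            rot = kabsch_rotation(centered[i], centered[j])
            diff = centered[i] @ rot.T - centered[j]
            mat[i, j] = mat[j, i] = np.sqrt(np.mean(np.sum(diff**2, axis=1)))
    return mat


def rmsd_cluster(
    ens: Ensemble,
    k: int = 12,
    selection: np.ndarray | None = None,
    stride: int = 1,
) -> ClusterResult:
    """Ward clustering of frames on the pairwise backbone-RMSD matrix.

    The default selection is backbone atoms of core residues 1-72 in every
    chain (the flexible C-terminal tails are excluded from the metric).
    """
    if selection is None:
        selection = ens.select(names=BACKBONE_NAMES, res_range=CORE_RANGE)
        if len(selection) == 0:
            selection = ens.select(res_range=CORE_RANGE)
    frames = np.arange(0, ens.n_frames, stride)
    if k > len(frames):
        raise ValidationError(f"k={k} exceeds {len(frames)} frames after stride")
    coords = ens.coords[np.ix_(frames, selection)]
    mat = rmsd_matrix(coords)
    if len(frames) == 1:
        labels = np.zeros(1, dtype=int)
    else:
        link = linkage(squareform(mat, checks=False), method="ward")
        labels = fcluster(link, t=k, criterion="maxclust") - 1
    centroids, populations = {}, {}
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        sums = mat[np.ix_(members, members)].sum(axis=1)
        centroids[int(lab)] = int(frames[members[int(np.argmin(sums))]])
        populations[int(lab)] = len(members) / len(frames)
    return ClusterResult(
        rmsd_matrix=mat,
        labels=labels,
        k=int(len(np.unique(labels))),
        centroids=centroids,
        populations=populations,
        frame_indices=frames,
    )


# --- collective variables and free-energy landscape -----------------------

def min_distance_cvs(
    ens: Ensemble,
    core: tuple[int, int] = CORE_RANGE,
    atom_name: str = "CA",
) -> np.ndarray:
    """Inter-domain minimum-distance collective variables, (frames, m).

    For each core residue of each chain, the minimum Calpha-Calpha distance
    to any core residue of the other chain; m = core residues per chain
    summed over the two chains (144 for two 72-residue cores).  Components
    are ordered first-chain residues ascending, then second-chain.
    """
    chains = ens.chains()
    if len(chains) != 2:
        raise ValidationError(f"need exactly 2 chains, found {chains}")
    idx = {}
    for ch in chains:
        sel = ens.select(chain=ch, names={atom_name}, res_range=core)
        res_present = [ens.atoms[i].res_index for i in sel]
        expected = [
            r for r in range(core[0], core[1] + 1)
            if any(a.chain == ch and a.res_index == r for a in ens.atoms)
        ]
        missing = sorted(set(expected) - set(res_present))
        if missing:
            raise ValidationError(f"chain {ch}: residues missing {atom_name}: {missing}")
        order = np.argsort(res_present, kind="stable")
        idx[ch] = sel[order]
    a_sel, b_sel = idx[chains[0]], idx[chains[1]]
    out = np.empty((ens.n_frames, len(a_sel) + len(b_sel)))
    for f in range(ens.n_frames):
        d = cdist(ens.coords[f, a_sel], ens.coords[f, b_sel])
        out[f, : len(a_sel)] = d.min(axis=1)
        out[f, len(a_sel):] = d.min(axis=0)
    return out


@dataclasses.dataclass
class CVLandscape:
    """2D embedding of CV vectors and the binned free-energy surface.

    ``free_energy`` is -ln(rho/rho_max) in k_B T on a ``bins x bins`` grid
    (NaN on empty bins, minimum 0 after the shift); ``minima`` lists
    (x, y, F) of local minima of the binned surface.
    """

    cvs: np.ndarray
    embedding: np.ndarray
    free_energy: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    temperature: float
    minima: list[tuple[float, float, float]]


def pca_embedding(cvs: np.ndarray) -> np.ndarray:
    """Default 2D reduction: projection on the first two principal components."""
    from sklearn.decomposition import PCA

    return PCA(n_components=2).fit_transform(cvs)


def landscape(
    cvs: np.ndarray,
    bins: int = 50,
    temperature: float = 300.0,
    embedding: np.ndarray | None = None,
) -> CVLandscape:
    """Free-energy landscape over a 2D embedding of the CV matrix.

    ``embedding`` accepts any precomputed (frames, 2) reduction; the
    default is a principal-component projection.  Bin occupancies are
    converted to F = -ln(rho/rho_max) in units of k_B T at ``temperature``.
    """
    cvs = np.asarray(cvs, dtype=float)
    if cvs.ndim != 2:
        raise ValidationError("cvs must be a (frames, m) matrix")
    if np.allclose(cvs.std(axis=0), 0.0):
        raise ValidationError("degenerate CVs: zero variance in every component")
    if embedding is None:
        embedding = pca_embedding(cvs)
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape != (cvs.shape[0], 2):
        raise ValidationError("embedding must be (frames, 2)")
    if cvs.shape[0] < 10 * bins:
        warnings.warn(
            f"{cvs.shape[0]} frames for {bins} bins per axis; landscape will be sparse",
            stacklevel=2,
        )
    hist, xe, ye = np.histogram2d(embedding[:, 0], embedding[:, 1], bins=bins)
    free = np.full_like(hist, np.nan)
    occupied = hist > 0
    free[occupied] = -np.log(hist[occupied] / hist.max())

    minima = []
    for i in range(hist.shape[0]):
        for j in range(hist.shape[1]):
            if not occupied[i, j]:
                continue
            val = free[i, j]
            neighborhood = free[
                max(i - 1, 0): i + 2, max(j - 1, 0): j + 2
            ]
            finite = neighborhood[np.isfinite(neighborhood)]
            if val <= finite.min():
                minima.append(
                    (float((xe[i] + xe[i + 1]) / 2), float((ye[j] + ye[j + 1]) / 2), float(val))
                )
    return CVLandscape(
        cvs=cvs,
        embedding=embedding,
        free_energy=free,
        x_edges=xe,
        y_edges=ye,
        temperature=temperature,
        minima=sorted(minima, key=lambda m: m[2]),
    )
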
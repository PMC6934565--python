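"""Readers and writers for the plain-text formats the pipeline exchanges.

Tabular inputs (peak lists, per-residue series, decay tables, 1D spectra)
are TSV/CSV with a mandatory header line; comment lines start with ``#``.
Coordinate ensembles travel as multi-model PDB, parsed and emitted through
biotite; van der Waals radii are assigned from the packaged table because
PDB files do not carry them.

All readers reject invariant breaches instead of silently repairing them.
"""

from __future__ import annotations

import numpy as np

from .types import (
    AtomRecord,
    DecayCurve,
    Ensemble,
    ParseError,
    Peak,
    PeakList,
    ResidueKey,
    ResidueSeries,
    Spectrum1D,
    ValidationError,
)
from .ubiquitin import UBIQUITIN_SEQUENCE, VDW_RADII

_DELIMS = {"tsv": "\t", "csv": ","}


def _rows(path, dialect: str):
    if dialect not in _DELIMS:
        raise ValueError(f"dialect must be tsv or csv, got {dialect!r}")
    delim = _DELIMS[dialect]
    with open(path) as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split(delim)]
            if header is None:
                header = [f.lower() for f in fields]
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            yield lineno, dict(zip(header, fields))
    if header is None:
        raise ParseError(f"{path}: empty file (header line required)")


def _get(row: dict, lineno, path, *names: str, optional: bool = False):
    for n in names:
        if n in row:
            return row[n]
    if optional:
        return None
    raise ParseError(f"{path}: line {lineno}: missing column (one of {names})")


def _to_float(text: str, lineno, path) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"{path}: line {lineno}: not a number: {text!r}") from exc


def read_peaklist(path, dialect: str = "tsv", label: str = "") -> PeakList:
    """Read an assigned peak list (columns: residue[, aa], h_ppm, n_ppm[, intensity]).

    The amino-acid column, when present, is cross-checked against the
    packaged ubiquitin sequence for indices within range.
    """
    entries: dict[ResidueKey, Peak] = {}
    seen: set[int] = set()
    for lineno, row in _rows(path, dialect):
        idx = int(_to_float(_get(row, lineno, path, "residue", "res", "index"), lineno, path))
        if idx in seen:
            raise ValidationError(f"{path}: line {lineno}: duplicate residue {idx}")
        seen.add(idx)
        aa = _get(row, lineno, path, "aa", optional=True)
        if aa:
            if 1 <= idx <= len(UBIQUITIN_SEQUENCE) and aa != UBIQUITIN_SEQUENCE[idx - 1]:
                raise ValidationError(
                    f"{path}: line {lineno}: residue {idx} is "
                    f"{UBIQUITIN_SEQUENCE[idx - 1]!r} in ubiquitin, file says {aa!r}"
                )
        else:
            aa = UBIQUITIN_SEQUENCE[idx - 1] if 1 <= idx <= len(UBIQUITIN_SEQUENCE) else "X"
        h = _to_float(_get(row, lineno, path, "h_ppm", "h", "shift_h"), lineno, path)
        n = _to_float(_get(row, lineno, path, "n_ppm", "n", "shift_n"), lineno, path)
        inten_text = _get(row, lineno, path, "intensity", optional=True)
        inten = _to_float(inten_text, lineno, path) if inten_text not in (None, "") else None
        entries[ResidueKey(idx, aa)] = Peak(h, n, inten)
    return PeakList(entries=entries, label=label or str(path))


def write_peaklist(peaks: PeakList, path, dialect: str = "tsv") -> None:
    delim = _DELIMS[dialect]
    with open(path, "w") as fh:
        fh.write(delim.join(["residue", "aa", "h_ppm", "n_ppm", "intensity"]) + "\n")
        for key in peaks:
            p = peaks.entries[key]
            inten = "" if p.intensity is None else repr(float(p.intensity))
            fh.write(
                delim.join([str(key.index), key.aa, repr(float(p.shift_h)), repr(float(p.shift_n)), inten])
                + "\n"
            )


def read_series(path, dialect: str = "tsv") -> ResidueSeries:
    """Read a per-residue series (columns: residue, aa, value, error, unit)."""
    values: dict[ResidueKey, tuple[float, float]] = {}
    unit = ""
    for lineno, row in _rows(path, dialect):
        idx = int(_to_float(_get(row, lineno, path, "residue", "res"), lineno, path))
        aa = _get(row, lineno, path, "aa", optional=True) or (
            UBIQUITIN_SEQUENCE[idx - 1] if 1 <= idx <= len(UBIQUITIN_SEQUENCE) else "X"
        )
        val = _to_float(_get(row, lineno, path, "value"), lineno, path)
        err_text = _get(row, lineno, path, "error", optional=True)
        err = _to_float(err_text, lineno, path) if err_text not in (None, "") else 0.0
        row_unit = _get(row, lineno, path, "unit", optional=True) or ""
        if unit and row_unit and row_unit != unit:
            raise ValidationError(f"{path}: line {lineno}: mixed units {unit!r}/{row_unit!r}")
        unit = unit or row_unit
        if ResidueKey(idx, aa) in values:
            raise ValidationError(f"{path}: line {lineno}: duplicate residue {idx}")
        values[ResidueKey(idx, aa)] = (val, err)
    return ResidueSeries(values=values, unit=unit, metadata=str(path))


def write_series(series: ResidueSeries, path, dialect: str = "tsv") -> None:
    delim = _DELIMS[dialect]
    with open(path, "w") as fh:
        fh.write(delim.join(["residue", "aa", "value", "error", "unit"]) + "\n")
        for key in series:
            val, err = series.values[key]
            fh.write(
                delim.join([str(key.index), key.aa, repr(float(val)), repr(float(err)), series.unit]) + "\n"
            )


def read_decay_table(path, kind: str, dialect: str = "tsv") -> dict[int, DecayCurve]:
    """Read per-residue decay curves (columns: residue, abscissa, intensity[, error])."""
    buckets: dict[int, list[tuple[float, float, float | None]]] = {}
    for lineno, row in _rows(path, dialect):
        idx = int(_to_float(_get(row, lineno, path, "residue", "res"), lineno, path))
        x = _to_float(
            _get(row, lineno, path, "abscissa", "delay", "time", "gradient", "g"), lineno, path
        )
        y = _to_float(_get(row, lineno, path, "intensity", "i"), lineno, path)
        err_text = _get(row, lineno, path, "error", optional=True)
        err = _to_float(err_text, lineno, path) if err_text not in (None, "") else None
        buckets.setdefault(idx, []).append((x, y, err))
    out = {}
    for idx, rows in buckets.items():
        xs = np.array([r[0] for r in rows])
        ys = np.array([r[1] for r in rows])
        errs = None
        if all(r[2] is not None for r in rows):
            errs = np.array([r[2] for r in rows])
        out[idx] = DecayCurve(abscissa=xs, intensity=ys, kind=kind, error=errs)
    return out


def read_decay_curve(path, kind: str, dialect: str = "tsv") -> DecayCurve:
    """Read a single decay curve (columns: abscissa, intensity[, error])."""
    xs, ys, errs = [], [], []
    have_err = True
    for lineno, row in _rows(path, dialect):
        xs.append(
            _to_float(
                _get(row, lineno, path, "abscissa", "delay", "time", "gradient", "g"),
                lineno,
                path,
            )
        )
        ys.append(_to_float(_get(row, lineno, path, "intensity", "i"), lineno, path))
        err_text = _get(row, lineno, path, "error", optional=True)
        if err_text in (None, ""):
            have_err = False
        else:
            errs.append(_to_float(err_text, lineno, path))
    return DecayCurve(
        abscissa=np.array(xs),
        intensity=np.array(ys),
        kind=kind,
        error=np.array(errs) if have_err and errs else None,
    )


def write_decay_curve(curve: DecayCurve, path, dialect: str = "tsv") -> None:
    delim = _DELIMS[dialect]
    with open(path, "w") as fh:
        cols = ["abscissa", "intensity"] + (["error"] if curve.error is not None else [])
        fh.write(delim.join(cols) + "\n")
        for i in range(len(curve)):
            row = [repr(float(curve.abscissa[i])), repr(float(curve.intensity[i]))]
            if curve.error is not None:
                row.append(repr(float(curve.error[i])))
            fh.write(delim.join(row) + "\n")


def read_spectrum(path, dialect: str = "tsv") -> Spectrum1D:
    """Read a 1D spectrum (columns: ppm, intensity)."""
    ppm, inten = [], []
    for lineno, row in _rows(path, dialect):
        ppm.append(_to_float(_get(row, lineno, path, "ppm"), lineno, path))
        inten.append(_to_float(_get(row, lineno, path, "intensity", "i"), lineno, path))
    return Spectrum1D(ppm=np.array(ppm), intensity=np.array(inten))


# --- PDB ensembles -------------------------------------------------------

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}
_AA1 = {v: k for k, v in _AA3.items()}


def read_ensemble(path) -> Ensemble:
    """Read a multi-MODEL PDB file into an :class:`Ensemble`.

    Frames keep file order; residue numbering is taken from the file.  All
    models must share one topology (differing atom counts are an error) and
    every element must appear in the packaged radius table.
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises on inconsistent models
        raise ValidationError(f"{path}: inconsistent models: {exc}") from exc
    if stack.stack_depth() == 0:
        raise ValidationError(f"{path}: no models")
    atoms: list[AtomRecord] = []
    for i in range(stack.array_length()):
        element = str(stack.element[i]).upper() or "X"
        if element not in VDW_RADII:
            raise ValidationError(
                f"{path}: atom {i + 1} ({stack.atom_name[i]}): unknown element {element!r}"
            )
        res3 = str(stack.res_name[i])
        atoms.append(
            AtomRecord(
                name=str(stack.atom_name[i]),
                element=element,
                radius=VDW_RADII[element],
                res_index=int(stack.res_id[i]),
                res_name=res3,
                chain=str(stack.chain_id[i]),
            )
        )
    return Ensemble(coords=np.asarray(stack.coord, dtype=float), atoms=atoms)


def write_ensemble(ens: Ensemble, path) -> None:
    """Write an :class:`Ensemble` as a multi-model PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = ens.n_atoms
    stack = struc.AtomArrayStack(ens.n_frames, n)
    stack.coord = np.asarray(ens.coords, dtype=np.float32)
    stack.chain_id = np.array([a.chain for a in ens.atoms], dtype="U4")
    stack.res_id = np.array([a.res_index for a in ens.atoms], dtype=int)
    stack.res_name = np.array([a.res_name for a in ens.atoms], dtype="U5")
    stack.atom_name = np.array([a.name for a in ens.atoms], dtype="U6")
    stack.element = np.array([a.element for a in ens.atoms], dtype="U2")
    stack.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def aa_one_letter(res_name: str) -> str:
    return _AA1.get(res_name.upper(), "X")


def aa_three_letter(code: str) -> str:
    return _AA3.get(code.upper(), "UNK")
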
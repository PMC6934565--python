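"""Reference data for ubiquitin and a fixed van der Waals radius table.

Ubiquitin is a 76-residue signaling protein.  Residue numbering in this
package is 1-based throughout, matching the convention of solution-NMR
assignments (PDB 1D3Z numbering).  Positions 19, 37 and 38 are proline and
therefore carry no backbone amide peak in a 1H-15N correlation spectrum.
"""

from __future__ import annotations

# Human ubiquitin, UniProt P0CG48, residues 1-76.
UBIQUITIN_SEQUENCE = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
)

#: 1-based positions of proline residues (no amide proton).
PROLINE_POSITIONS = frozenset({19, 37, 38})

#: Residues of the hydrophobic patch central to ligand recognition.
HYDROPHOBIC_PATCH = frozenset({8, 44, 70})

#: Globular core used for inter-domain collective variables; the flexible
#: C-terminal tail (73-76) is excluded.
CORE_RANGE = (1, 72)

# Fixed van der Waals radii in Angstrom (Bondi-style set).  PDB files do not
# carry radii, so every structure reader assigns them from this table.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    # "X" is used by the toy-ensemble generator for coarse beads.
    "X": 2.30,
}


def residue_letter(index: int) -> str:
    """One-letter code at 1-based position ``index`` of ubiquitin."""
    if not 1 <= index <= len(UBIQUITIN_SEQUENCE):
        raise ValueError(f"residue index {index} outside 1..{len(UBIQUITIN_SEQUENCE)}")
    return UBIQUITIN_SEQUENCE[index - 1]


def amide_positions() -> list[int]:
    """All 1-based positions expected to show a backbone amide peak.

    Excludes the prolines and Met1, whose N-terminal amine exchanges too
    fast to be observed.
    """
    return [
        i
        for i in range(2, len(UBIQUITIN_SEQUENCE) + 1)
        if i not in PROLINE_POSITIONS
    ]
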
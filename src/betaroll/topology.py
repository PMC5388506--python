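"""Ideal two-molecule beta-roll stack: sequence, geometry, and contact maps.

A beta roll (beta solenoid) winds an 8-residue repeat into strands that
alternate between two parallel beta sheets joined by short turns.  The
(GAGAGAGQ)x10 silk-inspired peptide studied here gives 10 strands of 8
residues per molecule: two 5-strand sheets, turns at the Q-containing ends,
and a second identical molecule stacked on top through its turns.

One bead per residue sits at the Calpha position.  Residue indices are
1-based and global across the stack (1..80 bottom molecule, 81..160 top).
The unfolding order parameter Omega counts residue pairs (i, i+16) — a
residue and the neighbour one winding above it in the same sheet — whose
separation lies in the 4.0–6.0 A window; a perfect 80-residue roll has 64
such pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InvalidResidueError, RestraintSelectionError

#: sequence offset between a residue and its same-sheet neighbour one winding up
OMEGA_OFFSET = 16
#: positions (0-based, within the 8-residue repeat) assigned to the turn: G, Q
TURN_POSITIONS = (6, 7)
#: Omega native-contact window, A (inclusive on both ends)
OMEGA_WINDOW = (4.0, 6.0)

_ONE_LETTER = set("ACDEFGHIKLMNPQRSTVWY")

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}


@dataclass(frozen=True)
class GeometryParams:
    """Ideal-stack geometry, all lengths in Angstrom.

    strand_spacing    distance between adjacent strands within one sheet
    sheet_separation  distance between the two sheets of one roll
    stack_separation  gap between the top sheet of the bottom molecule and
                      the bottom sheet of the top molecule
    residue_rise      per-residue advance along a strand
    """

    strand_spacing: float = 4.85
    sheet_separation: float = 5.0
    stack_separation: float = 5.0
    residue_rise: float = 3.4

    def __post_init__(self) -> None:
        for name in ("strand_spacing", "sheet_separation",
                     "stack_separation", "residue_rise"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.residue_rise >= self.sheet_separation:
            # the two turn beads bridge the sheets with bonds of length
            # residue_rise; the bridge needs 3 chords to span the sheet gap
            if self.sheet_separation < self.residue_rise / 3:
                raise GeometryError(
                    "sheet_separation too small for the turn bridge")


@dataclass(frozen=True)
class ResidueSequence:
    """One-letter residue codes with a molecule label per residue."""

    residues: tuple[str, ...]
    molecule_id: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.molecule_id):
            raise InvalidResidueError("residues and molecule ids differ in length")
        bad = sorted({r for r in self.residues if r not in _ONE_LETTER})
        if bad:
            raise InvalidResidueError(f"invalid residue codes: {bad}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_molecules(self) -> int:
        return len(set(self.molecule_id))

    @property
    def residues_per_molecule(self) -> int:
        n_mol = self.n_molecules
        if len(self.residues) % n_mol:
            raise InvalidResidueError("molecules of unequal length")
        return len(self.residues) // n_mol

    def molecule_slice(self, molecule: int) -> slice:
        """Global 0-based slice of one molecule's residues."""
        per = self.residues_per_molecule
        return slice(molecule * per, (molecule + 1) * per)


def build_sequence(repeat_unit: str = "GAGAGAGQ", n_repeats: int = 10,
                   n_molecules: int = 1) -> ResidueSequence:
    """Concatenate ``n_repeats`` copies of the repeat for each molecule."""
    if not repeat_unit:
        raise InvalidResidueError("repeat_unit must be non-empty")
    if n_repeats < 1 or n_molecules < 1:
        raise InvalidResidueError("counts must be >= 1")
    unit = tuple(repeat_unit.upper())
    bad = sorted({r for r in unit if r not in _ONE_LETTER})
    if bad:
        raise InvalidResidueError(f"invalid residue codes: {bad}")
    per = unit * n_repeats
    residues = per * n_molecules
    molecule_id = tuple(m for m in range(n_molecules) for _ in per)
    return ResidueSequence(residues=residues, molecule_id=molecule_id)


def enumerate_omega_pairs(n_residues_per_molecule: int) -> list[tuple[int, int]]:
    """All (i, i+16) pairs with i+16 <= n, 1-based, within one molecule."""
    if n_residues_per_molecule < 1:
        raise InvalidResidueError("need at least one residue")
    n = n_residues_per_molecule
    return [(i, i + OMEGA_OFFSET) for i in range(1, n - OMEGA_OFFSET + 1)]


@dataclass(frozen=True)
class Conformation:
    """Per-residue bead coordinates in Angstrom, shape (n_residues, 3)."""

    coordinates: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError("coordinates must have shape (n, 3)")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_residues(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class BetaRollTopology:
    """Index sets of the ideal beta-roll stack (all residue indices 1-based).

    ``strand_of_residue`` holds the within-molecule strand index (1..n_repeats)
    or 0 for turn residues.  ``sheet_of_strand`` maps a strand index to its
    layer ('bottom' for odd strands, 'top' for even).  Contact pair classes:

    * lateral: (i, i+16) pairs — hydrogen-bond ladder between adjacent strands
      of one sheet, and between adjacent turns on one side;
    * vertical intra: the turn-flanking pair bridging the two sheets of one
      roll across each turn;
    * vertical inter: one turn-to-turn pair per strand across the
      molecule-molecule interface.
    """

    sequence: ResidueSequence
    geometry: GeometryParams
    n_repeats: int
    strand_of_residue: tuple[int, ...]
    sheet_of_strand: dict[int, str] = field(hash=False)
    omega_pairs: tuple[tuple[int, int], ...]
    lateral_pairs: tuple[tuple[int, int], ...]
    vertical_intra_pairs: tuple[tuple[int, int], ...]
    vertical_inter_pairs: tuple[tuple[int, int], ...]

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_molecules(self) -> int:
        return self.sequence.n_molecules

    @property
    def residues_per_molecule(self) -> int:
        return self.sequence.residues_per_molecule

    @property
    def vertical_pairs(self) -> tuple[tuple[int, int], ...]:
        return self.vertical_intra_pairs + self.vertical_inter_pairs

    def molecule_of(self, residue: int) -> int:
        """Molecule id of a 1-based global residue index."""
        return self.sequence.molecule_id[residue - 1]

    def is_turn(self, residue: int) -> bool:
        return self.strand_of_residue[residue - 1] == 0

    def omega_pairs_of(self, molecule: int) -> tuple[tuple[int, int], ...]:
        return tuple(p for p in self.omega_pairs
                     if self.molecule_of(p[0]) == molecule)

    def repeat_position(self, residue: int) -> tuple[int, int]:
        """(repeat index 0-based, position-in-repeat 0-based) of a residue."""
        local = (residue - 1) % self.residues_per_molecule
        return local // 8, local % 8

    def lateral_subclass(self, pair: tuple[int, int]) -> str:
        """'strand' for sheet-ladder pairs, 'turn' for turn-to-turn pairs."""
        _, q = self.repeat_position(pair[0])
        return "turn" if q in TURN_POSITIONS else "strand"


def _molecule_coordinates(geometry: GeometryParams, n_repeats: int) -> np.ndarray:
    """Bead positions for one molecule at the ideal winding.

    Bottom-sheet strands (odd) run +x at z=0; top-sheet strands (even) run -x
    at z=sheet_separation with a uniform lateral slant of one strand spacing
    per strand so both turn bridges span the same 3D gap.  Each turn is a
    symmetric two-bead bulge of bond-length chords past the strand end.
    """
    a = geometry.strand_spacing
    b = geometry.residue_rise
    h = geometry.sheet_separation
    length = 5 * b                       # x span of the 6-residue strand
    delta = (h - b) / 2.0                # turn bead height above/below sheets
    if b * b - delta * delta <= 0:
        raise GeometryError(
            "residue_rise/sheet_separation leave no room for the turn bulge")
    bulge = math.sqrt(b * b - delta * delta)

    coords = np.empty((8 * n_repeats, 3), dtype=float)
    for r in range(n_repeats):
        w, parity = divmod(r, 2)
        base = 8 * r
        if parity == 0:                  # bottom sheet, +x
            for q in range(6):
                coords[base + q] = (b * q, a * w, 0.0)
            coords[base + 6] = (length + bulge, a * w, delta)
            coords[base + 7] = (length + bulge, a * w, h - delta)
        else:                            # top sheet, -x, slanted by one spacing
            for q in range(6):
                coords[base + q] = (length - b * q, a * w + a * q / 5.0, h)
            coords[base + 6] = (-bulge, a * (w + 1), h - delta)
            coords[base + 7] = (-bulge, a * (w + 1), delta)
    return coords


def ideal_conformation(topology: BetaRollTopology) -> Conformation:
    """Rebuild the ideal stack coordinates recorded in a topology."""
    g = topology.geometry
    one = _molecule_coordinates(g, topology.n_repeats)
    z_step = g.sheet_separation + g.stack_separation
    blocks = [one + np.array([0.0, 0.0, m * z_step])
              for m in range(topology.n_molecules)]
    return Conformation(np.vstack(blocks))


def _turn_flank_pairs(n_repeats: int, offset: int) -> list[tuple[int, int]]:
    # last strand residue (q=5) to first residue of the next strand (q=0)
    return [(offset + 8 * r + 6, offset + 8 * r + 9)
            for r in range(n_repeats - 1)]


def build_ideal_stack(
    geometry: GeometryParams | None = None,
    n_repeats: int = 10,
    n_molecules: int = 2,
    repeat_unit: str = "GAGAGAGQ",
) -> tuple[Conformation, BetaRollTopology]:
    """Construct the ideal stack and every index set downstream stages use.

    Raises :class:`GeometryError` (listing the offending pairs) if the
    requested geometry pushes any Omega pair outside the 4.0–6.0 A window.
    """
    geometry = geometry or GeometryParams()
    sequence = build_sequence(repeat_unit, n_repeats, n_molecules)
    per = 8 * n_repeats

    strand_of = []
    for _ in range(n_molecules):
        for r in range(n_repeats):
            for q in range(8):
                strand_of.append(0 if q in TURN_POSITIONS else r + 1)
    sheet_of_strand = {s: ("bottom" if s % 2 == 1 else "top")
                       for s in range(1, n_repeats + 1)}

    omega: list[tuple[int, int]] = []
    for m in range(n_molecules):
        off = m * per
        omega.extend((off + i, off + j) for i, j in enumerate_omega_pairs(per))

    # lateral hydrogen-bond ladder: identical index arithmetic to the Omega
    # pairs — adjacent strands of one sheet and adjacent turns on one side
    lateral = list(omega)

    vertical_intra: list[tuple[int, int]] = []
    for m in range(n_molecules):
        vertical_intra.extend(_turn_flank_pairs(n_repeats, m * per))

    vertical_inter: list[tuple[int, int]] = []
    for m in range(n_molecules - 1):
        lo, hi = m * per, (m + 1) * per
        for r in range(n_repeats):
            if r % 2 == 0:
                # +x turn: upper bead of the lower molecule's turn (q=7)
                # against the lower bead of the upper molecule's turn (q=6)
                vertical_inter.append((lo + 8 * r + 8, hi + 8 * r + 7))
            else:
                vertical_inter.append((lo + 8 * r + 7, hi + 8 * r + 8))

    topology = BetaRollTopology(
        sequence=sequence,
        geometry=geometry,
        n_repeats=n_repeats,
        strand_of_residue=tuple(strand_of),
        sheet_of_strand=sheet_of_strand,
        omega_pairs=tuple(omega),
        lateral_pairs=tuple(lateral),
        vertical_intra_pairs=tuple(vertical_intra),
        vertical_inter_pairs=tuple(vertical_inter),
    )
    conformation = ideal_conformation(topology)

    coords = conformation.coordinates
    lo, hi = OMEGA_WINDOW
    bad = []
    for i, j in topology.omega_pairs:
        d = float(np.linalg.norm(coords[j - 1] - coords[i - 1]))
        if not (lo <= d <= hi):
            bad.append((i, j, round(d, 3)))
    if bad:
        raise GeometryError(
            "geometry puts Omega pairs outside the "
            f"{lo}-{hi} A window: {bad[:8]}{'...' if len(bad) > 8 else ''}")
    return conformation, topology


def enumerate_hbond_pairs(
    topology: BetaRollTopology,
) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]:
    """(lateral pairs, vertical pairs) of a built topology."""
    return topology.lateral_pairs, topology.vertical_pairs


def select_fixed_atoms(topology: BetaRollTopology,
                       mode: str = "none") -> list[int]:
    """Residues restrained to mimic a substrate-bound bottom template.

    ``partial_template`` picks, for each bottom-sheet strand of the bottom
    molecule, the base glycine at either end of the strand where it meets a
    turn: the in-turn glycine (q=6) on the +x side and the strand-start
    glycine (q=0) on the -x side — 10 glycine beads, both sides, at the
    bottom of the turns.
    """
    if mode == "none":
        return []
    if mode != "partial_template":
        raise RestraintSelectionError(f"unknown restraint mode: {mode!r}")
    if topology.n_molecules < 2:
        raise RestraintSelectionError(
            "partial_template requires a bottom template molecule")
    fixed = []
    for r in range(topology.n_repeats):
        if r % 2 == 0:  # bottom-sheet strands
            fixed.append(8 * r + 1)   # strand-start G, -x side
            fixed.append(8 * r + 7)   # in-turn G, +x side
    for idx in fixed:
        if topology.sequence.residues[idx - 1] != "G":
            raise RestraintSelectionError(
                f"restraint selection hit non-glycine residue {idx}")
    return sorted(fixed)
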
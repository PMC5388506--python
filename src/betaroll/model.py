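"""Go-like coarse-grained energy model for the beta-roll stack.

The atomistic force field is replaced by a native-contact model whose
attractive interactions are exactly the lateral/vertical hydrogen-bond
pairs of the ideal stack.  Terms (kcal/mol, A, rad):

* bonds: ``k_b (r - r0)^2`` with per-bond native rest lengths;
* angles: harmonic ``k_a (theta - theta0)^2`` with per-angle native rest
  angles (ideal strands are collinear; the gradient is evaluated with a
  guarded sin(theta), which is well behaved because the force magnitude
  vanishes together with sin(theta) at the collinear reference);
* torsions: ``k_d (1 - cos(phi - phi0))`` over quadruples whose reference
  geometry is non-degenerate (turn regions); these supply the nonzero
  dihedral energy channel the dual-boost scheme requires;
* native contacts: 12-10 wells ``eps [5 (r0/r)^12 - 6 (r0/r)^10]`` with a
  per-class depth (lateral / vertical-intra / vertical-inter) encoding the
  measured hydrogen-bond hierarchy, and per-class rest lengths taken from
  the reference build;
* excluded volume: a purely repulsive shifted 12-6 wall below ``sigma`` on
  all remaining pairs;
* positional restraints: ``k |r - r_ref|^2`` over the fixed-atom selection.

The total potential splits exactly into dihedral and non-dihedral parts,
which is the decomposition the dual-boost accelerated-MD scheme boosts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, OverlapError
from .topology import BetaRollTopology, Conformation

#: residue bead masses, amu
MASS_OF = {"G": 57.05, "A": 71.08, "Q": 128.13}
DEFAULT_MASS = 110.0

CONTACT_CLASSES = ("lateral", "vertical_intra", "vertical_inter")


@dataclass(frozen=True)
class EnergyModel:
    """Force constants and interaction parameters of the CG model."""

    k_bond: float = 20.0             # kcal/mol/A^2
    bond_length: float = 3.4         # nominal rest length, A (native per bond)
    k_angle: float = 20.0            # kcal/mol/rad^2, strand backbone
    k_angle_turn: float = 10.0       # kcal/mol/rad^2, angles through turns
    k_dihedral: float = 1.0          # kcal/mol torsion amplitude
    eps_lateral: float = 1.5         # kcal/mol contact well depths
    eps_vertical_intra: float = 0.75
    eps_vertical_inter: float = 1.2
    sigma_excluded: float = 3.0      # A, excluded-volume radius
    eps_excluded: float = 1.0        # kcal/mol
    k_restraint: float = 10.0        # kcal/mol/A^2, template restraint

    def __post_init__(self) -> None:
        for name in ("k_bond", "k_angle", "k_angle_turn", "k_dihedral",
                     "eps_lateral",
                     "eps_vertical_intra", "eps_vertical_inter",
                     "eps_excluded", "k_restraint"):
            if getattr(self, name) < 0:
                raise GeometryError(f"{name} must be >= 0")
        if self.bond_length <= 0 or self.sigma_excluded <= 0:
            raise GeometryError("rest lengths must be positive")

    def contact_depth(self, contact_class: str) -> float:
        return {
            "lateral": self.eps_lateral,
            "vertical_intra": self.eps_vertical_intra,
            "vertical_inter": self.eps_vertical_inter,
        }[contact_class]


@dataclass(frozen=True)
class FrameEnergies:
    """Energy decomposition of one conformation, kcal/mol.

    ``v_total == v_non_dihedral + v_dihedral`` holds exactly by construction.
    """

    v_dihedral: float
    v_non_dihedral: float
    breakdown: dict[str, float] = field(default_factory=dict, hash=False)

    @property
    def v_total(self) -> float:
        return self.v_non_dihedral + self.v_dihedral


def _dihedral_angles(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    b1 = coords[quads[:, 1]] - coords[quads[:, 0]]
    b2 = coords[quads[:, 2]] - coords[quads[:, 1]]
    b3 = coords[quads[:, 3]] - coords[quads[:, 2]]
    m = np.cross(b1, b2)
    n = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    y = np.einsum("ij,ij->i", np.cross(m, n), b2) / np.maximum(nb2, 1e-12)
    x = np.einsum("ij,ij->i", m, n)
    return np.arctan2(y, x)


class ForceField:
    """Precomputed interaction lists for one topology + reference build.

    Construct once with :meth:`from_topology`; ``evaluate`` then returns the
    energy decomposition and the force arrays split into the dihedral and
    non-dihedral channels (the split the dual boost scales independently).
    """

    def __init__(self, model: EnergyModel, topology: BetaRollTopology,
                 reference: Conformation, fixed_atoms: tuple[int, ...] = ()):
        self.model = model
        self.topology = topology
        self.reference = reference
        self.fixed_atoms = tuple(fixed_atoms)
        ref = reference.coordinates
        n = topology.n_residues
        if ref.shape[0] != n:
            raise GeometryError("reference does not match topology size")
        mol = np.asarray(topology.sequence.molecule_id)

        # bonded terms within molecules
        idx = np.arange(n)
        same2 = mol[:-1] == mol[1:]
        self.bond_idx = np.stack([idx[:-1][same2], idx[1:][same2]], axis=1)
        d = ref[self.bond_idx[:, 1]] - ref[self.bond_idx[:, 0]]
        self.bond_r0 = np.linalg.norm(d, axis=1)

        same3 = (mol[:-2] == mol[1:-1]) & (mol[1:-1] == mol[2:])
        tri = np.stack([idx[:-2], idx[1:-1], idx[2:]], axis=1)[same3]
        self.angle_idx = tri
        u = ref[tri[:, 0]] - ref[tri[:, 1]]
        v = ref[tri[:, 2]] - ref[tri[:, 1]]
        cos0 = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        self.angle_theta0 = np.arccos(np.clip(cos0, -1.0, 1.0))
        # turns are more flexible than strands: angles through a turn
        # residue get the softer constant
        is_turn = np.array([topology.is_turn(i + 1)
                            for i in range(n)], dtype=bool)
        turn_angle = is_turn[tri].any(axis=1)
        self.angle_k = np.where(turn_angle, model.k_angle_turn,
                                model.k_angle)

        same4 = same3[:-1] & (mol[2:-1] == mol[3:])
        quads = np.stack([idx[:-3], idx[1:-2], idx[2:-1], idx[3:]], axis=1)[same4]
        # keep only torsions that are geometrically defined at the reference
        b1 = ref[quads[:, 1]] - ref[quads[:, 0]]
        b2 = ref[quads[:, 2]] - ref[quads[:, 1]]
        b3 = ref[quads[:, 3]] - ref[quads[:, 2]]
        ok = (np.linalg.norm(np.cross(b1, b2), axis=1) > 1e-8) & \
             (np.linalg.norm(np.cross(b2, b3), axis=1) > 1e-8)
        self.dihedral_idx = quads[ok]
        self.dihedral_phi0 = _dihedral_angles(ref, self.dihedral_idx)

        # native contacts, per class
        pair_sets = {
            "lateral": topology.lateral_pairs,
            "vertical_intra": topology.vertical_intra_pairs,
            "vertical_inter": topology.vertical_inter_pairs,
        }
        cidx, ceps, cr0 = [], [], []
        self.contact_class_slices: dict[str, slice] = {}
        start = 0
        self.contact_rest_length: dict[str, float] = {}
        for cls in CONTACT_CLASSES:
            pairs = np.asarray(pair_sets[cls], dtype=int).reshape(-1, 2) - 1
            dists = np.linalg.norm(ref[pairs[:, 1]] - ref[pairs[:, 0]], axis=1) \
                if len(pairs) else np.empty(0)
            if len(pairs) and np.ptp(dists) > 1e-6:
                raise GeometryError(
                    f"{cls} native distances are not uniform: "
                    f"{dists.min():.4f}..{dists.max():.4f} A")
            r0 = float(dists[0]) if len(pairs) else 0.0
            self.contact_rest_length[cls] = r0
            cidx.append(pairs)
            ceps.append(np.full(len(pairs), model.contact_depth(cls)))
            cr0.append(np.full(len(pairs), r0))
            self.contact_class_slices[cls] = slice(start, start + len(pairs))
            start += len(pairs)
        self.contact_idx = np.vstack(cidx)
        self.contact_eps = np.concatenate(ceps)
        self.contact_r0 = np.concatenate(cr0)

        # excluded volume: everything except 1-2, 1-3 and native contacts
        excluded = set()
        for i, j in self.bond_idx:
            excluded.add((int(i), int(j)))
        for i, _, k in self.angle_idx:
            excluded.add((int(i), int(k)))
        for i, j in self.contact_idx:
            excluded.add((min(int(i), int(j)), max(int(i), int(j))))
        ii, jj = np.triu_indices(n, k=1)
        keep = np.fromiter(
            ((int(a), int(b)) not in excluded for a, b in zip(ii, jj)),
            dtype=bool, count=len(ii))
        self.ev_idx = np.stack([ii[keep], jj[keep]], axis=1)

        self.restraint_idx = np.asarray(self.fixed_atoms, dtype=int) - 1
        self.restraint_ref = ref[self.restraint_idx].copy() \
            if len(self.restraint_idx) else np.empty((0, 3))

        self.masses = np.array(
            [MASS_OF.get(r, DEFAULT_MASS) for r in topology.sequence.residues])

    @classmethod
    def from_topology(cls, model: EnergyModel, topology: BetaRollTopology,
                      reference: Conformation,
                      fixed_atoms: tuple[int, ...] = ()) -> "ForceField":
        return cls(model, topology, reference, fixed_atoms)

    @property
    def n_residues(self) -> int:
        return self.topology.n_residues

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, coords: np.ndarray
                 ) -> tuple[FrameEnergies, np.ndarray, np.ndarray]:
        """Energies plus (dihedral-channel, non-dihedral-channel) forces."""
        m = self.model
        n = coords.shape[0]
        f_other = np.zeros((n, 3))
        f_dih = np.zeros((n, 3))

        # bonds
        d = coords[self.bond_idx[:, 1]] - coords[self.bond_idx[:, 0]]
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1e-10):
            raise OverlapError("bonded beads at zero separation")
        e_bond = float(np.sum(m.k_bond * (r - self.bond_r0) ** 2))
        g = (2.0 * m.k_bond * (r - self.bond_r0) / r)[:, None] * d
        np.add.at(f_other, self.bond_idx[:, 0], g)
        np.add.at(f_other, self.bond_idx[:, 1], -g)

        # harmonic angles (guarded sin for near-collinear references)
        ai, aj, ak = (self.angle_idx[:, c] for c in range(3))
        u = coords[ai] - coords[aj]
        v = coords[ak] - coords[aj]
        ru = np.linalg.norm(u, axis=1)
        rv = np.linalg.norm(v, axis=1)
        if np.any(ru < 1e-10) or np.any(rv < 1e-10):
            raise OverlapError("angle beads at zero separation")
        c = np.clip(np.einsum("ij,ij->i", u, v) / (ru * rv), -1.0, 1.0)
        theta = np.arccos(c)
        sin_t = np.maximum(np.sqrt(1.0 - c * c), 1e-8)
        e_angle = float(np.sum(self.angle_k *
                               (theta - self.angle_theta0) ** 2))
        pref = (2.0 * self.angle_k * (theta - self.angle_theta0) / sin_t)
        gi = pref[:, None] * (v / (ru * rv)[:, None] - (c / ru**2)[:, None] * u)
        gk = pref[:, None] * (u / (ru * rv)[:, None] - (c / rv**2)[:, None] * v)
        np.add.at(f_other, ai, gi)
        np.add.at(f_other, ak, gk)
        np.add.at(f_other, aj, -(gi + gk))

        # torsions (the dihedral channel)
        e_dih = 0.0
        if len(self.dihedral_idx):
            qd = self.dihedral_idx
            b1 = coords[qd[:, 1]] - coords[qd[:, 0]]
            b2 = coords[qd[:, 2]] - coords[qd[:, 1]]
            b3 = coords[qd[:, 3]] - coords[qd[:, 2]]
            mm = np.cross(b1, b2)
            nn = np.cross(b2, b3)
            m2 = np.einsum("ij,ij->i", mm, mm)
            n2 = np.einsum("ij,ij->i", nn, nn)
            nb2 = np.linalg.norm(b2, axis=1)
            defined = (m2 > 1e-16) & (n2 > 1e-16) & (nb2 > 1e-10)
            y = np.einsum("ij,ij->i", np.cross(mm, nn), b2) / np.maximum(nb2, 1e-12)
            phi = np.arctan2(y, np.einsum("ij,ij->i", mm, nn))
            dphi = phi - self.dihedral_phi0
            e_dih = float(np.sum(np.where(
                defined, m.k_dihedral * (1.0 - np.cos(dphi)), 0.0)))
            gphi = np.where(defined, m.k_dihedral * np.sin(dphi), 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                dphi_dri = -(nb2 / np.maximum(m2, 1e-16))[:, None] * mm
                dphi_drl = (nb2 / np.maximum(n2, 1e-16))[:, None] * nn
            p = np.einsum("ij,ij->i", b1, b2) / np.maximum(nb2**2, 1e-16)
            q = np.einsum("ij,ij->i", b3, b2) / np.maximum(nb2**2, 1e-16)
            s = p[:, None] * dphi_dri - q[:, None] * dphi_drl
            dphi_drj = -dphi_dri - s
            dphi_drk = -dphi_drl + s
            gv = -gphi[:, None]
            np.add.at(f_dih, qd[:, 0], gv * dphi_dri)
            np.add.at(f_dih, qd[:, 1], gv * dphi_drj)
            np.add.at(f_dih, qd[:, 2], gv * dphi_drk)
            np.add.at(f_dih, qd[:, 3], gv * dphi_drl)

        # native contacts (12-10)
        d = coords[self.contact_idx[:, 1]] - coords[self.contact_idx[:, 0]]
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1e-10):
            raise OverlapError("contact beads at zero separation")
        u10 = (self.contact_r0 / r) ** 10
        u12 = u10 * (self.contact_r0 / r) ** 2
        e_contact = float(np.sum(self.contact_eps * (5.0 * u12 - 6.0 * u10)))
        dvdr = 60.0 * self.contact_eps * (u10 - u12) / r
        g = (dvdr / r)[:, None] * d
        np.add.at(f_other, self.contact_idx[:, 0], g)
        np.add.at(f_other, self.contact_idx[:, 1], -g)

        # excluded volume (repulsive wall below sigma)
        d = coords[self.ev_idx[:, 1]] - coords[self.ev_idx[:, 0]]
        r2 = np.einsum("ij,ij->i", d, d)
        sig2 = m.sigma_excluded ** 2
        hit = r2 < sig2
        e_ev = 0.0
        if np.any(hit):
            r2h = r2[hit]
            if np.any(r2h < 1e-20):
                raise OverlapError("non-bonded beads at zero separation")
            s6 = (sig2 / r2h) ** 3
            e_ev = float(np.sum(m.eps_excluded * (s6 * s6 - 2.0 * s6 + 1.0)))
            dvdr_over_r = 12.0 * m.eps_excluded * (s6 - s6 * s6) / r2h
            g = dvdr_over_r[:, None] * d[hit]
            np.add.at(f_other, self.ev_idx[hit, 0], g)
            np.add.at(f_other, self.ev_idx[hit, 1], -g)

        # template restraints
        e_restraint = 0.0
        if len(self.restraint_idx):
            disp = coords[self.restraint_idx] - self.restraint_ref
            e_restraint = float(m.k_restraint * np.sum(disp * disp))
            np.add.at(f_other, self.restraint_idx, -2.0 * m.k_restraint * disp)

        breakdown = {
            "bond": e_bond, "angle": e_angle, "dihedral": e_dih,
            "contact": e_contact, "excluded_volume": e_ev,
            "restraint": e_restraint,
        }
        energies = FrameEnergies(
            v_dihedral=e_dih,
            v_non_dihedral=e_bond + e_angle + e_contact + e_ev + e_restraint,
            breakdown=breakdown,
        )
        return energies, f_dih, f_other


def _default_forcefield(model: EnergyModel, topology: BetaRollTopology,
                        reference: Conformation | None) -> ForceField:
    from .topology import ideal_conformation
    ref = reference or ideal_conformation(topology)
    return ForceField(model, topology, ref)


def energy(conformation: Conformation, model: EnergyModel,
           topology: BetaRollTopology,
           reference: Conformation | None = None) -> FrameEnergies:
    """Energy decomposition of one conformation under the Go model."""
    ff = _default_forcefield(model, topology, reference)
    energies, _, _ = ff.evaluate(conformation.coordinates)
    return energies


def forces(conformation: Conformation, model: EnergyModel,
           topology: BetaRollTopology,
           reference: Conformation | None = None) -> np.ndarray:
    """Total forces, kcal/mol/A, shape (n, 3)."""
    ff = _default_forcefield(model, topology, reference)
    _, f_dih, f_other = ff.evaluate(conformation.coordinates)
    return f_dih + f_other


def apply_restraints(conformation: Conformation, fixed_atoms,
                     reference: Conformation, k: float = 10.0
                     ) -> tuple[float, np.ndarray]:
    """Harmonic template restraint ``k |r - r_ref|^2`` over a selection.

    Returns (energy, forces); zero everywhere at the reference.
    """
    idx = np.asarray(list(fixed_atoms), dtype=int) - 1
    f = np.zeros_like(conformation.coordinates)
    if len(idx) == 0:
        return 0.0, f
    disp = conformation.coordinates[idx] - reference.coordinates[idx]
    f[idx] = -2.0 * k * disp
    return float(k * np.sum(disp * disp)), f
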
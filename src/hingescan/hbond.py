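"""Geometric hydrogen-bond detection and persistence along mode trajectories.

Bonds are called on heavy atoms only: any backbone or side-chain N/O
pair from two distinct residues (sequence separation >= 2) closer than a
distance cutoff (default 3.2 Å, strict inequality).  No donor-H-acceptor
angle is evaluated because the coarse-grained pipeline never places
hydrogens; the N atom of a mixed N/O pair is reported as the donor.

Persistence along a Cα-resolution trajectory uses a rigid-residue rule:
every heavy atom of a residue translates with its residue's Cα
displacement.  The persistence of a bond is the fraction of frames in
which the displaced heavy-atom distance stays below the cutoff — a bond
inside a rigid hinge flank survives the full mode sweep (persistence
1.0), while a bond across a shearing interface breaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enm import CalphaModel, EnmError
from .profiles import Trajectory
from .structure import Structure

__all__ = ["HBond", "HBondError", "detect_hbonds", "hbond_persistence", "hbond_table"]

_BACKBONE = {"N", "C", "O", "CA", "OXT"}


class HBondError(ValueError):
    pass


@dataclass
class HBond:
    """A donor/acceptor heavy-atom pair with its trajectory statistics."""

    donor_residue: str
    donor_atom: str
    acceptor_residue: str
    acceptor_atom: str
    distance: float  # reference distance, Å
    donor_bead: int
    acceptor_bead: int
    donor_coord: np.ndarray
    acceptor_coord: np.ndarray
    donor_backbone: bool = False
    acceptor_backbone: bool = False
    persistence: float | None = None
    frame_distances: np.ndarray | None = None

    def __post_init__(self):
        if not self.distance > 0:
            raise HBondError("reference distance must be > 0")


def _polar_atoms(structure: Structure, wanted: dict[tuple[str, int], int]):
    """Yield (key, bead, atom name, element, coord, backbone) for N/O atoms."""
    a = structure.atoms
    out = []
    for idx in range(a.array_length()):
        el = str(a.element[idx])
        if el not in ("N", "O"):
            continue
        key = (str(a.chain_id[idx]), int(a.res_id[idx]))
        if key not in wanted:
            continue
        name = str(a.atom_name[idx])
        out.append((key, wanted[key], name, el, np.asarray(a.coord[idx], float), name in _BACKBONE))
    return out


def detect_hbonds(
    structure: Structure,
    model: CalphaModel,
    residues: set[int] | list[int],
    cutoff: float = 3.2,
) -> list[HBond]:
    """Enumerate candidate hydrogen bonds among a residue set.

    ``residues`` are mature-numbering residue labels (integers) restricted
    to the beads of ``model``.  All N/O heavy-atom pairs across distinct
    candidate residues with bead separation >= 2 and distance strictly
    below ``cutoff`` are returned sorted by distance.
    """
    residues = set(int(r) for r in residues)
    bead_of = {}
    for b, (ch, rn) in enumerate(zip(model.chain_ids, model.resnums)):
        if int(rn) in residues:
            bead_of[(str(ch), int(rn))] = b
    found = {rn for (_, rn) in bead_of}
    missing = residues - found
    if missing:
        raise HBondError(f"candidate residues absent from model: {sorted(missing)}")

    # map model beads back to deposited numbering to look atoms up
    wanted = {}
    a = structure.atoms
    deposited = {(str(c), int(r)) for c, r in zip(a.chain_id, a.res_id)}
    for (ch, rn), b in bead_of.items():
        if (ch, rn) in deposited:
            wanted[(ch, rn)] = b
    if len(wanted) < len(bead_of):
        lost = sorted(rn for k, rn in ((k, k[1]) for k in bead_of) if k not in wanted)
        raise HBondError(
            f"candidate residues have no atoms in the structure: {lost} "
            "(is the numbering map consistent?)"
        )

    atoms = _polar_atoms(structure, wanted)
    bonds: list[HBond] = []
    for x in range(len(atoms)):
        for y in range(x + 1, len(atoms)):
            key1, b1, n1, e1, c1, bb1 = atoms[x]
            key2, b2, n2, e2, c2, bb2 = atoms[y]
            if b1 == b2:
                continue
            if key1[0] == key2[0] and abs(key1[1] - key2[1]) < 2:
                continue  # same chain, sequence separation < 2
            d = float(np.linalg.norm(c1 - c2))
            if not d < cutoff:
                continue
            # the N of a mixed N/O pair donates; otherwise keep file order
            if e2 == "N" and e1 == "O":
                key1, b1, n1, c1, bb1, key2, b2, n2, c2, bb2 = (
                    key2, b2, n2, c2, bb2, key1, b1, n1, c1, bb1,
                )
            bonds.append(
                HBond(
                    donor_residue=model.labels[b1],
                    donor_atom=n1,
                    acceptor_residue=model.labels[b2],
                    acceptor_atom=n2,
                    distance=d,
                    donor_bead=b1,
                    acceptor_bead=b2,
                    donor_coord=c1,
                    acceptor_coord=c2,
                    donor_backbone=bb1,
                    acceptor_backbone=bb2,
                )
            )
    bonds.sort(key=lambda b: (b.distance, b.donor_residue, b.donor_atom))
    return bonds


def hbond_persistence(
    bond: HBond, trajectory: Trajectory, cutoff: float = 3.2
) -> float:
    """Fraction of trajectory frames in which the bond distance stays
    below ``cutoff``, moving each atom rigidly with its residue's Cα.

    Stores per-frame distances and the persistence on the bond.
    """
    n = trajectory.n_beads
    for b in (bond.donor_bead, bond.acceptor_bead):
        if not 0 <= b < n:
            raise HBondError(f"bead {b} missing from trajectory of {n} beads")
    ref = trajectory.reference
    disp_d = trajectory.frames[:, bond.donor_bead, :] - ref[bond.donor_bead]
    disp_a = trajectory.frames[:, bond.acceptor_bead, :] - ref[bond.acceptor_bead]
    vec = (bond.donor_coord + disp_d) - (bond.acceptor_coord + disp_a)
    dists = np.linalg.norm(vec, axis=1)
    bond.frame_distances = dists
    bond.persistence = float(np.count_nonzero(dists < cutoff) / dists.shape[0])
    return bond.persistence


def hbond_table(bonds: list[HBond]) -> pd.DataFrame:
    """Bond list as a flat table (donor, acceptor, distance, persistence)."""
    return pd.DataFrame(
        {
            "donor_residue": [b.donor_residue for b in bonds],
            "donor_atom": [b.donor_atom for b in bonds],
            "acceptor_residue": [b.acceptor_residue for b in bonds],
            "acceptor_atom": [b.acceptor_atom for b in bonds],
            "distance": [b.distance for b in bonds],
            "persistence": [b.persistence for b in bonds],
        }
    )
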
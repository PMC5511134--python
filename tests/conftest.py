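"""Shared fixtures: small structures and solved mode sets.

Expensive eigendecompositions are session-scoped; tests must not mutate
the shared models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from hingescan import (
    CalphaModel,
    ModeSet,
    build_force_constants,
    build_hessian,
    compute_modes,
    extract_calpha,
)
from hingescan.structure import Structure
from hingescan.synthetic import (
    TwoDomainStandIn,
    make_dumbbell,
    make_helix,
    make_random_cloud,
    make_two_domain_inhibitor,
)


@dataclass
class Solved:
    structure: Structure
    model: CalphaModel
    modes: ModeSet
    linker: tuple[int, int] | None = None
    standin: TwoDomainStandIn | None = None


def solve(structure: Structure) -> tuple[CalphaModel, ModeSet]:
    model = extract_calpha(structure)
    build_force_constants(model)
    return model, compute_modes(build_hessian(model))


@pytest.fixture(scope="session")
def helix_solved() -> Solved:
    s = make_helix(30)
    return Solved(s, *solve(s))


@pytest.fixture(scope="session")
def dumbbell_solved() -> Solved:
    s, linker = make_dumbbell(30, 4, seed=1)
    model, modes = solve(s)
    return Solved(s, model, modes, linker=linker)


@pytest.fixture(scope="session")
def standin_solved() -> Solved:
    tw = make_two_domain_inhibitor(seed=0)
    model, modes = solve(tw.structure)
    return Solved(tw.structure, model, modes, linker=tw.linker_span, standin=tw)


@pytest.fixture(scope="session")
def cloud_model() -> CalphaModel:
    model = extract_calpha(make_random_cloud(10, seed=3))
    build_force_constants(model)
    return model


def bare_model(coords, resnums=None, chain="A", disulfides=(), helix_id=None, sheet=None):
    """Minimal CalphaModel straight from coordinates (unit tests)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    resnums = np.asarray(resnums if resnums is not None else np.arange(1, n + 1))
    return CalphaModel(
        coords=coords,
        resnums=resnums,
        resnames=["ALA"] * n,
        labels=[f"A{r}" for r in resnums],
        chain_ids=np.asarray([chain] * n),
        helix_id=np.asarray(helix_id if helix_id is not None else -np.ones(n, dtype=int)),
        sheet=np.asarray(sheet if sheet is not None else np.zeros(n, dtype=bool)),
        disulfides=list(disulfides),
    )


# minimal hand-written PDB with strict fixed columns
def pdb_atom_line(serial, name, resname, chain, resnum, xyz, occ=1.0, altloc=" ",
                  element=None, icode=" "):
    element = element or name[0]
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:3s} {chain}{resnum:4d}{icode}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}  0.00          {element:>2s}"
    )


def minimal_pdb_text(n_residues=3, ssbond=False):
    lines = []
    if ssbond:
        lines.append(f"SSBOND   1 CYS A {1:4d}    CYS A {n_residues:4d}")
    serial = 1
    for i in range(n_residues):
        resname = "CYS" if ssbond and i in (0, n_residues - 1) else "ALA"
        for name, off in [("N", (-1.2, 0.3, 0.0)), ("CA", (0.0, 0.0, 0.0)),
                          ("C", (1.2, 0.4, 0.0)), ("O", (1.5, 1.5, 0.2))]:
            xyz = (off[0] + 3.8 * i, off[1] + 0.9 * (i % 2), off[2] + 0.5 * i)
            lines.append(pdb_atom_line(serial, name, resname, "A", i + 1, xyz))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
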
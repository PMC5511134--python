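"""Cα elastic-network model: force constants, Hessian, normal modes.

The network couples Cα beads with harmonic springs whose stiffness
depends on sequence separation, distance, secondary structure and
disulfide bonding:

* chain neighbours (|i-j| = 1): a stiff virtual bond ``k_bond``;
* helix 1-4 contacts (2 <= |i-j| <= 4 inside one helix span) and beta
  bridges (sheet beads within ``r_bridge``): the distance-dependent
  constant scaled by ``gamma_sse`` — the "stronger beta bridges and
  helix 1-4 interactions" of Cα-level force fields;
* disulfide-bridged pairs: a fixed ``k_ss`` regardless of distance;
* every other pair within ``r_cut``: ``c / r**6``.

Normal modes are the eigenpairs of the 3N x 3N Hessian; for a connected
model in generic position exactly six eigenvalues vanish (rigid-body
translation and rotation) and the first non-rigid mode is, in the 1-based
numbering over all modes used throughout, "mode 7".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "ForceFieldParams",
    "CalphaModel",
    "ModeSet",
    "EnmError",
    "build_force_constants",
    "build_hessian",
    "compute_modes",
]


class EnmError(ValueError):
    """Raised for ill-posed network construction or mode requests."""


@dataclass(frozen=True)
class ForceFieldParams:
    """Spring-constant parameters (energy/Å² in arbitrary consistent units).

    ``k_bond``
        virtual Cα-Cα bond between chain neighbours.
    ``gamma_sse``
        multiplier applied to the distance term for helix 1-4 contacts
        and beta bridges.
    ``c``
        prefactor of the non-bonded ``c / r**6`` distance dependence.
    ``k_ss``
        disulfide-bridge constant, distance independent.
    ``r_cut``
        non-bonded interaction cutoff (Å).
    ``r_bridge``
        maximum Cα-Cα distance for a beta bridge (Å).
    """

    k_bond: float = 1000.0
    gamma_sse: float = 5.0
    c: float = 1.0e4
    k_ss: float = 500.0
    r_cut: float = 15.0
    r_bridge: float = 5.5

    def __post_init__(self):
        for name, value in asdict(self).items():
            if not (value > 0):
                raise EnmError(f"force-field parameter {name} must be > 0, got {value}")


@dataclass
class CalphaModel:
    """One bead per residue with pairwise force constants.

    ``helix_id`` is -1 outside helices and a shared span index inside, so
    the helix 1-4 rule applies only within one span; ``sheet`` flags sheet
    membership; ``disulfides`` are bead-index pairs.  ``k`` is the dense
    symmetric N x N force-constant matrix filled in by
    :func:`build_force_constants`.
    """

    coords: np.ndarray
    resnums: np.ndarray
    resnames: list[str]
    labels: list[str]
    chain_ids: np.ndarray
    helix_id: np.ndarray
    sheet: np.ndarray
    disulfides: list[tuple[int, int]] = field(default_factory=list)
    k: np.ndarray | None = None
    params: ForceFieldParams | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise EnmError("coords must be (N, 3)")
        for i, j in self.disulfides:
            if i == j:
                raise EnmError(f"disulfide pair ({i}, {j}) references one bead")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def in_sse(self) -> np.ndarray:
        """Boolean mask of beads inside any helix or sheet span."""
        return (self.helix_id >= 0) | self.sheet


@dataclass
class ModeSet:
    """Eigenpairs of the ENM Hessian.

    ``eigenvalues`` ascending; ``eigenvectors`` has unit-norm columns of
    length 3N.  Mode indices are 1-based over all modes so that the first
    non-rigid mode of a generic structure is mode 7.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    rigid: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def n_beads(self) -> int:
        return self.eigenvectors.shape[0] // 3

    @property
    def n_rigid(self) -> int:
        return int(np.count_nonzero(self.rigid))

    @property
    def first_nonrigid(self) -> int:
        """1-based index of the lowest-frequency internal mode."""
        idx = np.flatnonzero(~self.rigid)
        if idx.size == 0:
            raise EnmError("no non-rigid modes")
        return int(idx[0]) + 1

    def eigenvalue(self, mode_index: int) -> float:
        return float(self.eigenvalues[self._check(mode_index)])

    def eigenvector(self, mode_index: int) -> np.ndarray:
        return self.eigenvectors[:, self._check(mode_index)]

    def is_rigid(self, mode_index: int) -> bool:
        return bool(self.rigid[self._check(mode_index)])

    def displacement(self, mode_index: int) -> np.ndarray:
        """Eigenvector reshaped to per-bead (N, 3) displacements."""
        return self.eigenvector(mode_index).reshape(-1, 3)

    def frequency(self, mode_index: int) -> float:
        """sqrt(eigenvalue) in model units (uniform unit masses)."""
        return float(np.sqrt(max(self.eigenvalue(mode_index), 0.0)))

    def _check(self, mode_index: int) -> int:
        if not 1 <= mode_index <= self.n_modes:
            raise EnmError(
                f"mode index {mode_index} outside 1..{self.n_modes} (1-based)"
            )
        return mode_index - 1


def build_force_constants(
    model: CalphaModel, params: ForceFieldParams | None = None
) -> np.ndarray:
    """Fill the pairwise spring-constant matrix of ``model``.

    Rule precedence (highest wins): chain bond, disulfide, secondary
    structure (helix 1-4 / beta bridge), plain distance term.  The
    resulting network must be connected, otherwise the mode problem is
    ill-posed and an error names the fragments.
    """
    params = params or ForceFieldParams()
    n = model.n_beads
    if n < 2:
        raise EnmError("need at least 2 beads")
    r = squareform(pdist(model.coords))
    with np.errstate(divide="ignore"):
        base = np.where(r > 0, params.c / np.maximum(r, 1e-12) ** 6, 0.0)

    k = np.where(r <= params.r_cut, base, 0.0)

    seq_sep = np.abs(np.subtract.outer(model.resnums, model.resnums))
    same_chain = np.equal.outer(model.chain_ids, model.chain_ids)

    # helix 1-4: both beads in the same helix span, short sequence separation
    in_helix = model.helix_id >= 0
    same_helix = np.equal.outer(model.helix_id, model.helix_id) & np.outer(in_helix, in_helix)
    helix_mask = same_helix & (seq_sep >= 2) & (seq_sep <= 4)
    # beta bridge: sheet beads in spatial contact
    bridge_mask = np.outer(model.sheet, model.sheet) & (r <= params.r_bridge) & (seq_sep >= 2)
    k = np.where(helix_mask | bridge_mask, params.gamma_sse * base, k)

    for i, j in model.disulfides:
        k[i, j] = k[j, i] = params.k_ss

    bond_mask = same_chain & (seq_sep == 1)
    k = np.where(bond_mask, params.k_bond, k)

    np.fill_diagonal(k, 0.0)
    k = 0.5 * (k + k.T)

    n_comp, labels = connected_components(csr_matrix(k > 0), directed=False)
    if n_comp > 1:
        parts = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise EnmError(
            f"elastic network is disconnected ({n_comp} components): "
            + "; ".join(str(p[:8]) + ("..." if len(p) > 8 else "") for p in parts)
        )

    model.k = k
    model.params = params
    return k


def build_hessian(model: CalphaModel) -> np.ndarray:
    """Assemble the 3N x 3N ENM Hessian from the force-constant matrix.

    Off-diagonal 3x3 block for pair (i, j): ``-k_ij * r_hat r_hat^T``;
    diagonal blocks accumulate the negatives so each block row sums to
    zero (translation invariance).
    """
    if model.k is None:
        build_force_constants(model)
    k = model.k
    x = model.coords
    n = model.n_beads
    h = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(k, 1))
    for i, j in zip(ii, jj):
        d = x[j] - x[i]
        rij = np.linalg.norm(d)
        if rij < 1e-6:
            raise EnmError(f"coincident beads {i} and {j} (r = {rij:.2e} Å)")
        u = d / rij
        block = k[i, j] * np.outer(u, u)
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= block
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] -= block
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] += block
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] += block
    return h


def compute_modes(hessian: np.ndarray, zero_tol: float = 1e-12) -> ModeSet:
    """Full eigendecomposition of the Hessian with rigid-mode flagging.

    Modes with eigenvalue below ``zero_tol`` relative to the largest are
    flagged rigid (null frequency).  Eigenvector signs are fixed so the
    largest-magnitude component is positive, making the decomposition
    deterministic up to degeneracies.
    """
    hessian = np.asarray(hessian, dtype=float)
    if not np.allclose(hessian, hessian.T, atol=1e-8):
        raise EnmError("hessian is not symmetric")
    evals, evecs = scipy.linalg.eigh(hessian)
    lam_max = float(np.max(np.abs(evals))) if evals.size else 0.0
    rigid = np.abs(evals) < zero_tol * max(lam_max, 1e-300)
    if np.count_nonzero(rigid) > 6:
        warnings.warn(
            f"{np.count_nonzero(rigid)} near-null modes (> 6): degenerate "
            "geometry or disconnected network",
            RuntimeWarning,
            stacklevel=2,
        )
    for m in range(evecs.shape[1]):
        j = int(np.argmax(np.abs(evecs[:, m])))
        if evecs[j, m] < 0:
            evecs[:, m] = -evecs[:, m]
    return ModeSet(eigenvalues=evals, eigenvectors=evecs, rigid=rigid)
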
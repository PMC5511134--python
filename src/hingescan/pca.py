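"""Trajectory superposition and principal component analysis.

Frames are least-squares fitted (rotation + translation, Kabsch SVD)
onto a reference frame, then the 3N-dimensional coordinate covariance
about the trajectory mean is diagonalized.  The top components capture
the dominant collective motions; the squared per-residue norm of a unit
component vector gives each residue's contribution to the overall
displacement of that component (summing to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enm import CalphaModel
from .profiles import ResidueProfile, Trajectory

__all__ = ["PCAResult", "PcaError", "superpose", "pca", "residue_contribution"]


class PcaError(ValueError):
    pass


def _kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rigid-body fit of ``mobile`` onto ``target`` (both (N, 3))."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    p, q = mobile - mc, target - tc
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1e-300):
        raise PcaError("degenerate (collinear) frame: rotation underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return p @ rot.T + tc


def superpose(trajectory: Trajectory, reference_index: int | None = None) -> Trajectory:
    """Rigid-body fit every frame onto the reference frame.

    Returns a new aligned trajectory; each frame's RMSD to the reference
    is minimal over rotations and translations.
    """
    if trajectory.n_frames < 1:
        raise PcaError("empty trajectory")
    if trajectory.n_beads < 3:
        raise PcaError("need at least 3 beads to superpose")
    ref_idx = trajectory.reference_index if reference_index is None else reference_index
    ref = trajectory.frames[ref_idx]
    fitted = np.empty_like(trajectory.frames)
    for f in range(trajectory.n_frames):
        fitted[f] = _kabsch_fit(trajectory.frames[f], ref)
    return Trajectory(
        frames=fitted, phases=trajectory.phases, reference_index=ref_idx, aligned=True
    )


@dataclass
class PCAResult:
    """Eigenpairs of the superposed-coordinate covariance.

    ``eigenvalues`` (Å², descending) and unit ``components`` (rows,
    length 3N); ``total_variance`` is the trace of the covariance.
    """

    eigenvalues: np.ndarray
    components: np.ndarray
    total_variance: float
    reference_index: int
    n_retained: int = 3

    @property
    def n_beads(self) -> int:
        return self.components.shape[1] // 3

    def component(self, pc_index: int) -> np.ndarray:
        if not 1 <= pc_index <= self.components.shape[0]:
            raise PcaError(
                f"PC index {pc_index} outside 1..{self.components.shape[0]}"
            )
        return self.components[pc_index - 1]


def pca(trajectory: Trajectory, n_retained: int = 3) -> PCAResult:
    """Diagonalize the coordinate covariance of an aligned trajectory.

    Covariance is taken about the trajectory mean (the reference frame
    only defines the fit); the eigenvalue sum equals the total coordinate
    variance.  Component signs are fixed (largest-magnitude entry
    positive) for determinism.
    """
    if not trajectory.aligned:
        raise PcaError("trajectory must be superposed first (aligned flag unset)")
    f = trajectory.n_frames
    if f < 2:
        raise PcaError("PCA needs at least 2 frames")
    x = trajectory.frames.reshape(f, -1)
    xc = x - x.mean(axis=0)
    # SVD route: eigenvalues of cov = X^T X / (F-1) without forming 3N x 3N
    _, svals, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = svals**2 / (f - 1)
    components = vt
    for m in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[m])))
        if components[m, j] < 0:
            components[m] = -components[m]
    total_variance = float(np.sum(xc * xc) / (f - 1))
    return PCAResult(
        eigenvalues=eigenvalues,
        components=components,
        total_variance=total_variance,
        reference_index=trajectory.reference_index,
        n_retained=min(n_retained, components.shape[0]),
    )


def residue_contribution(
    result: PCAResult, pc_index: int, model: CalphaModel | None = None
) -> ResidueProfile:
    """Per-residue share of one principal component's displacement.

    contribution_i = |v_i|² for the unit component vector v, so the
    profile is non-negative and sums to 1.
    """
    v = result.component(pc_index).reshape(-1, 3)
    values = np.sum(v * v, axis=1)
    labels = list(model.labels) if model is not None else []
    resnums = model.resnums if model is not None else None
    return ResidueProfile(
        values=values, labels=labels, resnums=resnums,
        units="fraction", provenance=f"PC {pc_index}",
    )
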
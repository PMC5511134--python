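"""Per-mode, per-residue descriptors and mode-interpolated trajectories.

For a unit-norm eigenvector e of the ENM Hessian with eigenvalue λ:

* Cα fluctuation  f_i = |e_i|² / λ   (mean-squared displacement share,
  so Σ f_i = 1/λ and summing over all internal modes reproduces the
  diagonal of the Hessian pseudo-inverse);
* deformation energy  d_i = ½ Σ_j ½ k_ij (r̂_ij · (e_i − e_j))², the
  axis-projected pair energy split evenly between the two beads, so
  Σ d_i = λ/2 at unit mode amplitude;
* collectivity  κ = exp(−Σ p_i ln p_i)/N with p_i ∝ |e_i|², an
  entropy-based participation measure in (0, 1].

High deformation energy marks residues that are locally strained by a
mode while low fluctuation marks residues that barely move in space —
jointly, the signature of a hinge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .enm import CalphaModel, EnmError, ModeSet

__all__ = [
    "ResidueProfile",
    "Trajectory",
    "mode_fluctuation",
    "deformation_energy",
    "collectivity",
    "mode_trajectory",
]


@dataclass
class ResidueProfile:
    """A per-residue scalar track with its normalization state."""

    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    resnums: np.ndarray | None = None
    units: str = ""
    normalization: str = "raw"  # "raw" | "minmax"
    provenance: str = ""
    rigid_mode: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.labels and len(self.labels) != self.values.shape[0]:
            raise ValueError("labels and values length mismatch")
        if self.normalization == "minmax" and self.values.size:
            if not (abs(self.values.min()) < 1e-12 and abs(self.values.max() - 1) < 1e-12):
                raise ValueError("minmax profile must span [0, 1]")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class Trajectory:
    """Frames of a Cα trajectory, (F, N, 3) in Å."""

    frames: np.ndarray
    phases: np.ndarray | None = None
    reference_index: int = 0
    aligned: bool = False

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (F, N, 3)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite trajectory coordinates")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    @property
    def reference(self) -> np.ndarray:
        return self.frames[self.reference_index]


def _labels(model: CalphaModel | None, n: int):
    if model is None:
        return [], None
    if model.n_beads != n:
        raise EnmError("model bead count does not match mode length")
    return list(model.labels), model.resnums


def _require_nonrigid(modes: ModeSet, mode_index: int) -> None:
    if modes.is_rigid(mode_index):
        raise EnmError(
            f"mode {mode_index} is a rigid-body (null frequency) mode"
        )


def mode_fluctuation(
    modes: ModeSet, mode_index: int, model: CalphaModel | None = None
) -> ResidueProfile:
    """Per-residue squared displacement amplitude of one internal mode."""
    _require_nonrigid(modes, mode_index)
    e = modes.displacement(mode_index)
    lam = modes.eigenvalue(mode_index)
    values = np.sum(e * e, axis=1) / lam
    labels, resnums = _labels(model, e.shape[0])
    return ResidueProfile(
        values=values, labels=labels, resnums=resnums, units="Å²",
        provenance=f"mode {mode_index}",
    )


def deformation_energy(
    model: CalphaModel, modes: ModeSet, mode_index: int
) -> ResidueProfile:
    """Per-residue share of the elastic energy stored along one mode.

    Each spring's axis-projected harmonic energy is split evenly between
    its two beads; the profile totals λ/2 for a unit-amplitude mode.  A
    rigid mode yields an all-zero profile flagged ``rigid_mode`` rather
    than an error.
    """
    if model.k is None:
        raise EnmError("model has no force constants; run build_force_constants")
    u = modes.displacement(mode_index)
    labels, resnums = _labels(model, u.shape[0])
    prof = ResidueProfile(
        values=np.zeros(u.shape[0]), labels=labels, resnums=resnums,
        units="energy", provenance=f"mode {mode_index}",
        rigid_mode=modes.is_rigid(mode_index),
    )
    x = model.coords
    ii, jj = np.nonzero(np.triu(model.k, 1))
    d = x[jj] - x[ii]
    rhat = d / np.linalg.norm(d, axis=1, keepdims=True)
    proj = np.einsum("pk,pk->p", rhat, u[ii] - u[jj])
    pair_e = 0.5 * model.k[ii, jj] * proj**2
    np.add.at(prof.values, ii, 0.5 * pair_e)
    np.add.at(prof.values, jj, 0.5 * pair_e)
    return prof


def collectivity(modes: ModeSet, mode_index: int) -> float:
    """Entropy-based participation degree of a mode, in (1/N, 1].

    1 for a perfectly uniform mode, 1/N for a mode localized on a single
    bead; high collectivity marks global interdomain motions.
    """
    _require_nonrigid(modes, mode_index)
    f = np.sum(modes.displacement(mode_index) ** 2, axis=1)
    p = f / f.sum()
    nz = p[p > 0]
    entropy = -np.sum(nz * np.log(nz))
    return float(np.exp(entropy) / p.shape[0])


def mode_trajectory(
    model: CalphaModel,
    modes: ModeSet,
    mode_index: int,
    amplitude: float | None = None,
    n_frames: int = 21,
    rmsd_target: float = 2.0,
) -> Trajectory:
    """Sinusoidal interpolation of the structure along one mode.

    Frames follow x(φ) = x⁰ + A sin(φ) e over one full period; frame 0 is
    exactly the reference.  ``amplitude`` is the modal amplitude A in
    Å·√N; if omitted it is calibrated so the maximum Cα RMSD from the
    reference equals ``rmsd_target`` (default 2.0 Å).  With the default
    frame count the quarter-period frames hit sin φ = ±1 exactly, so the
    measured maximum RMSD equals A/√N.
    """
    _require_nonrigid(modes, mode_index)
    if n_frames < 3:
        raise EnmError("n_frames must be >= 3")
    n = modes.n_beads
    if amplitude is None:
        amplitude = rmsd_target * np.sqrt(n)
    if amplitude < 0:
        raise EnmError("amplitude must be >= 0")
    if model.n_beads != n:
        raise EnmError("model bead count does not match mode length")
    e = modes.displacement(mode_index)
    phases = np.linspace(0.0, 2.0 * np.pi, n_frames)
    frames = model.coords[None, :, :] + amplitude * np.sin(phases)[:, None, None] * e[None, :, :]
    frames[0] = model.coords  # phase 0: exact reference, no rounding
    return Trajectory(frames=frames, phases=phases, reference_index=0, aligned=False)


def normalize_minmax(profile: ResidueProfile) -> ResidueProfile:
    """Min-max rescale a raw profile to [0, 1] (monotone, idempotent-safe).

    Defined here for reuse; the hinge module re-exports it as
    ``normalize_profile``.
    """
    if len(profile) < 2:
        raise EnmError("normalization needs at least two residues")
    lo, hi = float(profile.values.min()), float(profile.values.max())
    if hi - lo == 0:
        raise EnmError("constant profile: min-max normalization undefined")
    values = (profile.values - lo) / (hi - lo)
    return replace(profile, values=values, normalization="minmax", units="")
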
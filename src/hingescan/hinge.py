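"""Hinge-region calling from superposed normal-mode profiles.

A residue belongs to a hinge when the mode that dominates interdomain
motion strains it strongly (high normalized deformation energy) while
barely displacing it in space (low normalized fluctuation).  Qualifying
residues are merged into contiguous regions, and residues inside helix
or sheet spans are excluded from mutational candidacy, since mutating
folded secondary structure risks misfolding rather than altered
dynamics.  The combined score S_i = def_i · (1 − fluct_i) ranks residues
independently of the thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enm import CalphaModel, EnmError, ModeSet
from .profiles import (
    ResidueProfile,
    deformation_energy,
    mode_fluctuation,
    normalize_minmax,
)

__all__ = [
    "HingeReport",
    "normalize_profile",
    "find_hinge_regions",
    "exclude_secondary_structure",
    "hinge_report",
]

normalize_profile = normalize_minmax


def _check_pair(def_norm: ResidueProfile, fluct_norm: ResidueProfile) -> int:
    if len(def_norm) != len(fluct_norm):
        raise EnmError(
            f"profile length mismatch: {len(def_norm)} vs {len(fluct_norm)}"
        )
    for p in (def_norm, fluct_norm):
        if p.normalization != "minmax":
            raise EnmError("profiles must be min-max normalized first")
    return len(def_norm)


def find_hinge_regions(
    def_norm: ResidueProfile,
    fluct_norm: ResidueProfile,
    tau_def: float = 0.4,
    tau_fluct: float = 0.25,
    max_gap: int = 1,
) -> list[tuple[int, int]]:
    """Call contiguous hinge regions on superposed normalized profiles.

    Residue i qualifies iff def_norm_i >= tau_def and fluct_norm_i <=
    tau_fluct.  Runs of qualifying residues separated by at most
    ``max_gap`` non-qualifying residues are merged.  Returns inclusive
    (start, end) bead-index spans in sequence order.
    """
    n = _check_pair(def_norm, fluct_norm)
    qualifying = np.flatnonzero(
        (def_norm.values >= tau_def) & (fluct_norm.values <= tau_fluct)
    )
    regions: list[tuple[int, int]] = []
    for idx in qualifying:
        if regions and idx - regions[-1][1] <= max_gap + 1:
            regions[-1] = (regions[-1][0], int(idx))
        else:
            regions.append((int(idx), int(idx)))
    assert all(0 <= a <= b < n for a, b in regions)
    return regions


def exclude_secondary_structure(
    regions: list[tuple[int, int]], model: CalphaModel
) -> tuple[list[int], list[tuple[int, int]]]:
    """Drop region residues that sit inside helix or sheet spans.

    Returns (candidate bead indices, regions entirely removed by the
    exclusion) — the latter are detected hinges that offer no safely
    mutable residue.
    """
    in_sse = model.in_sse()
    candidates: list[int] = []
    emptied: list[tuple[int, int]] = []
    for a, b in regions:
        kept = [i for i in range(a, b + 1) if not in_sse[i]]
        candidates.extend(kept)
        if not kept:
            emptied.append((a, b))
    return candidates, emptied


@dataclass
class HingeReport:
    """Full result of a single-mode hinge analysis."""

    mode_index: int
    def_norm: ResidueProfile
    fluct_norm: ResidueProfile
    regions: list[tuple[int, int]]
    region_labels: list[tuple[str, str]]
    excluded_residues: list[str]
    candidate_residues: list[str]
    emptied_regions: list[tuple[str, str]]
    thresholds: dict = field(default_factory=dict)
    scores: np.ndarray | None = None
    candidate_indices: list[int] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def to_dict(self) -> dict:
        return {
            "mode_index": self.mode_index,
            "thresholds": self.thresholds,
            "n_regions": self.n_regions,
            "regions": [list(r) for r in self.region_labels],
            "excluded_residues": self.excluded_residues,
            "candidate_residues": self.candidate_residues,
            "emptied_regions": [list(r) for r in self.emptied_regions],
            "score_ranking": [
                {"residue": lab, "score": round(float(s), 10)}
                for lab, s in sorted(
                    zip(self.def_norm.labels, self.scores),
                    key=lambda t: (-t[1], t[0]),
                )[:25]
            ]
            if self.scores is not None and self.def_norm.labels
            else [],
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_table(self, model: CalphaModel) -> pd.DataFrame:
        """Per-residue table: tracks, score and all call flags."""
        n = len(self.def_norm)
        in_region = np.zeros(n, dtype=bool)
        for a, b in self.regions:
            in_region[a:b + 1] = True
        in_sse = model.in_sse()
        candidate = np.zeros(n, dtype=bool)
        cand_set = set(self.candidate_residues)
        for i, lab in enumerate(model.labels):
            candidate[i] = lab in cand_set
        return pd.DataFrame(
            {
                "residue": model.labels,
                "def_norm": self.def_norm.values,
                "fluct_norm": self.fluct_norm.values,
                "score": self.scores,
                "qualifying": (self.def_norm.values >= self.thresholds["tau_def"])
                & (self.fluct_norm.values <= self.thresholds["tau_fluct"]),
                "in_region": in_region,
                "in_sse": in_sse,
                "candidate": candidate,
            }
        )


def hinge_report(
    model: CalphaModel,
    modes: ModeSet,
    mode_index: int | None = None,
    tau_def: float = 0.4,
    tau_fluct: float = 0.25,
    max_gap: int = 1,
) -> HingeReport:
    """Run the full hinge analysis for one mode (default: first non-rigid).

    Computes deformation-energy and fluctuation profiles, min-max
    normalizes and superposes them, calls regions, applies the
    secondary-structure exclusion, and records thresholds and the
    threshold-free score ranking.
    """
    if mode_index is None:
        mode_index = modes.first_nonrigid
    def_raw = deformation_energy(model, modes, mode_index)
    if def_raw.rigid_mode:
        raise EnmError(f"mode {mode_index} is rigid: hinge analysis undefined")
    fluct_raw = mode_fluctuation(modes, mode_index, model)
    def_norm = normalize_profile(def_raw)
    fluct_norm = normalize_profile(fluct_raw)
    regions = find_hinge_regions(def_norm, fluct_norm, tau_def, tau_fluct, max_gap)
    cand_idx, emptied = exclude_secondary_structure(regions, model)

    in_region = set()
    for a, b in regions:
        in_region.update(range(a, b + 1))
    excluded = sorted(
        (i for i in in_region if model.in_sse()[i])
    )
    scores = def_norm.values * (1.0 - fluct_norm.values)
    return HingeReport(
        mode_index=mode_index,
        def_norm=def_norm,
        fluct_norm=fluct_norm,
        regions=regions,
        region_labels=[(model.labels[a], model.labels[b]) for a, b in regions],
        excluded_residues=[model.labels[i] for i in excluded],
        candidate_residues=[model.labels[i] for i in cand_idx],
        emptied_regions=[(model.labels[a], model.labels[b]) for a, b in emptied],
        thresholds={
            "tau_def": tau_def,
            "tau_fluct": tau_fluct,
            "max_gap": max_gap,
        },
        scores=scores,
        candidate_indices=list(cand_idx),
    )
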
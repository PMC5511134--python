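"""PDB input/output and Cα coarse-graining.

Reads crystallographic structures into a light domain model keeping only
protein heavy atoms, secondary-structure spans (HELIX/SHEET records),
disulfide bridges (SSBOND records) and occupancy-resolved alternate
locations.  The Cα trace extracted here is the bead model on which the
elastic-network mode analysis runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .enm import CalphaModel

__all__ = [
    "SseSpan",
    "Structure",
    "NumberingMap",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "read_sse_table",
    "extract_calpha",
    "write_trajectory_pdb",
    "read_trajectory_frames",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(ValueError):
    """Raised for unreadable or inconsistent structural input."""


@dataclass(frozen=True)
class SseSpan:
    """A helix or sheet span, 1-based inclusive residue numbers."""

    kind: str  # "helix" or "sheet"
    chain: str
    first: int
    last: int

    def __post_init__(self):
        if self.kind not in ("helix", "sheet"):
            raise StructureError(f"unknown SSE kind {self.kind!r}")
        if self.last < self.first:
            raise StructureError(f"SSE span {self.first}-{self.last} reversed")


@dataclass
class Structure:
    """Protein heavy atoms plus the annotations the pipeline consumes.

    ``atoms`` is a biotite ``AtomArray`` (occupancy annotated, altlocs
    already resolved).  ``disulfides`` holds ``((chain, resnum), (chain,
    resnum))`` pairs.
    """

    atoms: struc.AtomArray
    sse_spans: list[SseSpan] = field(default_factory=list)
    disulfides: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        if not np.all(np.isfinite(self.atoms.coord)):
            raise StructureError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, resnum, insertion code) keys."""
        seen, keys = set(), []
        a = self.atoms
        for c, r, i in zip(a.chain_id, a.res_id, a.ins_code):
            k = (str(c), int(r), str(i))
            if k not in seen:
                seen.add(k)
                keys.append(k)
        return keys


@dataclass
class NumberingMap:
    """Maps deposited residue numbers to mature-protein numbering.

    ``offset`` is added to every residue number of ``chain`` (``None``
    means all chains); residues with insertion codes must be mapped
    through explicit ``overrides`` keyed by ``(resnum, icode)``.
    """

    chain: str | None = None
    offset: int = 0
    overrides: dict[tuple[int, str], int] = field(default_factory=dict)

    def apply(self, chain: str, resnum: int, icode: str = "") -> int:
        if self.chain is not None and chain != self.chain:
            return resnum
        if icode.strip():
            key = (resnum, icode)
            if key not in self.overrides:
                raise StructureError(
                    f"residue {resnum}{icode} carries an insertion code but no "
                    f"numbering override"
                )
            return self.overrides[key]
        return self.overrides.get((resnum, ""), resnum + self.offset)


def _parse_header_records(lines, chains: set[str]):
    """Pull SSE spans and disulfide pairs out of raw PDB records."""
    spans: list[SseSpan] = []
    bridges: list[tuple[tuple[str, int], tuple[str, int]]] = []
    for line in lines:
        rec = line[:6]
        try:
            if rec == "HELIX ":
                c1, r1 = line[19].strip(), int(line[21:25])
                c2, r2 = line[31].strip(), int(line[33:37])
                if c1 == c2 and (not chains or c1 in chains):
                    spans.append(SseSpan("helix", c1, r1, r2))
            elif rec == "SHEET ":
                c1, r1 = line[21].strip(), int(line[22:26])
                c2, r2 = line[32].strip(), int(line[33:37])
                if c1 == c2 and (not chains or c1 in chains):
                    spans.append(SseSpan("sheet", c1, r1, r2))
            elif rec == "SSBOND":
                c1, r1 = line[15].strip(), int(line[17:21])
                c2, r2 = line[29].strip(), int(line[31:35])
                if not chains or (c1 in chains and c2 in chains):
                    bridges.append(((c1, r1), (c2, r2)))
        except (ValueError, IndexError) as exc:
            raise StructureError(f"malformed {rec.strip()} record: {line!r}") from exc
    return spans, bridges


def read_pdb(path: str | os.PathLike, chain: str | None = None) -> Structure:
    """Read a PDB file, keeping protein heavy atoms of the selected chain(s).

    Altloc duplicates are resolved by highest occupancy (file order breaks
    ties); hydrogens, waters and all other HETATM records are dropped.
    HELIX/SHEET records populate ``sse_spans`` and SSBOND records the
    disulfide list, restricted to the residues actually present.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise StructureError(f"no such PDB file: {path}")
    pdb_file = pdbio.PDBFile.read(path)
    try:
        atoms = pdbio.get_structure(
            pdb_file, model=1, altloc="occupancy", extra_fields=["occupancy"]
        )
    except Exception as exc:
        raise StructureError(f"cannot parse ATOM records in {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise StructureError(f"no ATOM records in {path}")

    mask = (~atoms.hetero) & (atoms.element != "H") & (atoms.element != "D")
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise StructureError(f"no protein heavy atoms in {path}")
    if chain is not None:
        present = set(np.unique(atoms.chain_id))
        if chain not in present:
            raise StructureError(
                f"chain {chain!r} not found in {path}; available: {sorted(present)}"
            )
        atoms = atoms[atoms.chain_id == chain]

    chains = set(str(c) for c in np.unique(atoms.chain_id))
    spans, bridges = _parse_header_records(pdb_file.lines, chains)

    # drop annotations referencing residues that are not in the atom set
    present = {(str(c), int(r)) for c, r in zip(atoms.chain_id, atoms.res_id)}
    spans = [
        s for s in spans
        if any((s.chain, r) in present for r in range(s.first, s.last + 1))
    ]
    bridges = [b for b in bridges if b[0] in present and b[1] in present and b[0] != b[1]]

    return Structure(atoms=atoms, sse_spans=spans, disulfides=bridges, source=path)


def _format_header_lines(structure: Structure) -> list[str]:
    lines = []
    for i, s in enumerate(structure.sse_spans, start=1):
        if s.kind == "helix":
            lines.append(
                f"HELIX  {i:3d} {i:3d} ALA {s.chain:1s} {s.first:4d}  "
                f"ALA {s.chain:1s} {s.last:4d}  1{'':30s}{s.last - s.first + 1:5d}"
            )
        else:
            lines.append(
                f"SHEET  {i:3d}   S 1 ALA {s.chain:1s}{s.first:4d}  "
                f"ALA {s.chain:1s}{s.last:4d}  0"
            )
    for i, ((c1, r1), (c2, r2)) in enumerate(structure.disulfides, start=1):
        lines.append(
            f"SSBOND {i:3d} CYS {c1:1s} {r1:4d}    CYS {c2:1s} {r2:4d}"
        )
    return lines


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    """Write the structure with HELIX/SHEET/SSBOND records so that
    ``read_pdb`` round-trips annotations as well as coordinates."""
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(structure.atoms)
    pdb_file.lines = _format_header_lines(structure) + pdb_file.lines
    pdb_file.write(os.fspath(path))


def read_sse_table(path: str | os.PathLike) -> list[SseSpan]:
    """Read an external secondary-structure override table.

    Whitespace/tab-delimited, four columns: chain, first residue, last
    residue (1-based inclusive), kind (helix|sheet).  Lines starting with
    ``#`` are ignored.
    """
    spans = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise StructureError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            chain, first, last, kind = parts
            try:
                spans.append(SseSpan(kind.lower(), chain, int(first), int(last)))
            except ValueError as exc:
                raise StructureError(f"{path}:{ln}: {exc}") from exc
    return spans


def extract_calpha(
    structure: Structure, numbering: NumberingMap | None = None
) -> CalphaModel:
    """Collapse the structure to one Cα bead per residue.

    Beads are ordered by chain then (residue number, insertion code) and
    labelled in mature-protein numbering via ``numbering``.  Disulfide
    pairs are re-expressed as bead index pairs, and per-bead secondary
    structure membership is recorded for the force-field rules.
    """
    numbering = numbering or NumberingMap()
    a = structure.atoms
    ca = a[a.atom_name == "CA"]

    keys = structure.residue_keys()
    ca_keys = [
        (str(c), int(r), str(i))
        for c, r, i in zip(ca.chain_id, ca.res_id, ca.ins_code)
    ]
    counts: dict[tuple, int] = {}
    for k in ca_keys:
        counts[k] = counts.get(k, 0) + 1
    missing = [k for k in keys if k not in counts]
    if missing:
        raise StructureError(
            "residues missing a Calpha atom: "
            + ", ".join(f"{c}/{r}{i}" for c, r, i in missing)
        )
    dupes = [k for k, n in counts.items() if n > 1]
    if dupes:
        raise StructureError(
            "duplicate Calpha after altloc resolution: "
            + ", ".join(f"{c}/{r}{i}" for c, r, i in dupes)
        )

    order = sorted(range(len(ca_keys)), key=lambda j: (ca_keys[j][0], ca_keys[j][1], ca_keys[j][2]))
    coords = np.asarray(ca.coord[order], dtype=float)
    chains = [ca_keys[j][0] for j in order]
    resnums_raw = [ca_keys[j][1] for j in order]
    icodes = [ca_keys[j][2] for j in order]
    resnames = [str(ca.res_name[j]) for j in order]

    mature = [
        numbering.apply(c, r, i) for c, r, i in zip(chains, resnums_raw, icodes)
    ]
    for ch in set(chains):
        nums = [m for c, m in zip(chains, mature) if c == ch]
        if len(nums) != len(set(nums)):
            raise StructureError(f"numbering map is not injective on chain {ch}")

    labels = [
        f"{_THREE_TO_ONE.get(rn, 'X')}{m}" for rn, m in zip(resnames, mature)
    ]

    index = {(c, r): j for j, (c, r) in enumerate(zip(chains, resnums_raw))}

    helix_id = np.full(len(order), -1, dtype=int)
    sheet = np.zeros(len(order), dtype=bool)
    hx = 0
    for span in structure.sse_spans:
        members = [
            index[(span.chain, r)]
            for r in range(span.first, span.last + 1)
            if (span.chain, r) in index
        ]
        if span.kind == "helix":
            for j in members:
                helix_id[j] = hx
            hx += 1
        else:
            for j in members:
                sheet[j] = True

    ss_pairs = []
    for (c1, r1), (c2, r2) in structure.disulfides:
        if (c1, r1) in index and (c2, r2) in index:
            i, j = index[(c1, r1)], index[(c2, r2)]
            if i != j:
                ss_pairs.append((min(i, j), max(i, j)))

    return CalphaModel(
        coords=coords,
        resnums=np.asarray(mature, dtype=int),
        resnames=resnames,
        labels=labels,
        chain_ids=np.asarray(chains),
        helix_id=helix_id,
        sheet=sheet,
        disulfides=ss_pairs,
    )


def write_trajectory_pdb(
    frames: np.ndarray, path: str | os.PathLike, template: struc.AtomArray | None = None,
    resnums: np.ndarray | None = None, resnames: list[str] | None = None,
) -> None:
    """Write an (F, N, 3) Cα frame array as a multi-model PDB."""
    frames = np.asarray(frames, dtype=float)
    f, n, _ = frames.shape
    if template is None:
        template = struc.AtomArray(n)
        template.chain_id[:] = "A"
        template.res_id[:] = resnums if resnums is not None else np.arange(1, n + 1)
        template.res_name[:] = resnames if resnames is not None else "ALA"
        template.atom_name[:] = "CA"
        template.element[:] = "C"
        template.add_annotation("occupancy", float)
        template.occupancy[:] = 1.0
    stack = struc.stack([template] * f)
    stack.coord = frames
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(os.fspath(path))


def read_trajectory_frames(path: str | os.PathLike) -> np.ndarray:
    """Read a multi-model PDB into an (F, N, 3) Cα coordinate array."""
    pdb_file = pdbio.PDBFile.read(os.fspath(path))
    stack = pdbio.get_structure(pdb_file)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    ca = stack[:, stack.atom_name == "CA"]
    return np.asarray(ca.coord, dtype=float)
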
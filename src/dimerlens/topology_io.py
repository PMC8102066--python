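"""Topology and coordinate input for annotated two-protomer bead systems.

A dimer is described by two :class:`ProtomerTopology` objects (protomers
``A`` and ``B``) that map beads to residues and residues to named domains
(TM1..TM7 helices, intracellular/extracellular loops, termini).  Coordinates
come either from a plain whitespace table (``frame bead_id x y z``), or from
GRO/PDB files read through MDAnalysis with beads matched to the topology by
order.  All coordinates are stored internally in nanometers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from dimerlens.errors import TopologyError, TrajectoryError

ANGSTROM_PER_NM = 10.0

#: canonical domain names of a 7TM receptor; user-defined names are also allowed
CANONICAL_DOMAINS = (
    "TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7",
    "ICL1", "ICL2", "ICL3", "ECL1", "ECL2", "ECL3",
    "NTERM", "CTERM",
)

HELIX_DOMAINS = frozenset({"TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7"})


@dataclass(frozen=True)
class DomainDefinition:
    """A named domain covering inclusive residue-index intervals."""

    name: str
    residue_ranges: tuple[tuple[int, int], ...]

    def __contains__(self, residue_index: int) -> bool:
        return any(lo <= residue_index <= hi for lo, hi in self.residue_ranges)


@dataclass(frozen=True)
class Residue:
    index: int          # 1-based residue number
    domain: str
    bead_ids: tuple[str, ...]


@dataclass
class ProtomerTopology:
    """Ordered residues of one protomer with their domain and bead assignment."""

    protomer_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        seen_beads: set[str] = set()
        seen_res: set[int] = set()
        for res in self.residues:
            if res.index in seen_res:
                raise TopologyError(
                    f"protomer {self.protomer_id}: residue {res.index} assigned "
                    "to more than one domain (unassigned residue / overlap)"
                )
            seen_res.add(res.index)
            if not res.bead_ids:
                raise TopologyError(
                    f"protomer {self.protomer_id}: residue {res.index} has no beads"
                )
            for bead in res.bead_ids:
                if bead in seen_beads:
                    raise TopologyError(f"bead collision: {bead!r} appears twice")
                seen_beads.add(bead)

    @property
    def domains(self) -> tuple[str, ...]:
        out: list[str] = []
        for res in self.residues:
            if res.domain not in out:
                out.append(res.domain)
        return tuple(out)

    @property
    def bead_ids(self) -> tuple[str, ...]:
        return tuple(b for res in self.residues for b in res.bead_ids)

    @property
    def n_beads(self) -> int:
        return sum(len(res.bead_ids) for res in self.residues)


@dataclass
class DimerTrajectory:
    """Time-ordered bead coordinates (nm) of two annotated protomers.

    ``coords`` has shape (n_frames, n_beads, 3) with the bead axis ordered as
    ``bead_ids``.  ``bead_map`` resolves a bead id to (protomer_id,
    residue_index).
    """

    coords: np.ndarray
    bead_ids: tuple[str, ...]
    bead_map: dict[str, tuple[str, int]]
    frame_spacing: float  # ns per frame
    source: str = ""
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (n_frames, n_beads, 3)")
        if self.coords.shape[1] != len(self.bead_ids):
            raise TrajectoryError("topology/coordinate mismatch: bead count differs")
        if self.frame_spacing <= 0:
            raise TrajectoryError("frame_spacing must be > 0")
        self._index = {b: i for i, b in enumerate(self.bead_ids)}

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def protomer_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for bead in self.bead_ids:
            pid = self.bead_map[bead][0]
            if pid not in seen:
                seen.append(pid)
        return tuple(seen)

    def bead_position(self, frame: int, bead_id: str) -> np.ndarray:
        return self.coords[frame, self._index[bead_id]]


# ---------------------------------------------------------------------------
# topology config I/O (JSON)
# ---------------------------------------------------------------------------

def load_topology(topology_file: str | Path) -> tuple[ProtomerTopology, ProtomerTopology]:
    """Read a two-protomer topology from a JSON config.

    Expected layout::

        {"protomers": [
            {"protomer_id": "A",
             "residues": [{"index": 1, "domain": "TM1", "beads": ["A:1"]}, ...]},
            {"protomer_id": "B", "residues": [...]}]}

    Raises :class:`TopologyError` on duplicate beads, duplicated residues or
    mismatched domain schemas between the two protomers.
    """
    path = Path(topology_file)
    data = json.loads(path.read_text())
    protomers = data.get("protomers", [])
    if len(protomers) != 2:
        raise TopologyError(f"expected exactly two protomers, got {len(protomers)}")
    pair = []
    for entry in protomers:
        residues = tuple(
            Residue(int(r["index"]), str(r["domain"]), tuple(r["beads"]))
            for r in entry["residues"]
        )
        pair.append(ProtomerTopology(str(entry["protomer_id"]), residues))
    a, b = pair
    if set(a.domains) != set(b.domains):
        raise TopologyError("protomers declare different domain schemas")
    return a, b


def write_topology(pair: tuple[ProtomerTopology, ProtomerTopology], path: str | Path) -> None:
    data = {
        "protomers": [
            {
                "protomer_id": top.protomer_id,
                "residues": [
                    {"index": r.index, "domain": r.domain, "beads": list(r.bead_ids)}
                    for r in top.residues
                ],
            }
            for top in pair
        ]
    }
    Path(path).write_text(json.dumps(data, indent=1))


def domain_definitions(top: ProtomerTopology) -> tuple[DomainDefinition, ...]:
    """Collapse per-residue domain assignments into interval definitions."""
    ranges: dict[str, list[list[int]]] = {}
    for res in sorted(top.residues, key=lambda r: r.index):
        rs = ranges.setdefault(res.domain, [])
        if rs and rs[-1][1] == res.index - 1:
            rs[-1][1] = res.index
        else:
            rs.append([res.index, res.index])
    return tuple(
        DomainDefinition(name, tuple((lo, hi) for lo, hi in rs))
        for name, rs in ranges.items()
    )


# ---------------------------------------------------------------------------
# coordinate I/O
# ---------------------------------------------------------------------------

def _bead_map_from_pair(pair: tuple[ProtomerTopology, ProtomerTopology]) -> tuple[tuple[str, ...], dict[str, tuple[str, int]]]:
    bead_ids: list[str] = []
    bead_map: dict[str, tuple[str, int]] = {}
    for top in pair:
        for res in top.residues:
            for bead in res.bead_ids:
                if bead in bead_map:
                    raise TopologyError(f"bead collision: {bead!r} appears twice")
                bead_map[bead] = (top.protomer_id, res.index)
                bead_ids.append(bead)
    return tuple(bead_ids), bead_map


def _read_xyz_table(path: Path) -> tuple[list[str], np.ndarray]:
    """Plain whitespace table: columns frame, bead_id, x, y, z."""
    frames: dict[int, dict[str, tuple[float, float, float]]] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise TrajectoryError(f"corrupt frame: malformed line {line!r}")
        f, bead = int(parts[0]), parts[1]
        xyz = tuple(float(v) for v in parts[2:5])
        frames.setdefault(f, {})[bead] = xyz
    if not frames:
        raise TrajectoryError("empty trajectory")
    order = sorted(frames)
    bead_order = list(frames[order[0]])
    coords = np.empty((len(order), len(bead_order), 3))
    for fi, f in enumerate(order):
        fr = frames[f]
        if set(fr) != set(bead_order):
            raise TrajectoryError(f"frame {f}: bead set differs from first frame")
        for bi, bead in enumerate(bead_order):
            coords[fi, bi] = fr[bead]
    return bead_order, coords


def _read_mdtraj(path: Path) -> np.ndarray:
    """GRO/PDB coordinates via mdtraj (already in nm), multi-frame aware."""
    import mdtraj as md

    t = md.load(str(path))
    return np.asarray(t.xyz, dtype=float)


def load_trajectory(
    coordinate_file: str | Path,
    topology: tuple[ProtomerTopology, ProtomerTopology],
    units: str = "nm",
    frame_spacing: float = 1.0,
    stride: int = 1,
    fmt: str | None = None,
) -> DimerTrajectory:
    """Load coordinates and bind them to the topology's beads.

    ``units`` applies only to the plain-table dialect ({'angstrom', 'nm'});
    GRO/PDB formats carry their own unit conventions.  ``stride`` subsamples
    frames (default 1: every frame); ``frame_spacing`` is the time per
    *stored* frame in ns after striding.
    """
    path = Path(coordinate_file)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "xyz"
    bead_ids, bead_map = _bead_map_from_pair(topology)

    if fmt in ("xyz", "tsv", "txt", "dat"):
        file_beads, coords = _read_xyz_table(path)
        if set(file_beads) != set(bead_ids):
            raise TrajectoryError(
                "topology/coordinate mismatch: bead ids in file differ from topology"
            )
        # reorder columns to topology bead order
        perm = [file_beads.index(b) for b in bead_ids]
        coords = coords[:, perm, :]
        if units == "angstrom":
            coords = coords * 0.1
        elif units != "nm":
            raise TrajectoryError(f"unknown units {units!r}")
    elif fmt in ("gro", "pdb"):
        coords = _read_mdtraj(path)
        if coords.shape[1] != len(bead_ids):
            raise TrajectoryError(
                "topology/coordinate mismatch: "
                f"{coords.shape[1]} beads in file, {len(bead_ids)} in topology"
            )
    else:
        raise TrajectoryError(f"unsupported coordinate format {fmt!r}")

    coords = coords[::stride]
    if not np.all(np.isfinite(coords)):
        bad = np.argwhere(~np.isfinite(coords))
        raise TrajectoryError(
            f"corrupt frame: non-finite coordinate at frame {bad[0][0]}, "
            f"bead {bead_ids[bad[0][1]]}"
        )
    return DimerTrajectory(coords, bead_ids, bead_map, frame_spacing, source=str(path))


def write_trajectory(traj: DimerTrajectory, path: str | Path, fmt: str | None = None) -> None:
    """Write coordinates in the plain-table dialect (full precision) or GRO."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "xyz"
    if fmt in ("xyz", "tsv", "txt", "dat"):
        lines = ["# frame bead_id x_nm y_nm z_nm"]
        for f in range(traj.n_frames):
            for bi, bead in enumerate(traj.bead_ids):
                x, y, z = (float(v) for v in traj.coords[f, bi])
                lines.append(f"{f}\t{bead}\t{x!r}\t{y!r}\t{z!r}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "gro":
        import mdtraj as md

        n = len(traj.bead_ids)
        top = md.Topology()
        chain = top.add_chain()
        carbon = md.element.carbon
        for i in range(n):
            res = top.add_residue("BEA", chain)
            top.add_atom(f"B{i % 100000}", carbon, res)
        t = md.Trajectory(traj.coords.copy(), top)
        t.unitcell_vectors = np.tile(np.eye(3) * 100.0, (traj.n_frames, 1, 1))
        t.save_gro(str(path))
    else:
        raise TrajectoryError(f"unsupported coordinate format {fmt!r}")


def validate_trajectory(traj: DimerTrajectory) -> list[str]:
    """Report-only invariant check; an empty list means the trajectory is valid."""
    report: list[str] = []
    pids = traj.protomer_ids
    if len(pids) != 2:
        report.append(f"expected exactly two protomers, found {len(pids)}: {pids}")
    if traj.n_frames == 0:
        report.append("empty trajectory")
    if traj.frame_spacing <= 0:
        report.append(f"non-positive frame spacing {traj.frame_spacing}")
    bad = np.argwhere(~np.isfinite(traj.coords))
    for f, bi in {(int(r[0]), int(r[1])) for r in bad}:
        report.append(f"non-finite coordinate at frame {f}, bead {traj.bead_ids[bi]}")
    missing = [b for b in traj.bead_ids if b not in traj.bead_map]
    if missing:
        report.append(f"beads without topology assignment: {missing}")
    return report
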
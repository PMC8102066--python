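"""Interface discretization: residue contacts, domain labels, microstates.

The relative arrangement of two protomers in a frame is summarized by which
domains (helices, loops, termini) of each protomer touch the other protomer.
A residue pair is in contact when the minimal distance over its bead pairs is
within ``contact_cutoff`` (default 1.0 nm).  A domain enters a protomer's
interface label when it forms strictly more than ``label_count_threshold``
contacts (default 20) with the other protomer.  The ordered pair of domain
sets (protomer A | protomer B) is the interface microstate; both sets empty
means the frame is monomeric.

Per-microstate domain contact matrices C[D, D'] record, at a tighter cutoff
(default 0.9 nm), the fraction of the microstate's frames in which any residue
of domain D on protomer A lies within the cutoff of any residue of domain D'
on protomer B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dimerlens.errors import AnalysisError, TrajectoryError
from dimerlens.topology_io import DimerTrajectory, ProtomerTopology


@dataclass(frozen=True)
class AnalysisConfig:
    """Cutoffs and counting rules of the interface discretization."""

    contact_cutoff: float = 1.0          # nm; residue-contact definition
    label_count_threshold: int = 20      # strict "more than" rule
    contact_matrix_cutoff: float = 0.9   # nm; domain contact matrices
    count_mode: str = "residue_pairs"    # or "residues"

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0 or self.contact_matrix_cutoff <= 0:
            raise AnalysisError("cutoffs must be > 0")
        if self.label_count_threshold < 0:
            raise AnalysisError("label_count_threshold must be >= 0")
        if self.count_mode not in ("residue_pairs", "residues"):
            raise AnalysisError(f"unknown count_mode {self.count_mode!r}")


@dataclass(frozen=True)
class MicrostateLabel:
    """Ordered pair of contacting-domain sets; empty/empty = monomeric."""

    domains_A: frozenset[str]
    domains_B: frozenset[str]

    @property
    def is_monomeric(self) -> bool:
        return not self.domains_A and not self.domains_B

    def swapped(self) -> "MicrostateLabel":
        return MicrostateLabel(self.domains_B, self.domains_A)

    def __str__(self) -> str:
        a = ",".join(sorted(self.domains_A)) or "-"
        b = ",".join(sorted(self.domains_B)) or "-"
        return f"({a}|{b})"


MONOMER = MicrostateLabel(frozenset(), frozenset())


@dataclass
class ContactMatrix:
    """Domain x domain contact probabilities, protomer A rows, B columns."""

    values: np.ndarray
    domains_A: tuple[str, ...]
    domains_B: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise AnalysisError("contact probabilities must lie in [0, 1]")

    def transposed(self) -> "ContactMatrix":
        return ContactMatrix(self.values.T.copy(), self.domains_B, self.domains_A)


@dataclass
class DiscreteTrajectory:
    """Per-frame microstate codes with their label dictionary."""

    state_ids: np.ndarray
    label_dict: dict[int, MicrostateLabel]
    frame_spacing: float  # ns
    contact_matrices: dict[int, ContactMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.state_ids = np.asarray(self.state_ids, dtype=int)
        present = set(np.unique(self.state_ids).tolist())
        if not present <= set(self.label_dict):
            raise AnalysisError("every state_id must be present in label_dict")

    @property
    def n_states(self) -> int:
        return len(self.label_dict)


class _FrameGeometry:
    """Precomputed bead/residue bookkeeping for fast per-frame reductions."""

    def __init__(self, traj: DimerTrajectory, topology: tuple[ProtomerTopology, ProtomerTopology]):
        top_a, top_b = topology
        index = {b: i for i, b in enumerate(traj.bead_ids)}

        def gather(top: ProtomerTopology):
            bead_cols, res_of_bead, res_ids, res_domains = [], [], [], []
            for ri, res in enumerate(top.residues):
                if not res.bead_ids:
                    raise AnalysisError(f"degenerate residue {res.index} (no beads)")
                res_ids.append(res.index)
                res_domains.append(res.domain)
                for bead in res.bead_ids:
                    bead_cols.append(index[bead])
                    res_of_bead.append(ri)
            return (np.array(bead_cols), np.array(res_of_bead),
                    res_ids, res_domains)

        self.cols_a, self.res_of_bead_a, self.res_ids_a, self.res_domains_a = gather(top_a)
        self.cols_b, self.res_of_bead_b, self.res_ids_b, self.res_domains_b = gather(top_b)
        self.domains_a = tuple(top_a.domains)
        self.domains_b = tuple(top_b.domains)
        self._dom_idx_a = np.array([self.domains_a.index(d) for d in self.res_domains_a])
        self._dom_idx_b = np.array([self.domains_b.index(d) for d in self.res_domains_b])


def residue_min_distances(
    frame: np.ndarray,
    traj: DimerTrajectory,
    topology: tuple[ProtomerTopology, ProtomerTopology],
    _geom: _FrameGeometry | None = None,
) -> np.ndarray:
    """Minimal bead-pair distance for every (residue of A, residue of B) pair.

    ``frame`` is one row of ``traj.coords`` (shape (n_beads, 3), nm).
    Returns an (n_res_A, n_res_B) array.  Exchanging the protomer order in
    ``topology`` transposes the result.
    """
    geom = _geom or _FrameGeometry(traj, topology)
    # explicit sqrt(dx^2 + dy^2 + dz^2): reproducible bitwise against a
    # straightforward per-pair implementation
    diff = frame[geom.cols_a][:, None, :] - frame[geom.cols_b][None, :, :]
    sq = diff * diff
    d = np.sqrt(sq[..., 0] + sq[..., 1] + sq[..., 2])
    out = np.full((len(geom.res_ids_a), len(geom.res_ids_b)), np.inf)
    np.minimum.at(out, (geom.res_of_bead_a[:, None], geom.res_of_bead_b[None, :]), d)
    return out


def domain_contact_counts(
    distances: np.ndarray,
    geom: _FrameGeometry,
    config: AnalysisConfig,
) -> tuple[dict[str, int], dict[str, int]]:
    """Contact counts per domain, for protomer A and protomer B.

    In ``residue_pairs`` mode a contacting residue pair (r_A, r_B) counts once
    toward the domain of r_A (on A) and once toward the domain of r_B (on B).
    In ``residues`` mode each residue with at least one contact counts once
    toward its own domain.
    """
    mask = distances <= config.contact_cutoff
    if config.count_mode == "residue_pairs":
        per_res_a = mask.sum(axis=1)
        per_res_b = mask.sum(axis=0)
    else:
        per_res_a = mask.any(axis=1).astype(int)
        per_res_b = mask.any(axis=0).astype(int)
    counts_a = np.bincount(geom._dom_idx_a, weights=per_res_a, minlength=len(geom.domains_a))
    counts_b = np.bincount(geom._dom_idx_b, weights=per_res_b, minlength=len(geom.domains_b))
    return (
        {d: int(c) for d, c in zip(geom.domains_a, counts_a)},
        {d: int(c) for d, c in zip(geom.domains_b, counts_b)},
    )


def label_microstate(
    counts: tuple[dict[str, int], dict[str, int]],
    config: AnalysisConfig,
) -> MicrostateLabel:
    """Domains with strictly more than ``label_count_threshold`` contacts."""
    thr = config.label_count_threshold
    counts_a, counts_b = counts
    return MicrostateLabel(
        frozenset(d for d, c in counts_a.items() if c > thr),
        frozenset(d for d, c in counts_b.items() if c > thr),
    )


def _domain_min_distances(distances: np.ndarray, geom: _FrameGeometry) -> np.ndarray:
    """Reduce the residue distance table to a domain x domain minimum table."""
    out = np.full((len(geom.domains_a), len(geom.domains_b)), np.inf)
    np.minimum.at(out, (geom._dom_idx_a[:, None], geom._dom_idx_b[None, :]), distances)
    return out


def discretize_trajectory(
    traj: DimerTrajectory,
    topology: tuple[ProtomerTopology, ProtomerTopology],
    config: AnalysisConfig | None = None,
) -> DiscreteTrajectory:
    """Classify every frame into an interface microstate.

    Returns a :class:`DiscreteTrajectory` whose ``label_dict`` covers exactly
    the observed labels (state ids dense from 0 in order of first appearance)
    and whose ``contact_matrices`` hold the per-microstate domain contact
    probabilities at ``config.contact_matrix_cutoff``.
    """
    config = config or AnalysisConfig()
    if traj.n_frames == 0:
        raise TrajectoryError("empty trajectory")
    geom = _FrameGeometry(traj, topology)

    state_of_label: dict[MicrostateLabel, int] = {}
    state_ids = np.empty(traj.n_frames, dtype=int)
    event_sums: dict[int, np.ndarray] = {}
    frame_counts: dict[int, int] = {}

    for f in range(traj.n_frames):
        dist = residue_min_distances(traj.coords[f], traj, topology, _geom=geom)
        label = label_microstate(domain_contact_counts(dist, geom, config), config)
        sid = state_of_label.setdefault(label, len(state_of_label))
        state_ids[f] = sid
        event = (_domain_min_distances(dist, geom) <= config.contact_matrix_cutoff)
        if sid not in event_sums:
            event_sums[sid] = np.zeros(event.shape)
            frame_counts[sid] = 0
        event_sums[sid] += event
        frame_counts[sid] += 1

    label_dict = {sid: lab for lab, sid in state_of_label.items()}
    matrices = {
        sid: ContactMatrix(event_sums[sid] / frame_counts[sid], geom.domains_a, geom.domains_b)
        for sid in label_dict
    }
    return DiscreteTrajectory(state_ids, label_dict, traj.frame_spacing, matrices)
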
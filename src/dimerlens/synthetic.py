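"""Seeded synthetic-data generators for every pipeline stage.

Each generator emits data with exactly the statistical structure the
consuming module assumes — metastable interface-state kinetics, geometric
toy dimers with scheduled interfaces, binomial fluorophore labeling of
monomer/dimer mixtures, Hill-governed dose responses, alignments with
planted conservation, Gaussian steered-pull work — together with a manifest
recording parameters, seed and ground truth.  A fixed seed reproduces the
output exactly.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from dimerlens.contacts import MicrostateLabel, MONOMER
from dimerlens.errors import AnalysisError
from dimerlens.response import ApplicationWindow, FluorescenceTrace
from dimerlens.topology_io import DimerTrajectory, ProtomerTopology, Residue
from dimerlens.tpt import WorkSamples


# ---------------------------------------------------------------------------
# Markov chains
# ---------------------------------------------------------------------------

def simulate_chain(
    transition_matrix: np.ndarray,
    n_traj: int,
    n_steps: int,
    seed: int,
    start: int | None = None,
) -> list[np.ndarray]:
    """Sample discrete Markov trajectories from a row-stochastic matrix.

    Without an explicit ``start`` state, each trajectory starts from the
    stationary distribution.
    """
    P = np.asarray(transition_matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1] or np.any(P < 0) or \
            np.abs(P.sum(axis=1) - 1).max() > 1e-10:
        raise AnalysisError("invalid chain: transition matrix must be row-stochastic")
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    # stationary distribution for the default start
    vals, vecs = np.linalg.eig(P.T)
    k = np.argmin(np.abs(vals - 1.0))
    pi = np.abs(np.real(vecs[:, k]))
    pi /= pi.sum()
    cum = np.cumsum(P, axis=1)
    trajs = []
    for _ in range(n_traj):
        s = int(rng.choice(n, p=pi)) if start is None else start
        out = np.empty(n_steps, dtype=int)
        u = rng.random(n_steps)
        for t in range(n_steps):
            out[t] = s
            s = int(np.searchsorted(cum[s], u[t]))
        trajs.append(out)
    return trajs


def block_transition_matrix(
    block_sizes: Sequence[int],
    intra: float = 0.1,
    coupling: float = 1e-3,
) -> np.ndarray:
    """Reversible metastable chain: uniform in-block mixing at rate ``intra``
    per partner state, uniform out-of-block leakage ``coupling`` per state.

    The matrix is symmetric (hence doubly stochastic and reversible with a
    uniform stationary distribution), which keeps the planted block structure
    exactly recoverable.
    """
    n = sum(block_sizes)
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    P = np.full((n, n), coupling)
    for b in range(len(block_sizes)):
        idx = np.flatnonzero(labels == b)
        for i in idx:
            for j in idx:
                if i != j:
                    P[i, j] = intra
    np.fill_diagonal(P, 0.0)
    np.fill_diagonal(P, 1.0 - P.sum(axis=1))
    if np.any(np.diag(P) < 0):
        raise AnalysisError("invalid chain parameters: negative self-transition")
    return P


# ---------------------------------------------------------------------------
# geometric toy dimer
# ---------------------------------------------------------------------------

_N_RES_PER_HELIX = 12
_HELIX_Z_SPACING = 0.30      # nm between consecutive residues in a column
_RING_RADIUS = 2.5           # nm from protomer axis to each helix column
_INTERFACE_GAP = 0.7         # nm between facing helix columns
_MONOMER_SEPARATION = 10.0   # nm between protomer axes in monomer frames

_HELICES = tuple(f"TM{i}" for i in range(1, 8))
_LOOPS = ("ICL1", "ICL2", "ICL3", "ECL1", "ECL2", "ECL3")


def _base_protomer_coords() -> tuple[list[tuple[int, str]], np.ndarray]:
    """Residue list [(index, domain)] and local coordinates of one protomer."""
    residues: list[tuple[int, str]] = []
    coords: list[np.ndarray] = []
    idx = 1
    for k, helix in enumerate(_HELICES):
        theta = 2 * math.pi * k / 7
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        for j in range(_N_RES_PER_HELIX):
            residues.append((idx, helix))
            coords.append(_RING_RADIUS * u + np.array([0, 0, j * _HELIX_Z_SPACING]))
            idx += 1
    top_z = (_N_RES_PER_HELIX - 1) * _HELIX_Z_SPACING
    for li, loop in enumerate(_LOOPS):
        z = -0.6 - 0.3 * (li % 3) if loop.startswith("ICL") else top_z + 0.6 + 0.3 * (li % 3)
        theta = 2 * math.pi * li / 6
        for j in range(2):
            residues.append((idx, loop))
            coords.append(np.array([0.4 * math.cos(theta), 0.4 * math.sin(theta), z + 0.1 * j]))
            idx += 1
    for term, z in (("NTERM", top_z + 1.5), ("CTERM", -1.5)):
        residues.append((idx, term))
        coords.append(np.array([0.0, 0.0, z]))
        idx += 1
    return residues, np.array(coords)


def _normalize_schedule_entry(entry) -> MicrostateLabel:
    label = entry
    if label is None or label == "monomer":
        return MONOMER
    if isinstance(label, str):
        a, b = label.split("|")
        return MicrostateLabel(frozenset(a.split(",")) - {"-", ""},
                               frozenset(b.split(",")) - {"-", ""})
    if isinstance(label, MicrostateLabel):
        return label
    a, b = label
    return MicrostateLabel(frozenset(a), frozenset(b))


def _rotz(phi: float) -> np.ndarray:
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


def _brute_force_label(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    domains: list[str],
    cutoff: float,
    threshold: int,
) -> MicrostateLabel:
    """Independent O(n^2) contact count + label used for self-verification."""
    d = cdist(coords_a, coords_b)  # one bead per residue in the toy geometry
    contact = d <= cutoff
    counts_a: dict[str, int] = {}
    counts_b: dict[str, int] = {}
    for ri, dom in enumerate(domains):
        counts_a[dom] = counts_a.get(dom, 0) + int(contact[ri].sum())
        counts_b[dom] = counts_b.get(dom, 0) + int(contact[:, ri].sum())
    return MicrostateLabel(
        frozenset(d_ for d_, c in counts_a.items() if c > threshold),
        frozenset(d_ for d_, c in counts_b.items() if c > threshold),
    )


def build_toy_dimer(
    interface_schedule: list[tuple],
    seed: int = 0,
    jitter_sd: float = 0.01,
    frame_spacing: float = 1.0,
    contact_cutoff: float = 1.0,
    label_threshold: int = 20,
) -> tuple[tuple[ProtomerTopology, ProtomerTopology], DimerTrajectory, list[MicrostateLabel]]:
    """Geometric two-protomer trajectory realizing a scheduled label sequence.

    Each protomer is an idealized 7-helix bead model (one bead per residue,
    helices as columns on a ring, loops near the axis).  For a scheduled
    segment ``(label, n_frames)`` with single-helix label ``({TMa}|{TMb})``,
    protomer B is rotated and placed so that exactly TMa of A and TMb of B
    exceed the contact threshold; monomer segments separate the protomers by
    several cutoffs.  Every frame is re-checked against an independent
    brute-force contact oracle; an unrealizable schedule raises.

    Returns the topology pair, the trajectory, and the per-frame ground-truth
    labels.  The construction guarantees hold under the default
    residue-pair counting mode.
    """
    residues, base = _base_protomer_coords()
    domains = [dom for _, dom in residues]

    def make_top(pid: str) -> ProtomerTopology:
        return ProtomerTopology(pid, tuple(
            Residue(i, dom, (f"{pid}:{i}",)) for i, dom in residues
        ))

    top_a, top_b = make_top("A"), make_top("B")
    rng = np.random.default_rng(seed)
    frames: list[np.ndarray] = []
    truth: list[MicrostateLabel] = []

    for entry, n_frames in interface_schedule:
        label = _normalize_schedule_entry(entry)
        if label.is_monomeric:
            coords_b = base + np.array([2 * _RING_RADIUS + _MONOMER_SEPARATION, 0, 0])
        else:
            if len(label.domains_A) != 1 or len(label.domains_B) != 1:
                raise AnalysisError(
                    f"schedule unrealizable: only single-helix labels supported, got {label}"
                )
            (dom_a,), (dom_b,) = label.domains_A, label.domains_B
            if dom_a not in _HELICES or dom_b not in _HELICES:
                raise AnalysisError(f"schedule unrealizable: non-helix domain in {label}")
            th_a = 2 * math.pi * _HELICES.index(dom_a) / 7
            th_b = 2 * math.pi * _HELICES.index(dom_b) / 7
            u = np.array([math.cos(th_a), math.sin(th_a), 0.0])
            center = (2 * _RING_RADIUS + _INTERFACE_GAP) * u
            coords_b = base @ _rotz(th_a + math.pi - th_b).T + center
        check = _brute_force_label(base, coords_b, domains, contact_cutoff, label_threshold)
        if check != label:
            raise AnalysisError(
                f"schedule unrealizable: requested {label}, geometry yields {check}"
            )
        for _ in range(n_frames):
            jitter = rng.normal(0.0, jitter_sd, size=(2,) + base.shape)
            fa, fb = base + jitter[0], coords_b + jitter[1]
            got = _brute_force_label(fa, fb, domains, contact_cutoff, label_threshold)
            if got != label:
                raise AnalysisError(
                    f"schedule unrealizable under jitter: wanted {label}, got {got}"
                )
            frames.append(np.concatenate([fa, fb]))
            truth.append(label)

    bead_ids = tuple(f"A:{i}" for i, _ in residues) + tuple(f"B:{i}" for i, _ in residues)
    bead_map = {f"A:{i}": ("A", i) for i, _ in residues}
    bead_map.update({f"B:{i}": ("B", i) for i, _ in residues})
    traj = DimerTrajectory(
        np.array(frames), bead_ids, bead_map, frame_spacing, source="build_toy_dimer"
    )
    return (top_a, top_b), traj, truth


# ---------------------------------------------------------------------------
# photobleaching
# ---------------------------------------------------------------------------

def simulate_photobleaching(
    n_spots: int,
    dimer_fraction: float,
    label_efficiency: float,
    coincidence_rate: float = 0.03,
    n_movies: int = 4,
    seed: int = 0,
    condition: str = "default",
    channel: str = "LD555",
) -> tuple[pd.DataFrame, dict]:
    """Binomial-labeling photobleaching spot table for a monomer/dimer mixture.

    A dimer with per-subunit labeling efficiency p shows 2 steps with
    probability p^2, 1 step with 2p(1-p), and is invisible with (1-p)^2; a
    monomer shows 1 step with probability p.  Coincidental colocalization
    adds the steps of an extra molecule at the given rate (capped at 4
    steps).  Exactly ``n_spots`` *visible* spots are emitted, split evenly
    over ``n_movies`` movies.  Returns (spot table, manifest).
    """
    if not (0 <= dimer_fraction <= 1 and 0 < label_efficiency <= 1
            and 0 <= coincidence_rate <= 1):
        raise AnalysisError("invalid parameter: probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def visible_steps() -> int:
        while True:
            if rng.random() < dimer_fraction:
                k = rng.binomial(2, label_efficiency)
            else:
                k = rng.binomial(1, label_efficiency)
            if k > 0:
                return int(k)

    rows = []
    for i in range(n_spots):
        k = visible_steps()
        if rng.random() < coincidence_rate:
            k = min(4, k + visible_steps())
        rows.append({
            "movie_id": f"movie{i % n_movies:02d}",
            "spot_id": f"spot{i:05d}",
            "steps": k,
            "condition": condition,
            "channel": channel,
        })
    table = pd.DataFrame(rows)
    manifest = {
        "generator": "simulate_photobleaching",
        "seed": seed,
        "n_spots": n_spots,
        "dimer_fraction": dimer_fraction,
        "label_efficiency": label_efficiency,
        "coincidence_rate": coincidence_rate,
        "n_movies": n_movies,
        "expected_two_step_fraction":
            dimer_fraction * label_efficiency / (1 + dimer_fraction * (1 - label_efficiency)),
    }
    return table, manifest


def simulate_bleach_traces(
    step_counts: Iterable[int],
    amplitude: float = 100.0,
    noise_sd: float = 5.0,
    n_samples: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, list[int]]:
    """Piecewise-constant bleaching traces with Gaussian noise.

    Each trace starts at ``steps * amplitude`` and drops by one amplitude at
    each of ``steps`` ordered random bleach times.  Returns (traces array of
    shape (n, n_samples), true step counts).
    """
    rng = np.random.default_rng(seed)
    counts = [int(k) for k in step_counts]
    traces = np.empty((len(counts), n_samples))
    for i, k in enumerate(counts):
        times = np.sort(rng.integers(int(0.15 * n_samples), int(0.85 * n_samples), size=k))
        # enforce distinct, well-separated change points
        for j in range(1, k):
            times[j] = max(times[j], times[j - 1] + max(8, n_samples // 25))
        level = np.full(n_samples, float(k) * amplitude)
        for j, t in enumerate(times):
            level[t:] = (k - j - 1) * amplitude
        traces[i] = level + rng.normal(0.0, noise_sd, n_samples)
    return traces, counts


# ---------------------------------------------------------------------------
# dose responses and fluorescence traces
# ---------------------------------------------------------------------------

def simulate_dose_response(
    ec50: float,
    hill: float = 1.0,
    top: float = 1.0,
    bottom: float = 0.0,
    concentrations: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Four-parameter-logistic responses with multiplicative Gaussian noise."""
    if ec50 <= 0:
        raise AnalysisError("invalid parameter: ec50 must be > 0")
    if concentrations is None:
        concentrations = np.logspace(math.log10(ec50) - 3, math.log10(ec50) + 3, 9)
    c = np.asarray(concentrations, dtype=float)
    if np.any(c <= 0):
        raise AnalysisError("invalid concentrations")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        clean = bottom + (top - bottom) / (1 + (ec50 / c) ** hill)
        noisy = clean * (1 + rng.normal(0.0, noise_sd, len(c))) if noise_sd > 0 else clean
        for ci, (conc, r) in enumerate(zip(c, noisy)):
            rows.append({"conc_M": conc, "response": r, "replicate": rep})
    return pd.DataFrame(rows)


def simulate_fret_trace(
    relative_responses: Sequence[float],
    reference_index: int | None = None,
    donor_baseline: float = 300.0,
    acceptor_baseline: float = 100.0,
    transfer_amplitude: float = 80.0,
    noise_sd: float = 0.0,
    samples_per_window: int = 40,
    baseline_samples: int = 40,
    seed: int = 0,
) -> FluorescenceTrace:
    """Two-channel trace with programmed anti-correlated window responses.

    Window i moves ``relative_responses[i] * transfer_amplitude`` of intensity
    from donor to acceptor.  By default the last window is the saturating
    reference (relative response 1.0 expected after normalization).
    """
    rng = np.random.default_rng(seed)
    n_win = len(relative_responses)
    total = baseline_samples + n_win * (samples_per_window + baseline_samples)
    t = np.arange(total, dtype=float)
    donor = np.full(total, donor_baseline)
    acceptor = np.full(total, acceptor_baseline)
    windows = []
    pos = baseline_samples
    for i, resp in enumerate(relative_responses):
        sl = slice(pos, pos + samples_per_window)
        donor[sl] -= resp * transfer_amplitude
        acceptor[sl] += resp * transfer_amplitude
        windows.append(ApplicationWindow(
            ligand="glutamate", concentration=float(i + 1),
            start=float(pos), end=float(pos + samples_per_window - 1),
        ))
        pos += samples_per_window + baseline_samples
    if noise_sd > 0:
        donor = np.clip(donor + rng.normal(0, noise_sd, total), 0, None)
        acceptor = np.clip(acceptor + rng.normal(0, noise_sd, total), 0, None)
    return FluorescenceTrace(t, donor, acceptor, windows)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

_CLASS_LETTERS = {
    "aliphatic": "GAVLI",
    "hydroxyl_or_sulfur": "SCTM",
    "cyclic": "P",
    "aromatic": "FYW",
    "basic": "HKR",
    "acidic_and_amides": "DENQ",
}


def simulate_alignment(
    n_seqs: int,
    plan: Sequence[tuple],
    seed: int = 0,
):
    """Alignment whose columns satisfy exactly the planted properties.

    ``plan`` entries: ``("identical",)`` (all residues equal),
    ``("conserved", class_name)`` (one chemical class, >= 2 distinct
    letters), or ``("free",)`` (letters from >= 2 classes: guaranteed
    non-conserved).  Returns an :class:`dimerlens.conservation.AlignmentView`.
    """
    from dimerlens.conservation import AlignmentView

    if n_seqs < 2:
        raise AnalysisError("invalid plan: need at least two sequences")
    rng = np.random.default_rng(seed)
    all_letters = "".join(_CLASS_LETTERS.values())
    cols = []
    for entry in plan:
        kind = entry[0]
        if kind == "identical":
            cols.append(rng.choice(list(all_letters)) * n_seqs)
        elif kind == "conserved":
            letters = _CLASS_LETTERS[entry[1]]
            if len(letters) < 2:
                raise AnalysisError(
                    f"invalid plan: class {entry[1]!r} has a single member, "
                    "cannot be conserved without being identical"
                )
            col = [str(rng.choice(list(letters))) for _ in range(n_seqs)]
            if len(set(col)) == 1:  # force non-identity
                col[-1] = next(x for x in letters if x != col[0])
            cols.append("".join(col))
        elif kind == "free":
            classes = rng.choice(list(_CLASS_LETTERS), size=2, replace=False)
            col = [str(rng.choice(list(_CLASS_LETTERS[rng.choice(classes)])))
                   for _ in range(n_seqs)]
            # force at least two classes to appear
            col[0] = _CLASS_LETTERS[classes[0]][0]
            col[-1] = _CLASS_LETTERS[classes[1]][0]
            cols.append("".join(col))
        else:
            raise AnalysisError(f"invalid plan entry {entry!r}")
    seqs = ["".join(col[s] for col in cols) for s in range(n_seqs)]
    return AlignmentView(
        ids=[f"seq{s}" for s in range(n_seqs)],
        sequences=seqs,
        subsets={"all": list(range(len(plan)))},
    )


# ---------------------------------------------------------------------------
# steered-pull work
# ---------------------------------------------------------------------------

def simulate_work(
    mean_kT: float,
    sd_kT: float,
    n: int,
    seed: int = 0,
    temperature: float = 310.0,
    pull_id: str = "",
) -> WorkSamples:
    """Gaussian nonequilibrium work samples in kT units.

    For Gaussian work the Jarzynski estimate converges to
    ``mean - sd^2 / 2`` (in kT), which anchors the recovery tests.
    """
    if sd_kT < 0:
        raise AnalysisError("invalid parameter: sd must be >= 0")
    if n < 1:
        raise AnalysisError("invalid parameter: n must be >= 1")
    rng = np.random.default_rng(seed)
    w = rng.normal(mean_kT, sd_kT, size=n) if sd_kT > 0 else np.full(n, mean_kT)
    return WorkSamples(w, temperature=temperature, units="kT", pull_id=pull_id)
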
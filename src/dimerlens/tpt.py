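"""Transition path theory flux, interface-class symmetrization, and
Jarzynski free-energy estimation.

Interface labels that describe the same physical dimer interface — identical
helix sets up to a protomer swap, regardless of which loops happen to touch —
are aggregated into :class:`InterfaceClass` equivalence classes before flux
analysis.  Reactive flux between a source set A and a sink set B follows the
standard TPT construction: forward committors from the committor linear
system, backward committors from the time-reversed chain, gross flux
f_ij = pi_i q-_i P_ij q+_j, net flux f+ = max(0, f - f^T).

Free-energy differences between steered-pull targets are estimated from work
samples with Jarzynski's equality, dF = -kT ln < exp(-W/kT) >, evaluated via
log-sum-exp with bootstrap spread and an effective-sample-size bias warning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from dimerlens.contacts import MicrostateLabel
from dimerlens.errors import AnalysisError, EstimationError
from dimerlens.msm import MSMEstimate

#: molar gas constant, kJ mol^-1 K^-1
R_KJ_PER_MOL_K = 0.008314462618

_HELIX_RE = re.compile(r"^TM\d+$")


def is_helix(domain: str) -> bool:
    return bool(_HELIX_RE.match(domain))


Canonical = tuple[frozenset, frozenset]


@dataclass
class InterfaceClass:
    """Swap-invariant, loop-insensitive equivalence class of interface labels."""

    canonical_label: Canonical
    members: list = field(default_factory=list)

    @property
    def name(self) -> str:
        def fmt(s: frozenset) -> str:
            return ",".join(sorted(s)) or "-"
        a, b = self.canonical_label
        return f"{fmt(a)}|{fmt(b)}"


def canonical_form(label: MicrostateLabel) -> Canonical:
    """Unordered pair of the label's helix-only domain sets.

    Dropping loops/termini and forgetting the protomer order makes two labels
    equivalent iff they describe the same helix interface, possibly with
    swapped protomers or different loop participation.
    """
    a = frozenset(d for d in label.domains_A if is_helix(d))
    b = frozenset(d for d in label.domains_B if is_helix(d))
    key = sorted([a, b], key=lambda s: tuple(sorted(s)))
    return (key[0], key[1])


def symmetrize_labels(
    labels: dict[int, MicrostateLabel],
    strict_swap_and_loops: bool = False,
) -> dict[Canonical, InterfaceClass]:
    """Partition labeled states into interface classes.

    The default canonicalization realizes both aggregation rules at once:
    same helices with different loops, and protomer-swapped labels, land in
    the same class.  ``strict_swap_and_loops=True`` instead requires labels to
    be *both* helix-identical-with-different-loops *and* swap-equivalent
    (a far finer partition, kept for comparison).
    """
    classes: dict[Canonical, InterfaceClass] = {}
    if not strict_swap_and_loops:
        for sid, label in labels.items():
            key = canonical_form(label)
            classes.setdefault(key, InterfaceClass(key)).members.append(sid)
        return classes
    # strict reading: aggregate i, j only when both conditions hold jointly
    for sid, label in labels.items():
        key = canonical_form(label)
        cls = classes.setdefault((key[0], key[1]), InterfaceClass(key))
        swapped = label.swapped()
        if any(labels[m] == swapped for m in cls.members) or not cls.members:
            cls.members.append(sid)
        else:
            solo: Canonical = (frozenset({f"state{sid}"}), key[1])
            classes.setdefault(solo, InterfaceClass(key)).members.append(sid)
    return classes


@dataclass
class FluxNetwork:
    source_set: np.ndarray
    sink_set: np.ndarray
    forward_committor: np.ndarray
    backward_committor: np.ndarray
    gross_flux: np.ndarray      # per lag step
    net_flux: np.ndarray        # per lag step
    total_flux: float           # per lag step
    total_flux_per_ns: float
    coarse_flux: dict | None = None   # (class_name, class_name) -> net flux


def _committor(P: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Forward committor: q=0 on A, q=1 on B, harmonic elsewhere."""
    n = P.shape[0]
    q = np.zeros(n)
    q[B] = 1.0
    inter = np.setdiff1d(np.arange(n), np.concatenate([A, B]))
    if len(inter):
        M = np.eye(len(inter)) - P[np.ix_(inter, inter)]
        rhs = P[np.ix_(inter, B)].sum(axis=1)
        q[inter] = np.linalg.solve(M, rhs)
    return q


def tpt_flux(
    msm: MSMEstimate,
    A: list[int] | np.ndarray,
    B: list[int] | np.ndarray,
    state_classes: dict[int, str] | None = None,
) -> FluxNetwork:
    """Reactive A -> B flux network of the MSM.

    ``A`` and ``B`` are indices into the MSM active set.  ``state_classes``
    optionally maps active-set indices to class names; the coarse flux matrix
    then sums net flux over class pairs.
    """
    A = np.asarray(A, dtype=int)
    B = np.asarray(B, dtype=int)
    if len(np.intersect1d(A, B)):
        raise AnalysisError("overlapping endpoint sets")
    if len(A) == 0 or len(B) == 0:
        raise AnalysisError("endpoint sets must be nonempty")
    P, pi = msm.transition_matrix, msm.stationary
    qf = _committor(P, A, B)
    # backward committor from the time-reversed chain; states with pi = 0
    # carry no flux and get an absorbing row
    with np.errstate(invalid="ignore", divide="ignore"):
        Pb = np.where(pi[:, None] > 0, (P.T * pi[None, :]) / pi[:, None], 0.0)
    zero = pi == 0
    Pb[zero] = 0.0
    Pb[zero, zero] = 1.0
    qb = _committor(Pb, B, A)  # roles swapped: 1 on A, 0 on B

    f = pi[:, None] * qb[:, None] * P * qf[None, :]
    np.fill_diagonal(f, 0.0)
    fnet = np.maximum(0.0, f - f.T)
    mask = np.ones(len(pi), dtype=bool)
    mask[A] = False
    F = float(f[np.ix_(A, np.flatnonzero(mask))].sum())
    coarse = None
    if state_classes is not None:
        coarse = {}
        for i in range(len(pi)):
            for j in range(len(pi)):
                if fnet[i, j] > 0:
                    key = (state_classes[i], state_classes[j])
                    coarse[key] = coarse.get(key, 0.0) + fnet[i, j]
    return FluxNetwork(A, B, qf, qb, f, fnet, F, F / msm.lag_ns, coarse)


@dataclass
class WorkSamples:
    """Nonequilibrium pull work values with their temperature."""

    work_values: np.ndarray
    temperature: float = 310.0   # K
    units: str = "kJ/mol"        # or "kT"
    pull_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.work_values, dtype=float)
        if w.size < 1 or not np.all(np.isfinite(w)):
            raise AnalysisError("work values must be finite and nonempty")
        if self.temperature <= 0:
            raise AnalysisError("invalid temperature")
        self.work_values = w

    @property
    def kT(self) -> float:
        """Thermal energy in kJ/mol."""
        return R_KJ_PER_MOL_K * self.temperature

    def in_kT(self) -> np.ndarray:
        return self.work_values if self.units == "kT" else self.work_values / self.kT


@dataclass
class JarzynskiEstimate:
    delta_f: float               # same units as the input work
    delta_f_kT: float
    mean_work: float
    second_moment_estimate: float  # mean - var/(2 kT): Gaussian-limit check
    effective_sample_size: float
    bootstrap_se: float | None
    biased_warning: bool
    n: int


def jarzynski_free_energy(
    samples: WorkSamples,
    n_bootstrap: int = 200,
    seed: int | None = None,
    ess_warning_threshold: float = 10.0,
) -> JarzynskiEstimate:
    """Free-energy estimate dF = -kT ln mean(exp(-W/kT)) via log-sum-exp.

    Reports the Gaussian second-moment estimate mean(W) - var(W)/(2 kT) as a
    bias diagnostic, a seeded bootstrap standard error, and flags estimates
    whose exponential-weight effective sample size falls below the threshold.
    Always satisfies dF <= mean(W) (Jensen's inequality).
    """
    w_kT = samples.in_kT()
    n = len(w_kT)
    df_kT = -(logsumexp(-w_kT) - np.log(n))
    logw = -w_kT - logsumexp(-w_kT)
    ess = float(np.exp(-logsumexp(2 * logw)))
    boot_se = None
    if n_bootstrap > 0 and n > 1:
        rng = np.random.default_rng(seed)
        reps = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            res = rng.choice(w_kT, size=n, replace=True)
            reps[b] = -(logsumexp(-res) - np.log(n))
        boot_se = float(reps.std(ddof=1))
    scale = 1.0 if samples.units == "kT" else samples.kT
    mean_w = float(w_kT.mean())
    second = mean_w - float(w_kT.var()) / 2.0
    return JarzynskiEstimate(
        delta_f=float(df_kT) * scale,
        delta_f_kT=float(df_kT),
        mean_work=mean_w * scale,
        second_moment_estimate=second * scale,
        effective_sample_size=ess,
        bootstrap_se=None if boot_se is None else boot_se * scale,
        biased_warning=ess < ess_warning_threshold,
        n=n,
    )


def relative_free_energy(est_a: JarzynskiEstimate, est_b: JarzynskiEstimate) -> float:
    """ddF = dF_a - dF_b between two steered-pull targets (kT units)."""
    return est_a.delta_f_kT - est_b.delta_f_kT
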
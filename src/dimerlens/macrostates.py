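"""PCCA+ macrostate aggregation and macrostate-level interface statistics.

Microstates of a reversible MSM are aggregated into metastable macrostates
with PCCA+ (Perron cluster cluster analysis): fuzzy memberships rho_i(I) are
obtained from the inner-simplex construction on the leading right eigenvectors
of the transition matrix.  Macrostate equilibrium probabilities sum the
stationary microstate probabilities over the crisp (argmax-membership) sets,
helix-interface probability profiles

    p(D, alpha, I) = sum_{i in I, D in l_i_alpha} pi_i / pi_I

give the probability that domain D of protomer alpha is at the interface
within macrostate I, and domains with p >= 0.4 form the macrostate label.
Macrostate contact matrices are membership-weighted averages of the
microstate contact matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from dimerlens.contacts import ContactMatrix, MicrostateLabel
from dimerlens.errors import EstimationError
from dimerlens.msm import MSMEstimate, SpectralSummary


@dataclass
class MembershipMatrix:
    """Fuzzy microstate -> macrostate memberships; rows sum to 1."""

    values: np.ndarray  # n_micro x n_macro

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -1e-10) or np.any(v > 1 + 1e-10):
            raise EstimationError("memberships must lie in [0, 1]")
        if np.abs(v.sum(axis=1) - 1.0).max() > 1e-10:
            raise EstimationError("membership rows must sum to 1")
        self.values = v

    @property
    def n_macro(self) -> int:
        return self.values.shape[1]

    @property
    def crisp(self) -> np.ndarray:
        """Argmax assignment; exact ties go to the lowest macrostate index."""
        return self.values.argmax(axis=1)


@dataclass
class MacrostateDecomposition:
    memberships: MembershipMatrix
    crisp_assignment: np.ndarray
    macro_probabilities: np.ndarray                      # pi_I
    helix_profiles: dict[int, dict[str, dict[str, float]]]  # I -> {"A"/"B" -> {domain -> p}}
    macro_labels: dict[int, MicrostateLabel]
    macro_contact_matrices: dict[int, ContactMatrix] | None = None


def _right_eigenvectors(msm: MSMEstimate, m: int) -> np.ndarray:
    """First m right eigenvectors of a reversible P, pi-orthonormal, via the
    symmetrized matrix; the first column is normalized to the constant 1."""
    P, pi = msm.transition_matrix, msm.stationary
    s = np.sqrt(pi)
    sym = (s[:, None] * P) / s[None, :]
    vals, vecs = scipy.linalg.eigh((sym + sym.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if m < len(vals) and abs(vals[m - 1] - vals[m]) < 1e-10:
        raise EstimationError(
            "spectral gap too small: eigenvalues "
            f"{m} and {m + 1} are degenerate; try a different n_macro"
        )
    psi = vecs[:, :m] / s[:, None]
    psi[:, 0] = 1.0  # constant eigenvector, fixed sign/scale
    return psi


def _inner_simplex_vertices(psi: np.ndarray) -> np.ndarray:
    """Indices of the m rows of psi that span the inner simplex.

    Classic vertex search: start from the row farthest from the first pick,
    then repeatedly take the row farthest from the affine span of the
    vertices found so far (Gram-Schmidt deflation).
    """
    n, m = psi.shape
    ortho = psi.copy()
    idx = np.empty(m, dtype=int)
    idx[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho -= ortho[idx[0]]
    for k in range(1, m):
        dist = np.linalg.norm(ortho, axis=1)
        idx[k] = int(np.argmax(dist))
        v = ortho[idx[k]] / dist[idx[k]]
        ortho -= np.outer(ortho @ v, v)
    return idx


def pcca_memberships(msm: MSMEstimate, n_macro: int) -> MembershipMatrix:
    """PCCA+ fuzzy memberships from the inner-simplex construction.

    Requires a reversible estimate (real spectrum).  Tiny negative entries
    produced by the linear transform are clipped and rows renormalized.
    """
    if not msm.reversible:
        raise EstimationError("PCCA+ requires a reversible estimate")
    n = msm.n_states
    if not 1 <= n_macro <= n:
        raise EstimationError(f"n_macro must be in [1, {n}]")
    if n_macro == 1:
        return MembershipMatrix(np.ones((n, 1)))
    psi = _right_eigenvectors(msm, n_macro)
    vertices = _inner_simplex_vertices(psi)
    chi = psi @ np.linalg.inv(psi[vertices])
    chi = np.clip(chi, 0.0, 1.0)
    chi /= chi.sum(axis=1, keepdims=True)
    return MembershipMatrix(chi)


def propose_n_macro(spectral: SpectralSummary, min_ratio: float = 1.5) -> dict:
    """Suggest a macrostate count from the largest gap in the timescales.

    A gap after the m-th relaxation timescale separates m slow processes from
    the rest, i.e. m + 1 metastable states (including the stationary one).
    Advisory only; returns the full ratio table.
    """
    ts = spectral.timescales
    if len(ts) < 3:
        raise EstimationError("need at least three finite timescales")
    ratios = ts[:-1] / ts[1:]
    m = int(np.argmax(ratios)) + 1  # gap after the m-th timescale
    no_gap = bool(ratios.max() < min_ratio)
    return {
        "suggested_n_macro": m + 1,
        "gap_after_timescale": m,
        "ratios": ratios,
        "no_clear_gap": no_gap,
    }


def macrostate_statistics(
    msm: MSMEstimate,
    memberships: MembershipMatrix,
    label_dict: dict[int, MicrostateLabel],
    threshold: float = 0.4,
) -> MacrostateDecomposition:
    """Macrostate probabilities, helix profiles and threshold labels.

    Uses crisp (argmax) macrostate sets, so ``pi_I`` is a genuine partition of
    the stationary probability.
    """
    crisp = memberships.crisp
    pi = msm.stationary
    n_macro = memberships.n_macro
    pi_I = np.array([pi[crisp == I].sum() for I in range(n_macro)])
    if np.any(pi_I == 0):
        empty = np.flatnonzero(pi_I == 0).tolist()
        raise EstimationError(f"empty macrostate(s): {empty}")

    all_domains = sorted(
        {d for lab in label_dict.values() for d in lab.domains_A | lab.domains_B}
    )
    profiles: dict[int, dict[str, dict[str, float]]] = {}
    labels: dict[int, MicrostateLabel] = {}
    for I in range(n_macro):
        members = np.flatnonzero(crisp == I)
        prof = {"A": {}, "B": {}}
        for d in all_domains:
            for side in ("A", "B"):
                num = 0.0
                for i in members:
                    lab = label_dict[int(msm.active_set[i])]
                    doms = lab.domains_A if side == "A" else lab.domains_B
                    if d in doms:
                        num += pi[i]
                prof[side][d] = num / pi_I[I]
        profiles[I] = prof
        labels[I] = MicrostateLabel(
            frozenset(d for d, p in prof["A"].items() if p >= threshold),
            frozenset(d for d, p in prof["B"].items() if p >= threshold),
        )
    return MacrostateDecomposition(memberships, crisp, pi_I, profiles, labels)


def macrostate_contact_matrix(
    micro_matrices: dict[int, ContactMatrix],
    memberships: MembershipMatrix,
    msm: MSMEstimate,
    normalized: bool = True,
) -> dict[int, ContactMatrix]:
    """Membership-weighted averages C^I of the microstate contact matrices.

    With ``normalized=True`` the weights are w_i = pi_i rho_i(I) / sum_j pi_j
    rho_j(I) — a convex combination, so entries stay in [0, 1] and a singleton
    macrostate reproduces its microstate matrix exactly.  The raw form
    (``normalized=False``) is the unnormalized sum over rho_i(I) C^i.
    """
    rho = memberships.values
    pi = msm.stationary
    first = micro_matrices[int(msm.active_set[0])]
    out: dict[int, ContactMatrix] = {}
    for I in range(memberships.n_macro):
        w = pi * rho[:, I] if normalized else rho[:, I]
        if normalized:
            tot = w.sum()
            if tot == 0:
                raise EstimationError(f"empty macrostate {I}: all weights zero")
            w = w / tot
        acc = np.zeros_like(first.values)
        for i, sid in enumerate(msm.active_set):
            acc += w[i] * micro_matrices[int(sid)].values
        if normalized:
            acc = np.clip(acc, 0.0, 1.0)
            out[I] = ContactMatrix(acc, first.domains_A, first.domains_B)
        else:
            cm = ContactMatrix.__new__(ContactMatrix)
            cm.values, cm.domains_A, cm.domains_B = acc, first.domains_A, first.domains_B
            out[I] = cm
    return out
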
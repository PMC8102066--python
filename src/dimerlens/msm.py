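"""Markov state model estimation from discrete interface trajectories.

Transition counts are collected with a sliding window at lag ``tau`` and the
model is restricted to the largest strongly connected set of the count graph,
the standard prerequisite for a well-defined stationary distribution.  The
default estimator is the reversible maximum-likelihood estimator (detailed
balance enforced through the usual self-consistent iteration on the symmetric
flow matrix x_ij); the plain row-normalized non-reversible estimator is kept
for diagnostics.  Relaxation timescales follow from the eigenvalues as
``t_i = -tau / ln(lambda_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from dimerlens.errors import EstimationError
from dimerlens.contacts import MicrostateLabel


@dataclass
class MSMEstimate:
    """Estimated transition matrix with its stationary distribution."""

    lag_ns: float
    lag_frames: int
    count_matrix: np.ndarray        # full state space
    transition_matrix: np.ndarray   # active set only, row-stochastic
    stationary: np.ndarray          # over active set
    active_set: np.ndarray          # original state ids retained
    reversible: bool

    @property
    def n_states(self) -> int:
        return len(self.active_set)


@dataclass
class SpectralSummary:
    """Eigenvalues sorted by modulus (descending) and implied timescales.

    ``implied_timescales[i]`` is NaN where the corresponding eigenvalue does
    not admit a timescale (lambda_1 = 1, or lambda outside (0, 1), or complex).
    """

    eigenvalues: np.ndarray
    implied_timescales: np.ndarray
    lag_ns: float

    @property
    def timescales(self) -> np.ndarray:
        """Finite implied timescales only, slowest first."""
        t = self.implied_timescales
        return t[np.isfinite(t)]


def count_transitions(
    dtrajs: list[np.ndarray] | np.ndarray,
    lag_frames: int,
    n_states: int | None = None,
) -> np.ndarray:
    """Sliding-window transition counts C_ij = #{t : s_t=i, s_{t+lag}=j}.

    Counts never cross trajectory boundaries.
    """
    if lag_frames < 1:
        raise EstimationError("lag must be >= 1 frame")
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    usable = [d for d in dtrajs if len(d) > lag_frames]
    if not usable:
        raise EstimationError("lag too large: no trajectory longer than the lag")
    n = n_states if n_states is not None else int(max(d.max() for d in dtrajs)) + 1
    counts = np.zeros((n, n), dtype=np.int64)
    for d in usable:
        np.add.at(counts, (d[:-lag_frames], d[lag_frames:]), 1)
    return counts


def _largest_connected_set(counts: np.ndarray) -> np.ndarray:
    adj = sp.csr_matrix(counts > 0)
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    if n_comp == 0:
        raise EstimationError("disconnected data: no states observed")
    # largest component by total counts, ties broken by size
    best, best_key = None, None
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        key = (counts[np.ix_(members, members)].sum(), len(members))
        if best_key is None or key > best_key:
            best, best_key = members, key
    if best is None or counts[np.ix_(best, best)].sum() == 0:
        raise EstimationError("disconnected data: no connected transitions")
    return best


def _reversible_mle(counts: np.ndarray, tol: float = 1e-13, maxiter: int = 1_000_000):
    """Self-consistent iteration for the detailed-balance MLE.

    Iterates x_ij = (c_ij + c_ji) / (c_i/x_i + c_j/x_j) on the symmetric flow
    matrix; P_ij = x_ij / x_i and pi_i = x_i are exact detailed-balance
    solutions at every iterate, so the tolerance controls likelihood
    convergence only.
    """
    c = counts.astype(float)
    c_sym = c + c.T
    row = c.sum(axis=1)
    x = c_sym / c_sym.sum()
    for _ in range(maxiter):
        xi = x.sum(axis=1)
        denom = row[:, None] / xi[:, None] + row[None, :] / xi[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x_new = np.where(c_sym > 0, c_sym / denom, 0.0)
        x_new /= x_new.sum()
        delta = np.abs(x_new - x).max()
        x = x_new
        if delta < tol:
            break
    pi = x.sum(axis=1)
    P = x / pi[:, None]
    return P, pi


def estimate_msm(
    counts: np.ndarray,
    lag_ns: float,
    lag_frames: int,
    reversible: bool = True,
) -> MSMEstimate:
    """Estimate a transition matrix from a count matrix.

    The estimate is restricted to the largest strongly connected component.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise EstimationError("negative transition counts")
    active = _largest_connected_set(counts)
    sub = counts[np.ix_(active, active)].astype(float)
    if reversible:
        P, pi = _reversible_mle(sub)
    else:
        P = sub / sub.sum(axis=1, keepdims=True)
        vals, vecs = scipy.linalg.eig(P.T)
        k = np.argmin(np.abs(vals - 1.0))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi) / np.abs(pi).sum()
    return MSMEstimate(lag_ns, lag_frames, counts, P, pi, active, reversible)


def estimate_msm_from_dtrajs(
    dtrajs,
    lag_ns: float,
    frame_spacing: float,
    reversible: bool = True,
) -> MSMEstimate:
    """Convenience wrapper: counts + estimate with the lag given in ns."""
    lag_frames = lag_ns / frame_spacing
    if abs(lag_frames - round(lag_frames)) > 1e-9:
        raise EstimationError(
            f"lag {lag_ns} ns is not an integer number of frames "
            f"(frame spacing {frame_spacing} ns)"
        )
    lag_frames = int(round(lag_frames))
    counts = count_transitions(dtrajs, lag_frames)
    return estimate_msm(counts, lag_ns, lag_frames, reversible=reversible)


def _sorted_eigenvalues(msm: MSMEstimate) -> np.ndarray:
    P, pi = msm.transition_matrix, msm.stationary
    if msm.reversible:
        # symmetrized matrix has the same (real) spectrum
        s = np.sqrt(pi)
        sym = (s[:, None] * P) / s[None, :]
        vals = scipy.linalg.eigvalsh((sym + sym.T) / 2)
    else:
        vals = scipy.linalg.eigvals(P)
    order = np.lexsort((-np.real(vals), -np.abs(vals)))
    return vals[order]


def implied_timescales(msm: MSMEstimate) -> SpectralSummary:
    """Relaxation timescales t_i = -tau / ln(lambda_i) of the MSM eigenmodes.

    The stationary eigenvalue (lambda = 1) and eigenvalues outside (0, 1) get
    NaN instead of a timescale.
    """
    vals = _sorted_eigenvalues(msm)
    ts = np.full(len(vals), np.nan)
    for i, lam in enumerate(vals):
        if i == 0:
            continue  # stationary process
        if np.iscomplexobj(vals) and abs(np.imag(lam)) > 1e-12:
            continue
        lam_r = float(np.real(lam))
        if 0.0 < lam_r < 1.0 - 1e-14:
            ts[i] = -msm.lag_ns / np.log(lam_r)
    return SpectralSummary(vals, ts, msm.lag_ns)


def lag_scan(
    dtrajs,
    lags_frames: list[int],
    frame_spacing: float,
    n_timescales: int = 5,
    reversible: bool = True,
    rel_tol: float = 0.10,
) -> dict:
    """Implied timescales as a function of lag, with a convergence heuristic.

    Returns ``{"lags_ns", "timescales" (n_lags x n_timescales, NaN-padded),
    "converged_lag_ns"}`` where the converged lag is the smallest lag after
    which the slowest timescale changes by less than ``rel_tol`` relative to
    the next lag (advisory, not enforced).
    """
    if len(lags_frames) < 2:
        raise EstimationError("lag_scan needs at least two lags")
    lags_frames = sorted(lags_frames)
    table = np.full((len(lags_frames), n_timescales), np.nan)
    for li, lag in enumerate(lags_frames):
        m = estimate_msm(count_transitions(dtrajs, lag), lag * frame_spacing, lag,
                         reversible=reversible)
        ts = implied_timescales(m).timescales
        table[li, :min(n_timescales, len(ts))] = ts[:n_timescales]
    lags_ns = np.array(lags_frames, dtype=float) * frame_spacing
    converged = None
    for li in range(len(lags_frames) - 1):
        t0, t1 = table[li, 0], table[li + 1, 0]
        if np.isfinite(t0) and np.isfinite(t1) and abs(t1 - t0) < rel_tol * abs(t0):
            converged = lags_ns[li]
            break
    return {"lags_ns": lags_ns, "timescales": table, "converged_lag_ns": converged}


def dimeric_fraction(msm: MSMEstimate, label_dict: dict[int, MicrostateLabel]) -> float:
    """Stationary probability of being in any non-monomeric interface state."""
    missing = [s for s in msm.active_set if int(s) not in label_dict]
    if missing:
        raise EstimationError(f"label dictionary incomplete: missing states {missing}")
    mask = np.array([not label_dict[int(s)].is_monomeric for s in msm.active_set])
    return float(msm.stationary[mask].sum())
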
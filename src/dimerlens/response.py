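"""FRET and calcium fluorescence response quantification.

FRET is read out as the acceptor fraction I_A / (I_D + I_A).  Drug responses
are window means relative to a pre-application baseline, normalized within
the same recording to the response to a saturating reference application
(e.g. 1 mM glutamate); basal-activity measurements (saturating antagonist)
are reported as signed fractions of the same reference.  Concentration-
response relations are fit with the four-parameter logistic

    r(c) = bottom + (top - bottom) / (1 + (EC50 / c)^n)

in log10-concentration space with multi-start initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from dimerlens.errors import AnalysisError


@dataclass
class ApplicationWindow:
    ligand: str
    concentration: float  # M
    start: float          # s
    end: float


@dataclass
class FluorescenceTrace:
    """Dual-channel (or single-channel calcium) intensity time series."""

    time: np.ndarray
    donor: np.ndarray | None
    acceptor: np.ndarray | None
    windows: list[ApplicationWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("donor", "acceptor"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                if len(ch) != len(self.time):
                    raise AnalysisError(f"{name} channel length differs from time")
                if np.any(ch < 0):
                    raise AnalysisError(f"negative intensities in {name} channel")
                setattr(self, name, ch)
        ends = sorted((w.start, w.end) for w in self.windows)
        for (s0, e0), (s1, _) in zip(ends[:-1], ends[1:]):
            if s1 < e0:
                raise AnalysisError("application windows overlap")


def fret_index(trace: FluorescenceTrace) -> np.ndarray:
    """Pointwise acceptor fraction I_A / (I_D + I_A); NaN where both are 0."""
    if trace.donor is None or trace.acceptor is None:
        raise AnalysisError("two channels required for FRET")
    total = trace.donor + trace.acceptor
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, trace.acceptor / total, np.nan)
    return out


def _window_response(
    series: np.ndarray,
    time: np.ndarray,
    window: ApplicationWindow,
    baseline_samples: int,
) -> float:
    in_win = (time >= window.start) & (time <= window.end)
    if not in_win.any():
        raise AnalysisError(f"window [{window.start}, {window.end}] outside trace")
    start_idx = int(np.argmax(in_win))
    base_lo = max(0, start_idx - baseline_samples)
    if base_lo == start_idx:
        raise AnalysisError("no baseline samples before window onset")
    baseline = float(np.nanmean(series[base_lo:start_idx]))
    return float(np.nanmean(series[in_win])) - baseline


def normalize_response(
    series: np.ndarray,
    time: np.ndarray,
    windows: list[ApplicationWindow],
    reference: int | tuple[str, float],
    baseline_samples: int = 10,
) -> dict:
    """Baseline-subtracted window responses normalized to a reference window.

    ``reference`` is either the index of the reference window or a
    (ligand, concentration) pair identifying it.  Antagonist responses come
    out as signed fractions of the reference (negative when the window runs
    below baseline).  Gain changes of the whole recording cancel.
    """
    series = np.asarray(series, dtype=float)
    time = np.asarray(time, dtype=float)
    if isinstance(reference, int):
        ref_idx = reference
    else:
        lig, conc = reference
        matches = [i for i, w in enumerate(windows)
                   if w.ligand == lig and np.isclose(w.concentration, conc)]
        if not matches:
            raise AnalysisError(f"reference window {reference} not found")
        ref_idx = matches[0]
    responses = [_window_response(series, time, w, baseline_samples) for w in windows]
    ref = responses[ref_idx]
    if ref <= 0:
        raise AnalysisError("degenerate reference: reference response <= 0")
    return {
        "responses": np.array(responses),
        "normalized": np.array(responses) / ref,
        "reference_index": ref_idx,
        "reference_response": ref,
    }


@dataclass
class HillFit:
    ec50: float
    hill_slope: float
    top: float
    bottom: float
    log_ec50_se: float | None
    residual_rms: float
    converged: bool

    def predict(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1 + (self.ec50 / c) ** self.hill_slope)


def _four_pl(logc: np.ndarray, log_ec50: float, n: float, top: float, bottom: float) -> np.ndarray:
    expo = np.clip(n * (log_ec50 - logc), -300.0, 300.0)
    return bottom + (top - bottom) / (1.0 + 10.0 ** expo)


def fit_hill(
    concentrations: np.ndarray,
    responses: np.ndarray,
    pin_bottom: float | None = None,
    pin_top: float | None = None,
    flat_tol: float = 1e-12,
) -> HillFit:
    """Four-parameter logistic fit in log10-concentration space.

    Multi-start over a grid of initial log10 EC50 values spanning the tested
    concentrations; the best least-squares solution wins.  Scaling all
    concentrations by k scales EC50 by k and leaves slope/top/bottom alone.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if np.any(c <= 0):
        raise AnalysisError("invalid concentrations: must be > 0")
    if len(np.unique(c)) < 4:
        raise AnalysisError("need at least four distinct concentrations")
    if np.ptp(r) <= flat_tol:
        raise AnalysisError("no dynamic range: responses are flat")
    logc = np.log10(c)

    lo, hi = float(r.min()), float(r.max())
    increasing = np.corrcoef(logc, r)[0, 1] >= 0

    def model(lc, *params):
        if pin_bottom is not None and pin_top is not None:
            return _four_pl(lc, params[0], params[1], pin_top, pin_bottom)
        if pin_bottom is not None:
            return _four_pl(lc, params[0], params[1], params[2], pin_bottom)
        return _four_pl(lc, *params)

    best = None
    for lec0 in np.linspace(logc.min(), logc.max(), 7):
        for n0 in (1.0, 2.0) if increasing else (-1.0, -2.0):
            if pin_bottom is not None and pin_top is not None:
                p0 = [lec0, n0]
            elif pin_bottom is not None:
                p0 = [lec0, n0, hi if increasing else lo]
            else:
                p0 = [lec0, n0, hi if increasing else lo, lo if increasing else hi]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", OptimizeWarning)
                    popt, pcov = curve_fit(model, logc, r, p0=p0, maxfev=10000)
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((model(logc, *popt) - r) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt, pcov)
    if best is None:
        raise AnalysisError("Hill fit did not converge from any start")
    rss, popt, pcov = best
    log_ec50, n = float(popt[0]), float(popt[1])
    if pin_bottom is not None and pin_top is not None:
        top, bottom = pin_top, pin_bottom
    elif pin_bottom is not None:
        top, bottom = float(popt[2]), pin_bottom
    else:
        top, bottom = float(popt[2]), float(popt[3])
    # report with top >= bottom and positive slope direction made explicit
    if top < bottom:
        top, bottom, n = bottom, top, -n
    se = None
    if pcov is not None and np.all(np.isfinite(pcov)):
        se = float(np.sqrt(pcov[0, 0]))
    return HillFit(
        ec50=10.0 ** log_ec50,
        hill_slope=n,
        top=top,
        bottom=bottom,
        log_ec50_se=se,
        residual_rms=float(np.sqrt(rss / len(r))),
        converged=True,
    )
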
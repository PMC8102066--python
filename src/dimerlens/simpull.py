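"""Single-molecule pulldown (SiMPull) subunit-counting statistics.

Spots immobilized from detergent lysate photobleach in discrete steps; the
step count reports the number of labeled subunits.  The per-movie fraction of
two-step spots is converted to a percent dimerization by min-max
normalization against two calibration anchors: the fluorescence background
(default 5%) and the two-step percentage of an obligate full-length dimer
(default 55%) — no expression-level correction is applied.  Ligand conditions
are compared as percent change of the per-movie mean against a no-drug
reference, and two-color pulldowns are quantified as background-subtracted
prey/bait spot-count ratios normalized to a same-day homodimer control.

An automated change-point step counter is provided for synthetic traces; the
primary input contract is pre-classified per-spot step counts (TSV with
columns movie_id, spot_id, steps, condition, channel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dimerlens.errors import AnalysisError

DISCARDED = "discarded"

#: default min-max calibration anchors (percent two-step photobleaching)
BACKGROUND_MIN_PERCENT = 5.0
OBLIGATE_DIMER_MAX_PERCENT = 55.0


# ---------------------------------------------------------------------------
# automated step counting (optional plumbing; manual counts are the contract)
# ---------------------------------------------------------------------------

def _best_split(y: np.ndarray) -> tuple[int, float]:
    """Best single change point by SSE reduction (O(n) via cumulative sums)."""
    n = len(y)
    c1, c2 = np.cumsum(y), np.cumsum(y * y)
    total = c2[-1] - c1[-1] ** 2 / n
    best_k, best_gain = -1, 0.0
    for k in range(1, n):
        left = c2[k - 1] - c1[k - 1] ** 2 / k
        right = (c2[-1] - c2[k - 1]) - (c1[-1] - c1[k - 1]) ** 2 / (n - k)
        gain = total - left - right
        if gain > best_gain:
            best_k, best_gain = k, gain
    return best_k, best_gain


def count_steps(
    trace: np.ndarray,
    noise_sd: float | None = None,
    max_steps: int = 4,
    min_drop_sd: float = 3.0,
) -> int | str:
    """Count downward photobleaching steps by iterative change-point fitting.

    A piecewise-constant model is grown greedily: a split is accepted while it
    reduces the residual sum of squares by more than a BIC-style penalty of
    ``2 sigma^2 ln(n)``.  Steps smaller than ``min_drop_sd`` noise standard
    deviations are ignored; traces with a comparable upward jump (blinking /
    second molecule arriving), with no step at all, or with more than
    ``max_steps`` steps return :data:`DISCARDED`.
    """
    y = np.asarray(trace, dtype=float)
    if len(y) < 20:
        raise AnalysisError("trace too short (< 20 samples)")
    if np.all(y <= 0):
        return DISCARDED
    if noise_sd is None:
        diffs = np.diff(y)
        noise_sd = float(np.median(np.abs(diffs - np.median(diffs)))) / 0.6745 / math.sqrt(2)
        noise_sd = max(noise_sd, 1e-9)
    penalty = 2.0 * noise_sd**2 * math.log(len(y))

    boundaries = [0, len(y)]
    changed = True
    while changed:
        changed = False
        for si in range(len(boundaries) - 1):
            lo, hi = boundaries[si], boundaries[si + 1]
            if hi - lo < 4:
                continue
            k, gain = _best_split(y[lo:hi])
            if k > 0 and gain > penalty:
                boundaries.insert(si + 1, lo + k)
                changed = True
                break
    levels = [y[boundaries[i]:boundaries[i + 1]].mean() for i in range(len(boundaries) - 1)]
    n_down, n_up = 0, 0
    for a, b in zip(levels[:-1], levels[1:]):
        if a - b > min_drop_sd * noise_sd:
            n_down += 1
        elif b - a > min_drop_sd * noise_sd:
            n_up += 1
    if n_up > 0 or n_down == 0 or n_down > max_steps:
        return DISCARDED
    return n_down


# ---------------------------------------------------------------------------
# step-count distributions and dimerization normalization
# ---------------------------------------------------------------------------

def step_distribution(spots: pd.DataFrame, max_step: int = 4) -> pd.DataFrame:
    """Per-movie step-count fractions over the analyzed (non-discarded) spots.

    ``spots`` needs columns ``movie_id`` and ``steps`` (integers 1..4 or the
    string 'discarded').  Returns one row per movie with n_analyzed,
    fraction_1..fraction_4 and percent_two_step; movies with only discarded
    spots are excluded.
    """
    if "movie_id" not in spots or "steps" not in spots:
        raise AnalysisError("spot table needs movie_id and steps columns")
    rows = []
    for movie, grp in spots.groupby("movie_id", sort=True):
        steps = grp["steps"]
        analyzed = steps[steps.astype(str).str.lower() != DISCARDED]
        n = len(analyzed)
        if n == 0:
            continue  # only discarded spots: excluded with no summary row
        counts = analyzed.astype(int).value_counts()
        if not set(counts.index) <= set(range(1, max_step + 1)):
            bad = sorted(set(counts.index) - set(range(1, max_step + 1)))
            raise AnalysisError(f"step counts outside 1..{max_step}: {bad}")
        row = {"movie_id": movie, "n_analyzed": n}
        for s in range(1, max_step + 1):
            row[f"fraction_{s}"] = counts.get(s, 0) / n
        row["percent_two_step"] = counts.get(2, 0) / n * 100.0
        rows.append(row)
    if not rows:
        raise AnalysisError("no movie with analyzed spots")
    return pd.DataFrame(rows)


def percent_dimerization(
    observed_two_step: float,
    min_value: float = BACKGROUND_MIN_PERCENT,
    max_value: float = OBLIGATE_DIMER_MAX_PERCENT,
) -> float:
    """Min-max normalized percent dimerization.

    ((observed - min) / (max - min)) * 100, with the background anchor mapping
    to 0 and the obligate-dimer anchor to 100.  Values are *not* clipped;
    use :func:`dimerization_in_range` to flag out-of-range results.
    """
    if max_value <= min_value:
        raise AnalysisError("invalid calibration: max_value must exceed min_value")
    return (observed_two_step - min_value) / (max_value - min_value) * 100.0


def dimerization_in_range(value: float) -> bool:
    return 0.0 <= value <= 100.0


@dataclass
class DimerizationResult:
    condition: str
    per_movie_values: np.ndarray
    mean_percent_dimerization: float
    sem: float | None          # None with a single movie
    n_movies: int
    min_value: float
    max_value: float
    out_of_range: bool         # any per-movie value outside [0, 100]


def dimerization_by_condition(
    spots: pd.DataFrame,
    min_value: float = BACKGROUND_MIN_PERCENT,
    max_value: float = OBLIGATE_DIMER_MAX_PERCENT,
) -> dict[str, DimerizationResult]:
    """Per-condition dimerization: normalize per movie, then average movies.

    Per-movie normalization before averaging (rather than normalizing the
    pooled distribution) weights each movie equally, matching reporting of a
    per-movie mean with an s.e.m. over movies.
    """
    if "condition" not in spots:
        spots = spots.assign(condition="all")
    out: dict[str, DimerizationResult] = {}
    for cond, grp in spots.groupby("condition", sort=True):
        summary = step_distribution(grp)
        vals = np.array([
            percent_dimerization(p, min_value, max_value)
            for p in summary["percent_two_step"]
        ])
        n = len(vals)
        out[str(cond)] = DimerizationResult(
            condition=str(cond),
            per_movie_values=vals,
            mean_percent_dimerization=float(vals.mean()),
            sem=float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else None,
            n_movies=n,
            min_value=min_value,
            max_value=max_value,
            out_of_range=bool(np.any((vals < 0) | (vals > 100))),
        )
    return out


def aggregate_conditions(
    per_movie: dict[str, list[float] | np.ndarray],
    reference_condition: str,
) -> pd.DataFrame:
    """Condition means +/- s.e.m. and percent change versus the reference.

    ``per_movie`` maps condition name to its per-movie dimerization values.
    The ligand shift is (mean_drug - mean_reference) / mean_reference * 100.
    """
    if reference_condition not in per_movie:
        raise AnalysisError(f"reference condition absent: {reference_condition!r}")
    ref_mean = float(np.mean(per_movie[reference_condition]))
    rows = []
    for cond, vals in per_movie.items():
        vals = np.asarray(vals, dtype=float)
        n = len(vals)
        if n < 1:
            raise AnalysisError(f"condition {cond!r} has no movies")
        rows.append({
            "condition": cond,
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else np.nan,
            "n_movies": n,
            "percent_change_vs_reference":
                (float(vals.mean()) - ref_mean) / ref_mean * 100.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-color pulldown ratios
# ---------------------------------------------------------------------------

@dataclass
class TwoColorCounts:
    """Spot counts of a two-color pulldown (bait channel vs prey channel)."""

    n_red: int          # bait (e.g. LD655) spots
    n_green: int        # prey (e.g. DY547) spots
    n_background: int   # prey spots in the bait-free control

    def __post_init__(self) -> None:
        if min(self.n_red, self.n_green, self.n_background) < 0:
            raise AnalysisError("spot counts must be nonnegative")


def two_color_ratio(counts: TwoColorCounts, same_day_homodimer_ratio: float) -> dict:
    """Background-subtracted prey/bait ratio, normalized to the homodimer control.

    The background-subtracted prey count is floored at zero.
    """
    if counts.n_red == 0:
        raise AnalysisError("no bait spots")
    if same_day_homodimer_ratio <= 0:
        raise AnalysisError("homodimer reference ratio must be > 0")
    raw = max(0, counts.n_green - counts.n_background) / counts.n_red
    return {"raw_ratio": raw, "normalized_ratio": raw / same_day_homodimer_ratio}


# ---------------------------------------------------------------------------
# dimer-fraction inversion (binomial labeling model)
# ---------------------------------------------------------------------------

def estimate_dimer_fraction(two_step_fraction: float, label_efficiency: float) -> float:
    """Invert the binomial labeling model for the underlying dimer fraction.

    Among visible spots, dimers (labeling efficiency p per subunit) show two
    steps with probability p^2 / (1 - (1-p)^2) = p / (2 - p) and monomers are
    always one-step, so the visible two-step fraction t satisfies
    t = f_d p / (1 + f_d (1 - p)); solving gives
    f_d = t / (p - t (1 - p)).
    """
    p, t = label_efficiency, two_step_fraction
    if not 0 < p <= 1:
        raise AnalysisError("label efficiency must be in (0, 1]")
    denom = p - t * (1 - p)
    if denom <= 0:
        raise AnalysisError("two-step fraction inconsistent with label efficiency")
    return t / denom
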
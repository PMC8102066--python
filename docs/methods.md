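# Methods

This note documents the models implemented in `dimerlens`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions taken where the design was genuinely open.

## Interface discretization

The relative arrangement of two protomers is summarized per frame by which
domains of each protomer touch the partner.  A residue pair (one residue per
protomer) is *in contact* when the minimum Euclidean distance over its bead
pairs is ≤ `contact_cutoff` (default **1.0 nm**, inclusive at the boundary —
the strict/inclusive choice at an exact boundary is immaterial for noisy
coordinates but is fixed here for reproducibility).  A domain enters a
protomer's interface label when it forms **strictly more than**
`label_count_threshold` = 20 contacts with the other protomer.  Both sets
empty means the frame is monomeric.

Two counting modes are provided because "number of residue contacts" is
ambiguous:

* `residue_pairs` (default): each contacting residue pair counts once for
  the domain of its A-residue and once for the domain of its B-residue.
  A >20 threshold is then reachable by a well-packed single-helix
  interface, which matches the scale of observed interface labels.
* `residues`: each residue with ≥1 contact counts once.  With ~25 residues
  per helix a >20 threshold would require nearly the full helix in
  contact; the mode is retained for sensitivity analysis.

Per-microstate contact matrices `C_{DD'}` record, at a tighter
`contact_matrix_cutoff` = **0.9 nm**, the fraction of the microstate's
frames in which *any* residue of domain D (protomer A) is within the
cutoff of any residue of domain D' (protomer B).  The domain-level
any-pair event was chosen (rather than averaging per residue pair) because
the matrix is indexed by domains and the quantity of interest is "do these
two domains touch in this state".

All lengths are stored in nanometers; ångström inputs are converted on
load (×0.1, exact).  Frames with missing beads are rejected rather than
imputed, and no periodic-boundary minimum-image correction is applied —
inputs are assumed unwrapped (a documented limitation for raw simulation
output).

The optimized distance kernel computes `sqrt(dx² + dy² + dz²)` with the
same floating-point operation order as a naive per-pair loop, so it can be
(and is) tested for *exact* equality against a brute-force oracle.

## Markov state model

Transition counts use a sliding window at lag τ
(`C_ij = #{t : s_t = i, s_{t+τ} = j}`), never crossing trajectory
boundaries; sliding-window counting maximizes data use.  Estimation is
restricted to the largest strongly connected component of the count graph
(largest by total counts), the standard prerequisite for a well-defined
stationary distribution.

Two estimators are provided:

* **Reversible MLE** (default): the usual self-consistent iteration on the
  symmetric flow matrix, `x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j)`.
  Every iterate satisfies detailed balance exactly; iteration (tolerance
  1e-13 on the parameters, capped at 10⁶ sweeps) only refines the
  likelihood.  The reversible estimate has a real spectrum, which PCCA+
  requires.
* **Non-reversible**: row-normalized counts with the stationary vector
  from the leading left eigenvector.  This is the right choice for data
  whose generating process genuinely violates detailed balance — e.g. the
  scripted toy-dimer trajectories, which cycle deterministically through
  their schedule; on such data the reversible estimator visibly distorts
  `π` while the non-reversible one recovers occupancies.

Implied timescales are `t_i = −τ / ln λ_i` for eigenvalues in (0, 1),
sorted by modulus (ties by real part); the stationary eigenvalue and any
negative or complex eigenvalues are reported without a timescale.  The lag
scan flags the smallest lag after which the slowest timescale changes by
<10% between successive lags — advisory, mirroring the usual visual
flatness criterion, not enforced.

The *dimeric fraction* is the stationary probability of all states whose
interface label is non-empty on either protomer.

## PCCA+ macrostates

Memberships come from the inner-simplex construction on the first
`n_macro` right eigenvectors of the reversible transition matrix
(computed via the symmetrized matrix `D^{1/2} P D^{-1/2}` for numerical
stability, first eigenvector normalized to the constant 1): the algorithm
selects the `n_macro` most-spread rows as simplex vertices by repeated
Gram–Schmidt deflation and maps all rows through the inverse vertex
matrix.  No subsequent objective optimization is performed (the classic
vertex scheme); tiny negative entries from the linear transform are
clipped and rows renormalized, preserving row sums at 1e-12.  A
degenerate eigenvalue pair at the spectral cut raises an error suggesting
a different `n_macro`.

Macrostate statistics use **crisp** (argmax-membership, ties to the lowest
index) sets, so `π_I` genuinely partitions the stationary probability.
Helix profiles are conditional interface probabilities
`p_{D,α,I} = Σ_{i∈I, D∈l_iα} π_i / π_I`, and domains with `p ≥ 0.4` form
the macrostate label.  Macrostate contact matrices are convex combinations
`C^I = Σ_i w_i C^i` with `w_i = π_i ρ_i(I) / Σ_j π_j ρ_j(I)`; the
unnormalized membership-weighted sum is also exportable, but the
normalized form is the contract because it reduces exactly to `C^i` for a
singleton macrostate and keeps entries in [0, 1].

The suggested macrostate count maximizes the ratio of successive
timescales `t_m / t_{m+1}` (a gap after `m` slow processes implies `m+1`
metastable states); a maximum ratio below 1.5 is flagged as "no clear
gap".  The suggestion is advisory; the count is ultimately a user input.

## Interface classes and reactive flux

Labels are mapped to swap-invariant, loop-insensitive canonical forms:
drop non-helix domains, forget the protomer order.  This single
canonicalization simultaneously merges labels that differ only in loops
and labels that are protomer swaps of each other — the two aggregation
conditions are most naturally read as alternative routes into the same
equivalence class; requiring both *jointly* would aggregate almost
nothing, so the strict-AND variant exists only behind a flag for
comparison.

Transition path theory follows the standard construction: forward
committors from the linear system `q⁺_i = Σ_j P_ij q⁺_j` on intermediates
with `q⁺ = 0` on the source set and 1 on the sink set; backward committors
from the time-reversed chain (equal to `1 − q⁺` under detailed balance,
which is asserted); gross flux `f_ij = π_i q⁻_i P_ij q⁺_j`; net flux
`f⁺ = max(0, f − fᵀ)`.  Total flux is reported per lag step and per ns,
and the coarse flux matrix sums net flux over class pairs.  Endpoint sets
are user inputs (typically the monomeric class versus a named interface).

## Jarzynski free energies

`ΔF = −kT ln⟨e^{−W/kT}⟩` evaluated with log-sum-exp; kT from the molar gas
constant (0.008314462618 kJ mol⁻¹ K⁻¹) times the declared temperature,
with work accepted in kJ/mol or kT.  The estimator is biased for small
samples, so the result carries: the Gaussian second-moment estimate
`⟨W⟩ − var(W)/2kT` (for a Gaussian work distribution the exact limit), a
seeded bootstrap standard error (default 200 resamples), and an
effective-sample-size warning (`ESS = 1/Σ w̃_i²` of the normalized
exponential weights; warn below 10).  `ΔF ≤ ⟨W⟩` (Jensen) holds by
construction and is asserted in tests.  Relative ΔΔF between two pull
targets is a plain difference.

## SiMPull counting

Per-movie step-count fractions are computed over analyzed (non-discarded)
spots only; `%2-step = n₂ / n_analyzed × 100`, with ≥3-step spots in the
denominator but not the numerator.  Percent dimerization min-max
normalizes against two calibration anchors — fluorescence background
(default 5%) and the two-step percentage of an obligate dimer (default
55%) — without clipping (out-of-range values are flagged) and without any
expression-level correction.  Conditions are summarized as unweighted
per-movie means with s.e.m. over movies: normalizing per movie and then
averaging weights each movie equally and is how a per-movie s.e.m. is
meaningful; pooling spots first is available by computing on the pooled
distribution directly, and the two paths differ whenever movies vary in
spot count.  Two-color pulldown ratios subtract the bait-free background
from the prey count (floored at 0), divide by bait spots, and normalize to
a same-day homodimer control.

The automated step counter is optional plumbing (the primary contract is
pre-classified counts): greedy binary segmentation of a piecewise-constant
model, accepting a split while it reduces the residual sum of squares by
more than `2σ² ln n`, then counting downward level changes larger than 3σ.
Traces with an upward jump, no step, or more than 4 steps are discarded.
It ignores blinking and partial bleaching by design.

The binomial labeling model inverts to a dimer-fraction estimator: with
per-subunit labeling efficiency p, the visible two-step fraction is
`t = f_d p / (1 + f_d (1 − p))`, hence `f_d = t / (p − t(1 − p))`.  At
`f_d = 1` the visible two-step fraction is `p/(2 − p)`, which equals the
55% calibration anchor at p ≈ 0.71.

## Fluorescence responses

FRET index `I_A/(I_D + I_A)` pointwise (NaN where both channels are zero).
Window responses are means over the application window minus the mean of a
pre-application baseline (default 10 samples ending at onset; the width is
configurable because acquisition rates vary), normalized to the saturating
reference response in the same recording — whole-recording gain changes
cancel.  Antagonist (basal-activity) responses come out signed.

The Hill fit is the four-parameter logistic in log10-concentration space,
`r = bottom + (top − bottom) / (1 + 10^{n(log EC50 − log c)})`, multi-start
over 7 initial log-EC50 values × 2 slopes, best RSS wins.  Bottom is fit by
default (pinning available) because basal/antagonist data can sit below
zero.  EC50 equivariance under concentration-unit changes and the reported
log-space standard error follow from fitting in log space.

## Sequence conservation

Six side-chain chemistry classes partition the 20 standard residues:
aliphatic GAVLI; hydroxyl/sulfur SCTM; cyclic P; aromatic FYW; basic HKR;
acidic+amides DENQ.  A column is identical iff all residues are equal and
conserved iff all residues share one class (identity therefore implies
conservation); ambiguity codes (B, Z, X, U) are rejected rather than
guessed.  Gap-containing columns count as neither — the conservative
choice, flagged per column.  Column subsets (helices, outward-facing
residues) are user-supplied index lists, optionally mapped from residue
numbers of an ungapped reference sequence.

## Synthetic generators

All generators are seeded (NumPy `default_rng`) and byte-reproducible.

* `simulate_chain` samples Markov trajectories from any row-stochastic
  matrix, starting from the stationary distribution.
  `block_transition_matrix` builds symmetric (hence reversible,
  uniform-π) metastable chains with planted blocks; default inter-block
  coupling 1e-3 gives timescale separations of ~two orders of magnitude.
* `build_toy_dimer` constructs idealized protomers — helices as 12-bead
  columns (0.3 nm spacing) on a ring of radius 2.5 nm, 2-residue loops
  near the axis — and realizes each scheduled single-helix interface by
  rotating protomer B so the requested helix pair faces at a 0.7 nm gap
  (54 residue-pair contacts, comfortably above the >20 threshold, with
  the nearest off-interface helix ~2.5 nm away).  Monomer segments
  separate the protomers by 10 nm.  Coordinates get 0.01 nm Gaussian
  jitter; every frame is re-verified against an independent brute-force
  contact oracle and an unrealizable schedule raises.  Its guarantees
  hold under residue-pair counting; it makes no attempt at physically
  realistic bead chemistry, membrane context, or gradual
  association/dissociation pathways — passing tests demonstrate the
  correctness of the analysis rules, not force-field realism.
* `simulate_photobleaching` draws monomer/dimer spots under binomial
  labeling, emits only visible spots, and admixes coincidental
  colocalization (default rate 0.03, matching a small ≥3-step
  population); blinking and incomplete bleaching are not modeled.
* `simulate_dose_response` / `simulate_fret_trace` produce 4PL responses
  with multiplicative noise and two-channel traces with anti-correlated
  donor/acceptor window responses.
* `simulate_alignment` plants per-column properties (identical /
  class-conserved / free) exactly.
* `simulate_work` draws Gaussian work in kT units, for which the
  Jarzynski limit `μ − σ²/2` is analytic.

## Problem sizes and tolerances

The verification suite uses 20 × 50,000-step chains for MSM recovery
(max-abs error ≤ 0.01), a 9-state/3-block chain for PCCA+ recovery, an
800-frame scripted toy trajectory for the end-to-end pipeline (dimeric
fraction within ±0.03 of the scheduled 0.75), 10⁶ Gaussian work samples
for the Jarzynski limit (±0.2 kT), 2,000 spots for dimer-fraction
recovery (±0.05), 100 noisy dose-response seeds for EC50 recovery (median
log10 error < 0.07), and 500 traces for the step counter (≥95% correct).
These sizes keep each check well inside its statistical tolerance while
running the whole suite in well under a minute of compute.  Linear-algebra
identities (row-stochasticity, stationarity, detailed balance, committor
boundary conditions, flux conservation, membership row sums) are asserted
at 1e-10 or tighter.

## Known limitations

* No Bayesian MSM error bars, hidden Markov models, or
  Chapman–Kolmogorov testing beyond the lag scan.
* No non-reversible coarse-graining (GPCCA); PCCA+ requires the
  reversible estimator.
* No Crooks/BAR estimators for the work analysis.
* No image processing: SiMPull inputs are per-spot records, fluorescence
  inputs are extracted traces.
* Contact analysis assumes unwrapped coordinates (no minimum-image
  handling).
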
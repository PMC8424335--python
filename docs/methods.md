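# Methods

## Model class and assumptions

The package works with deterministic ODE models of small gene circuits at
bulk-culture scale (high molecular copy number, large reaction volume), so
measurement noise is additive on the outputs and the dynamics themselves
are noise-free. Network structure is always a property of a *linearization*
about an operating point — an equilibrium, or any nominal state for
transient/oscillatory regimes (a warning, not an error, is raised for
non-equilibrium points). The measured species must be a subset of the
state with identity readout (`C = [I 0]`); the circuits module reorders
states measured-first so the algebra layer never deals with permutations.

The dynamical structure function `(Q, P)` is computed by eliminating the
hidden block with the Faddeev–LeVerrier resolvent (numeric path) or sympy
matrix inversion (symbolic path, used for structural verification such as
the event-detector closed forms). Q's zero diagonal and the strict
properness of all entries are enforced as type invariants.

## Built-in circuits and parameters

Rate parameters follow their published values numerically, but the printed
unit bookkeeping is internally inconsistent (first-order rate constants
carrying concentration units), so the time and concentration units are
treated as abstract throughout.

* **Feedforward loop (ideal / loaded)** — 3 proteins (measured) + 3 mRNAs
  (hidden); protein production rates ρ = (641.4, 585.1, 652.8),
  transcription rates α = (7.8, 7.1, 7.92), degradation Michaelis constants
  k_d = 200, inducer Michaelis constants k_M,u = 4000, protease capacity
  C₀ = 1, mRNA turnover δ_m = 10. The TetR-repression Michaelis constant
  (k_M,2, no published value) defaults to 200, the scale of the other
  protein-binding constants. The loaded variant shares one saturable
  protease pool across all three degradation tags — the crosstalk
  mechanism.

  Two consequences of these numbers matter for experiment design. First,
  at strong induction (u ≳ 10) protein production exceeds the protease
  capacity C₀ and **no equilibrium exists**; feasible stable operating
  points need u₁ of order 1–10. The reference baseline
  `IFFL_BASELINE_INPUT = (1.6, 0.02, 4.0)` puts both variants at stable,
  well-separated positive equilibria (the loaded circuit loses its
  equilibrium near 1.5× this level as total protease demand approaches
  capacity) with every designed edge at least ~20% of the maximum edge
  gain. Second, the aTc input u₃ enters only through
  `x₂/(k_M,2 + u₃/k_M,u3)` and has almost no authority at these scales —
  one reason the estimation studies do not use the circuit's own inducers
  (below).

* **Event detector** — 4 proteins + 4 mRNAs, two measured (the memory
  module's TetR and LacI reporters), two inducer inputs. No published
  parameter values exist; implementation defaults are k_i = 10, k_l = 0.01,
  ρ_i = 5, δ_p = 0.1, δ_m = 1, k_M = 1000 (abstract units). Note the
  NIMPLY promoter model is non-cooperative (effective Hill coefficient 1),
  and a non-cooperative mutual-repression toggle is structurally
  monostable — the model reproduces the circuit's *network structure*, not
  the latching bistability of the physical implementation (which relies on
  cooperative repression and growth-phase effects). The symbolic DSF of
  this model, under parameter symmetry, is verified exactly against its
  closed forms.

* **Repressilator stand-in** — a generic 3-node cyclic repressor ring
  (Hill coefficient 2, hidden mRNAs, influence pattern y1←y3, y2←y1,
  y3←y2) with per-node gain attenuation factors (for deliberate-imbalance
  scenarios) and an optional shared-degradation loading term (K_load,
  default large enough to be inert). It reproduces the cyclic Q-support
  and step-inhibitor input design, not the full in-vitro genelet
  chemistry.

## Perturbation experiments (the synthetic-data generator)

A `StepDesign` applies one step per measured node — serially within one
trajectory or one trajectory per node. Steps are held by default (an added
DNA inhibitor does not degrade); a finite `duration` turns them into
pulses. Two input modes:

* `direct` (default): an additive rate perturbation injected straight into
  each measured node — the "pipette a small amount of inhibitor at node i"
  design. Its linearization has `B1 = I, B2 = 0`, so the control structure
  is **exactly** the diagonal `P = (sI − D)⁻¹`, which is precisely the
  identifiability premise of the estimator.
* `model`: steps on the circuit's own inducers. Useful for simulating
  induction experiments, but note that shared promoters break diagonality
  (in the feedforward loop, HSL drives two mRNAs at once, giving a
  genuinely non-diagonal P); the structured estimator is then
  misspecified by construction.

Noise is i.i.d. Gaussian on measured outputs only, with a mandatory seed;
`noise_relative=True` scales the standard deviation to each channel's peak
deviation (so "1% noise" means a per-channel signal-to-noise ratio of
100). Linearized generation (`linearized=True`) steps the exact
discrete-time map of the linearization; otherwise the stiff ODE is
integrated (BDF, rtol 1e-8 / atol 1e-10) segment-by-segment so input
discontinuities never cross an integrator step.

What the generator does *not* emulate: cell growth and dilution drifts,
stochastic (low-copy) kinetics, fluorophore maturation, and plate-reader
drift/background. Passing tests therefore demonstrate correctness of the
method under its own model class, not robustness to those effects.

### Reference study conditions

The end-to-end crosstalk-detection study uses the feedforward pair at the
reference baseline, `direct` serial perturbations with amplitude 0.013
(≈10–15% steady-state deflection per node), dt = 10, traces of length
26 500 (onsets at 2 500 / 10 500 / 18 500, several times the slowest
closed-loop time constant apart), and **N_exp = 12 replicate trajectories**
per suite, rotating the onset order and alternating held steps with 4 000
-long pulses. The replicate count follows from a variance analysis: the
worst-case gain of a noise-fitted spurious entry scales like
1/√(total samples) *independently of the signal-to-noise ratio* (the
offending coefficient combinations live in noise-scale regressor
directions), and ~30 000 stacked samples push that floor safely below the
0.05 normalized-gain edge threshold while the weakest genuine edge sits
near 0.17–0.22.

## Estimation numerics

* Regression columns per row: `n_d` own-output lags, `n_d` lags of every
  other output, `n_d` lags of the row's own input; structural zeros have
  no columns at all, so estimated `diag Q` and off-diagonal `P` are
  exactly zero.
* Least squares runs on the column-normalized matrix (max-abs scaling);
  condition numbers are reported on the scaled problem so they measure
  collinearity, not channel units. Rank-revealing `lstsq` with
  rcond = 1e-10; optional ridge (default 0); grid points with cond above
  1e12 are rejected, above 1e8 logged.
* `h_max` is realized as equal-stride **block-mean decimation**: each
  retained point is the average of its stride block. The averaging filter
  is applied identically to all outputs and inputs, so the LTI relation
  between them is preserved while per-sample noise shrinks by √stride.
* Hyperparameter search is exhaustive over the (n_d, h_max) grid:
  coefficients are fitted on the leading 75% of each trace and scored by
  free-run L1 error on the held-out tail; scores within 1e-6 relative are
  ties, broken toward smaller n_d then smaller h_max (parsimony); the
  winner is refitted on the full data. Free-run prediction is per-row
  (the row's own output is recursed; other outputs and the input stay
  measured), matching the row-wise p×1 structure of the model — rows may
  carry different strides, so a coupled all-row recursion would be
  ill-defined.
* Accuracy is `100·max(0, 1 − Σ|ŷ−y| / Σ|y|)` on detrended signals — the
  floor-at-zero normalized-L1 definition is this package's convention.
* Discrete-to-continuous: Tustin (default), zero-order-hold inversion via
  the matrix logarithm, or matched pole-zero with DC gain matching. The
  bilinear map does not preserve relative degree, so Tustin-converted
  entries are proper with a (usually small) feedthrough; zoh and matched
  preserve strict properness. A denominator root at z = −1 makes Tustin
  singular and the error message says to switch method. Entries are
  minimally cancelled before conversion so coincident poles across a
  row's entries cannot split numerically.

## Algebra-layer numerical policy

* Descending-power coefficients, monic denominators; the zero function is
  `0/1`. Pole-proximity guard on evaluation at 1e-12 relative.
* Near-common numerator/denominator root pairs are cancelled at 1e-7
  relative when explicitly requested (`cancel()`); *automatic*
  cancellation inside the derivation pipeline uses 1e-12, because
  genuinely common factors (the shared `det(sI − A22)`) agree to machine
  precision and anything looser measurably perturbs true poles (the
  pointwise DSF/transfer-function consistency is ~1e-14 without
  cancellation and degrades to ~1e-7 with aggressive pairing).
* Inverse Laplace kernels come from partial fractions with clustered poles
  (repeated poles yield polynomial-times-exponential terms); the
  independent check is a state-space `expm` simulation.
* H∞ is a 2000-point log-sweep over ω ∈ [1e-6, 1e6] plus DC, refined by
  bounded scalar maximization — adequate at desk scale without a
  Hamiltonian eigensolver. H2 uses the controllability-Gramian closed
  form (Lyapunov solve).
* The fully symbolic closed-loop `G = (I − Q)⁻¹P` (polynomial adjugate)
  accumulates roundoff with degree growth; it is accurate to ~1e-6
  relative on random 5-state systems, whereas the pointwise evaluation
  used for consistency checking is exact to ~1e-11. Use pointwise
  evaluation for quantitative work.

## First-order crosstalk prediction

For an idealized/loaded model pair driven by the same input step of
relative amplitude ε about their own equilibria, subtracting the two
linearized relations gives the complete first-order prediction of the
trajectory deviation ζ = y_ideal − y_loaded:

    L(ζ) ≈ (I − Q_a)⁻¹ [ (Q_a − Q_c) L(y_c) + (P_a − P_c) L(u) ],

with a remainder quadratic in ε. The package evaluates both sides with
finite-horizon Laplace transforms on a positive real s-grid
(trapezoidal quadrature, horizon ≥ several slowest time constants) and
reports the root-sum-square mismatch; halving ε shrinks it ~fourfold
(measured ratio ≈ 0.246 on the feedforward pair, bound 0.25 plus
truncation effects). The loaded trajectory's transform is used for the
first-order term; using the idealized one changes the remainder only at
second order.

## Known limitations

* Order selection is grid search with a parsimony tie-break; no
  Hankel-rank or information-criterion machinery.
* The H∞ of estimated entries integrates frequencies up to and beyond the
  sampling Nyquist where the data carry little information; with short,
  single-trace data this inflates spurious-edge gains (hence the
  replicate-based study design).
* Edge classification has no statistical significance machinery
  (no bootstrap bands); the normalized-gain threshold is a fixed design
  parameter (default 0.05, with the gain-mismatch band [0.5, 2]).
* Delay systems, descriptor systems, and stochastic single-cell inference
  are out of scope.
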
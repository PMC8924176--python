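# Methods

## The targeting model

Cas9-sgRNA recognition of a DNA target is modelled as a continuous-time
Markov chain over 22 states: free enzyme in solution (n = −1), PAM-bound
with a closed R-loop (n = 0), and R-loop (RNA-DNA hybrid) lengths
n = 1..20. Cleavage is a probability leak out of state 20 at the catalytic
rate k_cat; dCas9 is the same chain with k_cat = 0. The probability vector
obeys the master equation dP/dt = K·P with a tridiagonal generator K, whose
formal solution P(t) = exp(Kt)·P(0) is evaluated exactly (see Numerics).

Rates and free energies are tied by local detailed balance,
ΔF_n = ln(k_n^b / k_{n−1}^f) (all energies in kBT). Four structural
assumptions reduce the parameter space to 44 quantities:

1. only the *position* of a mismatch matters, not its base identity
   (measurements are averaged over mismatch types before fitting);
2. mismatch energetics are local and additive — a mismatch at position n
   adds a penalty δε_n to that landscape step, shifting all later states;
3. dCas9 differs from Cas9 only through k_cat = 0;
4. all hybrid-extension (forward) rates share one value k_f; selectivity
   lives entirely in the bond-reversal rates.

The parameters are: F0_ref (PAM-bound free energy at the 1 nM reference
concentration; concentration c rescales it as F_0 = F0_ref − ln c),
ε_1..ε_20 (on-target extension free energies, any sign), δε_1..δε_20
(mismatch penalties), and log10 of the three forward rates k_on (at 1 nM),
k_f, and k_cat. Position 1 is PAM-proximal throughout the package.

A *saturating* concentration (F_0 → −∞) is represented kinetically instead
of energetically: the reaction starts in state 0 with PAM unbinding
switched off, which is the exact limit and avoids exponentials of huge
energies.

## Experiment forward models

Predictions reproduce the data-analysis protocol of each assay, not an
idealized observable:

- **Effective cleavage rate** — saturating Cas9, survival
  (Σ_n P_n) recorded at t = 0, 12, 60, 180, 600, 1800, 6000, 18000,
  60000 s; a single exponential exp(−kt) fitted by unweighted least
  squares. The t = 0 point (survival 1 by construction) is kept to mirror
  the protocol grid; it carries no information. A log-linear fit is not
  used because survival can underflow at late times. Curves
  indistinguishable from 1 report rate 0; inside the training cost rates
  are floored at 1e−12 s⁻¹ on the log10 scale so the cost stays finite.
- **Effective association constant** — dCas9 from solution, bound fraction
  (Σ_{n≥0} P_n) after 600 s at 0.1–300 nM; the equilibrium isotherm
  c/(c + 1/K_A) fitted by least squares over K_A > 0. When no
  concentration shows binding above 1e−12 the fit is refused
  (PredictionError) rather than reporting a meaningless constant.
- **Relative association rate** — dCas9 at 1 nM; a straight line *with
  intercept* is fitted to the bound fraction at 500/1000/1500 s (the bound
  fraction is already nonzero at 500 s, so a through-origin fit would bias
  the slope); the slope is normalized by the on-target slope.
- **Relative dissociation rate** — 12 h of saturating dCas9 binding, then
  evolution with k_on = 0; a two-parameter decay A·exp(−kt) (amplitude
  free, since the bound fraction need not start at 1) is fitted at
  500/1000/1500 s and normalized by the on-target rate. Non-decaying
  curves are clipped to rate 0 with a warning.

All protocol fits are 1-D least-squares problems solved by a log-spaced
grid scan followed by golden-section refinement — deterministic and robust
to the many orders of magnitude the fitted constants span.

## Training

Sequence-resolved measurements are combined per mismatch pattern by an
inverse-variance weighted mean of log10 values (averaging in log space
approximates averaging transition-state free energies); the squared error
of the mean is 1/Σ(1/δ_s²), the standard propagation consistent with those
weights. Rows flagged non-physical (negative raw rates upstream) are
excluded first; a pattern left empty is dropped with a warning.

The cost is χ² = χ²_cleavage + χ²_binding over all patterns with at most
two mismatches (1 + 20 + 190 = 211 per experiment, 422 records), each term
w_p·(log10 prediction − averaged log10 measurement)², with
w_p = g_p / δ_p² and group factors g = 1 (on-target), 1/20 (single
mismatch), 1/190 (double mismatch), so the three groups contribute equally.

Simulated annealing minimizes the cost over the 44-vector. A trial move
adds uniform noise U(−α, α) to one randomly chosen coordinate (α starts at
0.1); perturbing all 44 coordinates at once is available as an option, but
single-coordinate proposals anneal this cost far more reliably — on the
recovery benchmark the all-coordinate walker consistently quenched into a
fast-rate local basin with several times the optimal cost, while
single-coordinate runs reach the global basin. The initial temperature is
calibrated by doubling/halving until the Metropolis acceptance fraction
over one batch lands in [0.40, 0.60]; the temperature then cools
exponentially, T_{k+1} = 0.99·T_k (full schedule; batches of 1000 moves).
At each temperature α is re-adapted to the band by factors of 1.5 (with a
1e−9 floor), then one further relaxation batch is run and its mean cost
recorded. The run stops when T ≤ 1% of its initial value *and* the batch
mean cost changes by at most a relative 1e−5 on two consecutive steps
(batch means are noisy; a single coincidence should not quench the run); a
max_temperature_steps cap guards against the stop rule never firing.
Non-finite costs reject the trial, are logged, and are excluded from the
acceptance fraction used for step adaptation (they are numerical guard
hits, not thermal rejections; counting them collapses the step size
against guard boundaries). Runs are bit-reproducible from the seed.
Parameters are unbounded during the walk; the exponential clamp (±700 kBT
per step, ±600 in the compiled kernel) and overflow guards keep the
numerics defined, returning +inf cost in unreachable regimes.
Initialization draws ε ~ U(−5, 5), δε ~ U(0, 10), F0_ref ~ U(−10, 0) and
log10 rates ~ U(−3, 3), which bracket plausible fitted values.

The fit landscape is multi-modal (an entry-limited fast-rate regime
mimics the catalysis-limited truth at moderately higher cost), so
production fits follow a multi-start protocol: several annealing runs,
near-equivalent solutions (final cost within 15% of the best) collected
into an ensemble with per-parameter spread summaries. The desk-scale
recovery benchmark does the same with two starts of the shortened
schedule (cooling 0.95, batches of 200, 140 temperature steps) on tables
with one record per pattern at log10 noise 0.1, and evaluates the
lowest-cost run: the mismatch-penalty profile correlates with the truth at
r > 0.95, and the free energies of the three metastable minima — each
landscape's own PAM-bound, intermediate-window and open minima — are
recovered within 1 kBT. Individual state energies inside basins and
barrier-region details are sloppy, as expected.

## Coarse-graining

The on-target landscape has three metastable states: closed (PAM-bound),
intermediate (free-energy minimum among hybrid lengths 7–13, located per
target; ties break toward the PAM), and open (20 bp). Effective rates
between them are inverse mean first-passage times: the chain is truncated
between the two metastable states, the reflecting edge's outward rate is
zeroed (for the closed→intermediate passage that is the PAM unbinding
rate), the rate into the destination acts as an absorbing leak, and
τ = −1ᵀ·K_tr⁻¹·P(0). The truncated generator has a strictly negative
spectrum, so the minus sign makes τ positive; the implementation is checked
against a closed-form two-step chain and against direct stochastic
(Gillespie) passage-time simulation. For the open→intermediate rate the
reflecting edge at state 20 also switches off the cleavage leak, so the
passage concerns the surviving complex only; this rate is the least
constrained by training data and should be treated with caution.

For occupancy dynamics the microscopic model is propagated and binned:
the intermediate basin is the set of states strictly between the two
barrier tops (argmax of F on either side of the intermediate minimum),
closed is everything below, and the open bin absorbs the remaining states
plus cleaved probability, so the three occupancies sum to one. The reduced
3-state model propagated with the first-passage rates reproduces the
binned microscopic occupancies within 10% sup-norm on the on-target.

## Off-target ranking

In the low-concentration limit the genomic cleavage rate is the
(sequence-independent) PAM-binding flux times the probability that a bound
complex cleaves before unbinding. That splitting probability is evaluated
in closed form, score = k_cat / (k_cat·Σ_{n=0..19} e^{F_n} + k_f·e^{F_20}),
via log-sum-exp. The score differs from the exact splitting probability by
a target-independent factor only, so rankings are identical (asserted
against an absorbing-chain linear solve) and independent of concentration.
Genome scanning enumerates every 20-mer followed by NGG on both strands
(windows containing N are skipped), derives the mismatch pattern with
position 1 adjacent to the PAM, and scores it. Classification against a
truth set is summarized by the precision-recall curve swept over unique
score values (ties cross the threshold together), its maximum F1, and the
area under it (AUPRC, trapezoid over recall with the conventional
recall-0/precision-1 anchor). Coordinates are 0-based half-open
internally, BED6 on disk, 1-based inclusive for display.

## Synthetic data

The generator emulates the structure of the training tables: 211 patterns
per experiment (on-target, 20 single, 190 double mismatches), log10 values
from the model's own forward predictions plus additive Normal(0, noise_sd)
noise (multiplicative on rates, matching the log-space averaging), per-row
errors equal to noise_sd (floored at 1e−3 so the noiseless case keeps a
positive error). The default truth has a three-minimum on-target landscape
(at 1 nM: PAM-bound ≈ +3 kBT, seed barrier ≈ 8 kBT over positions 1–8,
intermediate basin ≈ +2.5–3 kBT at 9–12, distal barrier ≈ 7 kBT, open
state ≈ −5 kBT) with N(0, 0.3) jitter, penalties N(5, 1) truncated
positive, and rates around k_on = 3e−4 s⁻¹ at 1 nM (3e5 M⁻¹s⁻¹),
k_f = 1e3 s⁻¹, k_cat = 0.03 s⁻¹. This regime was chosen to reproduce the
joint structure of the real assays: the weakly stable PAM state releases
seed-blocked targets within the 10-minute binding assay (so effective
association constants drop by an order of magnitude and more for seed
mismatches while responding weakly to distal ones), association at 1 nM
stays in its linear regime over 25 minutes (relative association rates
never exceed the on-target), catalysis is slow enough that cleavage assays
need hours, and the intermediate basin sits near the PAM-bound level so
the closed↔intermediate transition is reversible. What the synthetic tables do *not* emulate:
sequence-dependent (mismatch-type) effects, assay-specific systematic
errors (cluster calibration, PCR bias), and correlated noise between
patterns; recovery benchmarks therefore measure identifiability of the
model given its own assumptions, not robustness to model misspecification.

A toy-genome generator plants protospacer+PAM sites with chosen mismatch
patterns in random sequence for end-to-end scanning tests.

## Numerics

- The general propagator decomposes the chain into reversible segments
  (cuts where both connecting rates vanish; one-way edges are supported
  when the receiving state is absorbing, as in the dissociation protocol,
  via time-integrated leak flux) and solves each segment spectrally after
  symmetrization. The symmetrized matrix is assembled in long-double
  precision and the float64 eigenbasis is polished by a long-double Jacobi
  pass: float64 eigh mixes nearly degenerate slow modes (relative gaps
  near machine precision in multi-well landscapes), which exp(wt)
  amplifies into ~1e−8 occupancy errors at long times. The conservative
  zero mode is pinned exactly. When the symmetrization weights span more
  than e^18 (conditioning), the solver falls back to scaling-and-squaring
  expm.
- The training cost uses compiled kernels: a projected-eigenvector QL
  iteration for the cleavage protocol (one decomposition serves all nine
  time points) and, for the binding protocol, numerical Laplace inversion
  on a fixed Talbot contour (M = 28 nodes) of the solution-state
  resolvent, whose inner continued fraction is shared by all eight assay
  concentrations. Both agree with the reference predictors to ~1e−9 and
  are asserted against them in the tests.
- Free-energy steps entering exponentials are clamped at ±700 kBT (±600 in
  the compiled cost path) with a warning; any non-finite intermediate turns
  the cost into +inf, i.e. a rejected trial.
- Problem sizes used by the test suite and the acceptance script — 10,000
  trajectories for stochastic oracles, 500 patterns for the ranking
  comparison, and the shortened annealing schedule (cooling 0.95, batches
  of 200) for recovery benchmarks — keep the full run at desk scale while
  leaving the statistical assertions well-powered.

## Known limitations

- Mismatch-type (base-identity) energetics, non-canonical PAMs, and
  DNA/RNA bulges are outside the model by construction.
- The open→intermediate coarse rate is poorly constrained by bulk training
  data (see above).
- The annealing stop rule compares noisy batch averages; with small
  batches the stop can fire late, which is why the safety cap and the
  per-temperature trace are exposed.
- Relative association/dissociation rates can never cross the on-target
  value in this model; measured targets that do will be mispredicted.
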
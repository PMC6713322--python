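# Methods

## The estimation problem

Weight specific growth rate (SGR, % day⁻¹) is defined from two weighings of
the same individual: with g = (ln W₂ − ln W₁)/(t₂ − t₁),

* exponential convention: SGR = 100 (e^g − 1),
* linear convention: SGR = 100 g.

The two agree to second order in g (|difference| ≤ 100 g² for |g| ≤ 0.05);
both are provided in `growth_metrics`. For wild fish sampled once, neither
is computable, so SGR is instead estimated from three single-capture
covariates: weight (g), the trypsin/chymotrypsin activity ratio (T/C,
dimensionless) and Fulton's condition factor (CF = 100 · weight/length³).
The package treats these as a regression problem solved by a fixed random
recurrent network with a trained linear readout.

## Network and learning rule

The reservoir has N = 50 tanh neurons. Input weights `W_in` are uniform on
[−0.1, 0.1] and recurrent weights `W_sys` uniform on [−1, 1]; in both, a
uniformly random subset of exactly half the entries is zeroed (realized
sparsity is the nominal 50% to within one entry), and `W_sys` is then
multiplied by 0.9/ρ so its spectral radius is exactly 0.9. Sparsification
precedes spectral scaling. A sparsified matrix that comes out nilpotent
(spectral radius 0) cannot be rescaled; construction fails with an error
asking for a different seed. The whole construction is a pure function of
the seed (numpy `default_rng`).

State update: x(t+1) = (1 − λ) x(t) + λ tanh(W_in u(t+1) + W_sys x(t) + b₀)
with bias b₀ = 0.001 applied to every hidden neuron (keeps the network
weakly active even under zero input). The initial state is x(0) = 0, which
makes the state a convex combination of tanh outputs, hence bounded in
[−1, 1] forever — the test suite asserts this over 10⁴ random steps. No
washout period is applied; with spectral radius 0.9 two trajectories driven
by the same inputs contract to ~10⁻¹¹ of their initial gap within 200
steps, so the zero-start transient is negligible after a few dozen records.

The readout y = W_out x is trained online by recursive least squares with
forgetting factor λ_RLS = 0.99 and p(0) = I/β, β = 10⁻⁴, W_out(0) = 0,
one update per (record, SGR) pair. The auto-correlation matrix p is
re-symmetrized (averaged with its transpose) after every rank-one update;
without this, floating-point drift breaks positive-definiteness over long
runs. With λ_RLS = 1 a single pass is algebraically identical to ridge
regression with penalty β — the test suite exploits this as an independent
closed-form oracle. λ_RLS = 1.0 is exposed for exactly that purpose;
0.99 is the operational default.

## Protocols

**Normalization.** Every feature and the SGR target are mapped to [−1, 1]
(the tanh range) by x ↦ 2 (x − min)/(max − min) − 1. Ranges are computed
from the *training records only* (the held-out 15% is excluded — a
deliberate choice; the alternative of whole-dataset ranges differs
negligibly but leaks the test extremes) and are stored with the model. A
constant feature (max = min) raises an error rather than silently mapping
to zero: it carries no information and indicates a data problem. Values
outside the stored range extrapolate linearly beyond [−1, 1] with a logged
warning.

**Record order.** The tabular records are presented as a temporal sequence
in stored dataset order. The reservoir state is carried across records
within one training pass, reset to zero between passes and between the
training and estimation phases. The default is a single pass (strict
online learning); `passes` is configurable. Because of the echo-state
contraction, estimates are order-robust to about 1% — the same record
placed at two distant positions receives nearly, not exactly, the same
estimate, the residue coming from the memory of its immediate
predecessors.

**Time scale.** λ = 0.3 by default when a model is evaluated on held-out
data from its own dataset, λ = 1.0 for cross-dataset and cross-species
application; the package never auto-selects.

**Split.** `split_train_test` holds out round(n · 0.15) records (minimum
one), drawn uniformly without replacement, seeded. For a dataset combined
from several constituents the fraction is drawn per constituent, so every
part is represented in the test set.

**Error reporting.** MSE is the arithmetic mean of per-record squared
errors on the *normalized* scale, reported ± the SD of those squared
errors; the real-unit ((% day⁻¹)²) equivalent is reported alongside. The
normalized scale is primary because that is the scale on which the readout
is trained.

**Ablation.** `ablation_study` trains the seven feature subsets — three
singles, three pairs, the full triple — on one shared split and reservoir
seed, so rows differ only in the features driving the network, and ranks
the subsets by normalized MSE.

**Cross-dataset application.** Applying a model to a population whose body
sizes lie far outside the training envelope would extrapolate the
normalized weight input by orders of magnitude and saturate every tanh
neuron, destroying sensitivity to the other inputs. `estimate_sgr(...,
input_ranges="data")` therefore rescales each feature of the *new* dataset
to [−1, 1] by its own min/max (the new population must be normalized as
one table — per-group normalization would erase the between-group
differences of interest). Normalized outputs are always converted to
% day⁻¹ with the training SGR range, so absolute cross-species estimates
inherit the training population's growth scale; relative comparisons
(group rankings) are the meaningful output in that regime. The default
(`input_ranges="model"`) keeps the stored training ranges and extrapolates.

## Synthetic data

No suitable multi-stage dataset of (weight, T/C, CF, SGR) is publicly
distributable, so `synthetic` fabricates one. The ground-truth surface

SGR = α · W^(−γ) · (T/C)^δ · exp(−κ (CF − CF₀)) + ε,  ε ~ N(0, σ²)

with defaults α = 5, γ = 0.3, δ = 0.5, κ = 0.5, CF₀ = 1.2, σ = 0.05
% day⁻¹, is an *invented* smooth multiplicative form — not fish
bioenergetics — chosen so each covariate carries independent, monotone
signal (rising in T/C, falling in weight and in CF), which makes ablation
ordering well defined. The noiseless value is stored in `sgr_true` for
recovery tests; training ignores it.

Stage presets (invented, salmonid/tilapia-like scales; all configurable):
weight log-normal with medians 20 g (juvenile, log-SD 0.25, n = 499),
150 g (post-smolt, 0.2, n = 24), 1500 g (adult, 0.3, n = 109), 300 g
(tropical adult, 0.3, n = 31); T/C log-normal with medians 4.0/3.5/3.0/3.0
and log-SD 0.4; CF normal, truncated > 0, means 1.15/1.10/1.30/1.40 with
SD 0.12–0.15. Features are drawn independently by default — real data
correlate weight with CF, but independence keeps ablation attribution
clean; a Gaussian-copula `feature_correlation` option couples weight and
CF for users who want realism over attribution. Length is back-derived
from weight and CF so the three columns are mutually consistent.

`generate_ranked_populations` builds three 25-fish populations on the
adult preset differing only in T/C median (A: 6.0, C: 4.0, B: 2.5), giving
population-mean noiseless SGR ordered A > C > B with gaps large relative
to the standard error of a 25-fish mean, so the realized ordering is
stable across seeds.

What passing tests on these data show: that the pipeline recovers the
relative informativeness of the inputs and cross-population orderings when
the assumed qualitative structure holds. What they do not show: performance
on real assay data, where features are correlated, noise is heteroscedastic,
and the T/C–growth association varies with season and feeding state.

## Accuracy ceiling

On the default synthetic juveniles (n = 400), the three-input test MSE is
~0.007–0.018 on the normalized scale — reliably the best of the seven
subsets, but roughly an order of magnitude above the irreducible noise
floor (2σ/range)² ≈ 3 × 10⁻⁴. This gap is a property of the method, not
of the training rule: the batch-optimal ridge readout over the same
reservoir states (the best any RLS schedule could do) reaches ~0.005, while
a quadratic regression on the raw features reaches the floor. Two
mechanisms cap the reservoir: input weights confined to [−0.1, 0.1] couple
the current record weakly relative to the spectral-radius-0.9 recurrence,
so each state carries the preceding — statistically independent — records
as effective noise; and in the resulting near-linear operating regime the
readout cannot express the curvature of the target surface. The acceptance
suite measures and reports this ratio rather than hiding it.

## Numerical choices and sizes

* Spectral radius is enforced by dense eigenvalue computation
  (`numpy.linalg.eigvals`) and exact rescaling; at N = 50 this is
  microseconds.
* Model files are canonical JSON (sorted keys, fixed separators); Python's
  shortest-repr float encoding makes write → read → write byte-identical,
  which is the persistence contract and the determinism check.
* Simulation-based tests use 10 seeds × 400 fish for ablation and
  10 seeds × (3 × 25 + 2 training sets) for ranking; the whole test suite
  runs in a few seconds, the acceptance script in ~2 s.
* Test-set size is round(n · fraction) with a minimum of one; n = 2 is the
  smallest trainable dataset (two records are needed for non-degenerate
  ranges).

## Known limitations

* Absolute cross-species estimates are only as good as the overlap between
  the training SGR range and the target population's true rates; the
  package reports them but the intended use is comparative.
* The record-sequence reading of tabular data means estimates depend
  (weakly, ≲1%) on record order.
* No uncertainty quantification; no hyperparameter search (N, spectral
  radius, sparsity are fixed conventions of the method).
* The CLI covers the standard protocols; programmatic use is needed for
  custom presets, truth parameters, or correlation structure.
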
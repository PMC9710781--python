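# Methods

## Model

The reservoir is a leaky discrete-time recurrent network. Per step,
r'(t) = f(W_in(ε·x(t)) + W·r(t−1) + b·1) and
r(t) = α·r'(t) + (1−α)·r(t−1), with f = tanh (states bounded to [−1, 1]).
States are initialized at zero; because that start produces activity
unrelated to the input, the first `transient` steps (default 100) are
discarded from fitting *and* scoring, in both the training and the test
span. At test time the reservoir is restarted from zero on the test input
and its own leading `transient` steps are excluded from scoring.

An alternative integration form, selected by
`leak_integration="as-printed"`, applies the recurrent weights to the
carried-over state: r(t) = α·r'(t) + (1−α)·W·r(t−1). The standard leaky
form is the default; at the default α = 1 the two coincide exactly, so the
choice is unobservable in the main experiments.

The readout y(t) = g(W_out[x(t); r(t)]) is trained by ordinary least
squares, W_out = Z⁺Y, using a rank-revealing SVD (`numpy.linalg.lstsq`
with its default cutoff, singular values below max(T, N_x+N_r)·eps·σ_max
treated as zero): the minimum-norm solution among residual minimizers. No
ridge penalty is applied. The readout regressors use the *unscaled* input
x(t): least squares is invariant to regressor scaling, and with
ε = 10⁻⁵ the unscaled column is vastly better conditioned. Target rows
whose lagged value reaches before the start of the series are undefined
(NaN) and are dropped alongside the transient.

### Hyperparameters

| parameter | meaning | default | note |
|---|---|---|---|
| ρ (`spectral_radius`) | post-normalization largest \|eigenvalue\| of W | 0.99 | applied to every condition before running |
| ε (`input_scaling`) | input gain before W_in | 1e−5 | keeps the reservoir in its bias-driven operating point |
| α (`leakage`) | leak rate in (0, 1] | 1.0 | 1 = no leakage |
| b (`bias`) | constant bias, broadcast to all neurons | 1.0 | treated as a scalar hyperparameter in {0, 1} |
| `transient` | washout steps discarded per span | 100 | exceeds the default largest lag |
| g (`output_activation`) | readout nonlinearity | identity | ReLU for sequence recall (targets are ≥ 0) |

The grid used for tuning (`PAPER_GRID`) spans ρ ∈ {0.91…0.99},
ε ∈ {10⁻⁹…10⁰}, α ∈ {0.6, 0.8, 1}, b ∈ {0, 1} (300 constellations);
`grid_search` trains each constellation with independently instantiated
reservoirs (default 10) and selects by mean validation score. The
validation carve-out is the last 20% of the training span — the split
proportion is this package's choice, as is re-seeding per constellation.
The defaults above are the fixed constellation used by all main
experiments without searching.

## Connectivity conditions

Link weights for every condition are i.i.d. Uniform[−1, 1] (exact zeros
resampled so mask and weights agree); what differs is topology and
placement. `bio_rank` sorts the sampled weights and assigns them so the
assigned order matches the empirical strength order — most negative weight
on the weakest link, most positive on the strongest; ties in empirical
strength are broken by (source, target) index order. `bio_no_rank` keeps
the mask and permutes the weights uniformly. `random_density` redraws the
link positions uniformly among ordered off-diagonal pairs, conserving the
link count exactly. `random_k` fixes the fan-in (in-degree) of every
neuron to k; the fan-out variant is available via `degree="out"` — the
convention is not dictated by anything deeper than sparse-ESN custom.
`random_full` connects everything. No condition ever places self-loops.

Spectral normalization multiplies W by ρ/|λ|max using the largest-magnitude
eigenvalue (not a singular value). Nilpotent wiring (|λ|max numerically 0,
e.g. strictly feed-forward) cannot be rescaled and is rejected with
guidance.

## bio2art upscaling

Each area is replicated into `neurons_per_area` neurons. For every
area-level link (i, j) the full neurons_per_area² block is connected and
w_ij is partitioned over it — equally (homogeneous) or by proportions
u/Σu with u i.i.d. Uniform(0, 1) (heterogeneous). Block sums therefore
equal the empirical weights to rounding error, and empty blocks stay
empty, so the area-level wiring diagram survives upscaling exactly
(`area_mask` asserts this). "Random partition" is operationalized as
normalized uniforms — the simplest symmetric partition with full support.

Intrinsic (within-area) connectivity has no comprehensive empirical
counterpart; it follows a rule: each area's intrinsic total equals
`intrinsic_ratio` (default 0.8) times its extrinsic *outgoing* total. The
outgoing convention matches the row-as-source orientation; in-strength and
total-strength budgets are selectable via `extrinsic=`. A fraction
`intra_conn_fraction` (default 1: all) of the within-area ordered pairs is
formed and the intrinsic total is partitioned with the same
homogeneous/heterogeneous rule as the interareal blocks — one
heterogeneity axis, not two. With neurons_per_area = 1 there are no
within-area pairs and the result equals the source connectome.

For scaled experiments the surrogate condition is applied *after*
upscaling, to the neuron-level matrix, so every condition is well defined
at every size. On upscaled sources `bio_rank` rank-aligns the interareal
links only: intrinsic links are rule-generated and have no empirical
strength to rank against, so they receive randomly placed weights from the
same sampled pool. (Aligning them too makes every intrinsic block
sign-coherent under the rank map — the blocks then dominate the spectrum
at any scaling factor and the normalization suppresses everything else;
diagnostics showed 96–100% sign-coherent intrinsic blocks and a roughly
threefold inflated leading eigenvalue.)

## Tasks and scoring

**Memory capacity.** X(t) ~ Uniform(−0.5, 0.5), one input neuron, one
output per lag τ trained to Y_τ(t) = X(t−τ). Per-lag score: squared
Pearson correlation on the scored steps; a constant series (no memory
content) scores 0 by convention. MC is the sum over lags, bounded by the
number of lags. Default protocol: 4000 training steps, 1000 test steps,
lags 1…40. The lag set is configurable; desk-scale experiments in the
tests use lags 1…20 so the ceiling stays visible at 30-area reservoir
sizes.

**Sequence recall.** Two inputs: a stream X1 ~ Uniform(0, 1) and a cue X2
∈ {0, 1}. A trial is `fixation_len` fixation steps (target 0) followed by
L recall steps during which the target replays the last L fixation values
in order. Defaults chosen here: `fixation_len = L` (the shortest trial
that holds a full pattern) and X1 = 0 during recall (prevents incoming
values from interfering with replay; both configurable). Trials are
concatenated into one continuous stream per split, with a single leading
transient discarded per split, and the pooled R² over recall steps is
reported — fixation steps never enter the score, since predicting zeros is
trivially easy and would inflate it. Default protocol: 800 training
trials, 200 test trials, L ∈ {5…25}.

## Synthetic connectome generator

No empirical connectome ships with the package, so experiments run on a
generator that emulates the area-level statistics the pipeline is
sensitive to: a square non-negative matrix with zero diagonal; sparse at a
requested density over ordered off-diagonal pairs; modular (within-module
pairs are filled before between-module pairs, so below the within-module
capacity the graph is purely modular); heavy-tailed strictly positive
weights, marginally log-normal, exp(N(0,1))·`weight_scale`; and
reciprocal-weight correlation — log w_ij and log w_ji share a pair-level
component giving correlation `reciprocity` (default 0.8), mirroring the
strong weight reciprocity of tract-tracing and diffusion connectomes.
The reciprocity term matters: with fully independent link weights the
rank-preserving and rank-free placements are statistically exchangeable
and the conditions could not be distinguished in principle.

What the generator does **not** emulate: spatial embedding and
distance-dependent weight decay, hub/core–periphery organisation,
per-area size heterogeneity, and the multi-decade weight ranges of
tract-tracing data (the marginal spans roughly two orders of magnitude).
Passing desk-scale tests on these graphs shows the pipeline reproduces the
qualitative condition ordering on modular, reciprocal, heavy-tailed
networks — not that any particular empirical connectome would behave
identically.

## Experiment harness and reproducibility

`run_replicates` derives an independent seed for every (condition, size,
difficulty, replicate, stage) cell from the base seed via
`numpy.random.SeedSequence`, so replicates are genuinely new networks yet
the whole sweep is bit-reproducible; rerunning a plan yields an identical
table. Cell failures are isolated and logged rather than aborting a sweep.
Results are tidy long-format tables; runs that write to disk also emit a
manifest with the full plan, a config hash and all seeds.

Desk-scale protocol sizes used by the shipped experiments and tests —
30-area connectomes, 20 replicates per condition, lags 1…20, scaling
factors {1, 2, 4, 8} — were chosen to make the statistical comparisons
(Mann–Whitney at α = 0.01) decisive on a single workstation run.

## Known limitations

* The scaling experiments show the rank-preservation deficit *growing*
  with the bio2art scaling factor under both interareal modes, rather than
  shrinking under the heterogeneous mode. This follows from the
  construction: rank-preserving placement is a signed global-quantile
  transform of the upscaled weights, so each interareal block's mean
  assigned weight is monotone in the empirical weight; the block-mean
  matrix contributes an area-structured spectral mode that grows ~k with
  the scaling factor while within-block diversity grows only ~√k, and
  spectral normalization suppresses the diversity modes accordingly — for
  any weight-conserving partition. The heterogeneous/homogeneous switch
  modulates only the within-block variance and cannot reverse this.
* Plain pseudoinverse training is noise-free and can exploit numerically
  tiny state directions; measured MC therefore depends on floating-point
  conditioning in a way ridge-regularized training would not.
* No plasticity, no feedback connections, no classification tasks, no
  degree- or geometry-preserving null models beyond the five conditions.
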
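# Methods

This note documents the modelling choices behind `efnn`: the procedure, its
assumptions, the parameters that matter, what the synthetic generators do
and do not emulate, and the numerical conventions adopted where the design
was genuinely open.

## Cloud partitioning (module `eda_sof`)

Each class is partitioned independently into data clouds. Offline:

1. Exactly repeated rows are collapsed into a unique-point table with
   frequencies (bitwise equality; continuous data simply yields frequency 1
   everywhere).
2. The multimodal density of every unique point is its frequency times the
   normalised inverse cumulative proximity,
   `D(u) = f · Σ_l π(x_l) / (2K π(u))`.
3. Unique points are ordered densest-first, then by a greedy
   nearest-neighbour chain; strict local density maxima along that chain
   become prototypes. Endpoints use a one-sided comparison; if the chain is
   flat (no strict maximum) the head survives. Ties anywhere resolve to
   the lowest original index — all tie-breaks in the package do, which
   makes every fit deterministic.
4. Samples are attracted to their nearest prototype; clouds whose density
   `S_i · D(φ_i)` does not strictly exceed every neighbour within the
   influence radius are dropped, and clouds are re-formed around the
   survivors' centers.

The influence radius at granularity level `L` is a filtered-mean recursion:
level 1 is the mean squared pairwise distance over unordered distinct
pairs; each further level averages only the pairs strictly below the
previous radius and stops early when none qualify. Higher levels resolve
finer structure. The partitioner's API default is level 12 (the common
convention for this family of partitioners), but the *pipeline* default is
level 2: on continuous data the recursion approaches nearest-neighbour
scale within a few levels, and at level 12 the online distance condition
founds a new cloud on nearly every sample — a degenerate
one-rule-per-sample model. Level 2 grows the rule base at the rate the
method is designed for (tens of rules over thousands of samples, starting
from a handful).

Distances are squared Euclidean, either raw or on L2-normalised vectors
(`cosine`, the default for the pipeline: it equals `2(1 − cos θ)` and is
the customary choice for this partitioner). Euclidean is often preferable
when cluster geometry is radial, as in the structure-recovery experiments.

Online, the class mean, second-moment matrix and scatter follow the exact
recursive update rules, so after any number of single-sample updates they
match the batch statistics to numerical precision (tested at 1e−8). The
radius scales by the ratio of average cumulative proximities, which reduces
to the ratio of working-space variances and is maintained from running
sums; densities at prototypes are likewise evaluated from the recursive
statistics (`D(z) = v/(‖z − μ‖² + v)` with `v` the working-space variance)
rather than by rescanning history — exact for these metrics, and the only
option compatible with a single-pass contract.

Cloud widths: the per-dimension ddof-1 standard deviation of the members,
floored at 10 % of the global per-dimension spread of the offline slice
(and at 1e−6 absolutely), so singleton clouds still yield usable fuzzy
sets. The floor fraction is a smoothing choice, not fitted.

Degenerate inputs: all-identical samples get uniform density 1 (with a
warning); a single-sample class gets one cloud and borrows the whole
dataset's radius; a partition founded online obtains its first radius from
the level-1 estimate (twice the working-space variance) once two samples
exist.

## Feature weighting (module `feature_weighting`)

The separability criterion is `J = trace(S_w⁻¹ S_b)` with `S_w` the
unweighted average of class-wise ddof-1 covariance matrices and `S_b` the
class-count-weighted average of `(μ_c − μ)(μ_c − μ)ᵀ` — the textbook Fisher
form. Classes with fewer than two samples contribute zero covariance.
Singular `S_w` is ridge-regularised with `δ = 1e−8 · trace(S_w)/n`, which
matters only in the first stream moments. LOFO weights delete row/column j
of the *maintained* matrices rather than refitting from raw data; for this
criterion the two are identical, and the maintained route is what makes a
per-sample weight refresh affordable (n solves of an (n−1)-dimensional
system per sample; a `weight_update_every` knob thins the cadence if
needed). With fewer than two observed classes the weights fall back to
uniform 1 with a warning. Weights modulate the neurons and the rendered
impacts only — no feature is ever dropped from the model.

## Logical neurons (module `neuro_layers`)

Default norms are product / probabilistic sum; min / max are available.
The uninorm acts as a scaled t-norm on `[0,g]²`, a scaled t-conorm on
`[g,1]²`, and `min` on the strictly mixed region; both sub-squares are
closed so that `g` is a true identity. The nullnorm mirrors this with an
absorbing element `u`. The composed uninull operator applies one uninorm
(identity `g/β`) below the knot `β` and another (identity `(u−β)/(1−β)`)
above it; its mixed region evaluates to `β` itself. The min completion used
for plain uninorms is *not* monotone here — the lower sub-square is
internally disjunctive and can exceed `min(x,y)`, so crossing the knot
would drop the value; the `β` (median) completion is the constant
completion that preserves monotonicity and matches both sub-square
boundaries. At the corners of the `(g,u,β)` cube the operator collapses to
the pure conjunction or disjunction, which is verified on grids. Folds run
left-to-right in feature order; this matters only in the mixed regions
(the base norms are associative) and is fixed as the contract.

The relevancy transformation blends each membership with its aggregator's
neutral value: `b = w·a + (1−w)·g` (uninorm), `…·u` (nullnorm), and for
the uninull neuron the fill is `g` below the knot and `u` above. Weight 1
passes the raw membership; weight 0 makes the feature invisible to the
rule. AND neurons aggregate `T(w̄ s a)` by default — the complement of the
weight is fed to the textbook construction so that "weight 1 = fully
relevant" holds uniformly across all five neuron kinds and matches the
impact semantics of the rendered rules; `strict_weights=True` restores the
literal construction (where weight 1 suppresses an input). Neuron
parameters default to `g = u = β = 0.5` and are configuration, not learned.

Known limitation: in low dimensions the nullnorm neuron can saturate at its
absorbing element (any mixed pair of transformed memberships yields exactly
`u`), collapsing the regression vector and hurting the NULL variant's
accuracy on some streams; with many features and high weights (the
heart-sound-shaped regime) this rarely binds.

## Readout (module `output_readout`)

A bias column is prepended in both the batch and streaming paths (the model
names a bias term; the batch normal equations simply include it). The batch
fit is one pseudo-inverse solve against all class indicator vectors.
Streaming uses the recursive weighted least squares recursion with
forgetting factor `λ` (default 1 = none) on a shared inverse-Hessian `Q`
initialised to `ω·I`, `ω = 1000` by default (1e6 reproduces the batch
solution to 1e−3 on 200×10 problems). `Q` is re-symmetrised after each
rank-1 update to stop numerical drift. When the partitioner evolves a new
cloud mid-stream, `Q` gains a fresh `ω` diagonal entry and the weight
vectors a zero — prior estimates are untouched, the standard evolving
practice. Exact zero signed scores resolve to the majority training class.

## Rules and change tracking (module `interpretability`)

Per dimension the cloud centers are ranked and labelled from the ladder
*very small / small / medium / high / very high*; exactly four sets use the
*very small / small / medium / high* convention, one set is *medium*, more
than five anchor into the ladder with ordinal suffixes. The rule's
consequent is the class implied by the sign of its signed readout weight
(class 1 — "normal heart sound" in the heart-sound naming — for positive
certainty), the certainty is that weight, and antecedents with impact below
the display threshold are hidden from the text only.

Gaussian intersections come from the defining property (equal membership,
a quadratic in x) rather than any closed-form transcription: unequal widths
give two roots, equal widths with distinct centers give the symmetry
midpoint, identical curves return a sentinel and similarity 1. Antecedent
similarity is the membership value at the best intersection; rule
similarity aggregates dimensions with min (default; product available,
always ≤ min), and the change degree is its complement, reported together
with a consequent sign-flip flag. Snapshots are taken every
`snapshot_interval` (default 100) absorbed samples; each interval appends
per-rule rows (id, dimensions changed, degree, flip) to the change log.

## Pipeline (module `model_pipeline`)

Features are min–max scaled to [0,1] on the offline slice and the same
affine map is applied to the stream (Gaussian widths and the [0,1] neuron
algebra assume comparable scales); z-score and no scaling are options. The
offline/online split is by stream order (first 10 % by default), never
random. The per-sample update order is: partition update (possible cloud
birth → readout growth), feature-weight update and refresh, neuron rebuild
from the drifted clouds, change-degree bookkeeping at snapshot boundaries,
regressor computation, readout update. There is no randomness at update
time, so a fixed stream order and configuration reproduce trends, rules and
the serialised model bitwise. Models serialise to JSON (version field,
row-major matrices). The `efnn` console script wraps fit / stream / rules /
simulate.

## Synthetic generators (module `synthetic_data`)

`gen_mixture_stream` draws labelled samples class-by-prior and
component-by-weight with feature-wise independent Gaussians, optional mean
drift after an onset index, fully determined by `(spec, seed)`.

`gen_heartlike_table` emulates the published marginal summary table of a
27-feature heart-sound feature set: per-feature means and standard
deviations on the printed scale, values clipped to the printed ranges, and
a class prior of 0.7574 for class 1. Because only *marginal* moments are
published, the class-conditional structure is invented: a separation of 1.6
marginal standard deviations is injected on MFCC 3 and MFCC 4 (the features
reported as dominant for this problem), with within-class variance shrunk
so the marginals stay on target; MFCC 1 is an equal two-component mixture
(±2, variance-compensated) echoing the multi-source provenance of real
recordings. Right-skewed features (dispersion measures, kurtosis, dominant
frequency value, and — left-skewed — signal entropy) are shifted
log-normals matched to mean/std; the dominant-frequency magnitude, bounded
in [0.01, 1] with a large coefficient of variation, is a moment-matched
Beta on its printed range (a clipped log-normal cannot hold both moments
against the upper bound).

What passing tests on these streams show — and do not show: the generators
produce independent rows with Gaussian-ish class-conditional clusters and
exactly known structure, so they validate the mechanics (structure
recovery, evolving updates, weight trends, rule change) under the
assumptions the model itself makes. Real phonocardiogram features are
temporally dependent, not feature-wise independent, and their class overlap
is not controlled by a single separation knob; accuracy numbers on the
fixtures therefore say nothing quantitative about clinical performance.

## Experiment sizes

The packaged experiments use a 2000-sample mixture (10 % offline) for
structure recovery and a 5000-sample heart-shaped stream for the
evolving-vs-frozen comparison; both finish in seconds to tens of seconds on
one CPU and are large enough for the prequential trends to stabilise well
past the transient.
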
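# efnn — evolving fuzzy neural network with logical neurons

`efnn` is an interpretable stream classifier for tabular biomedical data,
built around the kind of feature tables extracted from phonocardiogram
(heart-sound) recordings: 13 MFCCs plus time- and frequency-domain signal
statistics, with a binary label (normal heart sound vs. heart murmur).
Unlike black-box stream learners it maintains a human-readable fuzzy rule
base that evolves as samples arrive, and it can quantify *how much* each
rule changed over any stream interval.

## Model

Three layers, trained in a single pass:

1. **Fuzzification** — per class, a self-organising partitioner groups the
   samples into *data clouds*: shape-free clusters attracted to prototypes
   that are local maxima of the empirical multimodal density
   `D(x) ∝ Σ_l π(x_l) / π(x)`, where `π(x) = Σ_j d²(x, x_j)` is the
   cumulative proximity. Each cloud projects to one Gaussian fuzzy set per
   dimension, `a(x) = exp(−½((x − c)/σ)²)`. During streaming the partition
   statistics (mean, second moment, scatter, influence radius) are updated
   recursively and a new cloud is founded whenever a sample is denser or
   sparser than every prototype, or farther than the influence radius from
   all of them — the rule base grows on demand.
2. **Logical neurons** — each cloud owns one fuzzy rule. Its antecedents are
   aggregated by a weighted logic neuron: classical AND (t-norm) / OR
   (t-conorm), or the uninorm / nullnorm / uninull operators that act
   conjunctively on one part of the unit square and disjunctively on the
   other, so a single rule can mix AND and OR behaviour. Feature weights
   come from a leave-one-feature-out (LOFO) Fisher separability criterion
   `J = trace(S_w⁻¹ S_b)`: feature j's weight is
   `w_j = 1 − (J_j − min_i J_i)/max_i J_i`, maintained incrementally, so the
   most discriminative feature always has weight exactly 1 and weights act
   as per-antecedent *impacts* in the rendered rules.
3. **Readout** — indicator-based linear regression per class, estimated by
   Moore–Penrose pseudo-inverse on the initial batch and by recursive
   weighted least squares (with optional forgetting) on the stream. Binary
   decisions take the sign of the class-score difference.

Evaluation is prequential (interleaved predict-then-train): the accumulated
one-step-ahead accuracy `Acc(K+1) = (Acc(K)·K + 1[ŷ=y])/(K+1)` is tracked
at every sample.

Rule change over an interval is `Λ = 1 − S`, where `S` aggregates (min by
default) the per-dimension overlap of each antecedent Gaussian before and
after the interval, measured as the membership value at the intersection
points of the two curves.

## Worked example

```python
from efnn import synthetic_data as sd, model_pipeline as mp, interpretability as interp
from efnn.eda_sof import SampleMatrix

data = sd.gen_heartlike_table(2000, seed=7)           # 27-feature synthetic stream
off = SampleMatrix(data.values[:200], data.labels[:200])
model = mp.fit_initial(off, mp.ModelConfig(neuron_kind="UNI"),
                       feature_names=sd.heartlike_feature_names(),
                       class_names=sd.HEARTLIKE_CLASS_NAMES)
print(interp.render_rules(model, impact_threshold=0.97))
metrics = mp.prequential_eval(model, SampleMatrix(data.values[200:], data.labels[200:]))
print(f"final prequential accuracy: {metrics.final_accuracy:.4f}")
print(f"rules after the stream: {model.n_neurons}")
```

prints

```
Rule 1 - If (MFCC 3 is small) with impact 1.0000 then (class is heart murmur) with certainty -4.3409.
Rule 2 - If (MFCC 3 is high) with impact 1.0000 then (class is normal heart sound) with certainty 3.6321.
final prequential accuracy: 0.8544
rules after the stream: 88
```

The offline fit found one cloud per class; at a display threshold of 0.97
only the highest-impact antecedent (MFCC 3, the feature whose removal hurts
class separability the most) is shown out of the 27. The certainty is the
rule's signed readout weight: negative values pull toward "heart murmur",
positive toward "normal heart sound". Over the remaining 1800 stream
samples the partitioner evolved the rule base to 88 rules while the
accumulated predict-then-train accuracy reached 0.854 (class-1 prior
≈ 0.757, so the model clearly learns beyond the majority class).

The same workflow is available from a shell:

```sh
efnn simulate stream.csv --n-samples 2000 --seed 7
efnn fit stream.csv model.json
efnn stream model.json stream.csv --trend-out trend.csv --rules-out rules.txt
efnn rules model.json --impact-threshold 0.97
```

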
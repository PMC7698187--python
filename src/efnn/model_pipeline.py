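"""End-to-end evolving fuzzy neural network: batch initialisation, per-sample
evolving updates, prequential evaluation and JSON persistence.

The model has three layers.  Per class, a self-organising cloud partition
supplies one Gaussian fuzzy set per cloud and dimension (first layer); each
cloud owns one weighted logical neuron, i.e. one fuzzy rule (second layer);
a linear readout with one indicator-regression weight vector per class turns
the rule activations into a signed class decision (third layer).  Feature
weights come from the leave-one-feature-out Fisher separability criterion
and modulate every neuron.

Training follows a batch phase on an initial slice of the stream (cloud
identification, LOFO weights, pseudo-inverse readout) and then a per-sample
update phase: evolve the winning class partition (new clouds grow the
readout), refresh the feature weights, rebuild the neuron parameters from
the drifted clouds, track rule change at snapshot boundaries and update the
readout recursively.  Evaluation is prequential: predict first, then train.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import eda_sof, feature_weighting, interpretability, neuro_layers, output_readout
from .eda_sof import ClassPartition, Cloud, SampleMatrix
from .feature_weighting import FeatureWeightState
from .interpretability import RuleSnapshot
from .neuro_layers import MIN_MAX, PRODUCT_PROBSUM, GaussianSet, LogicNeuron
from .output_readout import ReadoutState

__all__ = ["ModelConfig", "EFNNModel", "StreamMetrics", "fit_initial", "update",
           "predict", "prequential_eval", "accuracy", "run_experiment"]

SERIAL_VERSION = 1


@dataclass
class ModelConfig:
    """Hyper-parameters of the evolving model.

    ``offline_fraction`` is the share of the stream used for the batch
    phase; ``granularity_level`` controls the influence-radius recursion of
    the cloud partitioner (higher = finer partitions, more rules); ``lam``
    is the readout forgetting factor (1 = none) and ``omega`` the initial
    inverse-Hessian scale.  ``weight_update_every`` thins the per-sample
    LOFO recomputation for speed.
    """

    neuron_kind: str = "UNI"
    g: float = 0.5
    u: float = 0.5
    beta: float = 0.5
    metric: str = "cosine"
    granularity_level: int = 2
    offline_fraction: float = 0.10
    lam: float = 1.0
    omega: float = 1000.0
    impact_threshold: float = 0.0
    snapshot_interval: int = 100
    seed: int = 0
    class_column: str = "class"
    scaling: str = "minmax"
    norms: str = "prodsum"            # "prodsum" or "minmax"
    strict_weights: bool = False
    weight_update_every: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.offline_fraction < 1.0:
            raise ValueError("offline_fraction must lie in (0, 1)")
        if self.scaling not in ("none", "minmax", "zscore"):
            raise ValueError("scaling must be none, minmax or zscore")
        if self.norms not in ("prodsum", "minmax"):
            raise ValueError("norms must be prodsum or minmax")

    @property
    def norm_pair(self):
        return PRODUCT_PROBSUM if self.norms == "prodsum" else MIN_MAX


@dataclass
class StreamMetrics:
    """Prequential accuracy trend and confusion counts of a stream run."""

    trend: list = field(default_factory=list)   # (K, accumulated accuracy)
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def final_accuracy(self) -> float:
        return self.trend[-1][1] if self.trend else 0.0

    def record(self, y_true: int, y_pred: int) -> None:
        correct = int(y_pred == y_true)
        K = len(self.trend)
        prev = self.trend[-1][1] if self.trend else 0.0
        acc = (prev * K + correct) / (K + 1)
        self.trend.append((K + 1, acc))
        if y_true == 1:
            self.tp += correct
            self.fn += 1 - correct
        else:
            self.tn += correct
            self.fp += 1 - correct


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """Batch accuracy (TP + TN) / (TP + FN + TN + FP)."""
    total = tp + tn + fp + fn
    if total <= 0:
        raise ValueError("confusion counts sum to zero")
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    return (tp + tn) / total


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class EFNNModel:
    config: ModelConfig
    partitions: dict[int, ClassPartition]
    neuron_index: list[tuple[int, int]]       # (class_id, cloud index) per neuron
    weights: FeatureWeightState
    readout: ReadoutState
    feature_names: list[str]
    class_names: dict[int, str]
    scale_offset: np.ndarray
    scale_factor: np.ndarray
    global_spread: np.ndarray
    sample_count: int = 0
    centers: np.ndarray = None     # (L, n) current rule centers
    sigmas: np.ndarray = None      # (L, n) current rule widths
    snapshots: dict[int, RuleSnapshot] = field(default_factory=dict)
    change_log: list = field(default_factory=list)
    cloud_births: list = field(default_factory=list)   # (sample_count, class_id)

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_index)

    @property
    def neurons(self) -> list[LogicNeuron]:
        """Materialised logical neurons, one per cloud, in readout order."""
        cfg = self.config
        out = []
        for l, (class_id, cloud_idx) in enumerate(self.neuron_index):
            gsets = [GaussianSet(center=float(self.centers[l, j]),
                                 sigma=float(self.sigmas[l, j]),
                                 dimension=j, cloud=cloud_idx)
                     for j in range(self.centers.shape[1])]
            out.append(LogicNeuron(kind=cfg.neuron_kind, gaussians=gsets,
                                   g=cfg.g, u=cfg.u, beta=cfg.beta,
                                   norms=cfg.norm_pair,
                                   strict_weights=cfg.strict_weights,
                                   class_id=class_id, cloud_index=cloud_idx))
        return out

    def scale(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.scale_offset) / self.scale_factor

    def rule_certainty(self, l: int) -> float:
        """Signed output-weight contribution of rule l (binary: toward class 1)."""
        v = self.readout.v
        if v.shape[0] == 2:
            return float(v[1, l + 1] - v[0, l + 1])
        k = int(np.argmax(v[:, l + 1]))
        return float(v[k, l + 1])

    def activations(self, x_scaled: np.ndarray) -> np.ndarray:
        if self.n_neurons == 0:
            return np.empty(0)
        cfg = self.config
        return neuro_layers.layer_activations_fast(
            self.centers, self.sigmas, x_scaled, self.weights.weights,
            cfg.neuron_kind, cfg.g, cfg.u, cfg.beta, cfg.norm_pair,
            cfg.strict_weights)

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        def arr(a):
            return np.asarray(a, dtype=float).tolist()

        parts = {}
        for c, p in self.partitions.items():
            parts[str(c)] = {
                "class_id": p.class_id,
                "clouds": [{"prototype": arr(cl.prototype), "center": arr(cl.center),
                            "support": cl.support, "m2": arr(cl.m2)}
                           for cl in p.clouds],
                "mean": arr(p.mean), "second_moment": arr(p.second_moment),
                "scatter": arr(p.scatter), "radius": p.radius, "count": p.count,
                "granularity": p.granularity, "metric": p.metric,
                "t_mean": arr(p.t_mean), "t_sq_mean": p.t_sq_mean,
            }
        w = self.weights
        return {
            "version": SERIAL_VERSION,
            "config": asdict(self.config),
            "partitions": parts,
            "neuron_index": [list(t) for t in self.neuron_index],
            "weights": {
                "n_features": w.n_features,
                "class_means": {str(c): arr(m) for c, m in w.class_means.items()},
                "class_counts": {str(c): n for c, n in w.class_counts.items()},
                "class_m2": {str(c): arr(m) for c, m in w.class_m2.items()},
                "overall_mean": arr(w.overall_mean),
                "total_count": w.total_count,
                "weights": arr(w.weights),
            },
            "readout": {"v": arr(self.readout.v), "Q": arr(self.readout.Q),
                        "lam": self.readout.lam, "omega": self.readout.omega,
                        "classes": self.readout.classes.tolist(),
                        "majority_class": self.readout.majority_class},
            "feature_names": self.feature_names,
            "class_names": {str(c): n for c, n in self.class_names.items()},
            "scale_offset": arr(self.scale_offset),
            "scale_factor": arr(self.scale_factor),
            "global_spread": arr(self.global_spread),
            "sample_count": self.sample_count,
            "snapshots": {str(rid): {"centers": arr(s.centers), "sigmas": arr(s.sigmas),
                                     "sample_index": s.sample_index,
                                     "consequent_sign": s.consequent_sign}
                          for rid, s in self.snapshots.items()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "EFNNModel":
        cfg = ModelConfig(**d["config"])
        parts = {}
        for key, pd in d["partitions"].items():
            clouds = [Cloud(prototype=np.array(cl["prototype"]),
                            center=np.array(cl["center"]),
                            support=int(cl["support"]), m2=np.array(cl["m2"]))
                      for cl in pd["clouds"]]
            parts[int(key)] = ClassPartition(
                class_id=pd["class_id"], clouds=clouds,
                mean=np.array(pd["mean"]), second_moment=np.array(pd["second_moment"]),
                scatter=np.array(pd["scatter"]), radius=pd["radius"],
                count=pd["count"], granularity=pd["granularity"], metric=pd["metric"],
                t_mean=np.array(pd["t_mean"]), t_sq_mean=pd["t_sq_mean"])
        wd = d["weights"]
        weights = FeatureWeightState(
            n_features=wd["n_features"],
            class_means={int(c): np.array(m) for c, m in wd["class_means"].items()},
            class_counts={int(c): int(n) for c, n in wd["class_counts"].items()},
            class_m2={int(c): np.array(m) for c, m in wd["class_m2"].items()},
            overall_mean=np.array(wd["overall_mean"]),
            total_count=wd["total_count"], weights=np.array(wd["weights"]))
        rd = d["readout"]
        readout = ReadoutState(v=np.array(rd["v"]), Q=np.array(rd["Q"]),
                               lam=rd["lam"], omega=rd["omega"],
                               classes=np.array(rd["classes"], dtype=int),
                               majority_class=rd["majority_class"])
        model = cls(config=cfg, partitions=parts,
                    neuron_index=[tuple(t) for t in d["neuron_index"]],
                    weights=weights, readout=readout,
                    feature_names=list(d["feature_names"]),
                    class_names={int(c): n for c, n in d["class_names"].items()},
                    scale_offset=np.array(d["scale_offset"]),
                    scale_factor=np.array(d["scale_factor"]),
                    global_spread=np.array(d["global_spread"]),
                    sample_count=d["sample_count"])
        model.snapshots = {int(r): RuleSnapshot(rule_id=int(r),
                                                centers=np.array(s["centers"]),
                                                sigmas=np.array(s["sigmas"]),
                                                sample_index=s["sample_index"],
                                                consequent_sign=s["consequent_sign"])
                           for r, s in d["snapshots"].items()}
        _rebuild_neurons(model)
        return model

    @classmethod
    def load(cls, path) -> "EFNNModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_scaler(values: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray]:
    if scaling == "none":
        return np.zeros(values.shape[1]), np.ones(values.shape[1])
    if scaling == "minmax":
        lo = values.min(axis=0)
        rng = values.max(axis=0) - lo
        rng = np.where(rng == 0.0, 1.0, rng)
        return lo, rng
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.ones(values.shape[1])
    sd = np.where(sd == 0.0, 1.0, sd)
    return mu, sd


def _rebuild_neurons(model: EFNNModel) -> None:
    """Refresh the stacked rule centers/widths from current cloud state.

    Neuron order (and hence readout column order) is fixed by
    ``neuron_index``; cloud drift moves the rules continuously.  Widths are
    the per-dimension member spreads floored at a fraction of the global
    per-dimension spread of the offline slice.
    """
    floor = np.maximum(eda_sof.SIGMA_REL_FLOOR * model.global_spread,
                       eda_sof.SIGMA_ABS_FLOOR)
    L = len(model.neuron_index)
    n = model.global_spread.size
    centers = np.empty((L, n))
    sigmas = np.empty((L, n))
    for l, (class_id, cloud_idx) in enumerate(model.neuron_index):
        cl = model.partitions[class_id].clouds[cloud_idx]
        centers[l] = cl.center
        sigmas[l] = np.maximum(cl.member_spread, floor)
    model.centers = centers
    model.sigmas = sigmas


def _take_snapshots(model: EFNNModel) -> dict[int, RuleSnapshot]:
    return {l + 1: RuleSnapshot(rule_id=l + 1, centers=model.centers[l].copy(),
                                sigmas=model.sigmas[l].copy(),
                                sample_index=model.sample_count,
                                consequent_sign=float(np.sign(model.rule_certainty(l))))
            for l in range(model.n_neurons)}


def fit_initial(X: SampleMatrix, cfg: ModelConfig,
                feature_names: list[str] | None = None,
                class_names: dict[int, str] | None = None) -> EFNNModel:
    """Batch phase on the offline slice: clouds, weights, neurons, readout."""
    classes = np.unique(X.labels)
    if classes.size < 2:
        raise ValueError(
            "the offline slice contains a single class; enlarge offline_fraction")
    offset, factor = _fit_scaler(X.values, cfg.scaling)
    scaled = (X.values - offset) / factor
    parts_list = eda_sof.fit_offline(SampleMatrix(scaled, X.labels),
                                     level=cfg.granularity_level, metric=cfg.metric)
    partitions = {p.class_id: p for p in parts_list}
    if scaled.shape[0] > 1:
        global_spread = scaled.std(axis=0, ddof=1)
    else:
        global_spread = np.ones(scaled.shape[1])

    weights = FeatureWeightState(n_features=scaled.shape[1])
    for x, y in zip(scaled, X.labels):
        feature_weighting.update_scatter(weights, x, int(y))
    feature_weighting.recompute_weights(weights)

    neuron_index = [(c, i) for c in sorted(partitions)
                    for i in range(partitions[c].n_clouds)]
    if feature_names is None:
        feature_names = [f"feature {j + 1}" for j in range(scaled.shape[1])]
    if class_names is None:
        class_names = {int(c): f"class {int(c)}" for c in classes}

    model = EFNNModel(config=cfg, partitions=partitions,
                      neuron_index=neuron_index, weights=weights,
                      readout=None,  # type: ignore[arg-type]
                      feature_names=list(feature_names), class_names=class_names,
                      scale_offset=offset, scale_factor=factor,
                      global_spread=global_spread, sample_count=X.n_samples)
    _rebuild_neurons(model)
    Z = np.array([model.activations(x) for x in scaled])
    model.readout = output_readout.batch_estimate(Z, X.labels, lam=cfg.lam,
                                                  omega=cfg.omega, classes=classes)
    model.snapshots = _take_snapshots(model)
    return model


def update(model: EFNNModel, x: np.ndarray, y: int) -> EFNNModel:
    """One evolving update: partition, feature weights, neurons, rule-change
    bookkeeping, readout — in that order."""
    y = int(y)
    if y not in model.partitions:
        raise ValueError(f"unseen class label {y}")
    xs = model.scale(x)
    cfg = model.config

    part = model.partitions[y]
    n_before = part.n_clouds
    eda_sof.update_online(part, xs)
    if part.n_clouds > n_before:
        model.neuron_index.append((y, part.n_clouds - 1))
        model.readout.grow(1)
        model.cloud_births.append((model.sample_count, y))

    feature_weighting.update_scatter(model.weights, xs, y)
    if model.sample_count % cfg.weight_update_every == 0:
        feature_weighting.recompute_weights(model.weights)

    _rebuild_neurons(model)
    model.sample_count += 1

    if cfg.snapshot_interval > 0 and model.sample_count % cfg.snapshot_interval == 0:
        current = _take_snapshots(model)
        rows = interpretability.change_report(
            list(model.snapshots.values()), list(current.values()))
        for row in rows:
            row["sample_index"] = model.sample_count
        model.change_log.extend(rows)
        model.snapshots = current

    z = model.activations(xs)
    output_readout.rwls_update(model.readout, z, y)
    return model


def predict(model: EFNNModel, x: np.ndarray) -> int:
    return output_readout.predict_class(model.readout, model.activations(model.scale(x)))


def prequential_eval(model: EFNNModel, stream: SampleMatrix,
                     update_model: bool = True) -> StreamMetrics:
    """Interleaved predict-then-train evaluation over a stream.

    The accumulated accuracy starts at 0 and follows the running-ratio
    recursion; ``update_model=False`` scores a frozen model for comparison.
    """
    metrics = StreamMetrics()
    for x, yt in zip(stream.values, stream.labels):
        yhat = predict(model, x)
        metrics.record(int(yt), yhat)
        if update_model:
            update(model, x, int(yt))
    return metrics


def run_experiment(data: SampleMatrix, cfg: ModelConfig,
                   feature_names: list[str] | None = None,
                   class_names: dict[int, str] | None = None,
                   update_model: bool = True) -> tuple[EFNNModel, StreamMetrics]:
    """Split the stream by ``cfg.offline_fraction`` (in stream order), fit the
    batch phase and run prequential evaluation on the remainder."""
    K = data.n_samples
    k_off = max(2, int(round(cfg.offline_fraction * K)))
    offline = SampleMatrix(data.values[:k_off], data.labels[:k_off])
    online = SampleMatrix(data.values[k_off:], data.labels[k_off:])
    model = fit_initial(offline, cfg, feature_names, class_names)
    metrics = prequential_eval(model, online, update_model=update_model)
    return model, metrics
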
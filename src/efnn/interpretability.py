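"""Linguistic rule rendering and rule-change tracking.

Each logical neuron is one if-then rule: its Gaussian antecedents become
linguistic terms (per dimension, the cloud centers are ranked and labelled
from the ladder "very small" ... "very high"), the LOFO feature weight is
the antecedent's *impact*, the neuron kind fixes the connector, and the
neuron's contribution to the signed readout gives the consequent class and
certainty.  Antecedents with impact below a display threshold are suppressed
from the rendered text only — the model keeps using them.

Rule change over a stream interval is the complement of the aggregated
overlap similarity of each antecedent Gaussian before and after the update
interval: the membership value at the intersection point(s) of the two
Gaussians, aggregated across dimensions (min by default), gives a rule
similarity S in [0, 1]; the change degree is 1 - S.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LinguisticRule",
    "RuleSnapshot",
    "IDENTICAL",
    "linguistic_terms",
    "term_labels_for_dimension",
    "render_rules",
    "gaussian_intersections",
    "antecedent_similarity",
    "rule_similarity",
    "change_degree",
    "change_report",
    "write_change_report",
]

TERM_LADDER = ("very small", "small", "medium", "high", "very high")

#: Sentinel returned when two Gaussians coincide (no intersection, zero change).
IDENTICAL = "identical"


@dataclass
class LinguisticRule:
    """A rendered if-then rule: per-feature (term, impact, shown) antecedents."""

    rule_id: int
    antecedents: list[tuple[str, str, float, bool]]  # (feature, term, impact, shown)
    connector: str
    consequent_class: str
    certainty: float

    def text(self) -> str:
        parts = [f"({name} is {term}) with impact {imp:.4f}"
                 for name, term, imp, shown in self.antecedents if shown]
        joiner = f" {self.connector} "
        body = joiner.join(parts) if parts else "(no antecedent above threshold)"
        return (f"Rule {self.rule_id} - If {body} then (class is "
                f"{self.consequent_class}) with certainty {self.certainty:.4f}.")


@dataclass
class RuleSnapshot:
    """Frozen antecedent Gaussians of one rule at a given stream position."""

    rule_id: int
    centers: np.ndarray
    sigmas: np.ndarray
    sample_index: int
    consequent_sign: float = 0.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if np.any(self.sigmas <= 0):
            raise ValueError("snapshot sigmas must be positive")


# ---------------------------------------------------------------------------
# linguistic terms
# ---------------------------------------------------------------------------

def term_labels_for_dimension(n_terms: int) -> list[str]:
    """Ordered labels for ``n_terms`` fuzzy sets in one dimension.

    Four sets use the convention very small / small / medium / high; other
    counts anchor into the five-step ladder (a single set is "medium",
    more than five cycle with an ordinal suffix).
    """
    if n_terms == 1:
        return ["medium"]
    if n_terms == 2:
        return ["small", "high"]
    if n_terms == 3:
        return ["small", "medium", "high"]
    if n_terms == 4:
        return ["very small", "small", "medium", "high"]
    if n_terms == 5:
        return list(TERM_LADDER)
    labels = []
    for i in range(n_terms):
        base = TERM_LADDER[round(i * 4 / (n_terms - 1))]
        labels.append(base)
    # disambiguate repeated anchors with an ordinal suffix
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
        out.append(lab if labels.count(lab) == 1 else f"{lab} ({seen[lab]})")
    return out


def linguistic_terms(centers: np.ndarray) -> list[list[str]]:
    """Assign a term label to every cloud in every dimension.

    ``centers`` is L x n (clouds x features).  Within each dimension the
    labels follow ascending center order; ties keep appearance order.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    L, n = centers.shape
    labels = [[""] * n for _ in range(L)]
    names = term_labels_for_dimension(L)
    for j in range(n):
        order = np.argsort(centers[:, j], kind="stable")
        for rank, l in enumerate(order):
            labels[l][j] = names[rank]
    return labels


# ---------------------------------------------------------------------------
# rule rendering
# ---------------------------------------------------------------------------

_CONNECTOR = {"AND": "and", "OR": "or", "UNI": "and/or", "NULL": "and/or"}


def render_rules(model, impact_threshold: float = 0.0,
                 markdown: bool = False) -> str:
    """Rule text for every neuron of a fitted model.

    The consequent is the class implied by the sign of the neuron's signed
    output-weight contribution; the certainty is that weight.  Antecedents
    whose impact falls below the threshold are hidden from display only.
    """
    rules = extract_rules(model, impact_threshold)
    lines = []
    for r in rules:
        line = r.text()
        lines.append(f"- {line}" if markdown else line)
    return "\n".join(lines)


def extract_rules(model, impact_threshold: float = 0.0) -> list[LinguisticRule]:
    """Structured rules from a fitted model (see :func:`render_rules`)."""
    centers = np.array([nr.centers for nr in model.neurons])
    terms = linguistic_terms(centers)
    w = model.weights.weights
    names = list(model.feature_names)
    rules = []
    for l, nr in enumerate(model.neurons):
        signed = model.rule_certainty(l)
        consequent = model.class_names[1] if signed >= 0 else model.class_names[0]
        if nr.kind == "UNINULL":
            connector = f"and/or({nr.g:g},{nr.u:g},{nr.beta:g})"
        else:
            connector = _CONNECTOR[nr.kind]
        ants = [(names[j], terms[l][j], float(w[j]), bool(w[j] >= impact_threshold))
                for j in range(centers.shape[1])]
        rules.append(LinguisticRule(rule_id=l + 1, antecedents=ants,
                                    connector=connector,
                                    consequent_class=consequent,
                                    certainty=signed))
    return rules


# ---------------------------------------------------------------------------
# rule-change degree
# ---------------------------------------------------------------------------

def gaussian_intersections(c1: float, s1: float, c2: float, s2: float):
    """x-coordinates where two Gaussian membership functions are equal.

    Unequal widths give the two roots of the induced quadratic; equal widths
    with distinct centers give the single symmetry midpoint; identical
    parameters return the ``IDENTICAL`` sentinel (the curves coincide
    everywhere).
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("sigmas must be positive")
    if s1 == s2:
        if c1 == c2:
            return IDENTICAL
        return [0.5 * (c1 + c2)]
    # ((x-c1)/s1)^2 = ((x-c2)/s2)^2
    a = s2 ** 2 - s1 ** 2
    b = -2.0 * (c1 * s2 ** 2 - c2 * s1 ** 2)
    c = c1 ** 2 * s2 ** 2 - c2 ** 2 * s1 ** 2
    disc = b * b - 4.0 * a * c
    disc = max(disc, 0.0)
    sq = np.sqrt(disc)
    return [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]


def _membership(x: float, c: float, s: float) -> float:
    z = (x - c) / s
    return float(np.exp(-0.5 * z * z))


def antecedent_similarity(before: tuple[float, float],
                          after: tuple[float, float]) -> float:
    """Overlap similarity of one antecedent before/after an update interval:
    the maximal membership value over the intersection points (1 for
    identical Gaussians)."""
    c1, s1 = before
    c2, s2 = after
    pts = gaussian_intersections(c1, s1, c2, s2)
    if pts is IDENTICAL:
        return 1.0
    return max(_membership(x, c1, s1) for x in pts)


def rule_similarity(before: RuleSnapshot, after: RuleSnapshot,
                    agg: str = "min") -> float:
    """Aggregate the per-dimension antecedent similarities (min or product).

    Min follows the geometric argument that strong non-overlap in a single
    dimension already tears two rules apart; the product option is stricter
    than any single dimension and never exceeds the min result.
    """
    if before.centers.shape != after.centers.shape:
        raise ValueError("snapshots must cover the same feature set")
    sims = [antecedent_similarity((before.centers[j], before.sigmas[j]),
                                  (after.centers[j], after.sigmas[j]))
            for j in range(before.centers.size)]
    if agg == "min":
        return float(min(sims))
    if agg == "product":
        return float(np.prod(sims))
    raise ValueError(f"unknown aggregation {agg!r}")


def change_degree(before: RuleSnapshot, after: RuleSnapshot,
                  agg: str = "min") -> tuple[float, bool]:
    """Degree of change of one rule over an interval: 1 minus the rule
    similarity, plus a flag for a consequent sign flip."""
    if before.rule_id != after.rule_id:
        raise ValueError("snapshots belong to different rules")
    lam = 1.0 - rule_similarity(before, after, agg)
    flipped = (before.consequent_sign * after.consequent_sign) < 0
    return lam, bool(flipped)


def change_report(befores: list[RuleSnapshot], afters: list[RuleSnapshot],
                  agg: str = "min", sim_threshold: float = 1.0 - 1e-12) -> list[dict]:
    """Per-rule change rows for one snapshot interval."""
    by_id = {s.rule_id: s for s in befores}
    rows = []
    for aft in afters:
        bef = by_id.get(aft.rule_id)
        if bef is None:
            continue
        lam, flipped = change_degree(bef, aft, agg)
        n_changed = sum(
            antecedent_similarity((bef.centers[j], bef.sigmas[j]),
                                  (aft.centers[j], aft.sigmas[j])) < sim_threshold
            for j in range(bef.centers.size))
        rows.append({"rule_id": aft.rule_id, "n_dims_changed": int(n_changed),
                     "degree": lam, "consequent_changed": flipped})
    return rows


def write_change_report(rows: list[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["rule_id", "n_dims_changed", "degree",
                            "consequent_changed"])
        writer.writeheader()
        writer.writerows(rows)
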
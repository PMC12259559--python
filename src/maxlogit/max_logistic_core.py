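"""The max-logistic competing-factor classifier.

A *competing factor* (CF) is an affine combination of (possibly transformed)
gene expression values,

    CF_i = b_i + sum_g  w_{ig} * t(x_g),

where t is the factor's transform (identity, ln(x+1), or values used as
given on a platform log2 scale). A *panel* holds one or more competing
factors; the panel score of a sample is CF_max = max_i CF_i, and the risk of
the positive class is the logistic of that maximum:

    risk = exp(CF_max) / (1 + exp(CF_max)).

A sample is called positive when risk exceeds the threshold (default 0.5,
i.e. CF_max > 0); a risk of exactly 0.5 is a control call — the published
rule is "above 50% risk". Because the panel score is a maximum, adding a
factor can only raise risks: sensitivity never decreases and specificity
never increases with panel size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.special import expit

from .cohort_io import ExpressionMatrix, SampleLabels
from .errors import DomainError, ValidationError

TRANSFORMS = ("identity", "ln1p", "log2_as_given")

#: matrix scales on which each factor transform may be evaluated.
#: ``ln1p`` factors are evaluated on raw (identity) values and apply the
#: log themselves; ``log2_as_given`` uses platform-provided log-like values
#: verbatim.
_COMPATIBLE_SCALES = {
    "identity": {"identity"},
    "ln1p": {"identity"},
    "log2_as_given": {"log2", "ln1p"},
}


@dataclass(frozen=True)
class CompetingFactor:
    """One competing risk factor: intercept + sparse gene weights."""

    intercept: float
    coefficients: Mapping[str, float]
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValidationError(
                f"unknown transform {self.transform!r}; expected one of {TRANSFORMS}"
            )
        coeffs = dict(self.coefficients)
        if not coeffs:
            raise ValidationError("a competing factor needs at least one gene coefficient")
        for g, w in coeffs.items():
            if not math.isfinite(w):
                raise ValidationError(f"non-finite coefficient for gene {g!r}")
            if w == 0.0:
                raise ValidationError(f"zero coefficient for gene {g!r} must be omitted")
        if not math.isfinite(self.intercept):
            raise ValidationError("non-finite intercept")
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.coefficients)


def _apply_transform(x: float, transform: str, gene: str) -> float:
    if transform == "ln1p":
        if x + 1.0 <= 0.0:
            raise DomainError(f"ln(x+1) undefined for gene {gene!r} value {x}")
        return math.log1p(x)
    return x  # identity and log2_as_given both use the value as provided


def cf_value(cf: CompetingFactor, sample_expression: Mapping[str, float]) -> float:
    """Evaluate one competing factor on a gene -> expression mapping.

    Gene names are matched case-insensitively. A gene required by the
    factor but absent from the mapping is an error.
    """
    lookup = {str(g).strip().casefold(): float(v) for g, v in sample_expression.items()}
    total = float(cf.intercept)
    for gene, weight in cf.coefficients.items():
        key = gene.strip().casefold()
        if key not in lookup:
            raise ValidationError(f"gene {gene!r} missing from sample expression")
        total += weight * _apply_transform(lookup[key], cf.transform, gene)
    return total


@dataclass
class MaxLogisticPanel:
    """Ordered competing factors with class names and a risk threshold."""

    factors: list[CompetingFactor]
    positive_class: str
    control_class: str
    risk_threshold: float = 0.5
    name: str | None = None

    def __post_init__(self) -> None:
        self.factors = list(self.factors)
        if not self.factors:
            raise ValidationError("a panel needs at least one competing factor")
        if not 0.0 < self.risk_threshold < 1.0:
            raise ValidationError("risk_threshold must lie strictly between 0 and 1")
        if self.positive_class == self.control_class:
            raise ValidationError("positive and control class must differ")

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for f in self.factors:
            for g in f.genes:
                seen.setdefault(g, None)
        return tuple(seen)

    def with_factor(self, factor: CompetingFactor) -> "MaxLogisticPanel":
        return MaxLogisticPanel(
            self.factors + [factor], self.positive_class, self.control_class,
            self.risk_threshold, self.name,
        )


def cf_max(panel: MaxLogisticPanel, sample_expression: Mapping[str, float]) -> float:
    """Maximum competing-factor value of a sample."""
    return max(cf_value(f, sample_expression) for f in panel.factors)


_RISK_LO = float(np.nextafter(0.0, 1.0))
_RISK_HI = float(np.nextafter(1.0, 0.0))


def panel_risk(panel: MaxLogisticPanel, sample_expression: Mapping[str, float]) -> float:
    """Risk probability: logistic(CF_max), strictly inside (0, 1).

    The logistic saturates in floating point around |CF_max| ~ 37; the
    result is nudged to the nearest representable value inside the open
    unit interval so the strict bounds hold for arbitrarily extreme scores.
    """
    risk = float(expit(cf_max(panel, sample_expression)))
    return min(max(risk, _RISK_LO), _RISK_HI)


def _check_scale(panel: MaxLogisticPanel, matrix: ExpressionMatrix) -> None:
    for f in panel.factors:
        if matrix.scale not in _COMPATIBLE_SCALES[f.transform]:
            raise ValidationError(
                f"factor transform {f.transform!r} is not applicable to a matrix "
                f"on scale {matrix.scale!r}"
            )
    for g in panel.genes:
        if not matrix.has_gene(g):
            raise ValidationError(f"panel gene {g!r} not present in matrix")


def panel_risks(panel: MaxLogisticPanel, matrix: ExpressionMatrix) -> dict[str, float]:
    """Risk per sample over a whole matrix."""
    _check_scale(panel, matrix)
    return {
        s: panel_risk(panel, matrix.sample_expression(s)) for s in matrix.sample_ids
    }


def classify(panel: MaxLogisticPanel, matrix: ExpressionMatrix) -> dict[str, str]:
    """Predicted class per sample: positive iff risk strictly above threshold."""
    risks = panel_risks(panel, matrix)
    return {
        s: panel.positive_class if r > panel.risk_threshold else panel.control_class
        for s, r in risks.items()
    }


@dataclass
class ClassificationReport:
    """Confusion counts, summary metrics and per-sample risks."""

    tp: int
    fp: int
    tn: int
    fn: int
    per_sample_risk: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "total": self.total,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    def write_risks_tsv(self, path: str | Path) -> None:
        with open(path, "w") as f:
            f.write("sample_id\trisk\n")
            for s, r in self.per_sample_risk.items():
                f.write(f"{s}\t{r!r}\n")


def evaluate(
    predictions: Mapping[str, str],
    labels: SampleLabels,
    risks: Mapping[str, float] | None = None,
) -> ClassificationReport:
    """Confusion counts of predictions against labels.

    Prediction and label sample sets must coincide exactly.
    """
    pred_ids = set(predictions)
    label_ids = set(labels.sample_ids)
    if pred_ids != label_ids:
        missing = sorted(label_ids - pred_ids)[:5]
        extra = sorted(pred_ids - label_ids)[:5]
        raise ValidationError(
            f"prediction/label sample sets differ (missing {missing}, extra {extra})"
        )
    tp = fp = tn = fn = 0
    for s, truth in zip(labels.sample_ids, labels.labels):
        pos = predictions[s] == labels.positive_class
        if truth == labels.positive_class:
            tp += pos
            fn += not pos
        else:
            fp += pos
            tn += not pos
    return ClassificationReport(tp, fp, tn, fn, dict(risks) if risks else {})


def score_panel(
    panel: MaxLogisticPanel, matrix: ExpressionMatrix, labels: SampleLabels
) -> ClassificationReport:
    """Classify a matrix with a panel and evaluate against labels."""
    risks = panel_risks(panel, matrix)
    preds = {
        s: panel.positive_class if r > panel.risk_threshold else panel.control_class
        for s, r in risks.items()
    }
    return evaluate(preds, labels, risks)


# ---------------------------------------------------------------------------
# JSON serialization (bit-exact round trip via repr-style floats)
# ---------------------------------------------------------------------------

def panel_to_dict(panel: MaxLogisticPanel) -> dict:
    return {
        "positive_class": panel.positive_class,
        "control_class": panel.control_class,
        "risk_threshold": panel.risk_threshold,
        "factors": [
            {
                "intercept": f.intercept,
                "transform": f.transform,
                "coefficients": dict(f.coefficients),
            }
            for f in panel.factors
        ],
    }


def panel_from_dict(d: Mapping) -> MaxLogisticPanel:
    try:
        factors = [
            CompetingFactor(
                intercept=float(f["intercept"]),
                coefficients={str(g): float(w) for g, w in f["coefficients"].items()},
                transform=f.get("transform", "identity"),
            )
            for f in d["factors"]
        ]
        return MaxLogisticPanel(
            factors=factors,
            positive_class=str(d["positive_class"]),
            control_class=str(d["control_class"]),
            risk_threshold=float(d.get("risk_threshold", 0.5)),
            name=d.get("name"),
        )
    except KeyError as e:
        raise ValidationError(f"panel JSON missing field {e}") from None


def save_panel(panel: MaxLogisticPanel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(panel_to_dict(panel), indent=2) + "\n")


def load_panel(path: str | Path) -> MaxLogisticPanel:
    return panel_from_dict(json.loads(Path(path).read_text()))
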
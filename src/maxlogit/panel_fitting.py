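"""Gene screening and competing-factor panel fitting.

The construction emulates how the published panels behave:

1. **Screening** ranks genes by single-gene separability (best-threshold
   training accuracy over both decision directions, ties broken by absolute
   log2 fold change). This is a documented proxy for the original
   critical-DEG selection rules, which are not public; results carry a
   ``screening="best_threshold_proxy"`` marker in the trace.
2. **Factor fitting** estimates a direction with a ridge-penalized logistic
   fit (lambda = 1e-6 on internally standardized features, for stability
   under perfect separation), then places the intercept. In
   ``specificity_first`` mode the intercept is pushed down until every
   control scores at most ``-margin`` (training specificity 1.0 by
   construction) and sensitivity is whatever the direction then allows. In
   ``accuracy_first`` mode the intercept (and the direction's orientation)
   is chosen to maximize training accuracy — in one dimension this equals a
   brute-force scan over all thresholds.
3. **Greedy factor addition** exhaustively searches subsets (up to
   ``max_genes_per_factor`` genes) of the screened pool for the factor
   capturing the most still-missed positives; each new factor is fitted on
   all controls plus the currently missed positives only, mirroring how a
   dedicated factor can be built to "adjust for" an outlying patient.
   Addition stops when all positives are captured, no candidate adds
   coverage, or ``max_factors`` is reached.

Fitting is fully deterministic: subsets are enumerated in sorted order and
ties are broken by (fewer genes, lexicographic gene names). The config seed
only matters for synthetic data generation, never for fitting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .cohort_io import ExpressionMatrix, SampleLabels
from .errors import FitError, ValidationError
from .max_logistic_core import (
    ClassificationReport,
    CompetingFactor,
    MaxLogisticPanel,
    score_panel,
)

#: ridge penalty on the standardized design
RIDGE_LAMBDA = 1e-6

MODES = ("specificity_first", "accuracy_first")


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the subset search and factor construction."""

    max_genes_per_factor: int = 4
    max_factors: int = 3
    screen_top_m: int = 50
    specificity_floor: float = 1.0
    margin: float = 1e-6
    mode: str = "specificity_first"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_genes_per_factor < 1:
            raise ValidationError("max_genes_per_factor must be >= 1")
        if self.max_factors < 1:
            raise ValidationError("max_factors must be >= 1")
        if not 0.0 <= self.specificity_floor <= 1.0:
            raise ValidationError("specificity_floor must lie in [0, 1]")
        if self.margin <= 0:
            raise ValidationError("margin must be positive")
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}; expected one of {MODES}")


@dataclass
class FitResult:
    panel: MaxLogisticPanel
    training_report: ClassificationReport
    gene_subset_trace: list[tuple[tuple[str, ...], float]] = field(repr=False, default_factory=list)
    screening: str = "best_threshold_proxy"


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def best_threshold_accuracy(x: np.ndarray, y: np.ndarray) -> float:
    """Best training accuracy of any single threshold on x, either direction.

    ``y`` is boolean (True = positive). Thresholds are taken strictly, i.e.
    predict positive when x > t (or x < t); every distinct split of the
    sorted values is examined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=bool)
    n = len(x)
    order = np.argsort(x, kind="stable")
    ys = y[order]
    xs = x[order]
    n_pos = int(ys.sum())
    # positives below or at each split position i (first i samples negative call)
    pos_below = np.concatenate([[0], np.cumsum(ys)])
    neg_below = np.arange(n + 1) - pos_below
    # valid split points: between distinct values (and the two extremes)
    distinct = np.concatenate([[True], xs[1:] != xs[:-1], [True]])
    # direction "high is positive": first i samples -> control
    correct_hi = neg_below + (n_pos - pos_below)
    # direction "low is positive": first i samples -> positive
    correct_lo = pos_below + (n - n_pos - neg_below)
    best = max(correct_hi[distinct].max(), correct_lo[distinct].max())
    return float(best) / n


def _log2_values(matrix: ExpressionMatrix) -> np.ndarray:
    if matrix.scale == "identity":
        return np.log2(matrix.values + 1.0)
    return matrix.values  # already log-like


def screen_genes(
    matrix: ExpressionMatrix, labels: SampleLabels, top_m: int
) -> list[tuple[str, float]]:
    """Rank genes by single-gene separability; return the top_m with scores.

    A gene constant across all samples scores 0.5 (chance). Ties are broken
    by absolute log2 fold change between class means, then by gene name.
    """
    if top_m > matrix.n_genes:
        raise ValidationError(
            f"top_m={top_m} exceeds the {matrix.n_genes} genes available"
        )
    aligned = matrix.subset_samples(labels.sample_ids)
    y = labels.is_positive()
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValidationError("screening needs at least two samples per class")
    logv = _log2_values(aligned)
    ranked = []
    for i, gene in enumerate(aligned.gene_ids):
        x = aligned.values[i]
        if np.ptp(x) == 0.0:
            score, lfc = 0.5, 0.0
        else:
            score = best_threshold_accuracy(x, y)
            lfc = abs(float(logv[i][y].mean() - logv[i][~y].mean()))
        ranked.append((gene, score, lfc))
    ranked.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return [(g, s) for g, s, _ in ranked[:top_m]]


# ---------------------------------------------------------------------------
# Single-factor fitting
# ---------------------------------------------------------------------------

def _ridge_logistic_direction(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ridge-logistic coefficient vector on the original feature scale.

    Features are standardized internally; columns with zero variance are
    dropped (coefficient 0). Raises FitError if nothing varies.
    """
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise FitError("degenerate gene subset: all genes constant on the training set")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    model = LogisticRegression(
        C=1.0 / RIDGE_LAMBDA, solver="lbfgs", max_iter=1000, tol=1e-6
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Z, y.astype(int))
    w = np.zeros(X.shape[1])
    w[keep] = model.coef_[0] / sd[keep]
    return w


def _best_intercept(scores: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Intercept maximizing accuracy of `score + b > 0`; ties -> higher specificity.

    Returns (intercept, correct_count).
    """
    n = len(scores)
    order = np.argsort(scores, kind="stable")
    ss, ys = scores[order], y[order]
    n_pos = int(ys.sum())
    pos_below = np.concatenate([[0], np.cumsum(ys)])
    neg_below = np.arange(n + 1) - pos_below
    correct = neg_below + (n_pos - pos_below)  # first i samples called control
    distinct = np.concatenate([[True], ss[1:] != ss[:-1], [True]])
    correct = np.where(distinct, correct, -1)
    # among ties prefer the largest split index => more controls, higher specificity
    best_i = int(np.flatnonzero(correct == correct.max())[-1])
    if best_i == 0:
        b = -(ss[0] - 1.0)
    elif best_i == n:
        b = -(ss[-1] + 1.0)
    else:
        b = -0.5 * (ss[best_i - 1] + ss[best_i])
    return float(b), int(correct.max())


def fit_competing_factor(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    gene_subset: Sequence[str],
    config: FitConfig,
) -> CompetingFactor:
    """Fit one competing factor on a gene subset.

    specificity_first: every control's CF value ends at or below ``-margin``
    (training specificity 1.0 by construction), with sensitivity maximized
    given the fitted direction. accuracy_first: the intercept — and the
    orientation of the direction — maximize training accuracy.
    """
    genes = list(gene_subset)
    if not genes:
        raise FitError("empty gene subset")
    if len(genes) > config.max_genes_per_factor:
        raise ValidationError(
            f"subset of {len(genes)} genes exceeds max_genes_per_factor="
            f"{config.max_genes_per_factor}"
        )
    aligned = matrix.subset_genes(genes).subset_samples(labels.sample_ids)
    y = labels.is_positive()
    X = aligned.values.T  # samples x genes
    w = _ridge_logistic_direction(X, y)

    transform = "identity" if matrix.scale == "identity" else "log2_as_given"

    def build(w_vec: np.ndarray, intercept: float) -> CompetingFactor:
        coeffs = {g: float(c) for g, c in zip(aligned.gene_ids, w_vec) if c != 0.0}
        if not coeffs:
            raise FitError("degenerate fit: all coefficients zero")
        return CompetingFactor(float(intercept), coeffs, transform)

    if config.mode == "specificity_first":
        best = None
        for w_try in (w, -w):
            scores = X @ w_try
            ctrl_max = scores[~y].max()
            b = -float(ctrl_max) - config.margin
            captured = int(((scores + b) > 0)[y].sum())
            if best is None or captured > best[0]:
                best = (captured, w_try, b)
        _, w_best, b = best
        return build(w_best, b)

    # accuracy_first
    best = None
    for w_try in (w, -w):
        scores = X @ w_try
        b, correct = _best_intercept(scores, y)
        if best is None or correct > best[0]:
            best = (correct, w_try, b)
    _, w_best, b = best
    return build(w_best, b)


# ---------------------------------------------------------------------------
# Greedy panel construction
# ---------------------------------------------------------------------------

def _factor_scores(factor: CompetingFactor, matrix: ExpressionMatrix) -> np.ndarray:
    genes = list(factor.genes)
    sub = matrix.subset_genes(genes)
    w = np.array([factor.coefficients[g] for g in genes])
    vals = sub.values
    if factor.transform == "ln1p":
        vals = np.log1p(vals)
    return factor.intercept + w @ vals


def fit_panel(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    config: FitConfig | None = None,
    genes: Iterable[str] | None = None,
) -> FitResult:
    """Discover a max-logistic panel by greedy competing-factor addition.

    ``genes`` restricts the search pool; otherwise the pool is the
    ``config.screen_top_m`` best-screening genes. Subsets of the pool up to
    ``config.max_genes_per_factor`` genes are searched exhaustively for the
    factor capturing the most still-missed positive samples.
    """
    config = config or FitConfig()
    aligned = matrix.subset_samples(labels.sample_ids)
    if genes is None:
        pool = [g for g, _ in screen_genes(aligned, labels, min(config.screen_top_m, aligned.n_genes))]
    else:
        pool = list(genes)
        for g in pool:
            if not aligned.has_gene(g):
                raise ValidationError(f"pool gene {g!r} not present in matrix")
    if not pool:
        raise FitError("empty gene pool: nothing to search")
    pool = sorted(pool)

    y = labels.is_positive()
    sample_ids = list(aligned.sample_ids)
    pos_ids = [s for s, p in zip(sample_ids, y) if p]
    ctrl_ids = [s for s, p in zip(sample_ids, y) if not p]

    missed = list(pos_ids)
    factors: list[CompetingFactor] = []
    trace: list[tuple[tuple[str, ...], float]] = []

    while len(factors) < config.max_factors and missed:
        train_ids = ctrl_ids + missed
        train_labels = labels.subset(train_ids)
        train_matrix = aligned.subset_samples(train_ids)
        missed_matrix = aligned.subset_samples(missed)
        best = None  # (coverage, -n_genes, subset, factor)
        for size in range(1, config.max_genes_per_factor + 1):
            for subset in itertools.combinations(pool, size):
                try:
                    factor = fit_competing_factor(train_matrix, train_labels, subset, config)
                except FitError:
                    continue
                coverage = int((_factor_scores(factor, missed_matrix) > 0).sum())
                trace.append((subset, coverage))
                key = (coverage, -len(subset))
                if best is None or key > best[0]:
                    best = (key, subset, factor)
        if best is None:
            if factors:
                break
            raise FitError("no fittable gene subset in the pool")
        (coverage, _), subset, factor = best
        if coverage == 0 and factors:
            break  # nothing left to gain
        factors.append(factor)
        covered = _factor_scores(factor, missed_matrix) > 0
        missed = [s for s, c in zip(missed, covered) if not c]
        if coverage == 0:
            break  # a first factor is returned even if it captures nothing

    panel = MaxLogisticPanel(
        factors, labels.positive_class, labels.control_class,
    )
    report = score_panel(panel, aligned, labels)
    return FitResult(panel, report, trace)
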
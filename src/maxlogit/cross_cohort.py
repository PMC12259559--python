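"""Cohort-to-cohort cross-validation of a fixed gene set.

Cohorts from different platforms, tissues and populations cannot be pooled
without introducing batch effects. Instead of correcting batches, the gene
*set* is validated: coefficients are refit independently within every
cohort and each cohort is scored on its own refit. Metrics are then pooled
by summing confusion counts, and coefficient signs are compared across
cohorts — within a tissue group a real signal should keep one sign, while
whole-blood and plasma compartments may show a reversed pattern.

A frozen-coefficients transfer mode (:func:`transfer_panel`) is also
provided for users who want to apply one cohort's fitted panel verbatim to
another; it plays no role in the refit-based validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cohort_io import CohortMeta, ExpressionMatrix, SampleLabels
from .errors import ValidationError
from .max_logistic_core import (
    ClassificationReport,
    MaxLogisticPanel,
    score_panel,
)
from .panel_fitting import FitConfig, FitResult, fit_panel


@dataclass
class CohortBundle:
    """One cohort: metadata, expression matrix and labels."""

    meta: CohortMeta
    matrix: ExpressionMatrix
    labels: SampleLabels

    def __post_init__(self) -> None:
        if set(self.matrix.sample_ids) != set(self.labels.sample_ids):
            raise ValidationError(
                f"cohort {self.meta.cohort_id!r}: matrix and labels sample sets differ"
            )


@dataclass
class PooledMetrics:
    """Summed confusion counts over cohorts."""

    tp: int
    fp: int
    tn: int
    fn: int

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
            "total": self.total, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


@dataclass
class CrossValReport:
    per_cohort: dict[str, tuple[MaxLogisticPanel, ClassificationReport]]
    pooled: PooledMetrics
    sign_table: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_cohort": {
                c: report.to_dict() for c, (_, report) in self.per_cohort.items()
            },
            "pooled": self.pooled.to_dict(),
            "sign_table": self.sign_table,
        }


def pooled_metrics(reports: Sequence[ClassificationReport]) -> PooledMetrics:
    """Sum confusion counts; pooled metrics are sample-size weighted."""
    if not reports:
        raise ValidationError("pooled_metrics needs at least one report")
    return PooledMetrics(
        tp=sum(r.tp for r in reports),
        fp=sum(r.fp for r in reports),
        tn=sum(r.tn for r in reports),
        fn=sum(r.fn for r in reports),
    )


def _panel_gene_signs(panel: MaxLogisticPanel) -> dict[str, list[int]]:
    signs: dict[str, list[int]] = {}
    for f in panel.factors:
        for g, w in f.coefficients.items():
            signs.setdefault(g, []).append(1 if w > 0 else -1)
    return signs


def cross_cohort_validate(
    cohorts: Sequence[CohortBundle],
    gene_panel: Iterable[str],
    config: FitConfig | None = None,
) -> CrossValReport:
    """Refit the gene set independently in every cohort and pool the metrics.

    Samples are never mixed across cohorts: each cohort's panel and report
    depend only on that cohort's own matrix and labels.
    """
    if not cohorts:
        raise ValidationError("need at least one cohort")
    genes = list(gene_panel)
    if not genes:
        raise ValidationError("empty gene panel")
    ids = [c.meta.cohort_id for c in cohorts]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate cohort ids: {ids}")
    for c in cohorts:
        for g in genes:
            if not c.matrix.has_gene(g):
                raise ValidationError(
                    f"cohort {c.meta.cohort_id!r} lacks panel gene {g!r}"
                )
    per_cohort: dict[str, tuple[MaxLogisticPanel, ClassificationReport]] = {}
    sign_table: dict[str, dict[str, int]] = {g: {} for g in genes}
    for c in cohorts:
        result: FitResult = fit_panel(c.matrix, c.labels, config, genes=genes)
        per_cohort[c.meta.cohort_id] = (result.panel, result.training_report)
        for g, signs in _panel_gene_signs(result.panel).items():
            consensus = signs[0] if all(s == signs[0] for s in signs) else 0
            sign_table[g][c.meta.cohort_id] = consensus
    pooled = pooled_metrics([rep for _, rep in per_cohort.values()])
    return CrossValReport(per_cohort, pooled, sign_table)


def transfer_panel(
    panel: MaxLogisticPanel, cohorts: Sequence[CohortBundle]
) -> dict[str, ClassificationReport]:
    """Frozen-coefficients transfer: apply one panel verbatim to each cohort."""
    return {c.meta.cohort_id: score_panel(panel, c.matrix, c.labels) for c in cohorts}


@dataclass
class GeneSignVerdict:
    """Sign behaviour of one gene across cohorts, grouped by tissue."""

    per_tissue_signs: dict[str, list[int]]
    per_tissue_consistent: dict[str, bool]
    per_tissue_consensus: dict[str, int]  # +1/-1, or 0 if mixed
    reversed_whole_blood_vs_plasma: bool


def sign_consistency(
    panels: Mapping[str, MaxLogisticPanel],
    tissue: Mapping[str, str],
) -> dict[str, GeneSignVerdict]:
    """Per-gene coefficient-sign agreement within and across tissue groups.

    For every gene appearing in any panel, collects the signs of its
    non-zero coefficients per tissue group, reports whether each group is
    internally sign-consistent, and flags a whole-blood vs plasma reversal
    when both groups have a (consistent) consensus of opposite sign.
    """
    if not panels:
        raise ValidationError("sign_consistency needs at least one panel")
    gene_signs: dict[str, dict[str, list[int]]] = {}
    for cohort_id, panel in panels.items():
        tis = tissue.get(cohort_id, "whole_blood")
        for g, signs in _panel_gene_signs(panel).items():
            gene_signs.setdefault(g, {}).setdefault(tis, []).extend(signs)
    verdicts: dict[str, GeneSignVerdict] = {}
    for g, by_tissue in gene_signs.items():
        consistent = {t: all(s == ss[0] for s in ss) for t, ss in by_tissue.items()}
        consensus = {
            t: (ss[0] if consistent[t] else 0) for t, ss in by_tissue.items()
        }
        wb, pl = consensus.get("whole_blood", 0), consensus.get("plasma", 0)
        verdicts[g] = GeneSignVerdict(
            per_tissue_signs=by_tissue,
            per_tissue_consistent=consistent,
            per_tissue_consensus=consensus,
            reversed_whole_blood_vs_plasma=bool(wb and pl and wb != pl),
        )
    return verdicts
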
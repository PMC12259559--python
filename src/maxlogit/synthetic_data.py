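"""Synthetic case/control expression cohorts with stored ground truth.

The generator follows a log-normal model (Gaussian on the log2 scale),
which matches both microarray log intensities and the multiplicative
2^dCt scale of qPCR relative copy counts. For gene g and sample s,

    log2 x_gs = mu_g + batch_shift + [s is a case] * delta_{g, subgroup(s)} + eps_gs,

with gene baselines mu_g ~ Normal(6, 1) fixed by the seed, noise
eps_gs ~ Normal(0, noise_sd^2), and case effects delta in log2 units.
Case subgroups (each with its own per-gene effect override) encode cohort
heterogeneity: when two subgroups carry disjoint signals, no single linear
factor can capture all cases, which is exactly the situation competing
factors exist for. A plasma cohort flips the sign of every effect,
emulating the observed whole-blood vs plasma reversal (the compartment
mechanism behind it is not modelled). ``output_scale="identity_power"``
exponentiates to the positive 2^value scale.

Everything is reproducible bit-for-bit from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cohort_io import CohortMeta, ExpressionMatrix, SampleLabels, TISSUES
from .cross_cohort import CohortBundle
from .errors import ValidationError

OUTPUT_SCALES = ("log2", "identity_power")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full generative description of one simulated cohort."""

    cohort_id: str = "synthetic"
    n_case: int = 60
    n_control: int = 60
    n_genes: int = 100
    signal_genes: Mapping[str, float] = field(default_factory=dict)  # gene -> delta (log2)
    subgroups: Sequence[tuple[float, Mapping[str, float]]] = ((1.0, {}),)
    batch_shift: float = 0.0
    noise_sd: float = 1.0
    tissue: str = "whole_blood"
    output_scale: str = "log2"
    positive_class: str = "case"
    control_class: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("n_case and n_control must both be >= 1")
        if self.n_genes < len(self.signal_genes):
            raise ValidationError("n_genes must cover all signal genes")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.tissue not in TISSUES:
            raise ValidationError(f"unknown tissue {self.tissue!r}")
        if self.output_scale not in OUTPUT_SCALES:
            raise ValidationError(f"unknown output_scale {self.output_scale!r}")
        weights = [w for w, _ in self.subgroups]
        if not self.subgroups or any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError("subgroup weights must be >= 0 and sum to 1")


@dataclass
class GroundTruth:
    """What the generator planted: realized signal signs and subgroups."""

    signal_signs: dict[str, int]  # gene -> sign of its (tissue-adjusted) effect
    subgroup_of: dict[str, int]  # case sample -> subgroup index
    spec: SyntheticCohortSpec


def _gene_ids(spec: SyntheticCohortSpec) -> list[str]:
    ids = list(spec.signal_genes)
    width = max(3, len(str(spec.n_genes)))
    i = 0
    while len(ids) < spec.n_genes:
        i += 1
        name = f"G{i:0{width}d}"
        if name not in spec.signal_genes:
            ids.append(name)
    return ids


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[ExpressionMatrix, SampleLabels, GroundTruth]:
    """Draw one cohort from the log-normal model described in the module docs."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec)
    n = spec.n_case + spec.n_control
    mu = rng.normal(6.0, 1.0, size=spec.n_genes)
    flip = -1.0 if spec.tissue == "plasma" else 1.0

    weights = np.array([w for w, _ in spec.subgroups], dtype=float)
    subgroup = rng.choice(len(weights), size=spec.n_case, p=weights / weights.sum())
    eps = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))

    # delta matrix: genes x subgroups
    delta = np.zeros((spec.n_genes, len(spec.subgroups)))
    for gi, g in enumerate(genes):
        base = float(spec.signal_genes.get(g, 0.0))
        for k, (_, override) in enumerate(spec.subgroups):
            delta[gi, k] = flip * float(override.get(g, base))

    values = mu[:, None] + spec.batch_shift + eps
    values[:, : spec.n_case] += delta[:, subgroup]

    if spec.output_scale == "identity_power":
        values = 2.0 ** values
        scale = "identity"
    else:
        scale = "log2"

    case_ids = [f"{spec.cohort_id}_case{i+1:03d}" for i in range(spec.n_case)]
    ctrl_ids = [f"{spec.cohort_id}_ctrl{i+1:03d}" for i in range(spec.n_control)]
    sample_ids = tuple(case_ids + ctrl_ids)
    matrix = ExpressionMatrix(tuple(genes), sample_ids, values, scale)
    labels = SampleLabels(
        sample_ids,
        tuple([spec.positive_class] * spec.n_case + [spec.control_class] * spec.n_control),
        positive_class=spec.positive_class,
        control_class=spec.control_class,
    )
    # a gene's realized sign: sign of its weight-averaged effect over subgroups
    signs = {}
    for gi, g in enumerate(genes):
        eff = float(np.dot(weights, delta[gi]))
        if any(delta[gi] != 0):
            signs[g] = 1 if eff > 0 else (-1 if eff < 0 else 0)
    truth = GroundTruth(
        signal_signs=signs,
        subgroup_of=dict(zip(case_ids, subgroup.tolist())),
        spec=spec,
    )
    return matrix, labels, truth


def generate_multi_cohort(
    specs: Sequence[SyntheticCohortSpec],
    shared_signal: Mapping[str, float],
) -> tuple[list[CohortBundle], dict[str, GroundTruth]]:
    """Generate independent cohorts sharing a signal (plasma cohorts flipped).

    Each cohort keeps its own batch shift, noise level and seed; the shared
    per-gene effects are merged under any cohort-specific overrides.
    """
    ids = [s.cohort_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate cohort ids: {ids}")
    bundles: list[CohortBundle] = []
    truths: dict[str, GroundTruth] = {}
    for s in specs:
        merged = dict(shared_signal)
        merged.update(s.signal_genes)
        s2 = replace(s, signal_genes=merged)
        matrix, labels, truth = generate_cohort(s2)
        meta = CohortMeta(
            cohort_id=s.cohort_id,
            accession="synthetic",
            tissue=s.tissue,
            population="synthetic",
            n_case=s.n_case,
            n_control=s.n_control,
        )
        bundles.append(CohortBundle(meta, matrix, labels))
        truths[s.cohort_id] = truth
    return bundles, truths
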
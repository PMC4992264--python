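"""Chart-review validation statistics.

Case definitions are validated against physician chart review as the reference
standard: a 2×2 confusion matrix per condition, the four diagnostic-accuracy
metrics (sensitivity, specificity, PPV, NPV) each with an exact 95%
Clopper–Pearson binomial confidence interval, Cohen's kappa for inter-rater
agreement with an observed-agreement fallback when a zero marginal makes kappa
degenerate, and a best-definition selection rule over competing definition
architectures.

Percentages are rendered to one decimal place, rounding half up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats


class DomainError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DomainError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: dict[str, bool], truth: dict[str, bool]) -> ConfusionMatrix:
    """Tally predicted flags against reference labels over identical units."""
    if set(pred) != set(truth):
        only_pred = sorted(set(pred) - set(truth))
        only_truth = sorted(set(truth) - set(pred))
        raise DomainError(
            f"unit sets differ; only in predictions: {only_pred}; "
            f"only in truth: {only_truth}"
        )
    tp = fp = fn = tn = 0
    for unit, p in pred.items():
        t = truth[unit]
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def proportion_ci(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval for x/n.

    low = 0 when x = 0, else the alpha/2 quantile of Beta(x, n−x+1);
    high = 1 when x = n, else the 1−alpha/2 quantile of Beta(x+1, n−x).
    The interval always contains x/n.
    """
    if n < 1 or x < 0 or x > n:
        raise DomainError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def render_percent(p: float) -> str:
    """One-decimal percentage, rounding half up (e.g. 96/450 → '21.3')."""
    return str(Decimal(repr(p * 100)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricEstimate:
    estimate: float  # proportion in [0, 1]
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    def formatted(self) -> str:
        """'100.0 (96.2, 100.0)' — the conventional table cell."""
        return (
            f"{render_percent(self.estimate)} "
            f"({render_percent(self.ci_low)}, {render_percent(self.ci_high)})"
        )


@dataclass
class ValidityReport:
    """Point estimates and exact 95% CIs for the four accuracy metrics.

    A metric whose defining margin is empty (zero denominator) is undefined
    and reported as None, never as 0.
    """

    sensitivity: Optional[MetricEstimate]
    specificity: Optional[MetricEstimate]
    ppv: Optional[MetricEstimate]
    npv: Optional[MetricEstimate]
    matrix: ConfusionMatrix

    def metric(self, name: str) -> Optional[MetricEstimate]:
        return getattr(self, name)


def _estimate(x: int, n: int, alpha: float) -> Optional[MetricEstimate]:
    if n == 0:
        return None
    low, high = proportion_ci(x, n, alpha)
    return MetricEstimate(
        estimate=x / n, ci_low=low, ci_high=high, numerator=x, denominator=n
    )


def validity_report(cm: ConfusionMatrix, alpha: float = 0.05) -> ValidityReport:
    """sensitivity = tp/(tp+fn); specificity = tn/(tn+fp); ppv = tp/(tp+fp);
    npv = tn/(tn+fn); each with its exact binomial CI."""
    if cm.n == 0:
        raise DomainError("empty confusion matrix")
    return ValidityReport(
        sensitivity=_estimate(cm.tp, cm.tp + cm.fn, alpha),
        specificity=_estimate(cm.tn, cm.tn + cm.fp, alpha),
        ppv=_estimate(cm.tp, cm.tp + cm.fp, alpha),
        npv=_estimate(cm.tn, cm.tn + cm.fn, alpha),
        matrix=cm,
    )


@dataclass
class AgreementResult:
    """Inter-rater agreement for one condition.

    When a marginal row or column total of the 2×2 rater table is zero the
    chance-expected agreement is 1 and kappa is undefined; the observed
    agreement is then reported instead (method = 'observed_agreement').
    """

    observed_agreement: float
    kappa: Optional[float] = None
    method: str = "kappa"
    zero_cell_detected: bool = False


def cohen_kappa(table: Sequence[Sequence[int]]) -> AgreementResult:
    """Cohen's kappa from a 2×2 rater-agreement table [[a, b], [c, d]].

    po = (a+d)/n; pe = ((a+b)(a+c) + (c+d)(b+d))/n²; kappa = (po−pe)/(1−pe).
    """
    (a, b), (c, d) = ((int(v) for v in row) for row in table)
    if min(a, b, c, d) < 0:
        raise DomainError("rater-agreement counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise DomainError("rater-agreement table is empty")
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    marginals = (a + b, c + d, a + c, b + d)
    if 0 in marginals:  # degenerate: pe == 1, kappa undefined
        return AgreementResult(
            observed_agreement=po,
            kappa=None,
            method="observed_agreement",
            zero_cell_detected=True,
        )
    return AgreementResult(
        observed_agreement=po, kappa=(po - pe) / (1 - pe), method="kappa"
    )


def youden_j(report: ValidityReport) -> float:
    """Youden's J = sensitivity + specificity − 1 (undefined metrics count 0)."""
    sens = report.sensitivity.estimate if report.sensitivity else 0.0
    spec = report.specificity.estimate if report.specificity else 0.0
    return sens + spec - 1.0


def select_best(
    reports: Sequence[tuple[str, ValidityReport]],
    key: str = "youden",
) -> str:
    """Pick the definition with the highest validity.

    The default criterion ranks by Youden's J, breaking ties by PPV and then
    by definition id (lexicographic). ``key='ppv'`` ranks by PPV first. The
    criterion is configurable because 'highest validity' is a judgement call.
    """
    if not reports:
        raise DomainError("select_best requires at least one report")

    def ppv_of(r: ValidityReport) -> float:
        return r.ppv.estimate if r.ppv else 0.0

    if key == "youden":
        ranked = sorted(
            reports, key=lambda item: (-youden_j(item[1]), -ppv_of(item[1]), item[0])
        )
    elif key == "ppv":
        ranked = sorted(
            reports, key=lambda item: (-ppv_of(item[1]), -youden_j(item[1]), item[0])
        )
    else:
        raise ValueError(f"unknown selection key {key!r}")
    return ranked[0][0]


def sample_units(units: Sequence[str], n: int, seed: int) -> list[str]:
    """Uniform sampling without replacement, reproducible from the seed.

    ``units`` may be a sequence of unit ids or a corpus (whose patients are
    sampled). Uses numpy's PCG64 generator; record the seed alongside outputs.
    """
    if hasattr(units, "patient_ids"):
        units = units.patient_ids
    units = list(units)
    if n > len(units):
        raise DomainError(f"cannot sample {n} from {len(units)} units")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(units), size=n, replace=False)
    return [units[i] for i in sorted(idx)]
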
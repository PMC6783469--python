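"""Precision-based sample-size utilities for diagnostic-accuracy studies.

For an adaptive prospective validation study one asks: how many
patients must be recruited so that sensitivity (or specificity) is
estimated to within an absolute half-width d?  The normal-approximation
(Wald) bound gives, for an assumed metric value m,

    n_effective = ⌈ z²_{1−α/2} · m(1−m) / d² ⌉

patients *contributing to that metric* — i.e. diseased patients for
sensitivity, disease-free for specificity.  At disease prevalence π the
total recruitment inflates to

    total = ⌈ n_effective / f ⌉,   f = π (sensitivity) or 1−π (specificity).

``interim_update`` re-solves the bound with the observed interim metric
and returns how many further recruits are still needed.

A power-adjusted variant (flag ``power_adjusted``) replaces z_{1−α/2}
with z_{1−α/2} + z_{power}, the usual inflation when the estimate must
also demonstrate the metric exceeds m − d with the stated power; the
plain Wald bound is the default and ``power`` is documentation for it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import norm

from .errors import UsageError
from .metrics import ConfusionMatrix

SENSITIVITY = "sensitivity"
SPECIFICITY = "specificity"


@dataclass(frozen=True)
class DesignParams:
    """Design inputs: precision d, prevalence, assumed metric, α, power."""

    precision: float  # absolute half-width d of the estimate
    prevalence: float
    assumed_metric: float
    metric_kind: str = SPECIFICITY
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        for name in ("precision", "prevalence", "assumed_metric", "alpha", "power"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise UsageError(f"{name} must lie in (0, 1) (got {v})")
        if self.metric_kind not in (SENSITIVITY, SPECIFICITY):
            raise UsageError(
                f"metric_kind must be {SENSITIVITY!r} or {SPECIFICITY!r} "
                f"(got {self.metric_kind!r})"
            )
        if self.precision >= self.assumed_metric or self.precision >= 1 - self.assumed_metric:
            warnings.warn(
                "precision reaches the [0, 1] boundary of the assumed metric; "
                "the normal approximation is unstable there",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SampleSizeResult:
    n_effective: int  # patients contributing to the metric
    total: int  # total recruits after prevalence inflation
    z: float
    contributing_fraction: float


def _contributing_fraction(p: DesignParams) -> float:
    return p.prevalence if p.metric_kind == SENSITIVITY else 1.0 - p.prevalence


def n_for_precision(p: DesignParams, power_adjusted: bool = False) -> SampleSizeResult:
    """Wald precision bound with prevalence inflation (see module docstring).

    n_effective is maximal at m = 0.5 for fixed d and α, falls with
    |m − 0.5|, and scales as 1/d².
    """
    z = float(norm.ppf(1.0 - p.alpha / 2.0))
    if power_adjusted:
        z = z + float(norm.ppf(p.power))
    m = p.assumed_metric
    n_effective = math.ceil(z * z * m * (1.0 - m) / (p.precision**2))
    f = _contributing_fraction(p)
    total = math.ceil(n_effective / f)
    return SampleSizeResult(
        n_effective=n_effective, total=total, z=z, contributing_fraction=f
    )


def interim_update(
    observed: ConfusionMatrix, p: DesignParams, power_adjusted: bool = False
) -> int:
    """Remaining recruits after an interim look.

    The bound is re-solved with the observed metric in place of the
    assumed one, and the patients already recruited (all cells of the
    observed matrix) are subtracted; the result floors at 0.
    """
    if observed.n == 0:
        raise UsageError("observed confusion matrix is empty")
    if p.metric_kind == SENSITIVITY:
        denom = observed.tp + observed.fn
        metric = observed.tp / denom if denom else None
    else:
        denom = observed.tn + observed.fp
        metric = observed.tn / denom if denom else None
    if metric is None:
        raise UsageError(
            f"{p.metric_kind} is undefined on the observed matrix (empty denominator)"
        )
    metric = min(max(metric, 1e-9), 1 - 1e-9)  # keep the bound finite at 0/1
    updated = DesignParams(
        precision=p.precision,
        prevalence=p.prevalence,
        assumed_metric=metric,
        metric_kind=p.metric_kind,
        alpha=p.alpha,
        power=p.power,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        required = n_for_precision(updated, power_adjusted).total
    return max(required - observed.n, 0)
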
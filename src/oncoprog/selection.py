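"""NS:S ratio selection statistics.

Under neutral evolution roughly two thirds of coding single-nucleotide
substitutions are non-synonymous, so passenger mutations are expected at an
NS:S ratio of about 2:1.  An excess of non-synonymous mutations over that
expectation indicates positive selection; the excess count itself,
NS - 2*S, estimates how many of the non-synonymous mutations are drivers.
Significance is assessed with an exact one-tailed binomial test of the NS
count among NS+S trials against the null success probability 2/3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from scipy.special import gammaln, logsumexp

from .model import (
    Consequence,
    NS_SNV_CLASSES,
    PatientCohort,
    PipelineError,
)

__all__ = ["ClassConfig", "SelectionTestResult", "count_classes",
           "binom_tail_exact", "selection_test", "truncate"]


INDEL_CLASSES = frozenset(
    {Consequence.FRAMESHIFT_INS, Consequence.FRAMESHIFT_DEL,
     Consequence.NONFRAMESHIFT_INDEL}
)


@dataclass(frozen=True)
class ClassConfig:
    """Which consequence classes enter the NS count.

    By default the ratio test uses single-nucleotide substitutions only:
    NS = missense + stopgain + stoploss SNVs, S = synonymous SNVs.  Splice
    sites and indels, which the concordance analysis does include, can be
    added to NS for sensitivity analysis.
    """

    include_splice_in_ns: bool = False
    include_indels_in_ns: bool = False

    def ns_classes(self) -> frozenset:
        classes = set(NS_SNV_CLASSES)
        if self.include_splice_in_ns:
            classes.add(Consequence.SPLICE_SITE)
        if self.include_indels_in_ns:
            classes |= INDEL_CLASSES
        return frozenset(classes)


def truncate(x: float, digits: int = 2) -> float:
    """Truncate (not round) toward zero at `digits` decimals (display rule)."""
    scale = 10 ** digits
    return math.trunc(x * scale) / scale


@dataclass
class SelectionTestResult:
    label: str
    ns: int
    s: int
    p_value: float
    driver_estimate: int
    null_ns_fraction: float = 2.0 / 3.0

    @property
    def ratio(self) -> float:
        """NS/S at full precision; undefined (inf) when S = 0."""
        return self.ns / self.s if self.s > 0 else math.inf

    @property
    def ratio_display(self) -> float:
        """The two-decimal truncated ratio used in printed tables."""
        return truncate(self.ratio, 2) if self.s > 0 else math.inf


def count_classes(cohort: PatientCohort, decisions: Optional[dict] = None,
                  selector: Optional[Callable] = None,
                  class_config: Optional[ClassConfig] = None) -> tuple:
    """Count (ns, s) over a mutation group.

    ``selector`` is a predicate ``(mutation, decision) -> bool`` choosing the
    group (a patient, a stage, a progression category...); ``decisions``
    restricts to retained mutations when given.  Indels never enter either
    count unless enabled via ``class_config``.
    """
    class_config = class_config or ClassConfig()
    ns_classes = class_config.ns_classes()
    ns = s = 0
    for mut in cohort.mutations:
        decision = decisions.get(mut.key) if decisions is not None else None
        if decisions is not None and (decision is None or not decision.retained):
            continue
        if selector is not None and not selector(mut, decision):
            continue
        snv = mut.is_snv
        if mut.consequence is Consequence.SYNONYMOUS and snv:
            s += 1
        elif mut.consequence in ns_classes:
            if snv or mut.consequence in INDEL_CLASSES or (
                mut.consequence is Consequence.SPLICE_SITE
            ):
                ns += 1
    return ns, s


def binom_tail_exact(k: int, n: int, p0: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p0).

    Computed by log-space summation of pmf terms (log-gamma binomial
    coefficients, `logsumexp` accumulation), stable for large n and extreme
    tails.
    """
    if not (0 <= k <= n):
        raise PipelineError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise PipelineError(f"require 0 < p0 < 1, got {p0}")
    if k == 0:
        return 1.0
    import numpy as np

    j = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
        + j * math.log(p0) + (n - j) * math.log1p(-p0)
    )
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def selection_test(ns: int, s: int, null_ratio: float = 2.0,
                   label: str = "") -> SelectionTestResult:
    """One-tailed exact binomial test of NS against the neutral NS:S ratio.

    The null probability that a coding mutation is non-synonymous is
    null_ratio / (null_ratio + 1) (2/3 for the 2:1 neutral expectation); the
    driver estimate is the non-synonymous excess max(NS - round(null_ratio*S), 0).
    """
    if ns < 0 or s < 0 or ns + s == 0:
        raise PipelineError("selection test requires ns + s >= 1")
    p0 = null_ratio / (null_ratio + 1.0)
    p = binom_tail_exact(ns, ns + s, p0)
    driver = max(ns - round(null_ratio * s), 0)
    return SelectionTestResult(
        label=label, ns=ns, s=s, p_value=p, driver_estimate=driver,
        null_ns_fraction=p0,
    )


def selection_tests(groups: Iterable, null_ratio: float = 2.0) -> list:
    """Run the selection test for several labelled (ns, s) groups."""
    return [selection_test(ns, s, null_ratio=null_ratio, label=label)
            for label, ns, s in groups]
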
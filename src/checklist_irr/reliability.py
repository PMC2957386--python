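"""Variance-component kappa coefficients for an incomplete one-way design.

Each article is rated by its own subset of raters, so rater effects cannot
be separated from error: the only identifiable decomposition is

    score = article effect + error,

and every kappa here is the intraclass correlation

    kappa = sigma2_article / (sigma2_article + sigma2_error)

estimated by method-of-moments one-way random-effects ANOVA on the scored
categories.  Three variants cover the three scale kinds:

* ``intraclass_kappa`` — dichotomous items scored yes=1 / no=0;
* ``weighted_kappa_quadratic`` — ordinal items scored yes=1, ?=2, no=3.
  Quadratic-weighted kappa is numerically identical to the ANOVA ICC on
  these scores, and that identity is the computation used;
* ``si_kappa`` — nominal scales containing "na": every category-vs-rest
  dummy is analysed separately and the variance components are pooled,
  SI = sum_i sigma2_article(i) / sum_i (sigma2_article(i) + sigma2_error(i)).

Negative between-article components are truncated to zero (flagged), and a
kappa whose total variance is zero is reported as undefined, never coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import ItemDefinition

__all__ = [
    "VarianceComponents",
    "KappaResult",
    "KappaBands",
    "one_way_components",
    "intraclass_kappa",
    "weighted_kappa_quadratic",
    "si_kappa",
    "classify_kappa",
    "kappa_for_item",
]

FLAG_TRUNCATED = "variance_truncated"
FLAG_UNDEFINED = "undefined"


@dataclass(frozen=True)
class VarianceComponents:
    """One-way ANOVA decomposition of an item's scores.

    sigma2_article is the variance due to systematic differences between
    articles (truncated at zero), sigma2_error the residual variance; n0 is
    the effective group size of the unbalanced layout.
    """

    sigma2_article: float
    sigma2_error: float
    ms_between: float
    ms_within: float
    n0: float
    k_groups: int
    n_total: int
    truncated: bool = False


@dataclass(frozen=True)
class KappaResult:
    kappa: Optional[float]
    method: str
    components: VarianceComponents | tuple[VarianceComponents, ...]
    flags: frozenset[str] = frozenset()

    @property
    def undefined(self) -> bool:
        return self.kappa is None


@dataclass(frozen=True)
class KappaBands:
    """Interpretation bands: < poor_below poor, > excellent_above excellent."""

    poor_below: float = 0.40
    excellent_above: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.poor_below < self.excellent_above < 1:
            raise ValueError("bands must satisfy 0 < poor_below < excellent_above < 1")


def _as_units(units: Sequence) -> list[np.ndarray]:
    out = [np.asarray(u, dtype=float) for u in units]
    if any(u.ndim != 1 or u.size == 0 for u in out):
        raise ValueError("each unit must be a non-empty 1-d array of scores")
    return out


def one_way_components(units: Sequence[Sequence[float]]) -> VarianceComponents:
    """Method-of-moments variance components for unbalanced one-way data.

    ``units`` holds the numeric scores each article received.  Requires at
    least two articles and at least one article with two or more scores.
    With N total scores in k groups of sizes n_i:

        ms_within  = SSW / (N - k)
        ms_between = SSB / (k - 1)
        n0 = (N - sum(n_i^2)/N) / (k - 1)
        sigma2_article = max(0, (ms_between - ms_within) / n0)

    A negative raw between-article component sets ``truncated``.
    """
    groups = _as_units(units)
    k = len(groups)
    sizes = np.array([g.size for g in groups], dtype=float)
    n = int(sizes.sum())
    if k < 2:
        raise ValueError(f"one-way ANOVA needs >= 2 articles, got {k}")
    if n - k < 1:
        raise ValueError("at least one article needs >= 2 ratings")
    means = np.array([g.mean() for g in groups])
    grand = sum(g.sum() for g in groups) / n
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    ssb = float((sizes * (means - grand) ** 2).sum())
    ms_within = ssw / (n - k)
    ms_between = ssb / (k - 1)
    n0 = (n - float((sizes**2).sum()) / n) / (k - 1)
    raw = (ms_between - ms_within) / n0
    truncated = raw < 0
    return VarianceComponents(
        sigma2_article=max(0.0, raw),
        sigma2_error=ms_within,
        ms_between=ms_between,
        ms_within=ms_within,
        n0=n0,
        k_groups=k,
        n_total=n,
        truncated=truncated,
    )


def _icc_result(comp: VarianceComponents, method: str) -> KappaResult:
    flags = set()
    if comp.truncated:
        flags.add(FLAG_TRUNCATED)
    denom = comp.sigma2_article + comp.sigma2_error
    if denom == 0.0:
        flags.add(FLAG_UNDEFINED)
        return KappaResult(None, method, comp, frozenset(flags))
    return KappaResult(comp.sigma2_article / denom, method, comp, frozenset(flags))


def intraclass_kappa(units: Sequence[Sequence[float]]) -> KappaResult:
    """Intraclass kappa for dichotomous 0/1 scores."""
    groups = _as_units(units)
    vals = np.concatenate(groups)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("intraclass_kappa expects binary 0/1 scores")
    return _icc_result(one_way_components(groups), "intraclass")


def weighted_kappa_quadratic(units: Sequence[Sequence[float]]) -> KappaResult:
    """Quadratic-weighted kappa for ordinal scores, via the ANOVA ICC identity."""
    return _icc_result(one_way_components(units), "weighted_quadratic")


def si_kappa(
    units: Sequence[Sequence[str]], categories: Sequence[str]
) -> KappaResult:
    """Summary-intraclass kappa for nominal scales.

    Each declared category in turn is dichotomized into a 1-vs-rest dummy;
    variance components are estimated per dummy (negative between-article
    components truncated to zero) and pooled across dummies.
    """
    if len(categories) < 2:
        raise ValueError("si_kappa needs >= 2 declared categories")
    comps = []
    for cat in categories:
        dummy = [[1.0 if x == cat else 0.0 for x in u] for u in units]
        comps.append(one_way_components(dummy))
    flags = set()
    if any(c.truncated for c in comps):
        flags.add(FLAG_TRUNCATED)
    num = sum(c.sigma2_article for c in comps)
    den = sum(c.sigma2_article + c.sigma2_error for c in comps)
    if den == 0.0:
        flags.add(FLAG_UNDEFINED)
        return KappaResult(None, "si", tuple(comps), frozenset(flags))
    return KappaResult(num / den, "si", tuple(comps), frozenset(flags))


def classify_kappa(kappa: float, bands: KappaBands = KappaBands()) -> str:
    """Band label: poor below 0.40, excellent above 0.75, else moderate_good.

    The boundaries themselves fall in moderate_good.
    """
    if not 0 <= kappa <= 1:
        raise ValueError(f"kappa out of range: {kappa}")
    if kappa < bands.poor_below:
        return "poor"
    if kappa > bands.excellent_above:
        return "excellent"
    return "moderate_good"


def kappa_for_item(
    item: ItemDefinition, units: Sequence[Sequence[str]]
) -> KappaResult:
    """Dispatch to the kappa variant an item's scale calls for.

    ``units`` holds category tokens per article; scoring maps are applied
    here (binary -> intraclass on 0/1, ordinal -> quadratic-weighted on
    1/2/3, nominal with "na" -> SI over all dichotomizations).
    """
    for u in units:
        bad = [x for x in u if x not in item.categories]
        if bad:
            raise ValueError(
                f"item {item.item_id}: response {bad[0]!r} outside scale "
                f"{item.categories}"
            )
    if item.scale_kind == "binary_yes_no":
        score = item.score_map
        return intraclass_kappa([[score[x] for x in u] for u in units])
    if item.scale_kind == "ordinal_yes_q_no":
        score = item.score_map
        return weighted_kappa_quadratic([[score[x] for x in u] for u in units])
    return si_kappa(units, item.categories)
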
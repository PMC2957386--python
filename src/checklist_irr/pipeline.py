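"""Per-item analysis pipeline: from a validated rating table to a results table.

For every item the pipeline forms its analysis units (all ratings an article
received, with Generalisability-box administrations kept separate per
measurement property when pooling is on), computes modal percentage
agreement over multi-rated units, dispatches to the kappa variant the item's
scale calls for, and attaches flags: ``skewed`` (pooled modal share above
75%), ``variance_truncated``, ``undefined`` and ``small_n``.  Items with too
little data are reported with undefined fields rather than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import agreement as agr
from . import reliability as rel
from .io import ItemResult, RatingTable

__all__ = [
    "AnalysisConfig",
    "run_study",
    "summarize_step1",
    "pool_generalisability",
    "summary_statistics",
    "item_units",
]

log = logging.getLogger("checklist_irr")

FLAG_SKEWED = "skewed"
FLAG_SMALL_N = "small_n"


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the per-item analysis.

    include_singletons_in_kappa
        whether articles rated once still enter kappa estimation (they
        inform the between-article sums); they never enter percentage
        agreement.
    pool_generalisability
        treat each (article, measurement property) administration of a
        Generalisability-box item as its own analysis unit, enlarging N.
    small_n_warning
        flag items whose kappa sample size falls below this count.
    """

    agreement: agr.AgreementConfig = field(default_factory=agr.AgreementConfig)
    bands: rel.KappaBands = field(default_factory=rel.KappaBands)
    include_singletons_in_kappa: bool = True
    pool_generalisability: bool = True
    small_n_warning: int = 50
    small_n_secondary: int = 30

    def __post_init__(self) -> None:
        if self.small_n_warning <= 0 or self.small_n_secondary <= 0:
            raise ValueError("small-n thresholds must be positive")


def pool_generalisability(table: RatingTable) -> RatingTable:
    """View of the table in which GEN-box units are (article, property) pairs.

    Generalisability items are scored once per measurement property per
    article; pooling analyses all administrations together by giving each
    (article, context) pair its own analysis unit.  Non-GEN records are
    untouched.
    """
    df = table.records.copy()
    gen_items = {iid for iid, item in table.catalog.items() if item.box == "GEN"}
    mask = df["item_id"].isin(gen_items) & (df["context"] != "")
    df.loc[mask, "article_id"] = (
        df.loc[mask, "article_id"] + "::" + df.loc[mask, "context"]
    )
    df.loc[mask, "context"] = ""
    return RatingTable(records=df, catalog=table.catalog)


def item_units(table: RatingTable, item_id: str) -> dict[str, list[str]]:
    """Non-missing responses per analysis unit (keyed by article) for one item."""
    df = table.item_records(item_id)
    units: dict[str, list[str]] = {}
    for aid, grp in df.groupby("article_id"):
        responses = [r for r in grp["response"] if r is not None]
        if responses:
            units[aid] = responses
    return units


def _analyse_item(item_id: str, table: RatingTable,
                  config: AnalysisConfig) -> ItemResult:
    item = table.catalog[item_id]
    units = item_units(table, item_id)
    flags: set[str] = set()

    pooled = [r for u in units.values() for r in u]
    if pooled and agr.dispersal_flag(pooled, config.agreement):
        flags.add(FLAG_SKEWED)

    pa = agr.item_percent_agreement(units.values(), config.agreement)
    if pa is None:
        pct, n_agree = None, 0
        log.info("item %s: no unit with >= %d ratings; agreement undefined",
                 item_id, config.agreement.min_ratings_per_unit)
    else:
        pct, n_agree = pa

    if config.include_singletons_in_kappa:
        kappa_units = list(units.values())
    else:
        kappa_units = [u for u in units.values() if len(u) >= 2]
    n_kappa = sum(len(u) for u in kappa_units)

    kappa = None
    method = None
    try:
        result = rel.kappa_for_item(item, kappa_units)
        kappa, method = result.kappa, result.method
        flags |= result.flags
    except ValueError as exc:
        flags.add(rel.FLAG_UNDEFINED)
        log.info("item %s: kappa undefined (%s)", item_id, exc)

    if 0 < n_kappa < config.small_n_warning:
        flags.add(FLAG_SMALL_N)

    return ItemResult(
        item_id=item_id,
        n_agreement=n_agree,
        pct_agreement=pct,
        n_kappa=n_kappa,
        kappa=kappa,
        kappa_method=method,
        flags=frozenset(flags),
    )


def run_study(table: RatingTable,
              config: AnalysisConfig = AnalysisConfig()) -> list[ItemResult]:
    """Analyse every catalog item, returning one ItemResult per item."""
    if len(table) == 0:
        raise ValueError("run_study: empty rating table")
    view = pool_generalisability(table) if config.pool_generalisability else table
    return [_analyse_item(iid, view, config) for iid in sorted(table.catalog)]


def summarize_step1(table: RatingTable,
                    config: AnalysisConfig = AnalysisConfig()) -> list[ItemResult]:
    """Analyse only the step-1 'was the property evaluated' items.

    These are dichotomous per measurement property and always analysed with
    the intraclass kappa.  Properties without any rating are absent from the
    output (logged).
    """
    step1 = {iid for iid, item in table.catalog.items() if item.box == "STEP1"}
    results = [r for r in run_study(table, config) if r.item_id in step1]
    present = set(table.records["item_id"])
    for iid in sorted(step1 - present):
        log.info("step-1 item %s has no ratings; omitted", iid)
    return [r for r in results if r.item_id in present]


def summary_statistics(
    results: Sequence[ItemResult],
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Distribution of items over agreement and kappa bands, plus flag counts."""
    if not results:
        raise ValueError("summary_statistics: empty results")
    with_pct = [r for r in results if r.pct_agreement is not None]
    with_kappa = [r for r in results if r.kappa is not None]
    agree_counts = {"appropriate": 0, "low": 0}
    for r in with_pct:
        agree_counts[agr.classify_agreement(r.pct_agreement, config.agreement)] += 1
    kappa_counts = {"poor": 0, "moderate_good": 0, "excellent": 0}
    for r in with_kappa:
        kappa_counts[rel.classify_kappa(r.kappa, config.bands)] += 1
    n_pct = len(with_pct)
    n_kap = len(with_kappa)
    return {
        "n_items": len(results),
        "n_with_agreement": n_pct,
        "n_with_kappa": n_kap,
        "agreement_counts": agree_counts,
        "agreement_fractions": {
            k: v / n_pct if n_pct else None for k, v in agree_counts.items()
        },
        "kappa_counts": kappa_counts,
        "kappa_fractions": {
            k: v / n_kap if n_kap else None for k, v in kappa_counts.items()
        },
        "n_skewed": sum(FLAG_SKEWED in r.flags for r in results),
        "n_variance_truncated": sum(
            rel.FLAG_TRUNCATED in r.flags for r in results),
        "n_undefined": sum(r.kappa is None for r in results),
        "n_small_n": sum(FLAG_SMALL_N in r.flags for r in results),
    }
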
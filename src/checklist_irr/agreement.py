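"""Modal percentage agreement and the skewed-distribution (dispersal) rule.

Agreement is category-exact: for each analysis unit (all ratings one item
received on one article) the largest same-category group counts as agreement
and the rest as non-agreement, so no tie-breaking is ever needed — only the
size of the largest group matters, not which category it is.  Units with a
single rating carry no agreement information and are excluded from both the
numerator and the denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

__all__ = [
    "AgreementConfig",
    "modal_agreement_count",
    "item_percent_agreement",
    "dispersal_flag",
    "classify_agreement",
]


@dataclass(frozen=True)
class AgreementConfig:
    """Thresholds for the agreement analysis.

    appropriate_threshold
        percentage above which (strictly) agreement is called appropriate.
    skew_threshold
        pooled modal-category share above which (strictly) an item's score
        distribution is flagged skewed — the regime where kappa is attenuated.
    min_ratings_per_unit
        minimum ratings an article must have to enter percentage agreement.
    """

    appropriate_threshold: float = 80.0
    skew_threshold: float = 0.75
    min_ratings_per_unit: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.appropriate_threshold < 100:
            raise ValueError("appropriate_threshold must be in (0, 100)")
        if not 0 < self.skew_threshold < 1:
            raise ValueError("skew_threshold must be in (0, 1)")
        if self.min_ratings_per_unit < 2:
            raise ValueError("min_ratings_per_unit must be >= 2")


def modal_agreement_count(responses: Sequence[str]) -> Optional[int]:
    """Size of the largest same-category group among one article's ratings.

    Returns None for units with fewer than two responses — the unit is
    excluded by the caller rather than raising.
    """
    if len(responses) < 2:
        return None
    return max(Counter(responses).values())


def item_percent_agreement(
    units: Iterable[Sequence[str]],
    config: AgreementConfig = AgreementConfig(),
) -> Optional[tuple[float, int]]:
    """Percentage agreement for one item over all its qualifying articles.

    pct = 100 * (sum of modal counts) / (sum of unit sizes), over units with
    at least ``min_ratings_per_unit`` non-missing responses.  Returns
    ``(pct, n)`` where n is the total number of ratings entering the
    calculation, or None when no unit qualifies.
    """
    agree = 0
    total = 0
    for unit in units:
        if len(unit) < config.min_ratings_per_unit:
            continue
        agree += max(Counter(unit).values())
        total += len(unit)
    if total == 0:
        return None
    return 100.0 * agree / total, total


def dispersal_flag(
    responses: Sequence[str],
    config: AgreementConfig = AgreementConfig(),
) -> bool:
    """True when the item's pooled score distribution is skewed.

    Pooled over articles: skewed iff the share of the most-used response
    category strictly exceeds ``skew_threshold`` (exactly 75% is not skewed).
    """
    if len(responses) == 0:
        raise ValueError("dispersal_flag: no responses")
    share = max(Counter(responses).values()) / len(responses)
    return share > config.skew_threshold


def classify_agreement(
    pct: float, config: AgreementConfig = AgreementConfig()
) -> str:
    """Label a percentage agreement: 'appropriate' iff strictly above threshold."""
    if not 0 <= pct <= 100:
        raise ValueError(f"percentage out of range: {pct}")
    return "appropriate" if pct > config.appropriate_threshold else "low"
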
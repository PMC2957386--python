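"""Reading, validating and writing rating tables, item catalogs and result tables.

The on-disk formats are deliberately plain:

* ratings CSV — columns ``rater_id,article_id,item_id,context,response``,
  one row per rating; an empty ``response`` field marks a missing rating.
* catalog CSV — columns ``item_id,box,scale_kind``.
* results TSV — one row per item mirroring the layout of the study's
  published tables (separate N columns for agreement and kappa, percentage
  to 0 decimals, kappa to 2 decimals).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "SCALES",
    "CatalogError",
    "ValidationError",
    "ItemDefinition",
    "RatingRecord",
    "RatingTable",
    "ItemResult",
    "read_catalog",
    "read_ratings",
    "write_results",
    "read_results",
    "round_half_up",
]

#: Declared response categories and numeric score maps per scale kind.
#: Binary items are scored yes=1 / no=0; ordinal items yes=1, ?=2, no=3.
#: Nominal scales with "na" carry no ordinal scoring and are analysed only
#: through category-vs-rest dichotomizations.
SCALES: Mapping[str, dict] = {
    "binary_yes_no": {
        "categories": ("yes", "no"),
        "score_map": {"yes": 1.0, "no": 0.0},
    },
    "ordinal_yes_q_no": {
        "categories": ("yes", "?", "no"),
        "score_map": {"yes": 1.0, "?": 2.0, "no": 3.0},
    },
    "nominal_with_na_3": {
        "categories": ("yes", "no", "na"),
        "score_map": None,
    },
    "nominal_with_na_4": {
        "categories": ("yes", "?", "no", "na"),
        "score_map": None,
    },
}

RATINGS_COLUMNS = ("rater_id", "article_id", "item_id", "context", "response")
CATALOG_COLUMNS = ("item_id", "box", "scale_kind")
RESULT_COLUMNS = (
    "item_id",
    "n_agreement",
    "pct_agreement",
    "n_kappa",
    "kappa",
    "kappa_method",
    "flags",
)


class CatalogError(ValueError):
    """An item id or scale declaration could not be resolved."""


class ValidationError(ValueError):
    """A rating row violates the table invariants."""


@dataclass(frozen=True)
class ItemDefinition:
    """One checklist item: its box and declared response scale."""

    item_id: str
    box: str
    scale_kind: str

    def __post_init__(self) -> None:
        if self.scale_kind not in SCALES:
            raise CatalogError(
                f"item {self.item_id!r}: unknown scale_kind {self.scale_kind!r} "
                f"(expected one of {sorted(SCALES)})"
            )

    @property
    def categories(self) -> tuple[str, ...]:
        return SCALES[self.scale_kind]["categories"]

    @property
    def score_map(self) -> Optional[Mapping[str, float]]:
        return SCALES[self.scale_kind]["score_map"]


@dataclass(frozen=True)
class RatingRecord:
    """A single rating: one rater scoring one item on one article.

    ``context`` labels repeated administrations of the same item on the same
    article (for Generalisability-box items, the measurement property under
    which the box was completed); it is empty otherwise.  ``response`` is
    ``None`` when the rater left the item blank.
    """

    rater_id: str
    article_id: str
    item_id: str
    context: str = ""
    response: Optional[str] = None

    @property
    def is_missing(self) -> bool:
        return self.response is None


@dataclass
class RatingTable:
    """A validated collection of rating records plus the item catalog."""

    records: pd.DataFrame
    catalog: dict[str, ItemDefinition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing_cols = set(RATINGS_COLUMNS) - set(self.records.columns)
        if missing_cols:
            raise ValidationError(f"records missing columns: {sorted(missing_cols)}")

    def __len__(self) -> int:
        return len(self.records)

    def item_records(self, item_id: str) -> pd.DataFrame:
        return self.records[self.records["item_id"] == item_id]

    def items_present(self) -> list[str]:
        return sorted(self.records["item_id"].unique())


@dataclass
class ItemResult:
    """Per-item agreement and reliability summary (one published-table row)."""

    item_id: str
    n_agreement: int = 0
    pct_agreement: Optional[float] = None
    n_kappa: int = 0
    kappa: Optional[float] = None
    kappa_method: Optional[str] = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pct_agreement is None and self.n_agreement > 0:
            raise ValueError(
                f"item {self.item_id}: n_agreement > 0 requires pct_agreement"
            )


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), matching table rendering."""
    q = decimal.Decimal(10) ** -decimals
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def _canonical_response(raw, item: ItemDefinition, where: str) -> Optional[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    token = str(raw).strip().lower()
    if token == "":
        return None
    if token not in item.categories:
        raise ValidationError(
            f"{where}: response {raw!r} not in scale "
            f"{item.categories} of item {item.item_id!r}"
        )
    return token


def read_catalog(path: str | Path) -> dict[str, ItemDefinition]:
    """Read the item catalog CSV into a mapping item_id -> ItemDefinition."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise CatalogError(f"catalog {path}: missing columns {sorted(missing)}")
    catalog: dict[str, ItemDefinition] = {}
    for row in df.itertuples(index=False):
        if row.item_id in catalog:
            raise CatalogError(f"catalog {path}: duplicate item_id {row.item_id!r}")
        catalog[row.item_id] = ItemDefinition(row.item_id, row.box, row.scale_kind)
    return catalog


def read_ratings(path: str | Path, catalog_path: str | Path) -> RatingTable:
    """Read and validate a long-format ratings CSV against its item catalog.

    Rows with an empty response are retained (flagged missing); out-of-scale
    responses, unknown items and duplicate (rater, article, item, context)
    keys raise with the offending row named.
    """
    catalog = read_catalog(catalog_path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(RATINGS_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"ratings {path}: missing columns {sorted(missing)}")
    responses = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        item = catalog.get(row.item_id)
        if item is None:
            raise CatalogError(
                f"ratings {path} line {i}: unknown item_id {row.item_id!r}"
            )
        where = (
            f"ratings {path} line {i} "
            f"(rater={row.rater_id}, article={row.article_id}, item={row.item_id})"
        )
        responses.append(_canonical_response(row.response, item, where))
    out = df.loc[:, list(RATINGS_COLUMNS)].copy()
    out["context"] = out["context"].fillna("").astype(str)
    out["response"] = pd.Series(responses, index=out.index, dtype=object)
    dup = out.duplicated(subset=["rater_id", "article_id", "item_id", "context"])
    if dup.any():
        first = out[dup].iloc[0]
        raise ValidationError(
            f"ratings {path}: duplicate rating key (rater={first['rater_id']}, "
            f"article={first['article_id']}, item={first['item_id']}, "
            f"context={first['context']!r})"
        )
    return RatingTable(records=out, catalog=catalog)


def make_table(records: Iterable[RatingRecord] | pd.DataFrame,
               catalog: Mapping[str, ItemDefinition]) -> RatingTable:
    """Build a validated RatingTable from in-memory records."""
    if isinstance(records, pd.DataFrame):
        df = records.loc[:, list(RATINGS_COLUMNS)].copy()
    else:
        df = pd.DataFrame(
            [(r.rater_id, r.article_id, r.item_id, r.context, r.response)
             for r in records],
            columns=list(RATINGS_COLUMNS),
        )
    dup = df.duplicated(subset=["rater_id", "article_id", "item_id", "context"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate rating key (rater={first['rater_id']}, "
            f"article={first['article_id']}, item={first['item_id']}, "
            f"context={first['context']!r})"
        )
    for row in df.itertuples(index=False):
        item = catalog.get(row.item_id)
        if item is None:
            raise CatalogError(f"unknown item_id {row.item_id!r}")
        if row.response is not None and row.response not in item.categories:
            raise ValidationError(
                f"response {row.response!r} not in scale of item {row.item_id!r}"
            )
    return RatingTable(records=df, catalog=dict(catalog))


def _format_result(r: ItemResult) -> list[str]:
    pct = "NA" if r.pct_agreement is None else f"{round_half_up(r.pct_agreement, 0):.0f}"
    kappa = "NA" if r.kappa is None else f"{round_half_up(r.kappa, 2):.2f}"
    return [
        r.item_id,
        str(r.n_agreement),
        pct,
        str(r.n_kappa),
        kappa,
        r.kappa_method or "NA",
        ",".join(sorted(r.flags)) if r.flags else "",
    ]


def write_results(results: Sequence[ItemResult], path: str | Path) -> None:
    """Write per-item results as TSV at the published tables' precision."""
    if not results:
        raise ValueError("write_results: empty results")
    lines = ["\t".join(RESULT_COLUMNS)]
    lines += ["\t".join(_format_result(r)) for r in results]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame ('NA' -> missing)."""
    return pd.read_csv(path, sep="\t", dtype={"item_id": str, "flags": str},
                       na_values=["NA"], keep_default_na=False)
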
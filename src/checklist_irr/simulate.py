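"""Synthetic rating studies with known design structure and known reliability.

The study the package analyses never published its raw ratings, so every
estimator is validated by parameter recovery on data generated here.  The
generator reproduces the study design — 75 articles, 88 raters, three
articles per rater (one per workload stratum), a fixed histogram of ratings
per article, per-box missingness — and draws ratings from exchangeable
one-way latent models whose true reliability is known in closed form:

* beta-binomial (binary items): article quality p_a ~ Beta(alpha, beta),
  ratings Bernoulli(p_a); true ICC = 1 / (alpha + beta + 1);
* two-point latent with flip error (binary items at fixed rater error):
  article truth T_a ~ Bernoulli(prevalence), each rating flips T_a with
  probability flip_error; true ICC =
  (1-2e)^2 pi (1-pi) / (p(1-p)) with p = pi(1-2e) + e — the model that
  exhibits kappa attenuation as the pooled category share tends to 1;
* Dirichlet-categorical (ordinal/nominal items): per-article category
  probabilities p_a ~ Dirichlet(c * w); for any scoring of the categories
  the between-article variance is 1/(c+1) of the total, so the true ICC
  (and the true SI kappa) is 1 / (c + 1).

Workload strata are labels used only to balance rater burden; they do not
enter the rating model.  Missingness is completely at random per rating.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import SCALES, ItemDefinition, RatingTable, make_table

__all__ = [
    "StudyDesign",
    "ItemModel",
    "DesignAssignment",
    "DEFAULT_PROFILE",
    "DEFAULT_BOX_MISSING",
    "generate_design",
    "generate_ratings",
    "simulate_item_units",
    "true_kappa",
    "default_item_models",
]

#: (number of articles, ratings per article): 8 articles rated six times,
#: 7 five times, 11 four times, 38 three times, 11 twice — 263 ratings,
#: one short of the 264 the 88 raters supply (the generator pads one slot).
DEFAULT_PROFILE: tuple[tuple[int, int], ...] = (
    (8, 6), (7, 5), (11, 4), (38, 3), (11, 2),
)

#: Completely-at-random missingness per box, as fractions of ratings.
DEFAULT_BOX_MISSING: dict[str, float] = {
    "A": 0.07, "B": 0.05, "D": 0.01, "E": 0.11, "F": 0.07,
    "G": 0.05, "H": 0.05, "I": 0.18, "J": 0.03, "GEN": 0.01,
}

WORKLOAD_STRATA = ("low", "moderate", "high")


@dataclass(frozen=True)
class StudyDesign:
    """Design parameters of a rating study."""

    n_articles: int = 75
    n_raters: int = 88
    articles_per_rater: int = 3
    ratings_per_article_profile: tuple[tuple[int, int], ...] = DEFAULT_PROFILE
    seed: int = 0

    def __post_init__(self) -> None:
        n_prof = sum(c for c, _ in self.ratings_per_article_profile)
        if n_prof != self.n_articles:
            raise ValueError(
                f"profile covers {n_prof} articles, design has {self.n_articles}"
            )

    @property
    def profile_total_ratings(self) -> int:
        return sum(c * r for c, r in self.ratings_per_article_profile)

    @property
    def capacity(self) -> int:
        return self.n_raters * self.articles_per_rater


@dataclass
class DesignAssignment:
    """A realized rater-to-article assignment."""

    design: StudyDesign
    assignments: pd.DataFrame  # columns rater_id, article_id, stratum
    article_stratum: dict[str, str] = field(default_factory=dict)

    @property
    def ratings_per_article(self) -> Counter:
        return Counter(self.assignments["article_id"])

    def rating_count_histogram(self) -> Counter:
        """Counter mapping ratings-per-article -> number of articles."""
        return Counter(self.ratings_per_article.values())


@dataclass(frozen=True)
class ItemModel:
    """Generating model for one item.  Exactly one latent family applies:

    * alpha, beta        -> beta-binomial binary item
    * prevalence, flip_error -> two-point binary item with fixed rater error
    * concentration, base_weights -> Dirichlet-categorical item
    """

    item_id: str
    scale_kind: str
    box: str = "A"
    alpha: Optional[float] = None
    beta: Optional[float] = None
    prevalence: Optional[float] = None
    flip_error: Optional[float] = None
    concentration: Optional[float] = None
    base_weights: Optional[tuple[float, ...]] = None
    missing_rate: float = 0.0
    contexts: tuple[str, ...] = ()
    context_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.scale_kind not in SCALES:
            raise ValueError(f"unknown scale_kind {self.scale_kind!r}")
        fams = [self.alpha is not None and self.beta is not None,
                self.prevalence is not None and self.flip_error is not None,
                self.concentration is not None]
        if sum(fams) != 1:
            raise ValueError(
                f"item {self.item_id}: specify exactly one latent family"
            )
        if self.alpha is not None and (self.alpha <= 0 or self.beta <= 0):
            raise ValueError("alpha, beta must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        ncat = len(SCALES[self.scale_kind]["categories"])
        if self.family != "categorical" and ncat != 2:
            raise ValueError(
                f"item {self.item_id}: binary latent family on a {ncat}-category scale"
            )
        if self.base_weights is not None and len(self.base_weights) != ncat:
            raise ValueError(
                f"item {self.item_id}: base_weights must have {ncat} entries"
            )

    @property
    def family(self) -> str:
        if self.alpha is not None:
            return "beta_binomial"
        if self.prevalence is not None:
            return "two_point"
        return "categorical"

    @property
    def categories(self) -> tuple[str, ...]:
        return SCALES[self.scale_kind]["categories"]

    def definition(self) -> ItemDefinition:
        return ItemDefinition(self.item_id, self.box, self.scale_kind)


def true_kappa(model: ItemModel) -> float:
    """Closed-form reliability (one-way ICC) of an item's generating model."""
    if model.family == "beta_binomial":
        return 1.0 / (model.alpha + model.beta + 1.0)
    if model.family == "two_point":
        pi, e = model.prevalence, model.flip_error
        p = pi * (1 - 2 * e) + e
        if p in (0.0, 1.0):
            return 0.0
        return (1 - 2 * e) ** 2 * pi * (1 - pi) / (p * (1 - p))
    # Dirichlet(c*w): Var(sum s_i p_i) = Var(s)/(c+1) for any scoring s
    return 1.0 / (model.concentration + 1.0)


def _partition_strata(design: StudyDesign) -> tuple[dict[str, str], dict[str, int]]:
    """Split articles into workload strata, balancing target rating sums.

    Articles are sorted by descending target rating count and assigned
    greedily to the stratum with the smallest running sum that still has
    room, so each stratum's total is as close as possible to one rating
    per rater.
    """
    targets: list[int] = []
    for count, r in design.ratings_per_article_profile:
        targets += [r] * count
    article_ids = [f"article{i + 1:03d}" for i in range(design.n_articles)]
    target_of = dict(zip(article_ids, targets))
    s = design.articles_per_rater
    strata = [WORKLOAD_STRATA[i % len(WORKLOAD_STRATA)] + (
        "" if i < len(WORKLOAD_STRATA) else f"_{i // len(WORKLOAD_STRATA)}")
        for i in range(s)]
    cap = [design.n_articles // s + (1 if i < design.n_articles % s else 0)
           for i in range(s)]
    sums = [0] * s
    counts = [0] * s
    stratum_of: dict[str, str] = {}
    for aid in sorted(article_ids, key=lambda a: -target_of[a]):
        open_idx = [i for i in range(s) if counts[i] < cap[i]]
        j = min(open_idx, key=lambda i: (sums[i], counts[i]))
        stratum_of[aid] = strata[j]
        sums[j] += target_of[aid]
        counts[j] += 1
    return stratum_of, target_of


def generate_design(design: StudyDesign) -> DesignAssignment:
    """Assign raters to articles: one article per workload stratum per rater.

    Per-article rating counts follow the requested profile up to the +/-1
    slack between the profile total and rater capacity.  Deterministic
    given ``design.seed``.
    """
    delta = design.capacity - design.profile_total_ratings
    if abs(delta) > design.articles_per_rater:
        raise ValueError(
            f"profile supplies {design.profile_total_ratings} ratings but "
            f"{design.n_raters} raters x {design.articles_per_rater} articles "
            f"= {design.capacity}; mismatch exceeds the +/-1-per-stratum slack"
        )
    rng = np.random.default_rng(design.seed)
    stratum_of, target_of = _partition_strata(design)
    rater_ids = [f"rater{i + 1:03d}" for i in range(design.n_raters)]
    rows = []
    strata = sorted(set(stratum_of.values()))
    for stratum in strata:
        arts = sorted(a for a, st in stratum_of.items() if st == stratum)
        slots: list[str] = []
        for a in arts:
            slots += [a] * target_of[a]
        counts = Counter(slots)
        # pad or trim so every rater gets exactly one article in this stratum
        while len(slots) < design.n_raters:
            candidates = [a for a in arts if counts[a] < design.n_raters]
            a = candidates[int(np.argmin([counts[c] for c in candidates]))]
            slots.append(a)
            counts[a] += 1
        while len(slots) > design.n_raters:
            a = max(counts, key=lambda c: counts[c])
            slots.remove(a)
            counts[a] -= 1
        rng.shuffle(slots)
        rows += [(r, a, stratum) for r, a in zip(rater_ids, slots)]
    df = pd.DataFrame(rows, columns=["rater_id", "article_id", "stratum"])
    return DesignAssignment(design=design, assignments=df,
                            article_stratum=stratum_of)


def _draw_unit(model: ItemModel, n: int, rng: np.random.Generator) -> list[str]:
    cats = model.categories
    if model.family == "beta_binomial":
        p = rng.beta(model.alpha, model.beta)
        x = rng.random(n) < p
        return ["yes" if v else "no" for v in x]
    if model.family == "two_point":
        t = rng.random() < model.prevalence
        flip = rng.random(n) < model.flip_error
        return ["yes" if (t ^ f) else "no" for f in flip]
    w = np.asarray(model.base_weights
                   if model.base_weights is not None
                   else [1.0 / len(cats)] * len(cats))
    p = rng.dirichlet(model.concentration * w / w.sum())
    idx = rng.choice(len(cats), size=n, p=p)
    return [cats[i] for i in idx]


def simulate_item_units(
    rater_counts: Sequence[int], model: ItemModel, rng: np.random.Generator
) -> list[np.ndarray]:
    """Fast path: draw one item's numeric score units for given unit sizes.

    Returns per-article arrays of scores (0/1 for binary families, the
    ordinal score map for categorical items), without missingness or the
    DataFrame plumbing — used by recovery and attenuation studies.
    """
    score = SCALES[model.scale_kind]["score_map"]
    units = []
    for n in rater_counts:
        tokens = _draw_unit(model, n, rng)
        if score is None:
            units.append(np.array(tokens, dtype=object))
        else:
            units.append(np.array([score[t] for t in tokens]))
    return units


def generate_ratings(
    assignment: DesignAssignment, items: Sequence[ItemModel], seed: int
) -> RatingTable:
    """Draw a full rating table over a realized design.

    For each (article, item) — and each administered context for items that
    carry contexts — one latent parameter is drawn per article, then each
    assigned rater rates independently; missingness is applied per rating.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_article = {
        aid: sorted(grp["rater_id"])
        for aid, grp in assignment.assignments.groupby("article_id")
    }
    rows = []
    for model in items:
        contexts = model.contexts if model.contexts else ("",)
        for aid in sorted(by_article):
            raters = by_article[aid]
            for ctx in contexts:
                if ctx and model.context_rate < 1.0:
                    if rng.random() >= model.context_rate:
                        continue
                tokens = _draw_unit(model, len(raters), rng)
                miss = rng.random(len(raters)) < model.missing_rate
                for r, tok, m in zip(raters, tokens, miss):
                    rows.append((r, aid, model.item_id, ctx,
                                 None if m else tok))
    df = pd.DataFrame(
        rows, columns=["rater_id", "article_id", "item_id", "context", "response"]
    )
    catalog = {m.item_id: m.definition() for m in items}
    return make_table(df, catalog)


def default_item_models() -> list[ItemModel]:
    """A small COSMIN-style item battery covering all scale kinds and boxes."""
    mk = ItemModel
    return [
        mk("STEP1.reliability", "binary_yes_no", box="STEP1",
           alpha=0.5, beta=0.5, missing_rate=0.0),
        mk("A1", "ordinal_yes_q_no", box="A", concentration=1.5,
           base_weights=(0.6, 0.15, 0.25), missing_rate=0.07),
        mk("A9", "nominal_with_na_3", box="A", concentration=2.0,
           base_weights=(0.5, 0.3, 0.2), missing_rate=0.07),
        mk("B11", "binary_yes_no", box="B", alpha=1.0, beta=1.0,
           missing_rate=0.05),
        mk("I5", "binary_yes_no", box="I", alpha=9.0, beta=1.5,
           missing_rate=0.18),
        mk("GEN3", "ordinal_yes_q_no", box="GEN", concentration=1.0,
           base_weights=(0.7, 0.1, 0.2), missing_rate=0.01,
           contexts=("internal_consistency", "reliability", "responsiveness"),
           context_rate=0.8),
    ]


def write_provenance(path: str | Path, design: StudyDesign,
                     items: Sequence[ItemModel], seed: int) -> None:
    """Record seed, parameters and true kappas alongside a simulated dataset."""
    payload = {
        "seed": seed,
        "design": {
            "n_articles": design.n_articles,
            "n_raters": design.n_raters,
            "articles_per_rater": design.articles_per_rater,
            "profile": list(map(list, design.ratings_per_article_profile)),
            "design_seed": design.seed,
        },
        "items": [
            {
                "item_id": m.item_id,
                "scale_kind": m.scale_kind,
                "box": m.box,
                "family": m.family,
                "missing_rate": m.missing_rate,
                "true_kappa": true_kappa(m),
            }
            for m in items
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
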
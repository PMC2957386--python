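#!/usr/bin/env python
"""Generate the synthetic rating study used by the downstream analyses.

Emulates the design of the inter-rater study: 75 articles, 88 raters, three
articles per rater (one per workload stratum), per-article rating counts
following the reported histogram, per-box completely-at-random missingness,
and a small battery of items covering all scale kinds with known true
reliability.  Writes ratings.csv, catalog.csv and provenance.json under
results/synthetic_study/.
"""

from pathlib import Path

from checklist_irr.simulate import (
    StudyDesign,
    default_item_models,
    generate_design,
    generate_ratings,
    true_kappa,
    write_provenance,
)

SEED = 20260927
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic_study"


def main() -> None:
    design = StudyDesign(seed=SEED)
    assignment = generate_design(design)
    items = default_item_models()
    table = generate_ratings(assignment, items, seed=SEED)

    OUT.mkdir(parents=True, exist_ok=True)
    df = table.records.copy()
    df["response"] = df["response"].fillna("")
    df.to_csv(OUT / "ratings.csv", index=False)
    with open(OUT / "catalog.csv", "w", encoding="utf-8") as fh:
        fh.write("item_id,box,scale_kind\n")
        for item in table.catalog.values():
            fh.write(f"{item.item_id},{item.box},{item.scale_kind}\n")
    write_provenance(OUT / "provenance.json", design, items, SEED)

    hist = sorted(assignment.rating_count_histogram().items())
    print(f"design: {design.n_articles} articles, {design.n_raters} raters, "
          f"{len(assignment.assignments)} article-assignments")
    print(f"ratings-per-article histogram: {hist}")
    print(f"{len(table)} ratings for {len(items)} items -> {OUT}")
    for m in items:
        print(f"  {m.item_id:<18} {m.scale_kind:<18} true kappa "
              f"{true_kappa(m):.3f}  missing {m.missing_rate:.0%}")


if __name__ == "__main__":
    main()
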
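import numpy as np
import pytest

from checklist_irr.io import ItemDefinition, RatingRecord, make_table


@pytest.fixture
def tiny_catalog():
    return {
        "A1": ItemDefinition("A1", "A", "ordinal_yes_q_no"),
        "A9": ItemDefinition("A9", "A", "nominal_with_na_3"),
        "B11": ItemDefinition("B11", "B", "binary_yes_no"),
        "GEN3": ItemDefinition("GEN3", "GEN", "ordinal_yes_q_no"),
        "STEP1.reliability": ItemDefinition("STEP1.reliability", "STEP1",
                                            "binary_yes_no"),
    }


@pytest.fixture
def small_table(tiny_catalog):
    """Hand-built table: B11 has two articles with perfect within-article
    agreement and differing values, plus one singleton article; GEN3 is
    scored under two measurement properties on one article."""
    recs = [
        RatingRecord("r1", "a1", "B11", "", "yes"),
        RatingRecord("r2", "a1", "B11", "", "yes"),
        RatingRecord("r3", "a2", "B11", "", "no"),
        RatingRecord("r4", "a2", "B11", "", "no"),
        RatingRecord("r5", "a3", "B11", "", "yes"),  # singleton
        RatingRecord("r1", "a1", "A1", "", "yes"),
        RatingRecord("r2", "a1", "A1", "", "?"),
        RatingRecord("r3", "a2", "A1", "", "no"),
        RatingRecord("r4", "a2", "A1", "", "no"),
        RatingRecord("r1", "a1", "GEN3", "reliability", "yes"),
        RatingRecord("r2", "a1", "GEN3", "reliability", "yes"),
        RatingRecord("r3", "a1", "GEN3", "responsiveness", "no"),
        RatingRecord("r4", "a1", "GEN3", "responsiveness", "no"),
    ]
    return make_table(recs, tiny_catalog)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_units(rng, k_max=10, n_max=6, values=(0.0, 1.0)):
    """Random small one-way layout with >=2 groups, >=1 group of size >=2."""
    while True:
        k = int(rng.integers(2, k_max + 1))
        sizes = rng.integers(1, n_max + 1, size=k)
        if (sizes >= 2).any():
            break
    return [list(rng.choice(values, size=s)) for s in sizes]
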
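import pandas as pd
import pytest

import coldscore as cs


@pytest.fixture(scope="session")
def registry():
    return cs.default_registry()


def make_dataset(rows, registry=None, **kwargs):
    """Build a PhenotypeDataset from (genotype, treatment, replicate, trait, value) tuples."""
    df = pd.DataFrame(
        rows, columns=["genotype", "treatment", "replicate", "trait", "value"]
    )
    if registry is None:
        traits = sorted(df["trait"].unique())
        registry = cs.TraitRegistry(
            cs.TraitDefinition(t, t, "growth", "unit", +1) for t in traits
        )
    return cs.PhenotypeDataset(df, registry, **kwargs)


@pytest.fixture
def two_by_two_dataset():
    """2 genotypes x 2 treatments x 2 replicates, 1 trait; the ANOVA hand fixture."""
    cells = {
        ("g1", "CK"): (10.0, 12.0),
        ("g1", "LT"): (6.0, 8.0),
        ("g2", "CK"): (20.0, 22.0),
        ("g2", "LT"): (16.0, 18.0),
    }
    rows = [
        (g, t, r, "SL", v)
        for (g, t), values in cells.items()
        for r, v in enumerate(values, start=1)
    ]
    return make_dataset(rows)


@pytest.fixture
def hand_cohort():
    """4 genotypes x 3 traits with CK means of 1, so CRC equals the LT value.

    Traits A, B favour resistance (+1); trait C indicates damage (-1).
    Expected membership values were derived by hand (min-max within each
    trait, inverted for C) and are frozen in the tests that use this.
    """
    crc = {
        "A": {"g1": 0.4, "g2": 0.8, "g3": 1.0, "g4": 0.6},
        "B": {"g1": 1.0, "g2": 1.5, "g3": 2.0, "g4": 1.25},
        "C": {"g1": 3.0, "g2": 2.0, "g3": 1.0, "g4": 1.5},
    }
    registry = cs.TraitRegistry(
        [
            cs.TraitDefinition("A", "trait A", "growth", "u", +1),
            cs.TraitDefinition("B", "trait B", "growth", "u", +1),
            cs.TraitDefinition("C", "trait C", "membrane", "u", -1),
        ]
    )
    rows = []
    for trait, per_geno in crc.items():
        for genotype, lt in per_geno.items():
            rows.append((genotype, "CK", 1, trait, 1.0))
            rows.append((genotype, "LT", 1, trait, lt))
    return make_dataset(rows, registry=registry)
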
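"""Rate change, CRC, membership normalisation, CV_g and the full evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coldscore as cs
from coldscore.evaluation import CRCMatrix

from conftest import make_dataset


def brute_force_membership(crc_values, directions):
    """Independent per-row min-max normalisation oracle (plain loops)."""
    out = np.empty_like(crc_values)
    for i in range(crc_values.shape[1]):  # traits are columns
        col = crc_values[:, i]
        lo, hi = min(col), max(col)
        for j in range(crc_values.shape[0]):
            u = (col[j] - lo) / (hi - lo)
            out[j, i] = u if directions[i] == +1 else 1.0 - u
    return out


class TestRateChange:
    @pytest.mark.parametrize(
        "lt, ck, expected", [(10.0, 10.0, 0.0), (5.0, 10.0, -50.0), (15.0, 10.0, 50.0)]
    )
    def test_scalar_values(self, lt, ck, expected):
        assert cs.rate_change(lt, ck) == pytest.approx(expected)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(cs.DomainError):
            cs.rate_change(5.0, 0.0)


class TestCRC:
    def test_hand_fixture_matrix_and_extrema(self):
        # 3 genotypes x 2 traits, CK means chosen so ratios are hand-checkable
        cells = {
            ("g1", "CK", "A"): 10.0, ("g1", "LT", "A"): 5.0,
            ("g2", "CK", "A"): 10.0, ("g2", "LT", "A"): 10.0,
            ("g3", "CK", "A"): 20.0, ("g3", "LT", "A"): 15.0,
            ("g1", "CK", "B"): 4.0, ("g1", "LT", "B"): 6.0,
            ("g2", "CK", "B"): 5.0, ("g2", "LT", "B"): 4.0,
            ("g3", "CK", "B"): 8.0, ("g3", "LT", "B"): 8.0,
        }
        rows = [(g, t, 1, tr, v) for (g, t, tr), v in cells.items()]
        means = cs.replicate_means(make_dataset(rows))
        crc = cs.cold_resistance_coefficients(means)
        expected = pd.DataFrame(
            {"A": [0.5, 1.0, 0.75], "B": [1.5, 0.8, 1.0]},
            index=["g1", "g2", "g3"],
        )
        pd.testing.assert_frame_equal(
            crc.values, expected, check_names=False, check_like=True
        )
        assert crc.trait_min["A"] == 0.5 and crc.trait_max["A"] == 1.0
        assert crc.trait_min["B"] == 0.8 and crc.trait_max["B"] == 1.5

    def test_identity_with_rate_change(self):
        rows = [("g1", "CK", 1, "A", 8.0), ("g1", "LT", 1, "A", 6.0),
                ("g2", "CK", 1, "A", 8.0), ("g2", "LT", 1, "A", 10.0)]
        means = cs.replicate_means(make_dataset(rows))
        crc = cs.cold_resistance_coefficients(means)
        rc = cs.rate_change(np.array([6.0, 10.0]), np.array([8.0, 8.0]))
        np.testing.assert_allclose(crc.values["A"], 1.0 + rc / 100.0)

    def test_zero_control_mean_names_offender(self):
        registry = cs.TraitRegistry(
            [cs.TraitDefinition("A", "a", "growth", "u", +1, strictly_positive=False)]
        )
        rows = [("g1", "CK", 1, "A", 0.0), ("g1", "LT", 1, "A", 1.0),
                ("g2", "CK", 1, "A", 2.0), ("g2", "LT", 1, "A", 1.0)]
        means = cs.replicate_means(make_dataset(rows, registry=registry))
        with pytest.raises(cs.DomainError, match="g1.*A"):
            cs.cold_resistance_coefficients(means)


class TestMembership:
    @pytest.fixture
    def simple_crc(self):
        values = pd.DataFrame(
            {"pos": [0.5, 0.75, 1.0], "neg": [0.5, 0.75, 1.0]},
            index=["g1", "g2", "g3"],
        )
        return CRCMatrix(values=values, trait_min=values.min(), trait_max=values.max())

    @pytest.fixture
    def pos_neg_registry(self):
        return cs.TraitRegistry(
            [
                cs.TraitDefinition("pos", "p", "growth", "u", +1),
                cs.TraitDefinition("neg", "n", "membrane", "u", -1),
            ]
        )

    def test_hand_row_both_directions(self, simple_crc, pos_neg_registry):
        mm = cs.membership_values(simple_crc, pos_neg_registry)
        np.testing.assert_allclose(mm.values["pos"], [0.0, 0.5, 1.0])
        np.testing.assert_allclose(mm.values["neg"], [1.0, 0.5, 0.0])

    def test_endpoints(self, simple_crc, pos_neg_registry):
        mm = cs.membership_values(simple_crc, pos_neg_registry)
        assert mm.values["pos"].min() == 0.0 and mm.values["pos"].max() == 1.0
        assert mm.values["neg"].loc["g1"] == 1.0  # damage trait at its minimum CRC

    def test_direction_flip_maps_u_to_complement(self, simple_crc):
        flipped = cs.TraitRegistry(
            [
                cs.TraitDefinition("pos", "p", "growth", "u", -1),
                cs.TraitDefinition("neg", "n", "membrane", "u", +1),
            ]
        )
        base = cs.membership_values(
            simple_crc,
            cs.TraitRegistry(
                [
                    cs.TraitDefinition("pos", "p", "growth", "u", +1),
                    cs.TraitDefinition("neg", "n", "membrane", "u", -1),
                ]
            ),
        )
        inv = cs.membership_values(simple_crc, flipped)
        pd.testing.assert_frame_equal(inv.values, 1.0 - base.values)

    def test_missing_trait_is_registry_error(self, simple_crc):
        partial = cs.TraitRegistry([cs.TraitDefinition("pos", "p", "growth", "u", +1)])
        with pytest.raises(cs.RegistryError, match="neg"):
            cs.membership_values(simple_crc, partial)

    def test_degenerate_trait_gets_half_with_warning(self, pos_neg_registry):
        values = pd.DataFrame(
            {"pos": [1.0, 1.0, 1.0], "neg": [0.5, 1.0, 1.5]},
            index=["g1", "g2", "g3"],
        )
        crc = CRCMatrix(values=values, trait_min=values.min(), trait_max=values.max())
        with pytest.warns(UserWarning, match="pos"):
            mm = cs.membership_values(crc, pos_neg_registry)
        assert (mm.values["pos"] == 0.5).all()
        assert mm.degenerate_traits == ["pos"]

    @settings(deadline=None, max_examples=25)
    @given(
        data=st.lists(
            st.lists(st.floats(0.05, 5.0), min_size=5, max_size=5),
            min_size=5, max_size=5,
        ),
        directions=st.lists(st.sampled_from([+1, -1]), min_size=5, max_size=5),
    )
    def test_matches_brute_force_oracle_on_random_matrices(self, data, directions):
        values = pd.DataFrame(
            np.asarray(data), index=[f"g{j}" for j in range(5)],
            columns=[f"t{i}" for i in range(5)],
        )
        # skip accidental degenerate rows: the oracle divides by the range
        if (values.max() - values.min()).min() == 0:
            return
        crc = CRCMatrix(values=values, trait_min=values.min(), trait_max=values.max())
        registry = cs.TraitRegistry(
            cs.TraitDefinition(f"t{i}", "t", "growth", "u", d)
            for i, d in enumerate(directions)
        )
        mm = cs.membership_values(crc, registry)
        expected = brute_force_membership(values.to_numpy(), directions)
        np.testing.assert_allclose(mm.values.to_numpy(), expected, atol=1e-12)
        assert ((mm.values >= 0) & (mm.values <= 1)).all().all()
        np.testing.assert_allclose(mm.scores, expected.mean(axis=1))


class TestGeneticCV:
    def test_constant_is_zero(self):
        assert cs.genetic_cv([2.0, 2.0, 2.0]) == 0.0

    def test_hand_value(self):
        # sample SD of {1,2,3} is 1, mean 2 -> 50%
        assert cs.genetic_cv([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_population_convention_switchable(self):
        assert cs.genetic_cv([1.0, 2.0, 3.0], ddof=0) == pytest.approx(
            np.sqrt(2.0 / 3.0) / 2.0 * 100.0
        )

    @pytest.mark.parametrize("bad", [[1.0], [1.0, -1.0]])
    def test_domain_errors(self, bad):
        with pytest.raises(cs.DomainError):
            cs.genetic_cv(bad)

    @settings(deadline=None, max_examples=30)
    @given(
        values=st.lists(st.floats(0.5, 100.0), min_size=3, max_size=12),
        scale=st.floats(0.01, 100.0),
        shift=st.floats(1.0, 50.0),
    )
    def test_scale_invariant_translation_sensitive(self, values, scale, shift):
        x = np.asarray(values)
        base = cs.genetic_cv(x)
        assert cs.genetic_cv(x * scale) == pytest.approx(base, rel=1e-9)
        if x.std(ddof=1) > 1e-6:
            assert cs.genetic_cv(x + shift) < base  # mean grows, SD unchanged


class TestEvaluateCohort:
    def test_hand_cohort_full_table(self, hand_cohort):
        """Frozen hand computation: CK means are 1 so CRC equals the LT value;
        min-max within traits A/B, inverted for damage trait C."""
        ev = cs.evaluate_cohort(hand_cohort)
        expected_u = pd.DataFrame(
            {
                "A": {"g1": 0.0, "g2": 2 / 3, "g3": 1.0, "g4": 1 / 3},
                "B": {"g1": 0.0, "g2": 0.5, "g3": 1.0, "g4": 0.25},
                "C": {"g1": 0.0, "g2": 0.5, "g3": 1.0, "g4": 0.75},
            }
        )
        pd.testing.assert_frame_equal(
            ev.membership.values, expected_u.loc[ev.membership.values.index],
            check_names=False, atol=1e-12,
        )
        expected_scores = {"g1": 0.0, "g2": (2 / 3 + 0.5 + 0.5) / 3,
                           "g3": 1.0, "g4": (1 / 3 + 0.25 + 0.75) / 3}
        for g, u in expected_scores.items():
            assert ev.scores[g] == pytest.approx(u)

    def test_noise_free_identical_treatments_degenerate(self, registry):
        cfg = cs.GeneratorConfig(
            n_genotypes=4, seed=0, multipliers=1.0, genotype_cv=0.3,
            interaction_cv=0.0, residual_cv=0.0, resistance_effect=0.0,
        )
        ds, _ = cs.generate_phenotypes(cfg)
        with pytest.warns(UserWarning):
            ev = cs.evaluate_cohort(ds)
        assert np.allclose(ev.crc.values, 1.0)
        assert np.allclose(ev.membership.values, 0.5)
        assert np.allclose(ev.rc_summary["mean_rc"], 0.0)

    def test_dominating_genotype_scores_one(self):
        registry = cs.TraitRegistry(
            [
                cs.TraitDefinition("A", "a", "growth", "u", +1),
                cs.TraitDefinition("B", "b", "membrane", "u", -1),
            ]
        )
        # g1 has the highest CRC for +1 trait A and the lowest for damage trait B
        cells = {
            ("g1", "A"): 2.0, ("g2", "A"): 1.0, ("g3", "A"): 1.5,
            ("g1", "B"): 1.0, ("g2", "B"): 3.0, ("g3", "B"): 2.0,
        }
        rows = []
        for (g, tr), lt in cells.items():
            rows += [(g, "CK", 1, tr, 1.0), (g, "LT", 1, tr, lt)]
        ev = cs.evaluate_cohort(make_dataset(rows, registry=registry))
        assert ev.scores["g1"] == pytest.approx(1.0)

    def test_unit_rescaling_and_relabeling_invariance(self, hand_cohort):
        base = cs.evaluate_cohort(hand_cohort)
        scaled = hand_cohort.data.copy()
        scaled.loc[scaled["trait"] == "A", "value"] *= 37.5  # change trait A's units
        ds2 = cs.PhenotypeDataset(scaled, hand_cohort.registry)
        rescaled = cs.evaluate_cohort(ds2)
        pd.testing.assert_series_equal(base.scores, rescaled.scores, atol=1e-12)

        shuffled = hand_cohort.data.sample(frac=1.0, random_state=7)
        ds3 = cs.PhenotypeDataset(shuffled, hand_cohort.registry)
        perm = cs.evaluate_cohort(ds3)
        for g in base.scores.index:
            assert perm.scores[g] == pytest.approx(base.scores[g], abs=1e-12)

    def test_trait_subset_restricts_score(self, hand_cohort):
        ev = cs.evaluate_cohort(hand_cohort, traits=["A", "B"])
        assert list(ev.membership.values.columns) == ["A", "B"]
        assert ev.scores["g2"] == pytest.approx((2 / 3 + 0.5) / 2)
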
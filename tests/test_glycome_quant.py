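"""Glycome summarization: class shares, pathway usage, ratios, comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glycohex import glycome_quant as gq, synthetic as syn
from glycohex.glycan_model import GlycanClass


def small_table(values: dict[str, list[float]], compositions: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(values, index=pd.Index(
        [f"sp{i}" for i in range(len(compositions))], name="species"))
    df.insert(0, "composition", compositions)
    return df


class TestTypeSummary:
    def test_single_species_sample_is_100_percent(self):
        g = small_table({"s1": [1.0]}, ["Hex3HexNAc2dHex1"])
        shares = gq.type_summary(g)
        assert shares.loc["paucimannose", "s1"] == pytest.approx(100.0)

    def test_hand_computed_three_species_fixture(self):
        g = small_table(
            {"s1": [0.2, 0.3, 0.5]},
            ["Hex3HexNAc2dHex1", "Hex9HexNAc2", "Hex5HexNAc4dHex1NeuAc2"],
        )
        shares = gq.type_summary(g)
        assert shares.loc["paucimannose", "s1"] == pytest.approx(20.0)
        assert shares.loc["oligomannose", "s1"] == pytest.approx(30.0)
        assert shares.loc["complex", "s1"] == pytest.approx(50.0)

    def test_columns_sum_to_100(self, zero_noise_glycome):
        shares = gq.type_summary(zero_noise_glycome)
        assert np.allclose(shares.sum(), 100.0, atol=1e-9)

    def test_nat_round_trip_reproduces_printed_share(self, zero_noise_glycome):
        shares = gq.type_summary(zero_noise_glycome)
        assert shares.loc["paucimannose", "control_01"] == pytest.approx(6.7, abs=1e-9)

    def test_unparseable_composition_lands_in_other(self):
        g = small_table({"s1": [0.5, 0.5]}, ["Hex3HexNAc2", "Pent3Xyl1"])
        shares = gq.type_summary(g)
        assert shares.loc["other", "s1"] == pytest.approx(50.0)


class TestSpeciesShareWithinClass:
    def test_single_species_class_is_100(self):
        g = small_table({"s1": [0.3, 0.7]}, ["Hex3HexNAc2dHex1", "Hex9HexNAc2"])
        within = gq.species_share_within_class(g, GlycanClass.PAUCIMANNOSE)
        assert within.loc["sp0", "s1"] == pytest.approx(100.0)

    def test_two_equal_species_split_50_50(self):
        g = small_table(
            {"s1": [0.2, 0.2, 0.6]},
            ["Hex2HexNAc2dHex1", "Hex3HexNAc2dHex1", "Hex9HexNAc2"],
        )
        within = gq.species_share_within_class(g, "paucimannose")
        assert within.loc["sp0", "s1"] == pytest.approx(50.0)
        assert within.loc["sp1", "s1"] == pytest.approx(50.0)

    def test_absent_class_is_missing_not_zero(self):
        g = small_table({"s1": [1.0, 0.0], "s2": [0.5, 0.5]},
                        ["Hex9HexNAc2", "Hex3HexNAc2dHex1"])
        within = gq.species_share_within_class(g, "paucimannose")
        assert np.isnan(within.loc["sp1", "s1"])
        assert within.loc["sp1", "s2"] == pytest.approx(100.0)

    def test_tumor_default_m2f_m3f_band(self, design):
        profiles = syn.default_profiles(design, "tissue", dispersion=0.0)
        g = syn.generate_glycome_table(design, profiles, seed=1)
        within = gq.species_share_within_class(g, "paucimannose")
        combined = within.loc["M2F"] + within.loc["M3F"]
        assert ((combined >= 60) & (combined <= 70)).all()


class TestPathwayUsage:
    def test_all_paucimannose_is_pure_truncation(self):
        g = small_table({"s1": [1.0]}, ["Hex3HexNAc2dHex1"])
        usage = gq.pathway_usage(gq.type_summary(g))
        assert usage.loc["truncation", "s1"] == pytest.approx(100.0)

    def test_equal_pauci_complex_splits_50_50(self):
        g = small_table({"s1": [0.5, 0.5]}, ["Hex3HexNAc2dHex1", "Hex5HexNAc4dHex1"])
        usage = gq.pathway_usage(gq.type_summary(g))
        assert usage.loc["truncation", "s1"] == pytest.approx(50.0)
        assert usage.loc["elongation", "s1"] == pytest.approx(50.0)

    def test_inhibition_shifts_truncation_to_elongation(self):
        """Reducing paucimannose share in favor of complex glycans must
        monotonically lower truncation usage and raise elongation usage."""
        untreated = small_table(
            {"s1": [0.3, 0.2, 0.5]},
            ["Hex3HexNAc2dHex1", "Hex5HexNAc2", "Hex5HexNAc4dHex1"],
        )
        inhibited = small_table(
            {"s1": [0.1, 0.2, 0.7]},
            ["Hex3HexNAc2dHex1", "Hex5HexNAc2", "Hex5HexNAc4dHex1"],
        )
        u0 = gq.pathway_usage(gq.type_summary(untreated))
        u1 = gq.pathway_usage(gq.type_summary(inhibited))
        assert u1.loc["truncation", "s1"] < u0.loc["truncation", "s1"]
        assert u1.loc["elongation", "s1"] > u0.loc["elongation", "s1"]


class TestPairedRatio:
    def test_identical_samples_ratio_one(self):
        g = small_table({"tum": [0.4, 0.6], "nat": [0.4, 0.6]},
                        ["Hex3HexNAc2dHex1", "Hex9HexNAc2"])
        out = gq.paired_ratio(g, "tum", "nat")
        assert np.allclose(out["ratio"], 1.0)

    def test_hand_computed_ratios_and_zero_denominator_flag(self):
        g = small_table({"tum": [0.5, 0.3, 0.2], "nat": [0.25, 0.75, 0.0]},
                        ["Hex3HexNAc2dHex1", "Hex9HexNAc2", "Hex5HexNAc3"])
        out = gq.paired_ratio(g, "tum", "nat")
        assert out.loc["sp0", "ratio"] == pytest.approx(2.0)
        assert out.loc["sp1", "ratio"] == pytest.approx(0.4)
        assert np.isnan(out.loc["sp2", "ratio"]) and not out.loc["sp2", "defined"]

    def test_elevated_tumor_pauci_gives_ratios_above_one(self, design):
        profiles = {"control": syn.tissue_profile("control", 0.0),
                    "II": syn.tissue_profile("II", 0.0)}
        small = syn.CohortDesign(groups=(("control", 2), ("II", 2)), plexes=2)
        g = syn.generate_glycome_table(small, profiles, seed=0)
        out = gq.paired_ratio(g, "II_01", "control_01")
        pauci = [sp for sp, (_, c) in syn.DEFAULT_SPECIES.items()
                 if c is GlycanClass.PAUCIMANNOSE]
        assert (out.loc[pauci, "ratio"] > 1).all()


class TestCompareGroups:
    def test_identical_groups_give_zero_difference_p_one(self):
        pauci = [39.0, 40.0, 41.0]
        shares = pd.DataFrame(
            {f"a{i}": [pauci[i], 100 - pauci[i]] for i in range(3)}
            | {f"b{i}": [pauci[i], 100 - pauci[i]] for i in range(3)},
            index=pd.Index(["paucimannose", "complex"], name="glycan_class"),
        )
        groups = {f"a{i}": "control" for i in range(3)} | {f"b{i}": "I" for i in range(3)}
        out = gq.compare_groups(shares, groups)
        assert np.allclose(out["mean_diff"], 0.0, atol=1e-12)
        assert (out["p"] > 0.999).all()

    def test_planted_stage_elevation_detected_with_positive_sign(self, design):
        profiles = syn.default_profiles(design, "tissue", dispersion=0.1)
        g = syn.generate_glycome_table(design, profiles, seed=13)
        shares = gq.type_summary(g)
        st = design.sample_table()
        out = gq.compare_groups(shares, dict(zip(st.sample_id, st.group)))
        pauci = out[(out.glycan_class == "paucimannose") & (out.group_a.isin(["III", "IV"]))]
        assert (pauci["mean_diff"] > 0).all()
        assert (pauci["p"] < 0.05).all()

    def test_p_value_agrees_with_exhaustive_permutation(self):
        """Student t p on a 5+5 fixture is close to the exact permutation p
        (the t test is the approximation; enumeration is the oracle)."""
        a = np.array([3.1, 4.2, 2.8, 3.9, 3.5])
        b = np.array([5.0, 5.8, 4.9, 6.1, 5.4])
        from itertools import combinations
        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        count = 0
        total = 0
        idx = range(10)
        for pick in combinations(idx, 5):
            mask = np.zeros(10, dtype=bool)
            mask[list(pick)] = True
            diff = abs(pooled[mask].mean() - pooled[~mask].mean())
            count += diff >= observed - 1e-12
            total += 1
        perm_p = count / total
        shares = pd.DataFrame(
            {f"a{i}": [v] for i, v in enumerate(a)} | {f"b{i}": [v] for i, v in enumerate(b)},
            index=pd.Index(["paucimannose"], name="glycan_class"),
        )
        groups = {f"a{i}": "control" for i in range(5)} | {f"b{i}": "I" for i in range(5)}
        out = gq.compare_groups(shares, groups)
        assert out.iloc[0]["p"] == pytest.approx(perm_p, abs=0.01)

    def test_undersized_group_rejected(self):
        shares = pd.DataFrame({"a0": [1.0], "a1": [2.0], "b0": [3.0]},
                              index=pd.Index(["paucimannose"], name="glycan_class"))
        with pytest.raises(ValueError, match="fewer than 2"):
            gq.compare_groups(shares, {"a0": "control", "a1": "control", "b0": "I"})
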
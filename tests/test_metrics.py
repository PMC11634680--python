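import numpy as np
import pandas as pd
import pytest

import guilddiet as gd

from conftest import make_site_diet, random_diet_vector


class TestGenusProportions:
    def test_arithmetic(self):
        v = gd.genus_proportions({"A": 3, "B": 1})
        np.testing.assert_allclose(v.p, [0.75, 0.25])
        assert v.G == 2 and v.N == 4

    def test_single_genus(self):
        v = gd.genus_proportions({"A": 5})
        assert v.p.tolist() == [1.0] and v.G == 1

    def test_zero_counts_dropped_before_G(self):
        assert gd.genus_proportions({"A": 2, "B": 0}).G == 1

    def test_empty_diet_error(self):
        with pytest.raises(gd.GuildDietError, match="empty diet"):
            gd.genus_proportions({"A": 0})

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = gd.genus_proportions(random_diet_vector(rng))
            assert abs(v.p.sum() - 1.0) < 1e-12


class TestIndices:
    @pytest.mark.parametrize(
        "counts,h,b,j",
        [
            ({"A": 1, "B": 1, "C": 1, "D": 1}, np.log(4), 4.0, 1.0),
            ({"A": 3, "B": 1}, 0.5623351446188083, 1.6, 0.8112781244591328),
            ({"A": 7}, 0.0, 1.0, np.nan),
        ],
    )
    def test_worked_examples(self, counts, h, b, j):
        v = gd.genus_proportions(counts)
        assert gd.shannon_H(v) == pytest.approx(h, abs=1e-12)
        assert gd.levins_B(v) == pytest.approx(b, abs=1e-12)
        if np.isnan(j):
            assert np.isnan(gd.evenness_J(v))
        else:
            assert gd.evenness_J(v) == pytest.approx(j, abs=1e-12)

    def test_extreme_skew_drives_J_to_zero(self):
        v = gd.genus_proportions({"A": 10**9, "B": 1})
        assert gd.evenness_J(v) < 1e-6

    def test_hill_number_ordering_random_vectors(self):
        # ln B <= H <= ln G for any composition
        rng = np.random.default_rng(1)
        for _ in range(300):
            v = gd.genus_proportions(random_diet_vector(rng))
            H = gd.shannon_H(v)
            assert np.log(gd.levins_B(v)) <= H + 1e-12
            assert H <= np.log(v.G) + 1e-12

    def test_merging_genera_never_increases_H(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            counts = random_diet_vector(rng)
            keys = sorted(counts)
            a, b = keys[0], keys[1]
            merged = dict(counts)
            merged[a] = merged.pop(a) + merged.pop(b)
            h0 = gd.shannon_H(gd.genus_proportions(counts))
            h1 = gd.shannon_H(gd.genus_proportions(merged))
            assert h1 <= h0 + 1e-12

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        counts = random_diet_vector(rng)
        scaled = {g: 7 * c for g, c in counts.items()}
        v0, v1 = gd.genus_proportions(counts), gd.genus_proportions(scaled)
        assert gd.shannon_H(v0) == pytest.approx(gd.shannon_H(v1), abs=1e-12)
        assert gd.levins_B(v0) == pytest.approx(gd.levins_B(v1), abs=1e-12)


class TestPreySize:
    def test_weighted_mean(self, tiny_traits):
        traits = gd.TraitTable({"A": 20.0, "B": 40.0})
        v = gd.genus_proportions({"A": 10, "B": 30})
        assert gd.weighted_mean_prey_size(v, traits) == 35.0

    def test_single_genus_identity(self):
        traits = gd.TraitTable({"Apodemus": 27.3})
        v = gd.genus_proportions({"Apodemus": 50})
        assert gd.weighted_mean_prey_size(v, traits) == 27.3

    def test_bounded_by_mass_range(self):
        rng = np.random.default_rng(4)
        masses = {f"G{i:02d}": float(m) for i, m in enumerate(rng.lognormal(3, 1, 20))}
        traits = gd.TraitTable(masses)
        for _ in range(100):
            v = gd.genus_proportions(random_diet_vector(rng))
            w = gd.weighted_mean_prey_size(v, traits)
            sel = [masses[g] for g in v.genera]
            assert min(sel) <= w <= max(sel)

    def test_missing_mass_error(self):
        traits = gd.TraitTable({"A": 20.0})
        v = gd.genus_proportions({"A": 1, "B": 1})
        with pytest.raises(gd.GuildDietError, match="B"):
            gd.weighted_mean_prey_size(v, traits)


class TestMammalProportion:
    def test_basic_ratio(self):
        d = make_site_diet({"Mus": 80}, extra_classes={"bird": 20})
        assert gd.proportion_terrestrial_mammals(d) == 0.8

    def test_mammals_only_site_missing(self):
        d = make_site_diet({"Mus": 100}, mammals_only=True)
        assert np.isnan(gd.proportion_terrestrial_mammals(d))

    def test_bats_in_denominator_only(self):
        d = make_site_diet({"Mus": 10}, extra_classes={"mammal_bat": 2, "bird": 8})
        assert gd.proportion_terrestrial_mammals(d) == 0.5

    def test_unidentified_verts_in_denominator(self):
        d = make_site_diet({"Mus": 10}, extra_classes={"unidentified_vert": 10})
        assert gd.proportion_terrestrial_mammals(d) == 0.5


class TestCompositionSummary:
    def test_single_class_is_100pct(self, tiny_prey):
        mam = tiny_prey[tiny_prey["v_class"] == "mammal_terrestrial"].reset_index(drop=True)
        summary = gd.composition_summary(mam).set_index("category")
        assert summary.loc["mammal_terrestrial", "pct_items"] == 100.0
        assert summary.loc["vertebrate", "pct_items"] == 100.0

    def test_percentages_sum_and_genus_tallies(self, tiny_prey):
        summary = gd.composition_summary(tiny_prey).set_index("category")
        assert summary.loc["mammal_terrestrial", "n_items"] == 24
        assert summary.loc["bird", "n_items"] == 3
        assert summary.loc["mammal_terrestrial", "pct_items"] == pytest.approx(88.89, abs=0.01)
        assert summary.loc["mammal_terrestrial", "n_genera"] == 3
        assert summary.loc["bird", "n_genera"] == 1


class TestTopGenera:
    def test_identical_top_sets_union_k(self):
        diets = [
            make_site_diet({"Mus": 50, "Apodemus": 40, "Microtus": 30, "Rattus": 20, "Glis": 10, "Sorex": 1},
                           cluster_id=f"{p}:L1", predator=p)
            for p in ("LEO", "TAW", "EEO")
        ]
        res = gd.top_genus_union(diets, k=5)
        assert len(res.union) == 5

    def test_tie_breaks_alphabetical(self):
        d = make_site_diet({"B": 10, "A": 10, "C": 5})
        res = gd.top_genus_union([d], k=2)
        assert res.per_predator_top["LEO"] == ["A", "B"]

    def test_fewer_than_k_takes_all(self):
        d = make_site_diet({"Mus": 5, "Apodemus": 2})
        res = gd.top_genus_union([d], k=5)
        assert res.per_predator_top["LEO"] == ["Mus", "Apodemus"]
        assert res.coverage_pct["LEO"] == 100.0


class TestBiomassShare:
    def test_arithmetic(self):
        traits = gd.TraitTable({"Mus": 30.0, "Turdus": 20.0})
        d = make_site_diet({"Mus": 10}, extra_classes={"bird": 10},
                           extra_genus_counts={"bird": {"Turdus": 10}})
        shares = gd.biomass_share(d, traits)
        assert shares["mammal_terrestrial"] == pytest.approx(60.0)
        assert shares["bird"] == pytest.approx(40.0)

    def test_single_class_100(self):
        traits = gd.TraitTable({"Mus": 30.0})
        d = make_site_diet({"Mus": 10})
        assert gd.biomass_share(d, traits)["mammal_terrestrial"] == 100.0

    def test_scale_invariance(self):
        traits = gd.TraitTable({"Mus": 30.0, "Turdus": 20.0})
        d1 = make_site_diet({"Mus": 10}, extra_classes={"bird": 10},
                            extra_genus_counts={"bird": {"Turdus": 10}})
        d2 = make_site_diet({"Mus": 20}, extra_classes={"bird": 20},
                            extra_genus_counts={"bird": {"Turdus": 20}})
        assert gd.biomass_share(d1, traits) == gd.biomass_share(d2, traits)


class TestBirdsVariant:
    def test_no_birds_identity(self):
        d = make_site_diet({"A": 3, "B": 1})
        h, j = gd.metrics_with_birds_variant(d)
        v = gd.genus_proportions({"A": 3, "B": 1})
        assert h == gd.shannon_H(v) and j == gd.evenness_J(v)

    def test_even_split_gives_ln2(self):
        d = make_site_diet({"A": 50}, extra_classes={"bird": 50})
        h, j = gd.metrics_with_birds_variant(d)
        assert h == pytest.approx(np.log(2), abs=1e-12)
        assert j == pytest.approx(1.0, abs=1e-12)

    def test_bird_pool_increases_richness(self):
        d = make_site_diet({"A": 30, "B": 20}, extra_classes={"bird": 10})
        h, _ = gd.metrics_with_birds_variant(d)
        base = gd.shannon_H(gd.genus_proportions({"A": 30, "B": 20}))
        assert h > base


class TestCorrHB:
    def test_H_and_B_positively_correlated_across_sites(self, sim_metrics):
        _, _, mt = sim_metrics
        r = np.corrcoef(mt["H"], mt["B"])[0, 1]
        # brute-force covariance oracle
        h, b = mt["H"].to_numpy(), mt["B"].to_numpy()
        cov = np.mean((h - h.mean()) * (b - b.mean()))
        r_oracle = cov / (h.std() * b.std())
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert r > 0


class TestHypothesisInvariants:
    """Property-based invariants over arbitrary diet compositions."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    counts_strategy = st.lists(st.integers(1, 10**6), min_size=2, max_size=30)

    @given(counts_strategy)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_entropy_bounds(self, raw):
        counts = {f"G{i:03d}": c for i, c in enumerate(raw)}
        v = gd.genus_proportions(counts)
        H = gd.shannon_H(v)
        assert -1e-12 <= H <= np.log(v.G) + 1e-12
        assert np.log(gd.levins_B(v)) <= H + 1e-12
        assert 1.0 - 1e-12 <= gd.levins_B(v) <= v.G + 1e-9

    @given(counts_strategy, st.integers(2, 1000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rescaling_counts_leaves_H_and_B(self, raw, c):
        counts = {f"G{i:03d}": n for i, n in enumerate(raw)}
        scaled = {g: c * n for g, n in counts.items()}
        v0, v1 = gd.genus_proportions(counts), gd.genus_proportions(scaled)
        assert gd.shannon_H(v0) == pytest.approx(gd.shannon_H(v1), abs=1e-11)
        assert gd.levins_B(v0) == pytest.approx(gd.levins_B(v1), rel=1e-11)
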
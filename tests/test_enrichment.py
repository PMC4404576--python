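"""The randomization statistic, scaling correction, BH adjustment and cutoffs."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mbison as mb
from mbison.enrichment import (
    EnrichmentConfig,
    bh_adjust,
    count_targets,
    min_target_threshold,
    null_counts,
    randomization_pvalues,
    sample_random_set,
)


def exact_pvalues(observed, background, n):
    """Independent oracle: enumerate all n-subsets with the scaled->= rule."""
    universe = sorted(background.gene_universe)
    counts = {f: 0 for f in background.families}
    total = 0
    for sub in itertools.combinations(universe, n):
        zc = count_targets(frozenset(sub), background)
        for f in background.families:
            if zc.t_set == 0:
                ok = observed.m[f] == 0
            else:
                ok = zc.m[f] * observed.t_set >= observed.m[f] * zc.t_set
            counts[f] += ok
        total += 1
    return {f: counts[f] / total for f in background.families}


class TestCountTargets:
    def test_direct_count(self):
        bgr = mb.Background.from_pairs([("miR-1", 1), ("miR-1", 2), ("miR-2", 1)])
        obs = count_targets(frozenset({1}), bgr)
        assert obs.m == {"miR-1": 1, "miR-2": 1}
        assert obs.t_set == 2

    def test_full_universe_saturates_to_per_family_count(self, toy_background):
        obs = count_targets(toy_background.gene_universe, toy_background)
        assert obs.m == toy_background.per_family_count

    def test_random_subset_matches_membership_oracle(self, study_background):
        rng = np.random.default_rng(5)
        universe = sorted(study_background.gene_universe)
        sub = frozenset(universe[i] for i in rng.choice(len(universe), 15, replace=False))
        obs = count_targets(sub, study_background)
        for f in study_background.families:
            assert obs.m[f] == sum((f, g) in study_background.pairs for g in sub)


class TestSampleRandomSet:
    def test_exhaustive_draw_returns_universe(self, toy_background):
        rng = np.random.default_rng(0)
        got = sample_random_set(toy_background, len(toy_background.gene_universe), rng)
        assert got == toy_background.gene_universe

    def test_zero_draw_is_empty(self, toy_background):
        assert sample_random_set(toy_background, 0, np.random.default_rng(0)) == frozenset()

    def test_overdraw_is_an_error(self, toy_background):
        with pytest.raises(ValueError):
            sample_random_set(toy_background, 9, np.random.default_rng(0))

    def test_inclusion_frequencies_are_uniform(self):
        bgr = mb.Background.from_pairs([("miR-1", g) for g in range(1, 7)])
        rng = np.random.default_rng(2)
        n_draws, n = 10_000, 3
        freq = {g: 0 for g in range(1, 7)}
        for _ in range(n_draws):
            for g in sample_random_set(bgr, n, rng):
                freq[g] += 1
        p = n / 6
        se = (p * (1 - p) / n_draws) ** 0.5
        for g, c in freq.items():
            assert abs(c / n_draws - p) <= 3 * se, (g, c)


class TestNullCounts:
    def test_ratio_and_scaled_counts(self, toy_background):
        obs = count_targets(frozenset({1, 2, 3, 4}), toy_background)  # T_set = 7
        nc = null_counts(obs, toy_background, frozenset({5, 6}))
        # z: miR-A hits 5, miR-C hits 6 -> T_rand = 2, ratio = 3.5
        assert nc.z == {"miR-A": 1, "miR-B": 0, "miR-C": 1}
        assert nc.t_rand == 2
        assert nc.ratio == pytest.approx(3.5)
        assert nc.z_scaled["miR-A"] == pytest.approx(3.5)

    def test_empty_random_set_defines_zero_ratio(self, toy_background):
        obs = count_targets(frozenset({1, 2, 3, 4}), toy_background)
        nc = null_counts(obs, toy_background, frozenset())
        assert nc.t_rand == 0 and nc.ratio == 0.0
        assert all(v == 0.0 for v in nc.z_scaled.values())


class TestRandomizationPvalues:
    def test_zero_observed_gives_p_one(self, toy_background):
        obs = count_targets(frozenset(), toy_background)
        # an all-zero observation is never exceeded-from-below
        p = randomization_pvalues(obs, toy_background, 4, EnrichmentConfig(n_reps=200, seed=1))
        assert all(v == 1.0 for v in p.values())

    def test_converges_to_exact_enumeration(self, toy_background):
        obs = count_targets(frozenset({1, 2, 3, 4}), toy_background)
        exact = exact_pvalues(obs, toy_background, 4)
        reps = 20_000
        p = randomization_pvalues(obs, toy_background, 4, EnrichmentConfig(n_reps=reps, seed=13))
        for f in toy_background.families:
            se = (exact[f] * (1 - exact[f]) / reps) ** 0.5
            assert abs(p[f] - exact[f]) <= max(3 * se, 3 / (reps + 1)), f

    def test_add_one_estimator_keeps_p_positive(self, study_background):
        genes, _ = mb.generate_enriched_geneset(study_background, "miR-1", 30, 1.0, seed=0)
        obs = count_targets(frozenset(genes), study_background)
        p = randomization_pvalues(obs, study_background, 30, EnrichmentConfig(n_reps=1000, seed=0))
        assert all(0 < v <= 1 for v in p.values())
        assert min(p.values()) >= 1 / 1001

    def test_deterministic_given_seed(self, toy_background):
        obs = count_targets(frozenset({1, 2, 3, 4}), toy_background)
        cfg = EnrichmentConfig(n_reps=500, seed=99)
        assert randomization_pvalues(obs, toy_background, 4, cfg) == \
            randomization_pvalues(obs, toy_background, 4, cfg)

    def test_uncorrected_variant_differs_on_biased_input(self, biased_study):
        bgr, long_genes = biased_study
        obs = count_targets(frozenset(long_genes[:30]), bgr)
        cfg = EnrichmentConfig(n_reps=1000, seed=5)
        pc = randomization_pvalues(obs, bgr, 30, cfg, correction=True)
        pu = randomization_pvalues(obs, bgr, 30, cfg, correction=False)
        # the uncorrected test sees inflated counts everywhere, so its p-values sit lower
        assert np.median(list(pu.values())) < np.median(list(pc.values()))


class TestBhAdjust:
    def test_single_value_identity(self):
        assert bh_adjust({"f": 0.03}) == {"f": 0.03}

    def test_hand_computed_step_up(self):
        p = {"a": 0.01, "b": 0.02, "c": 0.03, "d": 0.04}
        # min over j>=i of p_(j) * m / j: all reduce to 0.04
        assert bh_adjust(p) == pytest.approx({"a": 0.04, "b": 0.04, "c": 0.04, "d": 0.04})

    def test_permutation_invariance(self):
        p = {"a": 0.4, "b": 0.01, "c": 0.2, "d": 0.03, "e": 1.0}
        fwd = bh_adjust(p)
        rev = bh_adjust(dict(reversed(list(p.items()))))
        assert fwd == rev

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40))
    def test_matches_independent_step_up_oracle(self, raw):
        p = {f"f{i}": v for i, v in enumerate(raw)}
        got = bh_adjust(p)
        # independent closed form: sort, p_(i) * m / i, cumulative min from the top
        fams = sorted(p, key=p.get)
        m = len(fams)
        adj = [min(p[f] * m / (i + 1), 1.0) for i, f in enumerate(fams)]
        for i in range(m - 2, -1, -1):
            adj[i] = min(adj[i], adj[i + 1])
        for f, a in zip(fams, adj):
            assert got[f] == pytest.approx(a)


class TestCutoffs:
    def _results(self, rows, cfg, n):
        import pandas as pd
        df = pd.DataFrame(rows, columns=["family_id", "m_a", "target_pct", "p_raw", "fdr",
                                         "over_represented"])
        return mb.apply_cutoffs(df, cfg, n)

    def test_fdr_boundary_is_inclusive(self):
        cfg = EnrichmentConfig(fdr_cutoff=0.05)
        out = self._results([("a", 5, 25.0, 0.01, 0.05, True)], cfg, 20)
        assert list(out["family_id"]) == ["a"]

    def test_min_target_ceiling_arithmetic(self):
        cfg = EnrichmentConfig(fdr_cutoff=0.05, min_target_pct=10)
        rows = [("a", 9, 9.0, 0.001, 0.01, True), ("b", 10, 10.0, 0.001, 0.01, True)]
        out = self._results(rows, cfg, 100)
        assert list(out["family_id"]) == ["b"]

    def test_zero_percentage_reduces_to_fdr_filter(self):
        cfg = EnrichmentConfig(fdr_cutoff=0.05, min_target_pct=0)
        rows = [("a", 1, 5.0, 0.001, 0.01, True), ("b", 3, 15.0, 0.5, 0.8, False)]
        out = self._results(rows, cfg, 20)
        assert list(out["family_id"]) == ["a"]

    def test_threshold_guard_against_float_noise(self):
        assert min_target_threshold(10, 100) == 10
        assert min_target_threshold(10.5, 100) == 11
        assert min_target_threshold(0, 50) == 0


class TestEnrich:
    def test_spiked_family_ranks_first(self, study_background):
        genes, manifest = mb.generate_enriched_geneset(study_background, "miR-7", 30, 1.0, seed=21)
        gs = mb.restrict_to_background(genes, study_background)
        df = mb.enrich(gs, study_background, EnrichmentConfig(n_reps=2000, seed=21))
        assert df.iloc[0]["family_id"] == "miR-7"
        assert df.iloc[0]["m_a"] == manifest["planted_m_target"]
        assert df.iloc[0]["fdr"] <= 0.05

    def test_table_is_sorted_and_complete(self, study_background):
        genes, _ = mb.generate_enriched_geneset(study_background, "miR-3", 25, 0.5, seed=2)
        gs = mb.restrict_to_background(genes, study_background)
        df = mb.enrich(gs, study_background, EnrichmentConfig(n_reps=500, seed=2))
        assert set(df["family_id"]) == set(study_background.families)
        assert list(df["fdr"]) == sorted(df["fdr"])
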
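"""Synthetic study generator: design arithmetic, mixtures, hit tables, traits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import microclade as mc
from microclade.labels import MAIN_CLADES, N_CLADES
from microclade.simulate import IDENTITY_GRID


class TestBuildDesign:
    def test_full_experiment_arithmetic(self, full_design):
        assert full_design.total_deployed == 300
        assert full_design.collected_per_timepoint == 100
        assert full_design.transplant_samples("T3") == 99
        assert full_design.transplant_samples("T1") == 100

    def test_identity_case(self):
        d = mc.build_design(1, 1, 1, 1)
        assert d.total_deployed == 1

    def test_invalid_missing_slot_is_descriptive(self):
        with pytest.raises(ValueError, match="timepoint 'T9'"):
            mc.build_design(missing_slots=[("desert", "desert", "T9", "r1")])
        with pytest.raises(ValueError, match="site 'moon'"):
            mc.build_design(missing_slots=[("moon", "desert", "T1", "r1")])

    @given(
        s=st.integers(1, 6),
        i=st.integers(1, 6),
        r=st.integers(1, 5),
        t=st.integers(1, 4),
    )
    def test_deployed_equals_product(self, s, i, r, t):
        assert mc.build_design(s, i, r, t).total_deployed == s * i * r * t

    def test_metadata_counts_missing_slot(self, full_design):
        md = full_design.metadata("T3")
        assert (md["type"] == "transplant").sum() == 99
        assert (md["type"] == "survey").sum() == 20
        assert "T3-grassland-desert-r1" not in md.index


class TestCladeMixtures:
    def test_rows_on_simplex(self, full_design):
        params = mc.ScenarioParams(scenario="climate", seed=3)
        mix = mc.simulate_clade_mixtures(full_design, params)
        assert list(mix.columns) == list(MAIN_CLADES)
        assert np.allclose(mix.sum(axis=1), 1.0)
        assert (mix.to_numpy() >= 0).all()

    def test_null_scenario_uniform_mean(self):
        """Symmetric concentrations: mean proportions near 1/12 (3 SE)."""
        d = mc.build_design(n_sites=5, n_inocula=5, n_replicates=40, n_timepoints=1)
        params = mc.ScenarioParams(scenario="null", seed=11)
        mix = mc.simulate_clade_mixtures(d, params, "T1")
        n = len(mix)
        assert n >= 1000
        # Dirichlet(1,...,1): mean 1/12, var = p(1-p)/(sum_alpha+1)
        p = 1.0 / N_CLADES
        se = np.sqrt(p * (1 - p) / (N_CLADES + 1) / n)
        assert np.abs(mix.mean(axis=0) - p).max() < 3 * se

    def test_dominant_concentration_dominates_site_mean(self):
        """alpha_1 = 100x others at one site -> clade 1 mean largest there."""
        d = mc.build_design(n_sites=2, n_inocula=2, n_replicates=100, n_timepoints=1)
        alpha = {s: np.ones(N_CLADES) for s in d.sites}
        alpha[d.sites[0]] = np.concatenate([[100.0], np.ones(N_CLADES - 1)])
        params = mc.ScenarioParams(scenario="climate", clade_means=alpha, seed=2)
        mix = mc.simulate_clade_mixtures(d, params, "T1")
        md = d.metadata("T1")
        site0 = mix.loc[md.index[md["site"] == d.sites[0]]]
        assert len(site0) >= 200
        means = site0.mean(axis=0)
        assert means["1"] == means.max() and means["1"] > 0.5

    def test_fixed_seed_reproducible_and_order_free(self, full_design):
        params = mc.ScenarioParams(scenario="substrate", seed=9)
        a = mc.simulate_clade_mixtures(full_design, params)
        b = mc.simulate_clade_mixtures(full_design, params)
        pd.testing.assert_frame_equal(a, b)
        # adding samples must not reshuffle existing ones
        bigger = mc.build_design(n_replicates=5)
        c = mc.simulate_clade_mixtures(bigger, params)
        pd.testing.assert_frame_equal(a, c.loc[a.index])

    def test_missing_condition_names_sample(self, full_design):
        params = mc.ScenarioParams(
            scenario="climate",
            clade_means={"desert": np.ones(N_CLADES)},
        )
        with pytest.raises(KeyError, match="scrubland"):
            mc.simulate_clade_mixtures(full_design, params)


class TestHitTables:
    def test_unambiguous_reads_recover_their_clade(self, marker_db):
        mix = np.full(N_CLADES, 1.0 / N_CLADES)
        params = mc.ScenarioParams(
            scenario="null", reads_per_sample=80, ambiguity_rate=0.0,
            decoy_fraction=0.0, seed=21,
        )
        hits, truth = mc.simulate_sample_hits("s", mix, marker_db, params)
        counts, diag = mc.classify_samples({"s": hits}, annotations=marker_db)
        expected = truth["true_label"].value_counts()
        for label, n in expected.items():
            assert counts.loc["s", label] == n
        assert diag.loc["s", "n_discarded"] == 0

    def test_forced_tie_set_yields_one_pseudo_clade(self, marker_db):
        mix = np.concatenate([[1.0], np.zeros(N_CLADES - 1)])
        params = mc.ScenarioParams(
            scenario="null", reads_per_sample=40, ambiguity_rate=1.0,
            decoy_fraction=0.0, forced_tie_set=(1, 2), seed=5,
        )
        hits, truth = mc.simulate_sample_hits("s", mix, marker_db, params)
        counts, _ = mc.classify_samples({"s": hits}, annotations=marker_db)
        assert counts.loc["s", "1-2"] == 40
        assert (truth["true_label"] == "1-2").all()

    def test_zero_reads_empty_table(self, marker_db):
        params = mc.ScenarioParams(scenario="null", reads_per_sample=0, seed=1)
        hits, truth = mc.simulate_sample_hits(
            "s", np.full(N_CLADES, 1 / N_CLADES), marker_db, params
        )
        assert len(hits) == 0 and len(truth) == 0

    def test_decoys_are_filtered_out(self, marker_db):
        mix = np.full(N_CLADES, 1.0 / N_CLADES)
        params = mc.ScenarioParams(
            scenario="null", reads_per_sample=100, ambiguity_rate=0.0,
            decoy_fraction=1.0, seed=8,
        )
        hits, truth = mc.simulate_sample_hits("s", mix, marker_db, params)
        assert (truth["true_label"] == "discarded").all()
        counts, diag = mc.classify_samples({"s": hits}, annotations=marker_db)
        assert counts.loc["s"].sum() == 0
        assert diag.loc["s", "n_discarded"] == diag.loc["s", "n_queries"]

    def test_identities_on_grid(self, marker_db):
        params = mc.ScenarioParams(scenario="null", reads_per_sample=50, seed=13)
        hits, _ = mc.simulate_sample_hits(
            "s", np.full(N_CLADES, 1 / N_CLADES), marker_db, params
        )
        passing = hits[(hits["evalue"] < 1e-20) & (hits["pct_identity"] >= 98.0)]
        assert set(passing["pct_identity"]).issubset(set(IDENTITY_GRID))


class TestTraitMatrix:
    def test_rows_sum_to_one(self):
        t = mc.simulate_trait_matrix(seed=4)
        assert t.shape == (12, 8)
        assert np.abs(t.sum(axis=1) - 1.0).max() < 1e-12

    def test_reproducible(self):
        pd.testing.assert_frame_equal(
            mc.simulate_trait_matrix(seed=4), mc.simulate_trait_matrix(seed=4)
        )

    def test_uniform_option(self):
        t = mc.simulate_trait_matrix(uniform=True)
        assert np.allclose(t.to_numpy(), 1.0 / 8)

    def test_category_count_is_fixed(self):
        with pytest.raises(ValueError):
            mc.simulate_trait_matrix(n_traits=7)
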
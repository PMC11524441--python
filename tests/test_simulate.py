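"""Synthetic data generators: determinism, limits, null calibration, planting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oasig import (
    SimConfig,
    SimConfigError,
    benjamini_hochberg,
    generate_annotation_and_targets,
    generate_compendium,
    generate_linked_de_tables,
)

from oracles import bh_oracle

SMALL = dict(n_genes=400, n_datasets=30, n_related=3)


class TestSimConfig:
    def test_seed_out_of_range_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(seed=2**31)
        with pytest.raises(SimConfigError):
            SimConfig(seed=-1)

    def test_mixing_outside_unit_interval_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(seed=0, mixing=1.5)

    def test_nonpositive_target_rho_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(seed=0, target_rho=0.0)
        with pytest.raises(SimConfigError):
            SimConfig(seed=0, target_rho=-0.5)

    def test_related_must_be_minority(self):
        with pytest.raises(SimConfigError):
            SimConfig(seed=0, n_datasets=5, n_related=5)

    def test_invalid_dropout_range_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(seed=0, dropout=(0.5, 0.2))

    def test_discordance_with_identical_tables_rejected(self):
        cfg = SimConfig(seed=0, n_genes=200, target_rho=1.0, discordance=0.1)
        with pytest.raises(SimConfigError):
            generate_linked_de_tables(cfg)


class TestBenjaminiHochberg:
    def test_single_pvalue_unchanged(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_textbook_example(self):
        adj = benjamini_hochberg([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(adj, bh_oracle([0.01, 0.04, 0.03, 0.005]), atol=1e-15)

    @given(ps=st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=100))
    @settings(max_examples=100, deadline=None)
    def test_matches_literal_step_up_oracle(self, ps):
        np.testing.assert_allclose(benjamini_hochberg(ps), bh_oracle(ps), atol=1e-12)


class TestCompendiumGenerator:
    def test_deterministic_for_a_seed(self):
        a = generate_compendium(SimConfig(seed=7, **SMALL))
        b = generate_compendium(SimConfig(seed=7, **SMALL))
        assert a[2] == b[2]
        pd.testing.assert_series_equal(a[1].values, b[1].values)
        for ds in a[0].profiles:
            pd.testing.assert_series_equal(a[0].profiles[ds].values, b[0].profiles[ds].values)

    def test_different_seeds_differ(self):
        a = generate_compendium(SimConfig(seed=7, **SMALL))
        b = generate_compendium(SimConfig(seed=8, **SMALL))
        assert not a[1].values.equals(b[1].values)

    def test_shapes_and_metadata(self):
        comp, query, related = generate_compendium(SimConfig(seed=3, **SMALL))
        assert len(comp.profiles) == 30
        assert len(related) == 3
        assert len(query.values) == 400
        assert set(comp.metadata.loc[related, "model"]) == {"planted"}
        assert (comp.metadata["model"] == "planted").sum() == 3

    def test_dropout_removes_genes_within_range(self):
        cfg = SimConfig(seed=1, n_genes=2000, n_datasets=20, n_related=2,
                        dropout=(0.10, 0.20))
        comp, _, _ = generate_compendium(cfg)
        rates = [1 - len(p.values) / 2000 for p in comp.profiles.values()]
        assert all(0.05 < r < 0.27 for r in rates)  # binomial spread around U(0.1, 0.2)

    def test_no_dropout_keeps_every_gene(self):
        cfg = SimConfig(seed=1, dropout=(0.0, 0.0), **SMALL)
        comp, _, _ = generate_compendium(cfg)
        assert all(len(p.values) == 400 for p in comp.profiles.values())

    def test_zero_mixing_decouples_query_from_planted(self):
        # with no shared signature all datasets are exchangeable noise
        cfg = SimConfig(seed=4, n_genes=1000, n_datasets=50, n_related=5,
                        mixing=0.0, dropout=(0.0, 0.0))
        comp, query, related = generate_compendium(cfg)
        q = query.values.to_numpy()
        cors = [float(np.corrcoef(q, comp.profiles[ds].values.to_numpy())[0, 1])
                for ds in related]
        assert max(abs(c) for c in cors) < 4 / np.sqrt(1000)

    def test_full_mixing_zero_noise_gives_exact_copies(self):
        cfg = SimConfig(seed=9, mixing=1.0, noise_sd=0.0, dropout=(0.0, 0.0), **SMALL)
        comp, query, related = generate_compendium(cfg)
        for ds in related:
            np.testing.assert_array_equal(
                comp.profiles[ds].values.to_numpy(), query.values.to_numpy()
            )


class TestLinkedDETables:
    def test_deterministic_for_a_seed(self):
        cfg = SimConfig(seed=21, n_genes=1000)
        a1, b1, t1 = generate_linked_de_tables(cfg)
        a2, b2, t2 = generate_linked_de_tables(cfg)
        pd.testing.assert_frame_equal(a1.frame, a2.frame)
        pd.testing.assert_frame_equal(b1.frame, b2.frame)
        assert t1["de_genes"] == t2["de_genes"]
        assert t1["decorrelation"] == t2["decorrelation"]

    def test_truth_matches_table_structure(self):
        cfg = SimConfig(seed=22, n_genes=1000)
        ta, tb, truth = generate_linked_de_tables(cfg)
        assert len(ta) == len(tb) == 1000
        assert len(truth["de_genes"]) == round(0.15 * 1000)
        assert truth["target_rho"] == 0.8
        assert truth["decorrelation"] > 0
        # non-DE genes carry pure measurement noise: no huge effects
        non_de = ~ta.frame["gene"].isin(truth["de_genes"])
        assert ta.frame.loc[non_de, "log2fc"].abs().max() < 0.25 * 6

    def test_pure_null_tables_have_uniform_pvalues(self):
        cfg = SimConfig(seed=23, n_genes=5000, frac_de=0.0)
        ta, tb, truth = generate_linked_de_tables(cfg)
        assert truth["de_genes"] == set()
        from scipy import stats

        assert stats.kstest(ta.frame["pvalue"], "uniform").pvalue > 0.01

    def test_global_null_rejection_rate_matches_alpha(self):
        """Under the global null BH rejects anything with prob. exactly alpha.

        The study's replication claim is that a pure-noise pair of tables
        yields no shared significant genes in the vast majority of runs.
        Per table, P(any rejection) = alpha = 0.05 exactly (Simes
        identity), so over 200 seeds the count of runs where table A
        rejects anything is Binomial(200, 0.05); we assert within 3 sigma
        of the mean.  Genes jointly significant in both independent null
        tables are rarer still, so the shared set must be empty in
        essentially every run.
        """
        nonempty_a = 0
        nonempty_shared = 0
        for seed in range(200):
            cfg = SimConfig(seed=seed, n_genes=800, frac_de=0.0)
            ta, tb, _ = generate_linked_de_tables(cfg)
            nonempty_a += int((ta.frame["fdr"] < 0.05).any())
            shared = ((ta.frame["fdr"] < 0.05) & (tb.frame["fdr"] < 0.05)).sum()
            nonempty_shared += int(shared > 0)
        mean, sd = 200 * 0.05, np.sqrt(200 * 0.05 * 0.95)
        assert abs(nonempty_a - mean) <= 3 * sd
        assert nonempty_shared <= 2  # joint null rejections are vanishingly rare

    def test_flip_planting_recorded_in_truth(self):
        cfg = SimConfig(seed=24, n_genes=2000, discordance=0.02)
        ta, tb, truth = generate_linked_de_tables(cfg)
        assert truth["expected_discordance"] == 0.02
        # flipped genes have their table-B effect negated exactly
        flips = sorted(truth["flip_genes"])[:20]
        if flips:
            a = ta.frame.set_index("gene").loc[flips, "log2fc"]
            b = tb.frame.set_index("gene").loc[flips, "log2fc"]
            # sign structure differs on flipped DE genes with big effects
            big = a.abs() > 1.0
            assert (np.sign(a[big]) == -np.sign(b[big])).all()

    def test_infeasible_discordance_rejected(self):
        cfg = SimConfig(seed=25, n_genes=500, discordance=0.9)
        with pytest.raises(SimConfigError):
            generate_linked_de_tables(cfg)


class TestAnnotationAndTargets:
    @staticmethod
    def _sets(n_bg=3000, n_up=450, n_down=450, seed=0):
        genes = [f"G{i:05d}" for i in range(n_bg)]
        rng = np.random.default_rng(seed)
        chosen = rng.choice(n_bg, size=n_up + n_down, replace=False)
        up = {genes[i] for i in chosen[:n_up]}
        down = {genes[i] for i in chosen[n_up:]}
        return up, down, set(genes)

    def test_counts_and_labels(self):
        up, down, bg = self._sets()
        cfg = SimConfig(seed=31, n_genes=3000)
        ann, targets, truth = generate_annotation_and_targets(cfg, up, down, bg)
        labels = list(ann.entries.values())
        assert labels.count("Protective") == 217
        assert labels.count("Detrimental") == 199
        assert labels.count("Ambiguous") == 60
        assert len(targets) == 500
        assert truth["background_up_fraction"] == pytest.approx(450 / 3000)

    def test_truth_counts_match_realized_overlaps(self):
        up, down, bg = self._sets()
        cfg = SimConfig(seed=32, n_genes=3000)
        ann, targets, truth = generate_annotation_and_targets(cfg, up, down, bg)
        prot = ann.genes_with("Protective")
        det = ann.genes_with("Detrimental")
        assert len(prot & up) == truth["protective_up"]
        assert len(det & up) == truth["detrimental_up"]
        assert len(targets.genes & up) == truth["targets_up"]

    def test_planting_inflates_protective_up_fraction(self):
        up, down, bg = self._sets()
        cfg = SimConfig(seed=33, n_genes=3000, annotation_odds_ratio=6.0)
        ann, _, truth = generate_annotation_and_targets(cfg, up, down, bg)
        f = truth["background_up_fraction"]
        assert truth["protective_up"] / 217 > f  # well above background rate
        # detrimental stays near background: binomial(199, f) 4-sigma bound
        sd = np.sqrt(199 * f * (1 - f))
        assert abs(truth["detrimental_up"] - 199 * f) < 4 * sd

    def test_annotation_larger_than_background_rejected(self):
        up, down, bg = self._sets(n_bg=300, n_up=50, n_down=50)
        cfg = SimConfig(seed=34, n_genes=300)
        with pytest.raises(SimConfigError):
            generate_annotation_and_targets(cfg, up, down, bg)

    def test_background_without_up_genes_rejected(self):
        cfg = SimConfig(seed=35, n_genes=100)
        bg = {f"G{i}" for i in range(100)}
        with pytest.raises(SimConfigError):
            generate_annotation_and_targets(cfg, set(), {"G1"}, bg)

    def test_deterministic_for_a_seed(self):
        up, down, bg = self._sets()
        cfg = SimConfig(seed=36, n_genes=3000)
        a1 = generate_annotation_and_targets(cfg, up, down, bg)
        a2 = generate_annotation_and_targets(cfg, up, down, bg)
        assert a1[0].entries == a2[0].entries
        assert a1[1].genes == a2[1].genes
        assert a1[2] == a2[2]
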
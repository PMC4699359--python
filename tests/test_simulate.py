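import numpy as np
import pandas as pd
import pytest

from stressclock import simulate as sim
from stressclock.clock import predict_dnam_age, transform_age
from stressclock.dex import direction_summary, paired_lrt
from stressclock.enrichment import permutation_enrichment
from stressclock.errors import ValidationError


class TestToyClock:
    def test_score_identity(self, toy, small_config):
        """intercept + w . beta(a) equals the transformed age by construction."""
        for age in (5.0, 20.0, 45.0, 70.0):
            t = transform_age(age, small_config.adult_age)
            betas = toy.probes["mean"] + toy.probes["loading"] * t
            score = toy.model.intercept + float(toy.model.weights @ betas)
            assert score == pytest.approx(t, abs=1e-10)

    def test_weights_match_hand_inversion(self):
        cfg = sim.SimulationConfig(n_clock_probes=2, n_background_probes=2)
        toy = sim.generate_toy_clock(cfg, seed=3)
        l = toy.probes["loading"].to_numpy()
        np.testing.assert_allclose(toy.model.weights.to_numpy(), l / (l @ l), atol=1e-12)

    def test_same_seed_identical(self, small_config):
        t1 = sim.generate_toy_clock(small_config, seed=9)
        t2 = sim.generate_toy_clock(small_config, seed=9)
        pd.testing.assert_frame_equal(t1.probes, t2.probes)
        assert t1.model.intercept == t2.model.intercept

    def test_infeasible_loading_scale_rejected(self, small_config, monkeypatch):
        # force means near 1 with positive loadings so betas must exit [0, 1]
        class FakeRng:
            def uniform(self, low, high, size=None):
                return np.full(size, 0.98 if high == 0.7 else 0.08)

            def choice(self, opts, size=None):
                return np.full(size, 1.0)

        monkeypatch.setattr(sim, "_rng", lambda seed: FakeRng())
        with pytest.raises(ValidationError, match="infeasible"):
            sim.generate_toy_clock(small_config, seed=0)


class TestCohort:
    def test_deterministic_given_seed(self, toy, small_config):
        m1, p1, t1 = sim.generate_cohort(toy, small_config, seed=21)
        m2, p2, t2 = sim.generate_cohort(toy, small_config, seed=21)
        pd.testing.assert_frame_equal(m1.betas, m2.betas)
        pd.testing.assert_frame_equal(p1.frame, p2.frame)

    def test_noiseless_perfect_age_correlation(self, toy):
        cfg = sim.SimulationConfig(
            n_samples=50, n_clock_probes=10, n_background_probes=10,
            beta_noise_sd=0.0, gamma_stress=0.0,
        )
        m, pheno, _ = sim.generate_cohort(toy, cfg, seed=4)
        pred = predict_dnam_age(m, toy.model, pheno)
        r = np.corrcoef(pred["dnam_age"], pheno.frame["age"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_ground_truth_round_trip(self, toy, small_config, tmp_path):
        _, _, truth = sim.generate_cohort(toy, small_config, seed=5)
        truth.save(tmp_path / "t.json")
        back = sim.GroundTruth.load(tmp_path / "t.json")
        assert back["gamma_stress"] == truth["gamma_stress"]
        np.testing.assert_allclose(back["ages"], truth["ages"])

    def test_output_passes_reader_validation(self, toy, small_config, tmp_path):
        from stressclock import io

        m, pheno, _ = sim.generate_cohort(toy, small_config, seed=6)
        io.write_beta_matrix(m, tmp_path / "b.tsv")
        io.write_phenotypes(pheno, tmp_path / "p.tsv")
        back = io.read_beta_matrix(tmp_path / "b.tsv")
        assert back.n_samples == m.n_samples
        assert io.read_phenotypes(tmp_path / "p.tsv").sample_ids == pheno.sample_ids


class TestDexPair:
    def test_all_down_mix_recovers_negative_effects(self, toy, small_config):
        cfg = sim.SimulationConfig(
            n_samples=40, n_clock_probes=10, n_background_probes=10,
            dex_down_frac=1.0, frac_dex_affected=0.5,
            dex_effect_size=0.1, dex_noise_sd=0.01,
        )
        m, _, _ = sim.generate_cohort(toy, cfg, seed=7)
        base = m.select_probes(toy.model.probe_ids)
        post, design, truth = sim.generate_dex_pair(base, cfg, seed=8)
        res = paired_lrt(pd.concat([base.betas, post.betas]), design)
        sig = res[res["q"] < 0.05]
        assert len(sig) > 0
        assert (sig["effect"] < 0).all()

    def test_directions_match_truth(self, toy):
        cfg = sim.SimulationConfig(
            n_samples=60, n_clock_probes=10, n_background_probes=10,
            frac_dex_affected=0.5, dex_effect_size=0.1, dex_noise_sd=0.01,
        )
        m, _, _ = sim.generate_cohort(toy, cfg, seed=9)
        base = m.select_probes(toy.model.probe_ids)
        post, design, truth = sim.generate_dex_pair(base, cfg, seed=10)
        res = paired_lrt(pd.concat([base.betas, post.betas]), design)
        effect = np.asarray(truth["effect"])
        affected = np.asarray(truth["affected"])
        called = res["q"].to_numpy() < 0.05
        # every planted probe recovered with the planted sign
        assert called[affected].all()
        assert (np.sign(res["effect"].to_numpy()[affected]) == np.sign(effect[affected])).all()


class TestPeaks:
    def test_zero_background_rate_gives_degenerate_null(self, manifest, small_config, toy):
        cfg = sim.SimulationConfig(
            n_samples=10, n_clock_probes=10, n_background_probes=200,
            enrich_frac_query=0.8, enrich_frac_background=0.0,
        )
        peaks, truth = sim.generate_peaks(
            manifest, cfg, query_probes=toy.model.probe_ids, seed=11
        )
        background = [p for p in manifest.probe_ids if p not in set(toy.model.probe_ids)]
        with pytest.warns(UserWarning, match="not in background"):
            res = permutation_enrichment(
                toy.model.probe_ids, background, manifest, peaks, n_perm=200, seed=12
            )
        assert res.null_mean == 0.0
        assert res.null_sd == 0.0

    def test_membership_truth_is_consistent(self, manifest, small_config, toy):
        peaks, truth = sim.generate_peaks(
            manifest, small_config, query_probes=toy.model.probe_ids, seed=13
        )
        from stressclock.enrichment import count_overlap

        actual = np.asarray(truth["actual_member"])
        assert count_overlap(manifest.probe_ids, manifest, peaks) == actual.sum()


class TestExpression:
    @staticmethod
    def _links_and_design(n_genes=40, n_subj=30):
        links = pd.DataFrame(
            {"probe_id": "cgX", "gene": [f"G{i}" for i in range(n_genes)], "distance_bp": 100}
        )
        from stressclock.dex import PairedDesign

        design = PairedDesign(
            pd.DataFrame(
                {
                    "baseline_sample": [f"b{i}" for i in range(n_subj)],
                    "post_sample": [f"p{i}" for i in range(n_subj)],
                },
                index=pd.Index([f"u{i}" for i in range(n_subj)], name="subject_id"),
            )
        )
        return links, design

    def test_silent_fraction_filtered(self):
        from stressclock.dex import filter_expressed

        links, design = self._links_and_design(n_genes=200)
        cfg = sim.SimulationConfig(expr_silent_frac=0.5)
        expr, det, truth = sim.generate_expression(links, design, cfg, seed=14)
        kept = filter_expressed(expr, det, 0.05, 0.5)
        n_silent = int(np.asarray(truth["silent"]).sum())
        assert kept.shape[1] == 200 - n_silent
        assert abs(n_silent / 200 - 0.5) < 0.15

    def test_strong_shifts_fully_recovered(self):
        links, design = self._links_and_design(n_genes=50, n_subj=40)
        cfg = sim.SimulationConfig(
            expr_effect_size=3.0, expr_noise_sd=0.3, expr_silent_frac=0.0,
            expr_frac_regulated=0.5,
        )
        expr, det, truth = sim.generate_expression(links, design, cfg, seed=15)
        res = paired_lrt(expr, design)
        shift = np.asarray(truth["shift"])
        regulated = np.asarray(truth["regulated"])
        called = res["q"].to_numpy() < 0.05
        assert called[regulated].all()
        assert (
            np.sign(res["effect"].to_numpy()[regulated]) == np.sign(shift[regulated])
        ).all()

    def test_no_shift_calibrated(self):
        links, design = self._links_and_design(n_genes=300, n_subj=50)
        cfg = sim.SimulationConfig(expr_frac_regulated=0.0, expr_silent_frac=0.0)
        expr, det, _ = sim.generate_expression(links, design, cfg, seed=16)
        res = paired_lrt(expr, design)
        frac = (res["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 300)
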
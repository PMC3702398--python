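"""Synthetic cohorts: determinism, calibration, and evidence structure."""

import json

import numpy as np
import pandas as pd
import pytest

from callconcord.callset_io import all_patterns
from callconcord.latent_class import LcmCIParams, ci_pattern_prob
from callconcord.simulate import (
    SimulationConfig,
    probit_intercept,
    signed_score_from_counts,
    simulate_cohort,
    simulate_truth,
    write_cohort,
)


class TestConfig:
    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(germline_fraction=0.7, wildtype_artifact_fraction=0.4)

    def test_identifiability_constraint(self):
        with pytest.raises(ValueError, match="sensitivity"):
            SimulationConfig(caller_fp=(0.5, 0.1, 0.1, 0.1), caller_fn=(0.6, 0.2, 0.2, 0.2))

    def test_rate_length_must_match_K(self):
        with pytest.raises(ValueError):
            SimulationConfig(K=3)

    def test_config_hash_tracks_every_field(self):
        base = SimulationConfig()
        assert base.config_hash() == SimulationConfig().config_hash()
        assert base.config_hash() != SimulationConfig(purity=0.7).config_hash()
        assert base.config_hash() != SimulationConfig(seed=1).config_hash()


class TestTruth:
    def test_eta_zero_all_clean_wildtype(self):
        cfg = SimulationConfig(
            n_patients=2, sites_per_patient=100, eta=0.0,
            germline_fraction=0.0, wildtype_artifact_fraction=0.0, seed=3,
        )
        truth = simulate_truth(cfg)
        assert (truth["D"] == "clean_wildtype").all()
        assert (truth["true_tumor_vaf"] == 0).all()
        assert (truth["true_normal_vaf"] == 0).all()

    def test_eta_one_mean_tumor_vaf_matches_closed_form(self):
        # somatic vaf = purity * c / 2, c ~ U(0.2, 1) => mean = purity * 0.3
        cfg = SimulationConfig(
            n_patients=100, sites_per_patient=1000, eta=1.0, purity=0.8, seed=3
        )
        truth = simulate_truth(cfg)
        assert (truth["D"] == "somatic").all()
        assert truth["true_tumor_vaf"].mean() == pytest.approx(0.8 * 0.3, abs=0.003)
        assert (truth.loc[truth["D"] == "somatic", "true_normal_vaf"] == 0).all()

    def test_somatic_fraction_within_binomial_error(self):
        cfg = SimulationConfig(n_patients=100, sites_per_patient=1000, eta=0.03, seed=4)
        truth = simulate_truth(cfg)
        frac = (truth["D"] == "somatic").mean()
        sd = np.sqrt(0.03 * 0.97 / len(truth))
        assert abs(frac - 0.03) < 3 * sd

    def test_germline_sites_have_variant_in_both_samples(self, small_cohort):
        truth, _ = small_cohort
        germ = truth[truth["D"] == "germline"]
        assert (germ["true_tumor_vaf"] > 0).all()
        assert (germ["true_normal_vaf"] > 0).all()


class TestCallerCalls:
    def test_perfect_callers_reproduce_truth_exactly(self):
        cfg = SimulationConfig(
            n_patients=2, sites_per_patient=500, sigma=0.0,
            caller_fp=(0.0,) * 4, caller_fn=(0.0,) * 4, seed=9,
        )
        truth, _ = simulate_cohort(cfg)
        som = (truth["D"] == "somatic").astype(int)
        for c in cfg.caller_ids:
            assert (truth[f"Y_{c}"] == som).all()

    def test_sigma_zero_pattern_frequencies_match_ci_model(self, big_cohort):
        cfg, truth, _ = big_cohort
        params = LcmCIParams(eta=cfg.eta, fp=np.array(cfg.caller_fp), fn=np.array(cfg.caller_fn))
        ycols = [f"Y_{c}" for c in cfg.caller_ids]
        observed = truth[ycols].apply(tuple, axis=1).value_counts()
        n = len(truth)
        for pat in all_patterns(4):
            p = ci_pattern_prob(params, pat)
            obs = observed.get(pat, 0)
            sd = np.sqrt(n * p * (1 - p))
            assert abs(obs - n * p) <= 3 * sd + 1e-9, f"cell {pat}"

    def test_marginal_rates_calibrated_under_random_effects(self):
        # Phi(a / sqrt(1+sigma^2)) identity: marginal rates should still
        # equal the configured ones at sigma = 1.5
        cfg = SimulationConfig(
            n_patients=100, sites_per_patient=1000, eta=0.10, sigma=1.5, seed=21
        )
        truth, _ = simulate_cohort(cfg)
        som = truth["D"] == "somatic"
        for k, c in enumerate(cfg.caller_ids):
            sens_hat = truth.loc[som, f"Y_{c}"].mean()
            target = 1 - cfg.caller_fn[k]
            sd = np.sqrt(target * (1 - target) / som.sum())
            assert abs(sens_hat - target) < 4 * sd
            fp_hat = truth.loc[~som, f"Y_{c}"].mean()
            sd0 = np.sqrt(cfg.caller_fp[k] * (1 - cfg.caller_fp[k]) / (~som).sum())
            assert abs(fp_hat - cfg.caller_fp[k]) < 4 * sd0

    def test_probit_intercept_identity(self):
        for rate, sigma in [(0.05, 0.0), (0.8, 1.5), (0.001, 2.0)]:
            a = probit_intercept(rate, sigma)
            from scipy.special import ndtr

            assert ndtr(a / np.sqrt(1 + sigma**2)) == pytest.approx(rate, rel=1e-9)


class TestEvidence:
    def test_clean_wildtype_zero_error_gives_zero_alt_everywhere(self):
        cfg = SimulationConfig(
            n_patients=2, sites_per_patient=200, eta=0.0,
            germline_fraction=0.0, wildtype_artifact_fraction=0.0,
            seq_error=0.0, seed=6,
        )
        _, ev = simulate_cohort(cfg)
        for assay in ("exome_tumor", "exome_normal", "deep_tumor", "deep_normal", "rna_tumor"):
            assert (ev[f"{assay}_alt"] == 0).all()
        covered = ev["exome_tumor_depth"] > 0
        assert (ev.loc[covered, "signed_q_tumor"] < 0).all()

    def test_artifact_strand_extremity_matches_configured_probability(self):
        cfg = SimulationConfig(
            n_patients=20, sites_per_patient=500, eta=0.0,
            germline_fraction=0.0, wildtype_artifact_fraction=1.0,
            strand_artifact_prob=0.5, seed=8,
        )
        truth, ev = simulate_cohort(cfg)
        enough = ev["exome_tumor_alt"] >= 8  # enough reads to resolve bias
        frac_fwd = ev.loc[enough, "exome_tumor_alt_fwd"] / ev.loc[enough, "exome_tumor_alt"]
        extreme = ((frac_fwd > 0.95) | (frac_fwd < 0.05)).mean()
        assert extreme == pytest.approx(0.5, abs=0.05)

    def test_rna_vaf_unbiased_for_somatic_sites(self):
        cfg = SimulationConfig(n_patients=50, sites_per_patient=400, eta=1.0, seed=12)
        truth, ev = simulate_cohort(cfg)
        deep_enough = ev["rna_tumor_depth"] >= 10
        assert (ev.loc[ev["rna_tumor_depth"] == 0, "rna_tumor_alt"] == 0).all()
        vaf = ev.loc[deep_enough, "rna_tumor_alt"] / ev.loc[deep_enough, "rna_tumor_depth"]
        expected = truth.loc[deep_enough.to_numpy(), "true_tumor_vaf"]
        assert vaf.mean() == pytest.approx(expected.mean(), abs=0.01)

    def test_rna_depth_mass_reaching_10x_is_realistic(self, big_cohort):
        _, _, ev = big_cohort
        frac = (ev["rna_tumor_depth"] >= 10).mean()
        assert 0.25 < frac < 0.45  # roughly a third of sites evaluable by RNA

    def test_signed_score_monotonicity(self):
        depth = np.full(5, 60)
        alts = np.array([0, 2, 5, 10, 30])
        scores = signed_score_from_counts(alts, depth)
        assert (np.diff(scores) > 0).all()
        assert scores[0] < 0 < scores[-1]


class TestWriteCohort:
    def test_manifest_lists_all_files(self, tmp_path):
        cfg = SimulationConfig(
            n_patients=2, sites_per_patient=30, K=3,
            caller_fp=(0.01,) * 3, caller_fn=(0.2,) * 3, seed=2,
        )
        truth, ev = simulate_cohort(cfg)
        manifest = write_cohort(truth, ev, tmp_path, cfg)
        vcfs = [f for f in manifest["files"] if f.endswith(".vcf")]
        assert len(vcfs) == 6  # 2 patients x 3 callers
        assert {"truth.tsv", "evidence.tsv"} <= set(manifest["files"])
        for f in manifest["files"]:
            assert (tmp_path / f).exists()

    def test_same_seed_byte_identical(self, tmp_path, small_config):
        import hashlib

        digests = []
        for sub in ("a", "b"):
            truth, ev = simulate_cohort(small_config)
            manifest = write_cohort(truth, ev, tmp_path / sub, small_config)
            h = hashlib.sha256()
            for f in sorted(manifest["files"]):
                h.update((tmp_path / sub / f).read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_manifest_json_round_trip(self, cohort_dir):
        manifest = json.loads((cohort_dir / "manifest.json").read_text())
        assert manifest["n_sites"] == 1000
        assert manifest["caller_ids"] == ["A", "B", "C", "D"]
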
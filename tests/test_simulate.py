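"""Generator contracts: determinism, planted correlation structure,
interaction-table content, qPCR plate inversion."""

import numpy as np
import pytest

from cernax.errors import ValidationError
from cernax.qpcr import analyze_target
from cernax.simulate import (GeneratorConfig, PlantedTruth, generate_cohort,
                             generate_interaction_tables, generate_qpcr_plate,
                             write_cohort)

SMALL = dict(n_datasets=3, samples_per_group=30, n_decoy_mrna=10,
             n_decoy_lncrna=3, n_decoy_mirna=3)


def test_identical_seed_identical_files(tmp_path):
    cfg = GeneratorConfig(seed=7, **SMALL)
    write_cohort(tmp_path / "a", cfg)
    write_cohort(tmp_path / "b", GeneratorConfig(seed=7, **SMALL))
    files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
    files_b = sorted(p.name for p in (tmp_path / "b").iterdir())
    assert files_a == files_b
    for name in files_a:
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_different_seed_differs(tmp_path):
    write_cohort(tmp_path / "a", GeneratorConfig(seed=7, **SMALL))
    write_cohort(tmp_path / "b", GeneratorConfig(seed=8, **SMALL))
    assert ((tmp_path / "a" / "SYN00_matrix.tsv").read_bytes()
            != (tmp_path / "b" / "SYN00_matrix.tsv").read_bytes())


def test_invalid_config_rejected_before_output():
    with pytest.raises(ValidationError):
        generate_cohort(GeneratorConfig(sponge_coupling=1.5))
    with pytest.raises(ValidationError):
        generate_cohort(GeneratorConfig(noise_sd=0.0))
    with pytest.raises(ValidationError):
        generate_cohort(GeneratorConfig(missing_feature_fraction=1.0))


def test_no_nan_outside_missing_pattern():
    datasets, truth = generate_cohort(GeneratorConfig(seed=3, **SMALL))
    for ds in datasets:
        assert not ds.values.isna().any().any()
        assert ds.feature_ids == truth.feature_presence[ds.dataset_id]


def test_every_feature_present_somewhere():
    cfg = GeneratorConfig(seed=5, missing_feature_fraction=0.5, **SMALL)
    datasets, truth = generate_cohort(cfg)
    all_features = (truth.bait_up_ids + truth.bait_down_ids + [truth.sponge_lncrna_id]
                    + truth.decoy_mrna_ids + truth.decoy_lncrna_ids + truth.decoy_mirna_ids)
    measured = set().union(*(set(ds.feature_ids) for ds in datasets))
    assert set(all_features) <= measured
    # planted features always measured in the reference dataset
    planted = {truth.sponge_lncrna_id, *truth.bait_up_ids, *truth.bait_down_ids}
    assert planted <= set(datasets[0].feature_ids)


def test_latent_factor_correlation_matches_closed_form():
    # with the severity shift switched off the sponge-mRNA coupling is the
    # pure latent factor: expected corr = lambda^2/(lambda^2+sigma^2)
    lam, sigma = 0.8, 1.0
    cfg = GeneratorConfig(seed=11, n_datasets=8, samples_per_group=60,
                          sponge_coupling=lam, noise_sd=sigma,
                          bait_effect_size=0.0,
                          missing_feature_fraction=0.0)
    datasets, truth = generate_cohort(cfg)
    expected = lam**2 / (lam**2 + sigma**2)
    # pair estimates within a dataset share the latent-factor realisation,
    # so aggregate per dataset before computing the standard error
    ds_means, n_sig, n_pairs = [], 0, 0
    for ds in datasets:
        sponge = ds.expression(truth.sponge_lncrna_id).to_numpy()
        rs = []
        for mrna in sorted({t for _, t in truth.axis_triplets}):
            from cernax.stats import pearson
            res = pearson(sponge, ds.expression(mrna).to_numpy())
            rs.append(res.r)
            n_sig += (res.r > 0 and res.p < 0.01)
            n_pairs += 1
        ds_means.append(np.mean(rs))
    mean_r = np.mean(ds_means)
    se = np.std(ds_means, ddof=1) / np.sqrt(len(ds_means))
    assert abs(mean_r - expected) < 3 * se


def test_module_correlation_with_severity_shift_matches_closed_form():
    # at the default effect size the sponge and each axis mRNA share both
    # the factor (loading lambda each) and the down-in-severe shift h
    # (equal group split: shift variance h^2/4), so
    # corr = (h^2/4 + lambda^2) / (h^2/4 + lambda^2 + sigma^2)
    lam, sigma, effect = 0.8, 1.0, 1.5
    h = effect * np.sqrt(lam**2 + sigma**2)
    cfg = GeneratorConfig(seed=11, sponge_coupling=lam, noise_sd=sigma,
                          bait_effect_size=effect, effect_jitter=0.0,
                          missing_feature_fraction=0.0)
    datasets, truth = generate_cohort(cfg)
    shared = h**2 / 4 + lam**2
    expected = shared / (shared + sigma**2)
    ds_means, n_sig, n_pairs = [], 0, 0
    for ds in datasets:
        sponge = ds.expression(truth.sponge_lncrna_id).to_numpy()
        rs = []
        for mrna in sorted({t for _, t in truth.axis_triplets}):
            from cernax.stats import pearson
            res = pearson(sponge, ds.expression(mrna).to_numpy())
            rs.append(res.r)
            n_sig += (res.r > 0 and res.p < 0.01)
            n_pairs += 1
        ds_means.append(np.mean(rs))
    se = np.std(ds_means, ddof=1) / np.sqrt(len(ds_means))
    assert abs(np.mean(ds_means) - expected) < 3 * se
    assert n_sig / n_pairs >= 0.9  # positive & significant in >= 90% of draws


def test_zero_effect_baits_behave_as_decoys(severity_contrast):
    from cernax.bait_screen import differential_by_contrast
    cfg = GeneratorConfig(seed=19, bait_effect_size=0.0, sponge_coupling=0.0,
                          missing_feature_fraction=0.0, **SMALL)
    datasets, truth = generate_cohort(cfg)
    bait_calls = 0
    for ds in datasets:
        calls = differential_by_contrast(ds, severity_contrast, alpha=0.01)
        bait_calls += sum(c.feature_id in truth.bait_up_ids + truth.bait_down_ids
                          for c in calls)
    # 3 datasets x 24 baits = 72 tests; after FDR essentially none pass
    assert bait_calls <= 2


class TestInteractionTables:
    def test_counts_without_decoys(self):
        cfg = GeneratorConfig(seed=2, n_axis_mirnas=3, n_axis_mrnas=1,
                              n_no_target_mirnas=0, interaction_false_positive_rows=0,
                              **SMALL)
        _, truth = generate_cohort(cfg)
        tables = generate_interaction_tables(truth, cfg)
        assert len(tables["mirna_mrna_validated"].rows) == 3  # 3 planted triplets
        assert len(tables["lncrna_mirna_binding"].rows) == 3
        assert set(tables["mirna_cancer"].rows["id_a"]) == set(truth.oncomir_ids)

    def test_no_target_mirnas_lack_target_rows(self):
        cfg = GeneratorConfig(seed=2, n_no_target_mirnas=2,
                              interaction_false_positive_rows=0, **SMALL)
        _, truth = generate_cohort(cfg)
        tables = generate_interaction_tables(truth, cfg)
        target_mirnas = set(tables["mirna_mrna_validated"].rows["id_a"])
        binding_mirnas = set(tables["lncrna_mirna_binding"].rows["id_b"])
        assert set(truth.no_target_mirna_ids) <= binding_mirnas
        assert not set(truth.no_target_mirna_ids) & target_mirnas

    def test_decoy_rows_recorded_in_truth(self):
        cfg = GeneratorConfig(seed=2, interaction_false_positive_rows=5, **SMALL)
        _, truth = generate_cohort(cfg)
        generate_interaction_tables(truth, cfg)
        assert len(truth.decoy_interaction_rows["targets"]) == 5


class TestQpcrPlate:
    @pytest.mark.parametrize("fc", [1.0, 2.0, 0.5])
    def test_noise_free_plate_inverts_exactly(self, fc):
        plate = generate_qpcr_plate({"T1": fc}, n_per_group=4, ct_noise_sd=0.0, seed=1)
        res = analyze_target(plate, "T1", "PPIA", "case", "control")
        assert res.fold_change == pytest.approx(fc, abs=1e-9)

    def test_noisy_plate_unbiased(self):
        estimates = [
            analyze_target(
                generate_qpcr_plate({"T1": 0.5}, n_per_group=6, ct_noise_sd=0.2, seed=s),
                "T1", "PPIA", "case", "control").fold_change
            for s in range(200)
        ]
        assert abs(np.mean(estimates) - 0.5) < 0.05  # within 10% of truth

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValidationError):
            generate_qpcr_plate({"T1": 0.0}, seed=1)


def test_truth_json_roundtrip(tmp_path):
    truth = write_cohort(tmp_path, GeneratorConfig(seed=7, **SMALL))
    back = PlantedTruth.from_json((tmp_path / "truth.json").read_text())
    assert back == truth
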
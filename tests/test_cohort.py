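"""Synthetic cohort generator, BOLD simulation, CVT parcellation."""

import dataclasses

import numpy as np
import pytest

from ftdnet.cohort import (
    CohortConfig,
    covariance_template,
    cvt_energy,
    generate_cohort,
    generate_cvt_parcellation,
    simulate_bold,
    subject_covariance,
)
from ftdnet.connectivity import select_wavelet_scale


class TestCohortGeneration:
    def test_default_group_sizes_total_172(self):
        cfg = CohortConfig()
        assert (cfg.n_gene_negative, cfg.n_carrier, cfg.n_ftd) == (80, 68, 24)
        assert cfg.n_total == 172

    def test_generated_counts_match_config(self, small_cohort_config):
        subjects, series, truth = generate_cohort(small_cohort_config)
        assert len(subjects) == len(series) == len(truth) == 30
        groups = [s.group for s in subjects]
        assert groups.count("gene_negative") == 12
        assert groups.count("carrier") == 10
        assert groups.count("ftd") == 8

    def test_seed_determinism_field_for_field(self, small_cohort_config):
        a_sub, a_ts, a_tr = generate_cohort(small_cohort_config)
        b_sub, b_ts, b_tr = generate_cohort(small_cohort_config)
        for sa, sb in zip(a_sub, b_sub):
            assert sa == sb
        for ta, tb in zip(a_ts, b_ts):
            np.testing.assert_array_equal(ta.signal, tb.signal)
        for ga, gb in zip(a_tr, b_tr):
            assert ga == gb

    def test_different_seeds_differ(self, small_cohort_config):
        a, _, _ = generate_cohort(small_cohort_config)
        b, _, _ = generate_cohort(dataclasses.replace(small_cohort_config, seed=12))
        assert any(sa.age != sb.age for sa, sb in zip(a, b))

    def test_onset_sign_conventions(self, small_cohort_config):
        subjects, _, _ = generate_cohort(small_cohort_config)
        for s in subjects:
            if s.group == "carrier":
                assert s.years_to_expected_onset < 0
            elif s.group == "ftd":
                assert s.years_to_expected_onset >= 0

    def test_every_subject_has_family_gene_label(self, small_cohort_config):
        subjects, _, _ = generate_cohort(small_cohort_config)
        assert all(s.gene in ("C9orf72", "MAPT", "GRN") for s in subjects)

    def test_null_effects_equalize_groups(self):
        """With all disease effects switched off, the generator's true mean
        off-diagonal correlation is equal across groups over Monte-Carlo
        cohorts."""
        means = {"gene_negative": [], "carrier": [], "ftd": []}
        for seed in range(20):
            cfg = CohortConfig(
                n_gene_negative=6, n_carrier=6, n_ftd=6,
                n_regions=24, n_timepoints=32, community_size=6,
                strength_decline_per_year=0.0,
                carrier_efficiency_offset=0.0,
                post_onset_efficiency_slope=0.0,
                noise_sd=0.0,
                seed=seed,
            )
            subjects, _, truth = generate_cohort(cfg)
            for s, g in zip(subjects, truth):
                means[s.group].append(g.true_covariance_summary)
        grand = [np.mean(means[g]) for g in means]
        assert max(grand) - min(grand) < 0.005

    def test_ftd_strength_scale_monotonically_lowers_ftd_connectivity(self):
        """Decreasing ftd_strength_scale strictly decreases FTD subjects'
        expected true connectivity over Monte-Carlo cohorts."""
        def ftd_mean(scale):
            vals = []
            for seed in range(8):
                cfg = CohortConfig(
                    n_gene_negative=2, n_carrier=2, n_ftd=8,
                    n_regions=24, n_timepoints=32, community_size=6,
                    ftd_strength_scale=scale, seed=seed,
                )
                subjects, _, truth = generate_cohort(cfg)
                vals += [
                    g.true_covariance_summary
                    for s, g in zip(subjects, truth)
                    if s.group == "ftd"
                ]
            return np.mean(vals)

        m1, m085, m07 = ftd_mean(1.0), ftd_mean(0.85), ftd_mean(0.7)
        assert m1 > m085 > m07

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="tr_seconds"):
            CohortConfig(tr_seconds=0.0)
        with pytest.raises(ValueError, match="ftd_strength_scale"):
            CohortConfig(ftd_strength_scale=1.5)
        with pytest.raises(ValueError, match="hub_fraction"):
            CohortConfig(hub_fraction=1.2)


class TestSubjectCovariance:
    def test_valid_correlation_matrix(self, small_cohort_config):
        tmpl = covariance_template(small_cohort_config)
        cov = subject_covariance(
            small_cohort_config, "carrier", -5.0, 1.0, 1.0,
            np.random.default_rng(0), tmpl,
        )
        np.testing.assert_allclose(np.diag(cov), 1.0)
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > -1e-8

    def test_pruning_lowers_total_connectivity(self, small_cohort_config):
        tmpl = covariance_template(small_cohort_config)
        off = ~np.eye(small_cohort_config.n_regions, dtype=bool)
        full = subject_covariance(small_cohort_config, "carrier", -24.0, 1.0, 1.0,
                                  None, tmpl)
        pruned = subject_covariance(small_cohort_config, "ftd", 9.0, 1.0, 1.0,
                                    None, tmpl)
        assert pruned[off].sum() < full[off].sum()


class TestSimulateBold:
    def band(self):
        return select_wavelet_scale(2.2)

    def test_identity_covariance_gives_near_zero_wavelet_correlations(self):
        from ftdnet.connectivity import ParcellatedTimeSeries, wavelet_correlation_matrix

        ests = []
        for seed in range(100):
            x = simulate_bold(np.eye(2), 512, 2.2, self.band(), seed)
            c = wavelet_correlation_matrix(ParcellatedTimeSeries("s", x, 2.2), self.band())
            ests.append(c.values[0, 1])
        assert abs(np.mean(ests)) < 0.03

    def test_duplicated_latent_row_gives_correlation_one(self):
        from ftdnet.connectivity import ParcellatedTimeSeries, wavelet_correlation_matrix

        cov = np.array([[1.0, 1.0], [1.0, 1.0]])
        x = simulate_bold(cov, 512, 2.2, self.band(), 4)
        c = wavelet_correlation_matrix(ParcellatedTimeSeries("s", x, 2.2), self.band())
        assert c.values[0, 1] >= 0.99

    def test_target_correlation_recovered(self):
        from ftdnet.connectivity import ParcellatedTimeSeries, wavelet_correlation_matrix

        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        ests = []
        for seed in range(40):
            x = simulate_bold(cov, 512, 2.2, self.band(), 100 + seed)
            c = wavelet_correlation_matrix(ParcellatedTimeSeries("s", x, 2.2), self.band())
            ests.append(c.values[0, 1])
        assert np.mean(ests) == pytest.approx(0.5, abs=0.1)

    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_bold(bad, 64, 2.2, self.band(), 0)

    def test_seeded_determinism(self):
        cov = np.eye(3)
        a = simulate_bold(cov, 128, 2.2, self.band(), 5)
        b = simulate_bold(cov, 128, 2.2, self.band(), 5)
        np.testing.assert_array_equal(a, b)


def ellipsoid_mask(n_target=60_000):
    """Synthetic ellipsoidal voxel mask with roughly n_target voxels."""
    a, b, c = 23, 28, 23
    g = np.mgrid[-a:a + 1, -b:b + 1, -c:c + 1].reshape(3, -1).T.astype(float)
    inside = (g[:, 0] / a) ** 2 + (g[:, 1] / b) ** 2 + (g[:, 2] / c) ** 2 <= 1.0
    return g[inside]


class TestCvtParcellation:
    def test_k_equal_one_is_the_whole_mask(self, rng):
        vox = rng.uniform(0, 10, size=(200, 3))
        labels = generate_cvt_parcellation(vox, 1, seed=0)
        assert (labels == 1).all()

    def test_k_exceeding_voxels_rejected(self, rng):
        vox = rng.uniform(0, 10, size=(5, 3))
        with pytest.raises(ValueError, match="k="):
            generate_cvt_parcellation(vox, 6, seed=0)

    def test_labels_partition_mask_into_k_nonempty_parcels(self, rng):
        vox = rng.uniform(0, 30, size=(3000, 3))
        labels = generate_cvt_parcellation(vox, 40, n_iterations=25, seed=1)
        assert labels.shape == (3000,)
        assert set(np.unique(labels)) == set(range(1, 41))

    def test_energy_non_increasing_across_lloyd_iterations(self, rng):
        vox = rng.uniform(0, 30, size=(4000, 3))
        _, history = generate_cvt_parcellation(
            vox, 30, n_iterations=30, seed=2, return_history=True
        )
        assert len(history) >= 2
        diffs = np.diff(history)
        assert (diffs <= 1e-9 * history[0]).all()

    def test_500_parcels_on_ellipsoid_are_approximately_equal_sized(self):
        """500 parcels on a ~60k-voxel ellipsoid: all non-empty, size CV < 0.25."""
        vox = ellipsoid_mask()
        assert 50_000 < len(vox) < 70_000
        labels = generate_cvt_parcellation(vox, 500, n_iterations=50, seed=3)
        sizes = np.bincount(labels)[1:]
        assert len(sizes) == 500 and (sizes > 0).all()
        cv = sizes.std() / sizes.mean()
        assert cv < 0.25


def test_parcellation_table_roundtrip(rng, tmp_path):
    from ftdnet.io import read_parcellation, write_parcellation

    vox = rng.uniform(0, 20, size=(500, 3))
    labels = generate_cvt_parcellation(vox, 12, n_iterations=10, seed=4)
    path = write_parcellation(vox, labels, tmp_path / "parcellation.tsv")
    vox_back, labels_back = read_parcellation(path)
    np.testing.assert_array_equal(labels_back, labels)
    np.testing.assert_allclose(vox_back, vox)
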
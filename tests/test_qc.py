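"""Background subtraction, quantile normalization, ratio computation,
outlier masking, exclusions and QC bookkeeping."""

import dataclasses
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtgwas.chip_model import ChipManifest, ProbeRecord
from mtgwas.qc import (
    LogRatioMatrix,
    QCParams,
    apply_probe_exclusions,
    build_qc_report,
    center,
    compute_log_ratio,
    detect_outliers,
    quantile_normalize,
    run_qc,
    subtract_background,
)
from mtgwas.simulate import (
    RawIntensityTensor,
    SimulationConfig,
    make_synthetic_manifest,
    simulate_heteroplasmy,
    simulate_intensities,
)


def tensor_from(values: np.ndarray, chip="c") -> RawIntensityTensor:
    n_i, n_p = values.shape[:2]
    return RawIntensityTensor(
        values.astype(float),
        [f"i{k}" for k in range(n_i)],
        [f"p{k}" for k in range(n_p)],
        chip,
    )


def ratio_matrix(z: np.ndarray, mask=None, centered=False) -> LogRatioMatrix:
    n_i, n_p = z.shape
    return LogRatioMatrix(
        z.astype(float),
        np.zeros_like(z, dtype=bool) if mask is None else mask,
        [f"i{k}" for k in range(n_i)],
        [f"p{k}" for k in range(n_p)],
        "c",
        centered=centered,
    )


class TestBackgroundSubtraction:
    def test_constant_tensor_goes_to_floor(self):
        t = tensor_from(np.full((3, 4, 2, 2), 7.0))
        out = subtract_background(t)
        assert (out.values == 0.0).all()

    def test_hand_computed_quantile(self):
        # one individual whose pooled measures are the integers 0..100 (each
        # appearing in both channels): the 5% quantile under linear
        # interpolation is 5, so the value 100 becomes 95
        vals = np.arange(101, dtype=float).reshape(1, 101, 1, 1).repeat(2, axis=2)
        out = subtract_background(tensor_from(vals))
        assert out.values.max() == pytest.approx(95.0)
        assert out.values.min() == 0.0

    def test_background_free_input_unchanged(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(10, 100, size=(4, 20, 2, 1))
        vals[:, 0, 0, 0] = 0.0  # ensures the 5% quantile is 0 for >5% mass at 0?
        vals[:, :2, :, :] = 0.0  # 10% of values at zero -> quantile 0
        t = tensor_from(vals)
        out = subtract_background(t)
        np.testing.assert_allclose(out.values, vals)

    def test_at_most_quantile_fraction_at_floor(self, base_config):
        t = simulate_intensities(base_config, simulate_heteroplasmy(base_config))
        out = subtract_background(t)
        frac_floor = (out.values.reshape(t.n_individuals, -1) == 0.0).mean(axis=1)
        assert (frac_floor <= 0.05 + 1e-9).all()


class TestQuantileNormalize:
    def test_two_by_two_hand_example(self):
        t = tensor_from(np.array([[1.0, 3.0], [2.0, 4.0]]).reshape(2, 2, 1, 1))
        out = quantile_normalize(t).values.reshape(2, 2)
        np.testing.assert_allclose(out, [[1.5, 3.5], [1.5, 3.5]])

    def test_identical_multisets_preserved(self):
        a = np.array([5.0, 1.0, 3.0]).reshape(1, 3, 1, 1)
        b = np.array([3.0, 5.0, 1.0]).reshape(1, 3, 1, 1)
        t = tensor_from(np.concatenate([a, b], axis=0))
        out = quantile_normalize(t).values.reshape(2, 3)
        np.testing.assert_allclose(out[0], [5.0, 1.0, 3.0])
        np.testing.assert_allclose(out[1], [3.0, 5.0, 1.0])

    def test_single_individual_unchanged(self):
        vals = np.random.default_rng(0).uniform(size=(1, 5, 2, 3))
        t = tensor_from(vals)
        np.testing.assert_array_equal(quantile_normalize(t).values, vals)

    @given(st.integers(2, 6), st.integers(2, 15), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sorted_vectors_identical_afterwards(self, n_ind, n_val, seed):
        # continuous draws: tie-free, so every individual ends up with the
        # exact reference multiset
        flat = np.random.default_rng(seed).uniform(0, 1e4, size=(n_ind, n_val))
        t = tensor_from(flat.reshape(n_ind, n_val, 1, 1))
        out = quantile_normalize(t).values.reshape(n_ind, -1)
        ref = np.sort(out[0])
        for i in range(out.shape[0]):
            np.testing.assert_allclose(np.sort(out[i]), ref, atol=1e-9)

    def test_ties_receive_mean_of_rank_means(self):
        # individual [1, 1] against [0, 1]: reference is [0.5, 1.0]; the
        # tied pair takes the average rank 1.5 -> (0.5 + 1.0) / 2 = 0.75
        t = tensor_from(np.array([[0.0, 1.0], [1.0, 1.0]]).reshape(2, 2, 1, 1))
        out = quantile_normalize(t).values.reshape(2, 2)
        np.testing.assert_allclose(out[1], [0.75, 0.75])
        np.testing.assert_allclose(out[0], [0.5, 1.0])

    def test_matches_limma_reference(self, tmp_path, rng):
        """Cross-check against Bioconductor limma's normalizeQuantiles."""
        n_ind, n_val = 6, 40
        mat = rng.uniform(0, 1000, size=(n_ind, n_val))
        mat[0, :5] = mat[0, 5]  # inject ties
        np.savetxt(tmp_path / "in.csv", mat.T, delimiter=",")  # limma: columns = samples
        script = (
            "m <- as.matrix(read.csv(file.path('%s','in.csv'), header=FALSE));"
            "suppressMessages(library(limma));"
            "write.table(normalizeQuantiles(m), file.path('%s','out.csv'),"
            "sep=',', row.names=FALSE, col.names=FALSE)" % (tmp_path, tmp_path)
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        expected = np.loadtxt(tmp_path / "out.csv", delimiter=",").T
        t = tensor_from(mat.reshape(n_ind, n_val, 1, 1))
        out = quantile_normalize(t).values.reshape(n_ind, n_val)
        np.testing.assert_allclose(out, expected, atol=1e-8)


class TestLogRatio:
    def manifest(self, n, n_measures=1):
        return ChipManifest(
            "c", [ProbeRecord(f"p{k}", k + 1, "A", "G", n_measures) for k in range(n)]
        )

    def test_equal_channels_give_zero(self):
        vals = np.full((2, 3, 2, 1), 8.0)
        z = compute_log_ratio(tensor_from(vals), self.manifest(3))
        assert (z.z == 0.0).all()

    def test_power_of_two_ratio(self):
        vals = np.zeros((1, 1, 2, 1))
        vals[0, 0, 0, 0] = 4000.0
        vals[0, 0, 1, 0] = 1000.0
        z = compute_log_ratio(tensor_from(vals), self.manifest(1))
        assert z.z[0, 0] == pytest.approx(2.0, abs=2e-3)  # eps perturbs slightly

    def test_replicate_means_with_epsilon(self):
        vals = np.zeros((1, 1, 2, 3))
        vals[0, 0, 0, :] = [2.0, 4.0, 6.0]
        vals[0, 0, 1, :] = [1.0, 1.0, 1.0]
        z = compute_log_ratio(tensor_from(vals), self.manifest(1, 3), epsilon=1.0)
        assert z.z[0, 0] == pytest.approx(np.log2((4 + 1) / (1 + 1)))

    def test_mask_initialized_false(self):
        z = compute_log_ratio(tensor_from(np.ones((2, 2, 2, 1))), self.manifest(2))
        assert not z.mask.any() and not z.centered


class TestOutlierDetection:
    def test_constant_probe_no_masks(self):
        z = ratio_matrix(np.zeros((50, 3)))
        assert detect_outliers(z).n_outliers == 0

    def test_single_gross_value_masked(self):
        vals = np.zeros((100, 1))
        vals[17, 0] = 10.0
        out = detect_outliers(ratio_matrix(vals))
        assert out.n_outliers == 1 and out.mask[17, 0]

    def test_idempotent(self, rng):
        vals = rng.normal(size=(200, 5))
        vals[0, :] = 50.0
        once = detect_outliers(ratio_matrix(vals))
        twice = detect_outliers(
            LogRatioMatrix(once.z, once.mask, once.individual_ids, once.probe_ids, "c")
        )
        assert np.array_equal(once.mask, twice.mask)

    def test_permutation_equivariant(self, rng):
        vals = rng.normal(size=(80, 4))
        vals[3, 2] = 99.0
        perm = rng.permutation(80)
        m1 = detect_outliers(ratio_matrix(vals)).mask
        m2 = detect_outliers(ratio_matrix(vals[perm])).mask
        assert np.array_equal(m1[perm], m2)

    def test_probe_order_invariant(self, rng):
        vals = rng.normal(size=(80, 4))
        vals[5, 1] = -60.0
        m1 = detect_outliers(ratio_matrix(vals)).mask
        m2 = detect_outliers(ratio_matrix(vals[:, ::-1])).mask
        assert np.array_equal(m1[:, ::-1], m2)

    def test_degenerate_probe_masks_only_off_median_values(self):
        # majority at the median with zero MAD: only the dissenters go
        vals = np.zeros((10, 1))
        vals[7:, 0] = [3.0, -4.0, 9.0]
        out = detect_outliers(ratio_matrix(vals))
        assert out.mask[7:, 0].all() and not out.mask[:7, 0].any()

    def test_requires_uncentered_input(self):
        with pytest.raises(ValueError):
            detect_outliers(ratio_matrix(np.zeros((5, 2)), centered=True))

    def test_injected_gross_corruptions_all_masked_and_rare(self):
        """With a small measure-level corruption rate, the masked fraction
        stays far below 0.5% and the detector reaches a fixed point (no
        unmasked value beyond its own cut)."""
        manifest = make_synthetic_manifest("big", 350, 1, seed=77)
        cfg = SimulationConfig(
            seed=78, n_individuals=1500, manifest=manifest,
            maf=0.0, background_level=0.0, noise_cv=0.1, outlier_rate=0.0005,
        )
        tensor = simulate_intensities(cfg, simulate_heteroplasmy(cfg))
        z = compute_log_ratio(tensor, manifest)
        out = detect_outliers(z)
        n_ratios = out.z.size  # 525,000
        assert out.n_outliers / n_ratios < 0.005
        work = np.where(out.mask, np.nan, out.z)
        med = np.nanmedian(work, axis=0)
        mad = np.nanmedian(np.abs(work - med), axis=0)
        cut = np.where(mad > 0, 5 * 1.4826 * mad, 1e-8)
        assert not ((np.abs(work - med) > cut) & ~np.isnan(work)).any()


class TestCentering:
    def test_simple(self):
        out = center(ratio_matrix(np.array([[1.0], [2.0], [3.0]])))
        np.testing.assert_allclose(out.z.ravel(), [-1, 0, 1])
        assert out.centered

    def test_masked_excluded_from_mean(self):
        vals = np.array([[1.0], [2.0], [3.0], [100.0]])
        mask = np.array([[False], [False], [False], [True]])
        out = center(ratio_matrix(vals, mask=mask))
        np.testing.assert_allclose(out.z[:3, 0], [-1, 0, 1])
        assert out.mask[3, 0]

    def test_idempotent(self, rng):
        z = ratio_matrix(rng.normal(size=(30, 4)))
        once = center(z)
        twice = center(once)
        np.testing.assert_allclose(once.z, twice.z, atol=1e-12)

    def test_unmasked_mean_within_tolerance(self, rng):
        vals = rng.normal(5, 2, size=(100, 6))
        mask = rng.random((100, 6)) < 0.1
        out = center(ratio_matrix(vals, mask=mask))
        resid = np.where(out.mask, np.nan, out.z)
        np.testing.assert_allclose(np.nanmean(resid, axis=0), 0.0, atol=1e-9)

    def test_underpopulated_probe_dropped(self):
        vals = np.zeros((3, 2))
        mask = np.array([[False, True], [False, True], [False, False]])
        out = center(ratio_matrix(vals, mask=mask))
        assert out.dropped_probes == ["p1"]


class TestProbeExclusions:
    def test_nothing_excluded(self, base_config):
        t = simulate_intensities(base_config, simulate_heteroplasmy(base_config))
        kept, _, excl = apply_probe_exclusions(base_config.manifest, t)
        assert excl.n_excluded_upper_bound == 0 and excl.n_excluded_no_build38 == 0
        assert kept.n_probes == base_config.manifest.n_probes

    def test_saturated_probe_excluded(self, base_config):
        t = simulate_intensities(base_config, simulate_heteroplasmy(base_config))
        t.values[:, 4, :, :] = base_config.manifest.saturation_cap
        kept, kept_t, excl = apply_probe_exclusions(base_config.manifest, t)
        assert excl.excluded_upper_bound == [base_config.manifest.probe_ids[4]]
        assert kept.n_probes == kept_t.n_probes == base_config.manifest.n_probes - 1

    def test_unmappable_counts_match_study_design(self):
        manifest = make_synthetic_manifest("affy-like", 465, 3, seed=5, n_unmappable=54)
        cfg = SimulationConfig(seed=6, n_individuals=20, manifest=manifest)
        t = simulate_intensities(cfg, simulate_heteroplasmy(cfg))
        kept, _, excl = apply_probe_exclusions(manifest, t)
        assert excl.n_excluded_no_build38 == 54 and kept.n_probes == 411


class TestQCReport:
    @pytest.mark.parametrize(
        "name,n_in,ub,no38,sample,nm,kept,itot",
        [
            ("affy-like", 465, 0, 54, 1647, 3, 411, 4_061_502),
            ("metabo-like", 135, 0, 9, 2815, 1, 126, 709_380),
        ],
    )
    def test_study_scale_reports(self, name, n_in, ub, no38, sample, nm, kept, itot):
        r = build_qc_report(name, n_in, ub, no38, sample, nm, n_outlier_ratios=0)
        assert r.n_probes_kept == kept and r.i_tot == itot

    def test_empty_chip(self):
        r = build_qc_report("empty", 0, 0, 0, 0, 1, 0)
        assert r.n_probes_kept == 0 and r.i_tot == 0 and r.outlier_fraction == 0.0

    def test_json_round_trip(self, tmp_path):
        import json

        r = build_qc_report("c", 10, 1, 2, 100, 3, 5)
        r.to_json(tmp_path / "r.json")
        with open(tmp_path / "r.json") as fh:
            d = json.load(fh)
        assert d["n_probes_kept"] == 7 and d["i_tot"] == 3 * 2 * 100 * 7


def test_run_qc_end_to_end(base_config):
    cfg = dataclasses.replace(base_config, outlier_rate=0.001)
    t = simulate_intensities(cfg, simulate_heteroplasmy(cfg))
    z, kept, report, excl = run_qc(t, cfg.manifest, QCParams())
    assert z.centered
    assert report.n_probes_kept == kept.n_probes
    assert report.i_tot == 3 * 2 * cfg.n_individuals * kept.n_probes
    assert report.n_outlier_ratios == z.n_outliers
    resid = np.where(z.mask, np.nan, z.z)
    keep_cols = [j for j, p in enumerate(z.probe_ids) if p not in z.dropped_probes]
    np.testing.assert_allclose(np.nanmean(resid[:, keep_cols], axis=0), 0.0, atol=1e-9)


def test_logratio_tsv_round_trip(tmp_path, base_config):
    t = simulate_intensities(base_config, simulate_heteroplasmy(base_config))
    z, _, _, _ = run_qc(t, base_config.manifest, QCParams())
    z.to_tsv(tmp_path / "z.tsv")
    back = LogRatioMatrix.from_tsv(tmp_path / "z.tsv", z.chip_name)
    assert np.array_equal(back.mask, z.mask)
    np.testing.assert_allclose(
        np.where(back.mask, 0, back.z), np.where(z.mask, 0, z.z), atol=1e-9
    )
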
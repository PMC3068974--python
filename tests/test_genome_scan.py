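import numpy as np
import pandas as pd
import pytest

import survscan as sv
from survscan.genome_scan import score_from_p
from survscan.genome_scan import tested_indices as strided_indices


def _matrix(values, chrom_sizes, sample_ids=None):
    rows = []
    for chrom, n in chrom_sizes:
        for i in range(n):
            rows.append((f"M_{chrom}_{i}", chrom, (i + 1) * 100))
    ann = sv.MarkerAnnotation(
        pd.DataFrame(rows, columns=["marker_id", "chromosome", "position"])
    )
    values = np.asarray(values, float)
    ids = sample_ids or [f"S{j}" for j in range(values.shape[1])]
    return sv.GenomeMatrix(values, ann, ids)


def _survival(rng, n):
    t = rng.exponential(20, n)
    c = rng.uniform(0, 60, n)
    return sv.SurvivalData(np.minimum(t, c), (t <= c).astype(float))


@pytest.fixture
def noisy_scan_inputs():
    rng = np.random.default_rng(50)
    values = 2.0 + rng.normal(0, 0.6, (100, 80))
    return _matrix(values, [("1", 60), ("2", 40)]), _survival(rng, 80)


class TestStride:
    def test_hundred_markers_stride_ten(self):
        m = _matrix(np.full((100, 2), 2.0), [("1", 100)])
        idx = strided_indices(m, 10)
        np.testing.assert_array_equal(idx, np.arange(0, 100, 10))

    def test_stride_restarts_each_chromosome(self):
        m = _matrix(np.full((25, 2), 2.0), [("1", 13), ("2", 12)])
        idx = strided_indices(m, 10)
        np.testing.assert_array_equal(idx, [0, 10, 13, 23])

    def test_doubling_stride_gives_nested_grid(self, noisy_scan_inputs):
        matrix, data = noisy_scan_inputs
        cfg10 = sv.ScanConfig(stride=10, smoothing=sv.SmoothingConfig(window=1))
        cfg20 = sv.ScanConfig(stride=20, smoothing=sv.SmoothingConfig(window=1))
        r10 = sv.scan_logrank(matrix, data, cfg10)
        r20 = sv.scan_logrank(matrix, data, cfg20)
        assert set(r20.table.marker_id) <= set(r10.table.marker_id)
        merged = r20.table.merge(r10.table, on="marker_id", suffixes=("_20", "_10"))
        np.testing.assert_allclose(
            merged.score_20.to_numpy(), merged.score_10.to_numpy(), equal_nan=True
        )

    def test_stride_one_single_marker_reduces_to_logrank_test(self):
        rng = np.random.default_rng(51)
        data = _survival(rng, 40)
        vals = np.concatenate([np.full(15, 1.0), np.full(15, 2.0), np.full(10, 3.0)])
        m = _matrix(vals[None, :], [("1", 1)])
        cfg = sv.ScanConfig(stride=1, smoothing=sv.SmoothingConfig(window=1))
        res = sv.scan_logrank(m, data, cfg)
        labels = np.array(sv.GROUP_LABELS)[sv.assign_cn_groups(vals, cfg.smoothing)]
        ref = sv.logrank_test(data, labels)
        assert res.table.statistic[0] == pytest.approx(ref.chi_square, rel=1e-10)
        assert res.table.score[0] == pytest.approx(-np.log10(ref.p_value), rel=1e-10)


class TestLogrankScan:
    def test_score_transform_anchor(self):
        assert score_from_p(0.001) == pytest.approx(3.0, abs=1e-12)

    def test_scores_are_neglog10_of_p(self, noisy_scan_inputs):
        matrix, data = noisy_scan_inputs
        res = sv.scan_logrank(
            matrix, data, sv.ScanConfig(stride=10, smoothing=sv.SmoothingConfig(window=1))
        )
        tab = res.table[np.isfinite(res.table.score)]
        np.testing.assert_allclose(tab.score, -np.log10(tab.p_value))

    def test_single_group_marker_missing_score(self):
        rng = np.random.default_rng(52)
        data = _survival(rng, 30)
        m = _matrix(np.full((1, 30), 2.0), [("1", 1)])
        cfg = sv.ScanConfig(stride=1, smoothing=sv.SmoothingConfig(window=1))
        with pytest.raises(ValueError, match="no testable marker"):
            sv.scan_logrank(m, data, cfg)
        # mixed case: one testable, one all-NoChange marker
        vals = np.vstack([np.full(30, 2.0), np.where(np.arange(30) < 10, 1.0, 2.0)])
        res = sv.scan_logrank(_matrix(vals, [("1", 2)]), data, cfg)
        assert np.isnan(res.table.score[0]) and np.isfinite(res.table.score[1])

    def test_sample_order_invariance(self, noisy_scan_inputs):
        matrix, data = noisy_scan_inputs
        cfg = sv.ScanConfig(stride=7, smoothing=sv.SmoothingConfig(window=1))
        a = sv.scan_logrank(matrix, data, cfg)
        rng = np.random.default_rng(1)
        perm = rng.permutation(matrix.n_samples)
        m2 = sv.GenomeMatrix(
            matrix.values[:, perm], matrix.annotation, [matrix.sample_ids[i] for i in perm]
        )
        d2 = sv.SurvivalData(data.time[perm], data.event[perm])
        b = sv.scan_logrank(m2, d2, cfg)
        np.testing.assert_allclose(a.scores, b.scores, equal_nan=True)

    def test_missing_copy_excludes_sample_at_that_marker_only(self):
        rng = np.random.default_rng(53)
        data = _survival(rng, 40)
        vals = np.tile(np.concatenate([np.full(20, 1.0), np.full(20, 2.5)]), (2, 1))
        vals[1, 0] = np.nan
        m = _matrix(vals, [("1", 2)])
        cfg = sv.ScanConfig(stride=1, smoothing=sv.SmoothingConfig(window=1))
        res = sv.scan_logrank(m, data, cfg)
        labels = np.array(sv.GROUP_LABELS)[sv.assign_cn_groups(vals[1, 1:], cfg.smoothing)]
        ref = sv.logrank_test(data.subset(np.arange(40) != 0), labels)
        assert res.table.statistic[1] == pytest.approx(ref.chi_square, rel=1e-10)
        assert res.table.statistic[0] != pytest.approx(res.table.statistic[1])


class TestCoxScan:
    def test_planted_deletion_peak_inside_region(self, demo_sim, demo_model):
        res = demo_model.fit("cox")
        chrom, lo, hi = demo_sim.region_interval(0)
        peak = res.table.iloc[int(np.nanargmax(np.abs(res.scores)))]
        assert peak.chromosome == chrom and lo <= peak.position <= hi
        assert peak.score < 0  # deletion carriers die faster: copies protective

    def test_flipping_association_flips_z_sign(self, demo_sim):
        import dataclasses

        spec = demo_sim.spec
        flipped = dataclasses.replace(
            spec,
            regions=(dataclasses.replace(spec.regions[0], log_hr=-spec.regions[0].log_hr),),
        )
        sim2 = sv.simulate(flipped)
        model2 = sv.GenomeSurvivalScan(sim2.matrix, sim2.sample_table, sv.ScanConfig())
        res2 = model2.fit("cox")
        peak2 = res2.table.iloc[int(np.nanargmax(np.abs(res2.scores)))]
        assert peak2.score > 0

    def test_constant_marker_missing_score(self):
        rng = np.random.default_rng(54)
        data = _survival(rng, 30)
        vals = np.vstack([np.full(30, 2.0), rng.normal(2, 0.3, 30)])
        res = sv.scan_cox(
            _matrix(vals, [("1", 2)]),
            data,
            sv.ScanConfig(stride=1, smoothing=sv.SmoothingConfig(window=1)),
        )
        assert np.isnan(res.table.score[0]) and np.isfinite(res.table.score[1])

    def test_adjusted_scan_runs(self, demo_sim):
        cfg = sv.ScanConfig(stride=100, covariates=("Carrier1(numeric)",), method="cox")
        model = sv.GenomeSurvivalScan(demo_sim.matrix, demo_sim.sample_table, cfg)
        res = model.fit()
        assert np.isfinite(res.scores).sum() > 0


class TestModelObject:
    def test_results_round_trip_and_summary(self, demo_model, tmp_path):
        res = demo_model.fit("logrank")
        out = tmp_path / "scan.txt"
        res.write(out)
        back = pd.read_csv(out, sep="\t")
        assert len(back) == res.n_tested
        assert "peak" in res.summary()

    def test_km_at_marker_gating(self, demo_sim, demo_model):
        res = demo_model.fit("logrank")
        peak = res.table.iloc[int(np.nanargmax(res.threshold_scores))]
        curves, lr = demo_model.km_at_marker(peak.marker_id)
        assert lr is not None and lr.eligible
        labels = {c.label for c in curves}
        assert "Deletion" in labels

    def test_misaligned_survival_rejected(self, demo_sim):
        data = sv.SurvivalData([1.0, 2.0], [1.0, 0.0])
        with pytest.raises(ValueError, match="align"):
            sv.GenomeSurvivalScan(demo_sim.matrix, data)
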
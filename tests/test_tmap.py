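"""Voxel-wise GLM t-maps, FWE threshold and cluster extraction."""

import collections

import numpy as np
import pytest
from scipy import optimize, stats

from dlbpet.phantom import AGE_REF, SubjectScan, make_atlas, make_control
from dlbpet.preprocess import preprocess_cohort
from dlbpet.tmap import (TMap, extent_voxels, extract_clusters,
                         fit_group_tmap, fit_subject_tmap, fwe_threshold)


def _voxel_scan(values, sid="s", age=65.0, cohort="control"):
    vol = np.asarray(values, dtype=float).reshape(1, 1, -1)
    return SubjectScan(volume=vol, voxel_size_mm=4.0, age=age,
                       subject_id=sid, cohort=cohort)


ONE_VOXEL_MASK = np.ones((1, 1, 1), bool)


class TestSubjectGLM:
    def test_template_patient_gives_zero_t(self, atlas):
        controls = [make_control(atlas, AGE_REF, seed=0, noise_sd=0.0,
                                 global_factor=1.0, subject_id=f"c{i}")
                    for i in range(12)]
        subject = make_control(atlas, AGE_REF, seed=1, noise_sd=0.0,
                               global_factor=1.0, subject_id="p")
        tm = fit_subject_tmap(subject, controls, atlas.brain, use_age=False)
        np.testing.assert_array_equal(tm.t, np.zeros(atlas.shape))
        assert tm.df == 12 + 1 - 2

    def test_matches_pooled_two_sample_t(self):
        """Direct two-sample oracle on a single voxel."""
        controls = [_voxel_scan([v], sid=f"c{i}")
                    for i, v in enumerate([1.0, 1.2, 0.8, 1.0, 1.0])]
        subject = _voxel_scan([0.5], sid="p")
        tm = fit_subject_tmap(subject, controls, ONE_VOXEL_MASK, use_age=False)
        res = stats.ttest_ind([1.0, 1.2, 0.8, 1.0, 1.0], [0.5])
        assert tm.t[0, 0, 0] == pytest.approx(res.statistic, rel=1e-12)
        assert tm.df == 4

    def test_age_covariate_absorbs_regional_age_effect(self):
        """An age-atypical but metabolically normal subject is cleared by
        the age-covariate model and flagged by the no-covariate model."""
        atlas = make_atlas()
        rng = np.random.default_rng(21)
        slope = -0.01
        controls = [make_control(atlas, float(rng.normal(AGE_REF, 5.0)),
                                 seed=3000 + i, age_slope=slope,
                                 subject_id=f"c{i}") for i in range(60)]
        subject = make_control(atlas, AGE_REF + 30.0, seed=4000,
                               age_slope=slope, subject_id="old")
        sc, sp, mask = preprocess_cohort(controls, [subject])
        with_age = fit_subject_tmap(sp[0], sc, mask, use_age=True)
        without = fit_subject_tmap(sp[0], sc, mask, use_age=False)
        thr_with = fwe_threshold(with_age, 0.05)
        thr_without = fwe_threshold(without, 0.05)
        assert (with_age.t < thr_with).all()
        assert (without.t >= thr_without).any()

    def test_constant_ages_with_covariate_raises(self):
        controls = [_voxel_scan([1.0 + 0.01 * i], sid=f"c{i}", age=70.0)
                    for i in range(12)]
        subject = _voxel_scan([0.9], sid="p", age=70.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_subject_tmap(subject, controls, ONE_VOXEL_MASK, use_age=True)

    def test_grid_mismatch_raises(self, atlas):
        controls = [make_control(atlas, 65.0, seed=i) for i in range(12)]
        bad = _voxel_scan([1.0], sid="bad")
        with pytest.raises(ValueError, match="grid mismatch"):
            fit_subject_tmap(bad, controls, atlas.brain)


class TestGroupGLM:
    def test_duplicated_template_patients_give_zero_t(self, atlas):
        controls = [make_control(atlas, AGE_REF, seed=0, noise_sd=0.0,
                                 global_factor=1.0, subject_id=f"c{i}")
                    for i in range(8)]
        patients = [make_control(atlas, AGE_REF, seed=0, noise_sd=0.0,
                                 global_factor=1.0, subject_id=f"p{i}")
                    for i in range(4)]
        tm = fit_group_tmap(patients, controls, atlas.brain, use_age=False)
        np.testing.assert_array_equal(tm.t, np.zeros(atlas.shape))
        assert tm.df == 12 - 2

    def test_label_swap_flips_sign(self, rng):
        controls = [_voxel_scan(rng.normal(1.0, 0.1, 5), sid=f"c{i}")
                    for i in range(6)]
        patients = [_voxel_scan(rng.normal(0.8, 0.1, 5), sid=f"p{i}")
                    for i in range(4)]
        mask = np.ones((1, 1, 5), bool)
        fwd = fit_group_tmap(patients, controls, mask, use_age=False)
        rev = fit_group_tmap(controls, patients, mask, use_age=False)
        np.testing.assert_allclose(fwd.t, -rev.t, rtol=1e-10)


class TestFWEThreshold:
    @staticmethod
    def _tmap(v, df):
        mask = np.ones((1, 1, v), bool)
        return TMap(t=np.zeros((1, 1, v)), df=df, mask=mask, n_controls=0,
                    n_test=1, used_age=False, voxel_size_mm=4.0)

    def test_single_voxel_is_plain_quantile(self):
        tm = self._tmap(1, 30)
        assert fwe_threshold(tm, 0.05) == pytest.approx(
            stats.t.isf(0.05, 30), rel=1e-12)

    def test_monotone_in_voxels_and_alpha(self):
        t_small = fwe_threshold(self._tmap(10, 40), 0.05)
        t_large = fwe_threshold(self._tmap(1000, 40), 0.05)
        assert t_large > t_small
        loose = fwe_threshold(self._tmap(100, 40), 0.10)
        strict = fwe_threshold(self._tmap(100, 40), 0.01)
        assert strict > loose

    def test_matches_independent_cdf_inversion(self):
        """Root-finding oracle on the Student CDF."""
        tm = self._tmap(30000, 110)
        thr = fwe_threshold(tm, 0.05)
        target = 0.05 / 30000
        oracle = optimize.brentq(lambda x: stats.t.sf(x, 110) - target, 0, 50,
                                 xtol=1e-10)
        assert thr == pytest.approx(oracle, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fwe_threshold(self._tmap(10, 40), 1.5)
        with pytest.raises(ValueError):
            fwe_threshold(self._tmap(10, 0), 0.05)


def _cluster_tmap(binary, voxel=4.0):
    t = np.where(binary, 10.0, 0.0)
    return TMap(t=t, df=40, mask=np.ones(binary.shape, bool), n_controls=40,
                n_test=1, used_age=False, voxel_size_mm=voxel)


class TestClusters:
    def test_empty_when_nothing_suprathreshold(self):
        cs = extract_clusters(_cluster_tmap(np.zeros((6, 6, 6), bool)), 5.0,
                              k=1)
        assert cs.n_clusters == 0

    def test_extent_boundary_inclusive(self):
        vol = np.zeros((20, 20, 20), bool)
        vol[1:5, 1:5, 1:5] = True          # 64 voxels
        vol[10:13, 10:13, 10:15] = True    # 45 voxels
        tm = _cluster_tmap(vol)
        keep_64 = extract_clusters(tm, 5.0, k=64)
        assert keep_64.sizes == [64]
        strict = extract_clusters(tm, 5.0, k=64, strict_gt=True)
        assert strict.n_clusters == 0
        both = extract_clusters(tm, 5.0, k=45)
        assert both.sizes == [64, 45]
        assert both.labels.max() == 2

    def test_default_extent_rescales_with_voxel_volume(self):
        assert extent_voxels(800.0, 2.0) == 100
        assert extent_voxels(800.0, 4.0) == 13  # ceil(800 / 64)

    def test_matches_flood_fill_oracle(self, rng):
        """Independent BFS flood fill on a random binary volume."""
        binary = rng.random((12, 12, 12)) < 0.3
        cs = extract_clusters(_cluster_tmap(binary), 5.0, k=1,
                              connectivity=6)
        # oracle: breadth-first flood fill, 6-connectivity
        seen = np.zeros(binary.shape, bool)
        components = []
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                   (0, 0, 1), (0, 0, -1)]
        for idx in np.argwhere(binary):
            idx = tuple(idx)
            if seen[idx]:
                continue
            queue, comp = collections.deque([idx]), set()
            seen[idx] = True
            while queue:
                cur = queue.popleft()
                comp.add(cur)
                for off in offsets:
                    nb = tuple(np.add(cur, off))
                    if all(0 <= nb[d] < binary.shape[d] for d in range(3)) \
                            and binary[nb] and not seen[nb]:
                        seen[nb] = True
                        queue.append(nb)
            components.append(comp)
        assert sorted(cs.sizes, reverse=True) == sorted(
            (len(c) for c in components), reverse=True)
        # identical partition: every labeled cluster is one oracle component
        for lab in range(1, cs.n_clusters + 1):
            voxels = {tuple(v) for v in np.argwhere(cs.labels == lab)}
            assert voxels in components

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError, match="connectivity"):
            extract_clusters(_cluster_tmap(np.zeros((4, 4, 4), bool)), 1.0,
                             k=1, connectivity=10)
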
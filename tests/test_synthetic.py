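"""Generator checks: mask construction, effect calibration, determinism,
and cohort/manifest structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comanet import SyntheticConfig, make_brain_mask, synthesize_cohort, synthesize_subject
from comanet.exceptions import ConfigurationError
from comanet.synthetic import cohort_table, roi_mask, _subject_rng

SMALL_GRID = (24, 24, 24)


class TestBrainMask:
    def test_volume_fraction_and_determinism(self):
        m1 = make_brain_mask((64, 64, 64), seed=0)
        m2 = make_brain_mask((64, 64, 64), seed=0)
        assert 0.3 <= m1.mean() <= 0.6
        assert np.array_equal(m1, m2)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            make_brain_mask((4, 64, 64), seed=0)

    def test_rois_inside_mask_and_disjoint(self):
        cfg = SyntheticConfig()
        mask = make_brain_mask(cfg.grid_shape, cfg.seed)
        rois = {n: roi_mask(cfg, n) for n in cfg.index_names}
        for n, r in rois.items():
            assert not (r & ~mask).any(), f"{n} ROI leaves the brain mask"
        names = list(rois)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not (rois[a] & rois[b]).any(), f"{a} and {b} ROIs overlap"


def _roi_means(cfg, n_subj, class_label, outcome, index="GM", key_base=0):
    roi = roi_mask(cfg, index)
    mask = make_brain_mask(cfg.grid_shape, cfg.seed)
    out = []
    for i in range(n_subj):
        rng = _subject_rng(cfg.seed, key_base + i, 0)
        vol = synthesize_subject(cfg, class_label, outcome, index, rng,
                                 brain_mask=mask)
        out.append(vol[roi].mean())
    return np.asarray(out)


class TestEffectInjection:
    def test_unknown_index_is_a_key_error(self):
        cfg = SyntheticConfig(grid_shape=SMALL_GRID)
        with pytest.raises(KeyError):
            synthesize_subject(cfg, "coma", None, "T2star", np.random.default_rng(0))

    def test_zero_effect_classes_indistinguishable(self):
        cfg = SyntheticConfig(grid_shape=SMALL_GRID,
                              effect_size_per_index={n: 0.0 for n in
                                                     SyntheticConfig().index_names})
        a = _roi_means(cfg, 30, "control", None)
        b = _roi_means(cfg, 30, "coma", "unfavorable", key_base=1000)
        assert stats.ttest_ind(a, b).pvalue > 0.01

    def test_effect_three_recovered_in_class_mean_difference(self):
        """Monte-Carlo oracle: with effect 3 and noise SD 1 the difference
        of class means inside the ROI is 3 within sampling error."""
        cfg = SyntheticConfig(grid_shape=SMALL_GRID, noise_sd=1.0)
        a = _roi_means(cfg, 100, "control", None)
        b = _roi_means(cfg, 100, "coma", "unfavorable", key_base=1000)
        diff = b.mean() - a.mean()
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert diff == pytest.approx(3.0, abs=max(4 * se, 0.1))

    def test_full_attenuation_makes_favorable_patients_look_like_controls(self):
        cfg = SyntheticConfig(grid_shape=SMALL_GRID,
                              effect_attenuation_for_favorable=0.0)
        a = _roi_means(cfg, 60, "control", None)
        b = _roi_means(cfg, 60, "coma", "favorable", key_base=1000)
        assert stats.ttest_ind(a, b).pvalue > 0.01


class TestCohort:
    def test_default_counts_and_outcome_fraction(self, tmp_path):
        cfg = SyntheticConfig(grid_shape=(16, 16, 16), seed=3)
        manifest, truth = synthesize_cohort(cfg, tmp_path / "c")
        assert len(manifest) == (34 + 29) * 6
        assert manifest["subject_id"].nunique() == 63
        pat = truth.table[truth.table["class"] == "coma"]
        assert (pat["outcome"] == "favorable").sum() == round(0.5 * 29)

    def test_all_favorable_when_fraction_is_one(self):
        cfg = SyntheticConfig(grid_shape=(16, 16, 16),
                              fraction_favorable_outcome=1.0)
        t = cohort_table(cfg)
        pat = t[t["class"] == "coma"]
        assert (pat["outcome"] == "favorable").all()

    def test_same_seed_gives_byte_identical_manifests_and_volumes(self, tmp_path):
        cfg = SyntheticConfig(grid_shape=(16, 16, 16), n_controls=2,
                              n_patients=2, seed=11)
        synthesize_cohort(cfg, tmp_path / "a")
        synthesize_cohort(cfg, tmp_path / "b")
        ma = (tmp_path / "a" / "manifest.csv").read_bytes()
        mb = (tmp_path / "b" / "manifest.csv").read_bytes()
        assert ma == mb
        va = (tmp_path / "a" / "volumes" / "patient-01_GM.nii").read_bytes()
        vb = (tmp_path / "b" / "volumes" / "patient-01_GM.nii").read_bytes()
        assert va == vb

    def test_generation_order_does_not_matter(self):
        """Counter-based substreams: a subject's volume does not depend on
        which subjects were generated before it."""
        cfg = SyntheticConfig(grid_shape=SMALL_GRID, n_controls=2, n_patients=2)
        rng_a = _subject_rng(cfg.seed, 3, 2)
        rng_b = _subject_rng(cfg.seed, 3, 2)
        va = synthesize_subject(cfg, "coma", "unfavorable", cfg.index_names[2], rng_a)
        _ = synthesize_subject(cfg, "control", None, "GM", _subject_rng(cfg.seed, 0, 0))
        vb = synthesize_subject(cfg, "coma", "unfavorable", cfg.index_names[2], rng_b)
        assert np.array_equal(va, vb)
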
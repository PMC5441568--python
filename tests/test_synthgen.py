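import numpy as np
import pytest
from scipy import stats as sstats
from scipy.signal import periodogram

from icnpipe import classify, synthgen
from icnpipe.errors import InvalidConfigurationError, InvalidInputError
from tests.conftest import truth_features


class TestMakeAtlas:
    def test_dispersed_maps(self):
        atlas = synthgen.make_atlas((16, 16, 8), k=20, seed=1)
        assert atlas.maps.shape == (20, 16 * 16 * 8)
        assert np.all(atlas.maps >= 0)
        assert np.allclose(atlas.maps.max(axis=1), 1.0)
        corr = np.corrcoef(atlas.maps)
        off = corr[~np.eye(20, dtype=bool)]
        assert np.all(np.abs(off) < 0.3)

    def test_determinism(self):
        a = synthgen.make_atlas((16, 16, 8), k=20, seed=1)
        b = synthgen.make_atlas((16, 16, 8), k=20, seed=1)
        assert np.array_equal(a.maps, b.maps)
        assert a.labels == b.labels

    def test_seed_changes_atlas(self):
        a = synthgen.make_atlas((16, 16, 8), k=20, seed=1)
        b = synthgen.make_atlas((16, 16, 8), k=20, seed=2)
        assert not np.array_equal(a.maps, b.maps)

    def test_grid_too_small(self):
        with pytest.raises(InvalidConfigurationError):
            synthgen.make_atlas((4, 4, 1), k=20, seed=1)

    def test_k_too_small(self):
        with pytest.raises(InvalidConfigurationError):
            synthgen.make_atlas((16, 16, 8), k=1, seed=1)

    def test_anchor_labels(self):
        atlas = synthgen.make_atlas((16, 16, 8), k=6, seed=0)
        assert atlas.labels[atlas.anchor_indices["DMN"]] == "DMN"
        assert atlas.labels[atlas.anchor_indices["MTL"]] == "MTL"
        assert len(atlas.affected_default) == 6


class TestTimeCourses:
    def test_band_power_fraction(self):
        tc = synthgen.simulate_time_courses(20, 240, 2.0, seed=7)
        assert tc.shape == (20, 240)
        freqs, power = periodogram(tc, fs=0.5, axis=1)
        band = (freqs >= 0.01) & (freqs <= 0.08)
        frac = power[:, band].sum(axis=1) / power.sum(axis=1)
        assert np.all(frac >= 0.8)

    def test_moments(self):
        tc = synthgen.simulate_time_courses(5, 120, 2.0, seed=3)
        assert np.all(np.abs(tc.mean(axis=1)) < 1e-10)
        assert np.all(np.abs(tc.var(axis=1) - 1.0) < 1e-10)

    def test_near_orthogonal_rows(self):
        tc = synthgen.simulate_time_courses(12, 240, 2.0, seed=1)
        corr = np.corrcoef(tc)
        assert np.all(np.abs(corr[~np.eye(12, dtype=bool)]) < 0.2)

    def test_too_few_volumes(self):
        with pytest.raises(InvalidConfigurationError):
            synthgen.simulate_time_courses(2, 10, 2.0, seed=0)

    def test_determinism(self):
        a = synthgen.simulate_time_courses(4, 60, 2.0, seed=9)
        b = synthgen.simulate_time_courses(4, 60, 2.0, seed=9)
        assert np.array_equal(a, b)


class TestCohortConfig:
    def test_defaults_match_study_design(self):
        cfg = synthgen.CohortConfig()
        assert (cfg.n_patients, cfg.n_controls) == (34, 34)
        assert (cfg.n_followup_ect, cfg.n_followup_med) == (13, 16)
        assert cfg.n_volumes == 240
        assert cfg.tr_seconds == 2.0
        assert cfg.k_components == 20
        assert len(cfg.affected) == 6
        cfg.validate()

    def test_negative_delta_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            synthgen.CohortConfig(delta=-1.0).validate()

    def test_affected_out_of_range(self):
        with pytest.raises(InvalidConfigurationError):
            synthgen.CohortConfig(k_components=4, affected=(0, 9)).validate()


class TestSimulateCohort:
    def test_structure(self, tiny_cohort):
        co = tiny_cohort
        assert len(co.baseline_scans()) == 8
        assert len(co.followup_scans()) == 3
        base_ids = {s.subject_id for s in co.baseline_scans()}
        for s in co.followup_scans():
            assert s.subject_id in base_ids
        arms = co.records[co.records.session == "baseline"].set_index("subject_id").arm
        assert (arms == "ECT").sum() == 2
        assert (arms == "MED").sum() == 1

    def test_records_schema(self, tiny_cohort):
        from icnpipe.io import PHENOTYPE_COLUMNS

        assert list(tiny_cohort.records.columns) == PHENOTYPE_COLUMNS
        base = tiny_cohort.records[tiny_cohort.records.session == "baseline"]
        assert set(base.group) == {"patient", "control"}
        controls = base[base.group == "control"]
        assert controls.panss_total.isna().all()

    def test_truth_supports_recovery(self, tiny_cohort):
        t = tiny_cohort.truth
        assert set(t.rho) == set(t.loadings_followup)
        for sid, rho in t.rho.items():
            b0 = t.loadings_baseline[sid][list(t.affected)]
            b1 = t.loadings_followup[sid][list(t.affected)]
            assert np.allclose(b1, (1 - rho) * b0)

    def test_followup_panss_matches_truth_response(self, tiny_cohort):
        rec = tiny_cohort.records
        base = rec[rec.session == "baseline"].set_index("subject_id")
        post = rec[rec.session == "followup"].set_index("subject_id")
        for sid, resp in tiny_cohort.truth.response.items():
            expect = (base.loc[sid].panss_total - post.loc[sid].panss_total) / base.loc[
                sid
            ].panss_total
            assert resp == pytest.approx(expect)

    def test_determinism(self, atlas8):
        cfg = synthgen.CohortConfig(
            n_patients=2, n_controls=2, n_followup_ect=1, n_followup_med=0,
            n_volumes=40, k_components=8, affected=(0, 1), seed=11,
        )
        a = synthgen.simulate_cohort(atlas8, cfg)
        b = synthgen.simulate_cohort(atlas8, cfg)
        for sa, sb in zip(a.scans, b.scans):
            assert np.array_equal(sa.data, sb.data)
        assert a.records.equals(b.records)

    def test_delta_zero_group_distributions_match(self, atlas8):
        cfg = synthgen.CohortConfig(
            n_patients=40, n_controls=40, n_followup_ect=0, n_followup_med=0,
            n_volumes=30, k_components=8, affected=(0, 1, 2, 3), delta=0.0, seed=2,
        )
        co = synthgen.simulate_cohort(atlas8, cfg)
        signs = co.truth.signs[:4]
        proj = {
            g: np.array(
                [
                    co.truth.loadings_baseline[sid][:4] @ signs
                    for sid in co.truth.loadings_baseline
                    if sid.startswith(g)
                ]
            )
            for g in ("P", "C")
        }
        assert sstats.ks_2samp(proj["P"], proj["C"]).pvalue > 1e-3

    def test_affected_mismatch_with_atlas(self, atlas8):
        cfg = synthgen.CohortConfig(
            n_patients=2, n_controls=2, n_followup_ect=0, n_followup_med=0,
            n_volumes=40, k_components=10, affected=(0, 9), seed=0,
        )
        with pytest.raises(InvalidConfigurationError):
            synthgen.simulate_cohort(atlas8, cfg)

    def test_panss_baseline_near_printed_profile(self, atlas8):
        cfg = synthgen.CohortConfig(
            n_patients=30, n_controls=1, n_followup_ect=0, n_followup_med=0,
            n_volumes=30, k_components=8, affected=(), seed=4,
        )
        co = synthgen.simulate_cohort(atlas8, cfg)
        base = co.records[
            (co.records.session == "baseline") & (co.records.group == "patient")
        ]
        assert abs(base.panss_total.mean() - 80.59) < 5.0
        assert np.allclose(
            base.panss_pos + base.panss_neg + base.panss_gen, base.panss_total
        )
        assert base.panss_total.between(30, 210).all()


class TestWriteCohort:
    def test_manifest_and_files(self, tiny_cohort, tmp_path):
        manifest = synthgen.write_cohort(tiny_cohort, tmp_path / "cohort")
        d = tmp_path / "cohort"
        niftis = sorted(d.glob("*_bold.nii"))
        assert len(niftis) == 11  # 8 baseline + 3 follow-up
        assert (d / "phenotypes.csv").exists()
        assert (d / "truth.csv").exists()
        assert (d / "manifest.json").exists()
        assert manifest["n_scans"] == 11

    def test_roundtrip_precision(self, tiny_cohort, tmp_path):
        from icnpipe import io as cio

        synthgen.write_cohort(tiny_cohort, tmp_path / "c")
        scan = tiny_cohort.scans[0]
        back = cio.read_scan(
            tmp_path / "c" / f"sub-{scan.subject_id}_ses-{scan.session}_bold.nii"
        )
        assert np.max(np.abs(back.data - scan.data)) < 1e-6
        assert back.tr_seconds == pytest.approx(scan.tr_seconds)
        assert back.subject_id == scan.subject_id
        assert back.session == scan.session

    def test_empty_cohort_rejected(self, tiny_cohort, tmp_path):
        import dataclasses

        empty = dataclasses.replace(tiny_cohort, scans=[])
        with pytest.raises(InvalidInputError):
            synthgen.write_cohort(empty, tmp_path / "x")


@pytest.mark.slow
def test_accuracy_monotone_in_delta(small_grid):
    """LOO ensemble accuracy is non-decreasing across delta in {0, mid, large}
    by majority vote over 3 seeds (planted-truth feature route)."""
    atlas = synthgen.make_atlas((16, 16, 8), 8, seed=1)
    accs = np.zeros((3, 3))
    for i, delta in enumerate((0.0, 0.8, 2.0)):
        for j, seed in enumerate((1, 2, 3)):
            cfg = synthgen.CohortConfig(
                n_patients=8, n_controls=8, n_followup_ect=0, n_followup_med=0,
                n_volumes=30, k_components=8, affected=(0, 1, 2, 3), delta=delta,
                affected_anticorr=1.0, affected_within_sd=1.5,
                affected_indep_sd=0.3, seed=seed,
            )
            co = synthgen.simulate_cohort(atlas, cfg)
            fs, y = truth_features(co)
            _, m = classify.loo_ensemble(fs, y, anchors=(0, 1), grid=small_grid)
            accs[i, j] = m.accuracy
    assert np.median(accs[1] - accs[0]) >= 0
    assert np.median(accs[2] - accs[1]) >= 0
    assert np.median(accs[2]) >= 0.8
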
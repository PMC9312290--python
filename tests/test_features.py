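"""Feature-catalog contracts: counts, oracles, unit/scale behaviour."""

import numpy as np
import pytest

from ecgfusion import complexity as cx
from ecgfusion.catalog import (FAMILY_COUNTS, FEATURE_CATEGORY, FEATURE_NAMES,
                               manifest)
from ecgfusion.features import (FeatureVector, InsufficientBeatsError, ZParams,
                                build_window_matrix, extract_all,
                                extract_frequency_domain, extract_morphological,
                                extract_nonlinear, extract_time_domain)
from ecgfusion.fiducial import FiducialPoints, extract_fiducials
from ecgfusion.synthetic import TEMPLATE, default_spec, generate_record


def _fid_from_rr(rr_s, fs=500.0):
    r = np.cumsum(np.concatenate([[1.0], rr_s])) * fs
    r = r.astype(int)
    n = r.size
    absent = np.full(n, -1)
    return FiducialPoints(r_idx=r, q_idx=absent, s_idx=absent, p_idx=absent,
                          t_idx=absent, fs=fs)


class TestCatalog:
    def test_counts_are_frozen(self):
        assert len(FEATURE_NAMES) == 118
        assert len(set(FEATURE_NAMES)) == 118
        counts = {fam: sum(1 for n in FEATURE_NAMES
                           if FEATURE_CATEGORY[n] == fam)
                  for fam in FAMILY_COUNTS}
        assert counts == {"time_domain": 27, "frequency_domain": 35,
                          "morphological": 30, "nonlinear": 26}

    def test_manifest_has_units_and_definitions(self):
        entries = manifest()
        assert len(entries) == 118
        assert all(e["unit"] and e["definition"] for e in entries)


class TestTimeDomain:
    def test_constant_rr_sequence(self):
        feats = extract_time_domain(_fid_from_rr([1.0] * 6))
        assert feats["td_rr_min"] == feats["td_rr_max"] == pytest.approx(1.0)
        assert feats["td_rr_mean"] == pytest.approx(1.0)
        assert feats["td_rr_rmssd"] == pytest.approx(0.0)
        assert feats["td_rr_sd"] == pytest.approx(0.0)

    def test_rmssd_hand_computed(self):
        # RR (0.8, 1.0, 1.2): successive diffs 0.2, 0.2 -> RMSSD = 0.2
        feats = extract_time_domain(_fid_from_rr([0.8, 1.0, 1.2]))
        assert feats["td_rr_rmssd"] == pytest.approx(0.2, abs=1e-2)

    def test_median_heart_rate_60bpm(self, normal_jittered_record):
        fid = extract_fiducials(normal_jittered_record)
        feats = extract_time_domain(fid)
        assert feats["td_hr_median"] == pytest.approx(60.0, abs=1.0)

    def test_too_few_beats_rejected(self):
        with pytest.raises(InsufficientBeatsError):
            extract_time_domain(_fid_from_rr([1.0]))


class TestFrequencyDomain:
    def test_sinusoid_centroid_at_line_frequency(self):
        t = np.arange(5000) / 500.0
        feats = extract_frequency_domain(np.sin(2 * np.pi * 10.0 * t), 500.0)
        assert feats["fd_spectral_centroid"] == pytest.approx(10.0, abs=1.0)
        assert feats["fd_spectral_peak_freq"] == pytest.approx(10.0, abs=1.0)

    def test_white_noise_band_powers_proportional_to_width(self):
        rng = np.random.default_rng(0)
        nbp = {"low": [], "high": []}
        for _ in range(100):
            feats = extract_frequency_domain(rng.standard_normal(1000), 500.0)
            nbp["low"].append(feats["fd_nbp_low"])
            nbp["high"].append(feats["fd_nbp_high"])
        # flat spectrum: normalized power ~ bandwidth / nyquist
        assert np.mean(nbp["low"]) == pytest.approx(4.5 / 250.0, rel=0.15)
        assert np.mean(nbp["high"]) == pytest.approx(25.0 / 250.0, rel=0.15)

    def test_normalized_band_powers_sum_to_one(self, normal_record):
        feats = extract_frequency_domain(normal_record.lead("II"), 500.0)
        total = sum(feats[f"fd_nbp_{b}"] for b in
                    ("vlf", "low", "mid", "high", "vhigh", "ultra"))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_window_convention(self):
        feats = extract_frequency_domain(np.zeros(1000), 500.0)
        for b in ("vlf", "low", "mid", "high", "vhigh", "ultra"):
            assert feats[f"fd_bp_{b}"] == 0.0
            assert feats[f"fd_nbp_{b}"] == 0.0
        assert np.isnan(feats["fd_spectral_centroid"])


class TestMorphological:
    def test_template_amplitudes_recovered(self, normal_record,
                                           normal_fiducials):
        sig = normal_record.lead("II")
        feats = extract_morphological(sig, normal_fiducials, 500.0)
        # oracle: evaluate the 5-Gaussian template sum at each bump argmin/max
        t = np.arange(-0.45, 0.45, 0.002)
        tpl = sum(a * np.exp(-0.5 * ((t - mu) / s) ** 2)
                  for mu, a, s in TEMPLATE.values())
        assert feats["mg_r_amp_mean"] == pytest.approx(tpl.max(), abs=0.02)
        assert feats["mg_q_depth_mean"] == pytest.approx(
            tpl[t < 0].min(), abs=0.02)

    def test_pvc_widens_mean_qrs(self, normal_record, normal_fiducials):
        pvc = generate_record(default_spec("PVC", 60.0), 10.0, 500.0, 0.0,
                              seed=3)
        fid = extract_fiducials(pvc)
        f_pvc = extract_morphological(pvc.lead("II"), fid, 500.0)
        f_n = extract_morphological(normal_record.lead("II"),
                                    normal_fiducials, 500.0)
        assert f_pvc["mg_qrs_width_mean"] > f_n["mg_qrs_width_mean"]

    def test_flat_st_segment_has_zero_slope(self, normal_record,
                                            normal_fiducials):
        feats = extract_morphological(normal_record.lead("II"),
                                      normal_fiducials, 500.0)
        # template S and T bumps leave the 20-80 ms post-S segment nearly flat
        assert abs(feats["mg_st_slope_mean"]) < 2.0

    def test_no_complete_beat_rejected(self):
        fid = FiducialPoints(r_idx=[100], q_idx=[-1], s_idx=[-1], p_idx=[-1],
                             t_idx=[-1], fs=500.0)
        with pytest.raises(InsufficientBeatsError):
            extract_morphological(np.zeros(1000), fid, 500.0)


class TestNonlinear:
    def test_constant_series_sample_entropy_zero(self):
        assert cx.sample_entropy(np.ones(100), 2) == pytest.approx(0.0)

    def test_periodic_less_complex_than_noise(self):
        rng = np.random.default_rng(1)
        periodic = np.sin(np.linspace(0, 40 * np.pi, 400))
        noise = rng.standard_normal(400)
        assert (cx.sample_entropy(periodic, 2, 0.2 * periodic.std())
                < cx.sample_entropy(noise, 2, 0.2 * noise.std()))

    def test_sampen_matches_brute_force_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 2.0, 1.0, 2.0, 3.0, 2.0, 1.0, 2.5])
        m, r = 2, 0.2 * np.std(x)

        def brute(m_):
            count = 0
            n = x.size - m  # compare equal numbers of templates
            for i in range(n):
                for j in range(i + 1, n):
                    if max(abs(x[i + k] - x[j + k]) for k in range(m_)) <= r:
                        count += 1
            return count

        b, a = brute(m), brute(m + 1)
        assert cx.sample_entropy(x, m, r) == pytest.approx(
            -np.log(a / b), abs=1e-10)

    def test_full_nonlinear_family_size(self, normal_record):
        fid = extract_fiducials(normal_record)
        feats = extract_nonlinear(normal_record.lead("II"), 500.0,
                                  rr=fid.rr_intervals_s)
        assert len(feats) == 26


class TestExtractAll:
    def test_length_and_category_counts(self, normal_jittered_record):
        fv = extract_all(normal_jittered_record)
        assert len(fv.values) == 118
        from collections import Counter
        assert Counter(fv.categories) == {"time_domain": 27,
                                          "frequency_domain": 35,
                                          "morphological": 30,
                                          "nonlinear": 26}

    def test_deterministic(self, normal_jittered_record):
        a = extract_all(normal_jittered_record).values
        b = extract_all(normal_jittered_record).values
        np.testing.assert_array_equal(a, b)

    def test_amplitude_scaling_audit(self, normal_jittered_record):
        rec = normal_jittered_record
        import copy
        rec2 = copy.copy(rec)
        rec2.signal = 2.0 * rec.signal
        a = extract_all(rec).as_dict()
        b = extract_all(rec2).as_dict()
        # RR-based time-domain features are amplitude invariant
        for k in ("td_rr_mean", "td_rr_rmssd", "td_hr_median"):
            assert b[k] == pytest.approx(a[k], rel=1e-9)
        # morphological amplitudes scale linearly
        for k in ("mg_r_amp_mean", "mg_q_depth_mean", "mg_t_amp_mean"):
            assert b[k] == pytest.approx(2.0 * a[k], rel=1e-6)


class TestWindowMatrix:
    def test_row_count(self, normal_jittered_record):
        wm = build_window_matrix(normal_jittered_record,
                                 ["fd_spectral_centroid"], 2.0, 1.0)
        assert wm.X.shape[0] == 9  # floor((10 - 2)/1) + 1

    def test_self_fit_zscore_columns(self, normal_jittered_record):
        sel = ["fd_spectral_centroid", "fd_total_power", "mg_r_amp_mean"]
        wm = build_window_matrix(normal_jittered_record, sel, 2.0, 1.0)
        z = ZParams.fit(wm.X, wm.colnames)
        Xz = z.transform(wm.X)
        np.testing.assert_allclose(Xz.mean(axis=0), 0.0, atol=1e-9)
        varying = wm.X.std(axis=0) > 1e-9 * np.abs(wm.X.mean(axis=0))
        np.testing.assert_allclose(Xz.std(axis=0)[varying], 1.0, atol=1e-9)

    def test_empty_selection_rejected(self, normal_jittered_record):
        with pytest.raises(ValueError):
            build_window_matrix(normal_jittered_record, [], 2.0, 1.0)

    def test_unknown_feature_rejected(self, normal_jittered_record):
        with pytest.raises(ValueError):
            build_window_matrix(normal_jittered_record, ["nope"], 2.0, 1.0)
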
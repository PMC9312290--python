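"""The frozen 118-attribute feature catalog.

Four families with fixed cardinalities — 27 time-domain (RR-interval
statistics), 35 frequency-domain (periodogram + wavelet sub-band
statistics of the analysis-lead window), 30 morphological (per-beat
wave amplitude/interval statistics, mean and SD over beats) and 26
nonlinear (entropy, fractal, Poincare, Hjorth measures).  The handful of
attributes the source taxonomy names explicitly (RR min/max, median heart
rate, RMSSD, spectral centroid, normalized LF/HF power, wavelet
coefficients, Q/R/S depth, ST slope, QRS width, sample/approximate/fuzzy
entropy) anchor each family; the remainder are standard HRV/spectral/
morphology/complexity measures filling the family to its fixed count.

Order and names are versioned: downstream models address features by
name, and the manifest is part of every experiment's provenance.
"""

from __future__ import annotations

import json

CATALOG_VERSION = "1.0"

TIME_DOMAIN = [
    ("td_rr_min", "s", "minimum RR interval"),
    ("td_rr_max", "s", "maximum RR interval"),
    ("td_rr_mean", "s", "mean RR interval"),
    ("td_rr_median", "s", "median RR interval"),
    ("td_rr_sd", "s", "SD of RR intervals (SDNN)"),
    ("td_rr_range", "s", "RR max - min"),
    ("td_rr_cv", "1", "RR coefficient of variation"),
    ("td_rr_rmssd", "s", "root mean square of successive RR differences"),
    ("td_rr_sdsd", "s", "SD of successive RR differences"),
    ("td_rr_pnn20", "1", "fraction of successive RR differences > 20 ms"),
    ("td_rr_pnn50", "1", "fraction of successive RR differences > 50 ms"),
    ("td_rr_p10", "s", "10th percentile of RR"),
    ("td_rr_p25", "s", "25th percentile of RR"),
    ("td_rr_p75", "s", "75th percentile of RR"),
    ("td_rr_p90", "s", "90th percentile of RR"),
    ("td_rr_iqr", "s", "RR interquartile range"),
    ("td_rr_skewness", "1", "skewness of RR"),
    ("td_rr_kurtosis", "1", "excess kurtosis of RR"),
    ("td_rr_mad", "s", "median absolute deviation of RR"),
    ("td_rr_diff_max", "s", "largest absolute successive RR difference"),
    ("td_rr_frac_accel", "1", "fraction of successive RR differences < 0"),
    ("td_hr_mean", "bpm", "mean heart rate"),
    ("td_hr_median", "bpm", "median heart rate"),
    ("td_hr_min", "bpm", "minimum heart rate"),
    ("td_hr_max", "bpm", "maximum heart rate"),
    ("td_hr_sd", "bpm", "SD of heart rate"),
    ("td_beat_count", "count", "number of detected beats"),
]

_BANDS = [("vlf", 0.0, 0.5), ("low", 0.5, 5.0), ("mid", 5.0, 15.0),
          ("high", 15.0, 40.0), ("vhigh", 40.0, 100.0), ("ultra", 100.0, None)]

FREQUENCY_DOMAIN = (
    [("fd_total_power", "mV^2", "total periodogram power")]
    + [(f"fd_bp_{b}", "mV^2", f"absolute power, {b} band") for b, *_ in _BANDS]
    + [(f"fd_nbp_{b}", "1", f"normalized power, {b} band") for b, *_ in _BANDS]
    + [
        ("fd_lf_hf_ratio", "1", "low-band to high-band power ratio"),
        ("fd_spectral_centroid", "Hz", "power-weighted mean frequency"),
        ("fd_spectral_spread", "Hz", "power-weighted SD of frequency"),
        ("fd_spectral_skewness", "1", "spectral skewness"),
        ("fd_spectral_kurtosis", "1", "spectral excess kurtosis"),
        ("fd_spectral_entropy", "1", "normalized spectral Shannon entropy"),
        ("fd_spectral_flatness", "1", "geometric/arithmetic spectral mean"),
        ("fd_spectral_rolloff85", "Hz", "85% cumulative-power frequency"),
        ("fd_spectral_rolloff95", "Hz", "95% cumulative-power frequency"),
        ("fd_spectral_peak_freq", "Hz", "frequency of the spectral peak"),
        ("fd_spectral_peak_power", "mV^2/Hz", "power at the spectral peak"),
        ("fd_median_freq", "Hz", "50% cumulative-power frequency"),
        ("fd_spectral_crest", "1", "peak power / mean power"),
        ("fd_spectral_slope", "mV^2/Hz^2", "linear slope of the spectrum"),
    ]
    + [(f"fd_wv_rel_energy_{lvl}", "1", f"relative wavelet energy, {lvl}")
       for lvl in ("a5", "d5", "d4", "d3", "d2", "d1")]
    + [
        ("fd_wv_entropy", "1", "Shannon entropy of wavelet sub-band energies"),
        ("fd_wv_total_energy", "mV^2", "total wavelet coefficient energy"),
    ]
)

_MORPH_QUANTITIES = [
    ("r_amp", "mV", "R-wave amplitude"),
    ("q_depth", "mV", "Q-wave amplitude (signed depth)"),
    ("s_depth", "mV", "S-wave amplitude (signed depth)"),
    ("p_amp", "mV", "P-wave amplitude"),
    ("t_amp", "mV", "T-wave amplitude"),
    ("qrs_width", "s", "QRS width (S - Q)/fs"),
    ("pr_interval", "s", "P-to-R interval"),
    ("qt_interval", "s", "Q-to-T interval"),
    ("st_slope", "mV/s", "ST-segment slope"),
    ("st_level", "mV", "ST-segment level vs PR baseline"),
    ("rs_ratio", "1", "|R| / |S| amplitude ratio"),
    ("rt_ratio", "1", "|R| / |T| amplitude ratio"),
    ("qrs_area", "mV*s", "area under |signal| across QRS"),
    ("r_sharpness", "mV", "negative second difference at R"),
    ("beat_energy", "mV^2", "mean squared signal over the beat"),
]

MORPHOLOGICAL = [(f"mg_{q}_{stat}", unit, f"{stat} over beats of {desc}")
                 for q, unit, desc in _MORPH_QUANTITIES
                 for stat in ("mean", "sd")]

_ENTROPY_GRID = [("m2_r015", 2, 0.15), ("m2_r020", 2, 0.20),
                 ("m2_r025", 2, 0.25), ("m3_r020", 3, 0.20)]

NONLINEAR = (
    [(f"nl_sampen_{tag}", "1", f"sample entropy, m={m}, r={r}*SD")
     for tag, m, r in _ENTROPY_GRID]
    + [(f"nl_apen_{tag}", "1", f"approximate entropy, m={m}, r={r}*SD")
       for tag, m, r in _ENTROPY_GRID]
    + [(f"nl_fuzzyen_{tag}", "1", f"fuzzy entropy, m={m}, r={r}*SD")
       for tag, m, r in _ENTROPY_GRID]
    + [
        ("nl_higuchi_fd", "1", "Higuchi fractal dimension"),
        ("nl_katz_fd", "1", "Katz fractal dimension"),
        ("nl_petrosian_fd", "1", "Petrosian fractal dimension"),
        ("nl_dfa_alpha1", "1", "short-range DFA exponent"),
        ("nl_poincare_sd1", "s", "Poincare SD1 of RR"),
        ("nl_poincare_sd2", "s", "Poincare SD2 of RR"),
        ("nl_poincare_ratio", "1", "Poincare SD2/SD1"),
        ("nl_poincare_area", "s^2", "Poincare ellipse area"),
        ("nl_rr_sampen", "1", "sample entropy of the RR sequence"),
        ("nl_rr_shannon", "nat", "Shannon entropy of the RR histogram"),
        ("nl_hjorth_mobility", "1", "Hjorth mobility of the signal"),
        ("nl_hjorth_complexity", "1", "Hjorth complexity of the signal"),
        ("nl_zero_cross_rate", "1", "signal zero-crossing rate"),
        ("nl_turning_point_ratio", "1", "fraction of local extrema"),
    ]
)

FAMILIES = {
    "time_domain": TIME_DOMAIN,
    "frequency_domain": FREQUENCY_DOMAIN,
    "morphological": MORPHOLOGICAL,
    "nonlinear": NONLINEAR,
}

FAMILY_COUNTS = {"time_domain": 27, "frequency_domain": 35,
                 "morphological": 30, "nonlinear": 26}

FEATURE_NAMES = [name for fam in ("time_domain", "frequency_domain",
                                  "morphological", "nonlinear")
                 for name, _, _ in FAMILIES[fam]]

FEATURE_CATEGORY = {name: fam for fam, entries in FAMILIES.items()
                    for name, _, _ in entries}

N_FEATURES = len(FEATURE_NAMES)

for fam, count in FAMILY_COUNTS.items():
    assert len(FAMILIES[fam]) == count, (fam, len(FAMILIES[fam]))
assert N_FEATURES == 118
assert len(set(FEATURE_NAMES)) == 118


def manifest() -> list[dict]:
    """The catalog as a list of {name, category, unit, definition} dicts."""
    return [{"name": name, "category": fam, "unit": unit, "definition": desc}
            for fam in ("time_domain", "frequency_domain", "morphological",
                        "nonlinear")
            for name, unit, desc in FAMILIES[fam]]


def write_manifest(path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"version": CATALOG_VERSION, "features": manifest()}, fh,
                  indent=1)
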
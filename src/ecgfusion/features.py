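"""Feature extraction: the 118-attribute catalog and the window matrix.

``extract_all`` computes the full catalog on one record (time-domain RR
statistics, spectral/wavelet statistics of the analysis lead, per-beat
morphology aggregated over beats, nonlinear complexity measures) in the
frozen catalog order.  ``build_window_matrix`` slides a window over the
record and re-computes a selected feature subset per window, yielding the
two-dimensional (timestamps x attributes) matrix the fusion classifier
consumes; its first column is the window's RMS signal amplitude.

Sentinel policy: a feature that is undefined on a given input (too few
beats in a window, zero-power spectrum, ...) is reported as NaN here and
imputed with the *training-set* column median before any modeling; no NaN
ever reaches the linear algebra downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps
from scipy import stats

from ecgfusion import complexity as cx
from ecgfusion.catalog import (_BANDS, _ENTROPY_GRID, _MORPH_QUANTITIES,
                               FAMILY_COUNTS, FEATURE_CATEGORY, FEATURE_NAMES,
                               CATALOG_VERSION)
from ecgfusion.fiducial import ABSENT, FiducialPoints, extract_fiducials

#: sampling rate the signal is decimated to before O(N^2) entropy estimates
ENTROPY_FS = 100.0


class InsufficientBeatsError(ValueError):
    pass


class FeatureExtractionError(RuntimeError):
    """Wraps a sub-extractor failure with feature-family context."""

    def __init__(self, family, cause):
        super().__init__(f"{family}: {cause}")
        self.family = family
        self.cause = cause


# --------------------------------------------------------------------------
# time domain — RR interval statistics
# --------------------------------------------------------------------------

def extract_time_domain(fiducials: FiducialPoints, fs: float | None = None) -> dict:
    """27 RR-interval statistics.  Requires >= 3 beats."""
    if len(fiducials) < 3:
        raise InsufficientBeatsError("time-domain features need >= 3 beats")
    rr = fiducials.rr_intervals_s
    drr = np.diff(rr)
    hr = 60.0 / rr
    out = {
        "td_rr_min": rr.min(),
        "td_rr_max": rr.max(),
        "td_rr_mean": rr.mean(),
        "td_rr_median": np.median(rr),
        "td_rr_sd": rr.std(),
        "td_rr_range": np.ptp(rr),
        "td_rr_cv": rr.std() / rr.mean(),
        "td_rr_rmssd": np.sqrt(np.mean(drr ** 2)) if drr.size else np.nan,
        "td_rr_sdsd": drr.std() if drr.size else np.nan,
        "td_rr_pnn20": np.mean(np.abs(drr) > 0.020) if drr.size else np.nan,
        "td_rr_pnn50": np.mean(np.abs(drr) > 0.050) if drr.size else np.nan,
        "td_rr_p10": np.percentile(rr, 10),
        "td_rr_p25": np.percentile(rr, 25),
        "td_rr_p75": np.percentile(rr, 75),
        "td_rr_p90": np.percentile(rr, 90),
        "td_rr_iqr": np.percentile(rr, 75) - np.percentile(rr, 25),
        "td_rr_skewness": stats.skew(rr) if rr.size > 2 else np.nan,
        "td_rr_kurtosis": stats.kurtosis(rr) if rr.size > 2 else np.nan,
        "td_rr_mad": np.median(np.abs(rr - np.median(rr))),
        "td_rr_diff_max": np.max(np.abs(drr)) if drr.size else np.nan,
        "td_rr_frac_accel": np.mean(drr < 0) if drr.size else np.nan,
        "td_hr_mean": hr.mean(),
        "td_hr_median": np.median(hr),
        "td_hr_min": hr.min(),
        "td_hr_max": hr.max(),
        "td_hr_sd": hr.std(),
        "td_beat_count": float(len(fiducials)),
    }
    return {k: float(v) for k, v in out.items()}


# --------------------------------------------------------------------------
# frequency domain — periodogram + wavelet sub-bands
# --------------------------------------------------------------------------

def extract_frequency_domain(signal: np.ndarray, fs: float) -> dict:
    """35 spectral statistics of a single-lead window (>= 1 s)."""
    signal = np.asarray(signal, dtype=float)
    if signal.size < fs:
        raise FeatureExtractionError("frequency_domain", "window shorter than 1 s")
    nyq = fs / 2.0
    nperseg = min(signal.size, int(fs))  # ~1 Hz resolution
    f, pxx = sps.welch(signal, fs=fs, nperseg=nperseg)
    total = float(np.sum(pxx))
    out = {}

    band_abs = {}
    for name, lo, hi in _BANDS:
        hi_edge = nyq if hi is None else min(hi, nyq)
        # the lowest band includes the DC bin so normalized powers sum to 1
        mask = ((f >= lo) if lo == 0 else (f > lo)) & (f <= hi_edge)
        band_abs[name] = float(np.sum(pxx[mask]))
        out[f"fd_bp_{name}"] = band_abs[name]
    out["fd_total_power"] = total
    for name in band_abs:
        out[f"fd_nbp_{name}"] = band_abs[name] / total if total > 0 else 0.0
    out["fd_lf_hf_ratio"] = (band_abs["low"] / band_abs["high"]
                             if band_abs["high"] > 0 else np.nan)

    if total > 0:
        p = pxx / total
        centroid = float(np.sum(f * p))
        spread = float(np.sqrt(np.sum((f - centroid) ** 2 * p)))
        out["fd_spectral_centroid"] = centroid
        out["fd_spectral_spread"] = spread
        if spread > 0:
            out["fd_spectral_skewness"] = float(np.sum((f - centroid) ** 3 * p) / spread ** 3)
            out["fd_spectral_kurtosis"] = float(np.sum((f - centroid) ** 4 * p) / spread ** 4 - 3.0)
        else:
            out["fd_spectral_skewness"] = np.nan
            out["fd_spectral_kurtosis"] = np.nan
        pn = p[p > 0]
        out["fd_spectral_entropy"] = float(-np.sum(pn * np.log(pn)) / np.log(p.size))
        out["fd_spectral_flatness"] = (float(stats.gmean(pxx[pxx > 0]) / np.mean(pxx))
                                       if np.any(pxx > 0) else np.nan)
        cum = np.cumsum(p)
        out["fd_spectral_rolloff85"] = float(f[np.searchsorted(cum, 0.85)])
        out["fd_spectral_rolloff95"] = float(f[np.searchsorted(cum, 0.95)])
        out["fd_median_freq"] = float(f[np.searchsorted(cum, 0.50)])
        k = int(np.argmax(pxx))
        out["fd_spectral_peak_freq"] = float(f[k])
        out["fd_spectral_peak_power"] = float(pxx[k])
        out["fd_spectral_crest"] = float(pxx[k] / np.mean(pxx))
        out["fd_spectral_slope"] = float(np.polyfit(f, pxx, 1)[0])
    else:  # zero window convention: powers 0, shape statistics undefined
        for k in ("fd_spectral_centroid", "fd_spectral_spread",
                  "fd_spectral_skewness", "fd_spectral_kurtosis",
                  "fd_spectral_entropy", "fd_spectral_flatness",
                  "fd_spectral_rolloff85", "fd_spectral_rolloff95",
                  "fd_median_freq", "fd_spectral_peak_freq",
                  "fd_spectral_peak_power", "fd_spectral_crest",
                  "fd_spectral_slope"):
            out[k] = np.nan
        out["fd_lf_hf_ratio"] = np.nan

    # discrete wavelet sub-band energies (db4, 5 levels or as many as fit)
    level = min(5, pywt.dwt_max_level(signal.size, pywt.Wavelet("db4").dec_len))
    labels = ["a5", "d5", "d4", "d3", "d2", "d1"]
    energies = {lbl: 0.0 for lbl in labels}
    if level >= 1:
        coeffs = pywt.wavedec(signal, "db4", level=level)
        # coeffs = [aL, dL, ..., d1]; map into the fixed a5,d5..d1 slots
        energies["a5"] = float(np.sum(coeffs[0] ** 2))
        for i, c in enumerate(coeffs[1:]):
            energies[f"d{level - i}"] = float(np.sum(c ** 2))
    wtotal = sum(energies.values())
    for lbl in labels:
        out[f"fd_wv_rel_energy_{lbl}"] = (energies[lbl] / wtotal
                                          if wtotal > 0 else 0.0)
    rel = np.array([energies[lbl] / wtotal for lbl in labels if wtotal > 0])
    rel = rel[rel > 0]
    out["fd_wv_entropy"] = float(-np.sum(rel * np.log(rel))) if rel.size else np.nan
    out["fd_wv_total_energy"] = float(wtotal)
    return out


# --------------------------------------------------------------------------
# morphology — per-beat wave measurements aggregated over beats
# --------------------------------------------------------------------------

def _beat_morphology(signal, fid: FiducialPoints, i: int, fs: float) -> dict | None:
    q, r, s = fid.q_idx[i], fid.r_idx[i], fid.s_idx[i]
    if q == ABSENT or s == ABSENT:
        return None
    p, t = fid.p_idx[i], fid.t_idx[i]
    m = {"r_amp": signal[r], "q_depth": signal[q], "s_depth": signal[s]}
    m["p_amp"] = signal[p] if p != ABSENT else np.nan
    m["t_amp"] = signal[t] if t != ABSENT else np.nan
    m["qrs_width"] = (s - q) / fs
    m["pr_interval"] = (r - p) / fs if p != ABSENT else np.nan
    m["qt_interval"] = (t - q) / fs if t != ABSENT else np.nan

    # ST segment: 20-80 ms after S, vs a PR baseline just before Q
    st_lo, st_hi = s + int(0.020 * fs), min(signal.size, s + int(0.080 * fs))
    base_lo, base_hi = max(0, q - int(0.040 * fs)), max(1, q - int(0.010 * fs))
    if st_hi - st_lo >= 3:
        seg = signal[st_lo:st_hi]
        tt = np.arange(seg.size) / fs
        m["st_slope"] = float(np.polyfit(tt, seg, 1)[0])
        m["st_level"] = float(np.mean(seg) - np.mean(signal[base_lo:base_hi]))
    else:
        m["st_slope"] = np.nan
        m["st_level"] = np.nan

    m["rs_ratio"] = (np.abs(signal[r]) / np.abs(signal[s])
                     if signal[s] != 0 else np.nan)
    m["rt_ratio"] = (np.abs(signal[r]) / np.abs(signal[t])
                     if t != ABSENT and signal[t] != 0 else np.nan)
    m["qrs_area"] = float(np.sum(np.abs(signal[q:s + 1])) / fs)
    if 1 <= r < signal.size - 1:
        m["r_sharpness"] = float(-(signal[r - 1] - 2 * signal[r] + signal[r + 1]))
    else:
        m["r_sharpness"] = np.nan
    blo = p if p != ABSENT else q
    bhi = t if t != ABSENT else s
    m["beat_energy"] = float(np.mean(signal[blo:bhi + 1] ** 2))
    return m


def extract_morphological(signal: np.ndarray, fiducials: FiducialPoints,
                          fs: float) -> dict:
    """30 features: mean and SD over beats of 15 per-beat quantities."""
    signal = np.asarray(signal, dtype=float)
    beats = [_beat_morphology(signal, fiducials, i, fs)
             for i in range(len(fiducials))]
    beats = [b for b in beats if b is not None]
    if not beats:
        raise InsufficientBeatsError("no complete beat with Q, R, S present")
    out = {}
    for q, _, _ in _MORPH_QUANTITIES:
        vals = np.array([b[q] for b in beats], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[f"mg_{q}_mean"] = float(np.mean(vals)) if vals.size else np.nan
        out[f"mg_{q}_sd"] = float(np.std(vals)) if vals.size else np.nan
    return out


# --------------------------------------------------------------------------
# nonlinear — complexity of the decimated signal and of the RR sequence
# --------------------------------------------------------------------------

def _decimate_for_entropy(signal: np.ndarray, fs: float) -> np.ndarray:
    step = max(1, int(round(fs / ENTROPY_FS)))
    return np.asarray(signal, dtype=float)[::step]


def extract_nonlinear(signal: np.ndarray, fs: float,
                      rr: np.ndarray | None = None) -> dict:
    """26 complexity measures.

    Entropy/fractal/Hjorth measures act on the signal decimated to
    ~100 Hz; Poincare and RR-entropy measures act on the RR sequence
    (NaN sentinels when absent or too short).
    """
    x = _decimate_for_entropy(signal, fs)
    if x.size < 30:
        raise FeatureExtractionError("nonlinear", "series too short")
    out = {}
    sd = np.std(x)
    for tag, m, rmult in _ENTROPY_GRID:
        r = rmult * sd
        out[f"nl_sampen_{tag}"] = cx.sample_entropy(x, m, r)
        out[f"nl_apen_{tag}"] = cx.approximate_entropy(x, m, r)
        out[f"nl_fuzzyen_{tag}"] = cx.fuzzy_entropy(x, m, r)
    out["nl_higuchi_fd"] = cx.higuchi_fd(x)
    out["nl_katz_fd"] = cx.katz_fd(x)
    out["nl_petrosian_fd"] = cx.petrosian_fd(x)
    out["nl_dfa_alpha1"] = cx.dfa_alpha(x)
    rr = np.asarray(rr, dtype=float) if rr is not None else np.array([])
    sd1, sd2, ratio, area = cx.poincare_descriptors(rr)
    out["nl_poincare_sd1"] = sd1
    out["nl_poincare_sd2"] = sd2
    out["nl_poincare_ratio"] = ratio
    out["nl_poincare_area"] = area
    out["nl_rr_sampen"] = (cx.sample_entropy(rr, 2, 0.2 * np.std(rr))
                           if rr.size >= 10 else np.nan)
    out["nl_rr_shannon"] = cx.shannon_entropy_hist(rr)
    mob, comp = cx.hjorth_params(x)
    out["nl_hjorth_mobility"] = mob
    out["nl_hjorth_complexity"] = comp
    out["nl_zero_cross_rate"] = cx.zero_crossing_rate(x)
    out["nl_turning_point_ratio"] = cx.turning_point_ratio(x)
    return out


# --------------------------------------------------------------------------
# full catalog + window matrix
# --------------------------------------------------------------------------

@dataclass
class FeatureVector:
    values: np.ndarray
    names: list = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        assert self.values.shape == (len(FEATURE_NAMES),)

    @property
    def categories(self):
        return [FEATURE_CATEGORY[n] for n in self.names]

    def as_dict(self):
        return dict(zip(self.names, self.values))


def _all_feature_dict(record, lead="II", fiducials=None) -> dict:
    sig = record.lead(lead)
    if fiducials is None:
        fiducials = extract_fiducials(record, lead=lead)
    merged = {}
    for family, fn in (
        ("time_domain", lambda: extract_time_domain(fiducials, record.fs)),
        ("frequency_domain", lambda: extract_frequency_domain(sig, record.fs)),
        ("morphological", lambda: extract_morphological(sig, fiducials, record.fs)),
        ("nonlinear", lambda: extract_nonlinear(
            sig, record.fs, rr=fiducials.rr_intervals_s)),
    ):
        try:
            merged.update(fn())
        except FeatureExtractionError:
            raise
        except Exception as exc:  # noqa: BLE001 — re-raise with family context
            raise FeatureExtractionError(family, exc) from exc
    return merged


def extract_all(record, lead: str = "II", fiducials=None) -> FeatureVector:
    """The full 118-attribute vector in frozen catalog order."""
    d = _all_feature_dict(record, lead=lead, fiducials=fiducials)
    vec = np.array([d[name] for name in FEATURE_NAMES], dtype=float)
    return FeatureVector(values=vec)


@dataclass
class ZParams:
    """Per-column z-score + median-imputation parameters (fit on training data)."""

    mean: np.ndarray
    sd: np.ndarray
    median: np.ndarray
    colnames: list

    @classmethod
    def fit(cls, X: np.ndarray, colnames) -> "ZParams":
        X = np.asarray(X, dtype=float)
        med = np.zeros(X.shape[1])
        for j in range(X.shape[1]):  # a column can be all-NaN in short windows
            col = X[:, j][np.isfinite(X[:, j])]
            if col.size:
                med[j] = np.median(col)
        Ximp = np.where(np.isfinite(X), X, med[None, :])
        mean = Ximp.mean(axis=0)
        sd = Ximp.std(axis=0)
        # numerically constant columns get sd := 1 (z-scores to zero)
        sd = np.where(sd > 1e-12 * np.maximum(1.0, np.abs(mean)), sd, 1.0)
        return cls(mean=mean, sd=sd, median=med, colnames=list(colnames))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        X = np.where(np.isfinite(X), X, self.median[None, :])
        return (X - self.mean[None, :]) / self.sd[None, :]


@dataclass
class WindowFeatureMatrix:
    """Sliding-window (timestamps x attributes) matrix for one record.

    Column 0 is the window RMS signal amplitude; the remaining columns are
    the selected catalog features re-computed per window.
    """

    X: np.ndarray
    colnames: list
    window_length_s: float
    stride_s: float
    zparams: ZParams | None = None


_FAMILY_PREFIX = {"td_": "time_domain", "fd_": "frequency_domain",
                  "mg_": "morphological", "nl_": "nonlinear"}


def _window_features(sig, fs, fid_all, lo, hi, families):
    """Catalog features on one window, NaN where locally undefined."""
    sub = sig[lo:hi]
    mask = (fid_all.r_idx >= lo) & (fid_all.r_idx < hi)

    def shift(a):
        return np.where((a[mask] >= lo) & (a[mask] < hi), a[mask] - lo, ABSENT)

    fid = None
    if mask.sum() >= 1:
        fid = FiducialPoints(r_idx=fid_all.r_idx[mask] - lo,
                             q_idx=shift(fid_all.q_idx),
                             s_idx=shift(fid_all.s_idx),
                             p_idx=shift(fid_all.p_idx),
                             t_idx=shift(fid_all.t_idx), fs=fs)
    out = {}
    if "time_domain" in families:
        try:
            out.update(extract_time_domain(fid, fs) if fid else {})
        except Exception:
            pass
    if "frequency_domain" in families:
        try:
            out.update(extract_frequency_domain(sub, fs))
        except Exception:
            pass
    if "morphological" in families:
        try:
            out.update(extract_morphological(sub, fid, fs) if fid else {})
        except Exception:
            pass
    if "nonlinear" in families:
        try:
            rr = fid.rr_intervals_s if fid else None
            out.update(extract_nonlinear(sub, fs, rr=rr))
        except Exception:
            pass
    return out


def build_window_matrix(record, selected_features, window_length_s: float = 2.0,
                        stride_s: float = 1.0, zparams: ZParams | None = None,
                        lead: str = "II", fiducials=None) -> WindowFeatureMatrix:
    """Assemble the per-record sliding-window feature matrix.

    Row t = [window RMS, selected features on window t].  If *zparams* is
    given the matrix is imputed and z-scored with those (training-fit)
    parameters; otherwise the raw matrix is returned (fit z-parameters on
    the pooled training windows, then transform).
    """
    if not selected_features:
        raise ValueError("selected_features must be nonempty")
    unknown = [n for n in selected_features if n not in FEATURE_CATEGORY]
    if unknown:
        raise ValueError(f"unknown feature names: {unknown}")
    sig = record.lead(lead)
    fs = record.fs
    wlen = int(round(window_length_s * fs))
    stride = int(round(stride_s * fs))
    if wlen > sig.size:
        raise ValueError("window longer than the record")
    if fiducials is None:
        fiducials = extract_fiducials(record, lead=lead)
    families = {_FAMILY_PREFIX[n[:3]] for n in selected_features}

    rows = []
    for lo in range(0, sig.size - wlen + 1, stride):
        hi = lo + wlen
        feats = _window_features(sig, fs, fiducials, lo, hi, families)
        rms = float(np.sqrt(np.mean(sig[lo:hi] ** 2)))
        rows.append([rms] + [feats.get(n, np.nan) for n in selected_features])
    X = np.array(rows, dtype=float)
    colnames = ["signal_rms"] + list(selected_features)
    if zparams is not None:
        X = zparams.transform(X)
    return WindowFeatureMatrix(X=X, colnames=colnames,
                               window_length_s=window_length_s,
                               stride_s=stride_s, zparams=zparams)
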
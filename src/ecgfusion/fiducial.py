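"""R-peak detection and P/Q/R/S/T wave delineation.

R peaks are found with a Pan-Tompkins-style chain: band-pass (5-15 Hz,
zero-phase Butterworth) -> differentiate -> square -> 150 ms moving-window
integration -> adaptive signal/noise thresholding with a 200 ms refractory
period, followed by refinement to the local maximum of the band-passed
signal.  This is a standard, well-tested stand-in detector: the clinical
pipeline it emulates delegates QRS detection to a published external
algorithm whose internals are not reproduced here.

Delineation uses fixed physiologic search windows relative to each R peak
(all overridable): Q = minimum within 50 ms before R, S = minimum within
50 ms after R, P = maximum in [-200, -80] ms, T = maximum in [80, 400] ms
truncated at the next beat.  A wave whose search window is empty (or, for
T, shorter than 40 ms) is flagged absent with index -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

ABSENT = -1


class InsufficientDataError(ValueError):
    """Signal too short for the requested operation."""


@dataclass
class FiducialPoints:
    """Per-beat sample indices of the five ECG waves (-1 = absent)."""

    r_idx: np.ndarray
    q_idx: np.ndarray
    s_idx: np.ndarray
    p_idx: np.ndarray
    t_idx: np.ndarray
    fs: float

    def __post_init__(self):
        for name in ("r_idx", "q_idx", "s_idx", "p_idx", "t_idx"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        if np.any(np.diff(self.r_idx) <= 0):
            raise ValueError("r_idx must be strictly increasing")
        for beat in range(len(self.r_idx)):
            seq = [self.p_idx[beat], self.q_idx[beat], self.r_idx[beat],
                   self.s_idx[beat], self.t_idx[beat]]
            present = [v for v in seq if v != ABSENT]
            if any(np.diff(present) <= 0):
                raise ValueError(f"wave ordering violated at beat {beat}")

    def __len__(self):
        return len(self.r_idx)

    @property
    def rr_intervals_s(self) -> np.ndarray:
        return np.diff(self.r_idx) / self.fs


def detect_r_peaks(signal: np.ndarray, fs: float,
                   refractory_s: float = 0.2) -> np.ndarray:
    """Detect R-peak sample indices in a single-lead signal.

    Returns a strictly increasing index array; an empty array for a flat
    signal.  Raises :class:`InsufficientDataError` below 2 s of data.
    """
    signal = np.asarray(signal, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if signal.ndim != 1:
        raise ValueError("expected a single-lead 1-D signal")
    if signal.size < 2 * fs:
        raise InsufficientDataError("need at least 2 s of signal")
    if np.ptp(signal) == 0:
        return np.array([], dtype=int)

    nyq = fs / 2.0
    sos = sps.butter(2, [5.0 / nyq, min(15.0, 0.9 * nyq) / nyq],
                     btype="band", output="sos")
    bp = sps.sosfiltfilt(sos, signal)
    deriv = np.gradient(bp)
    sq = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    dist = max(1, int(round(refractory_s * fs)))
    cand, _ = sps.find_peaks(mwi, distance=dist)
    if cand.size == 0:
        return np.array([], dtype=int)

    # Adaptive signal/noise levels (relative, hence amplitude-scale invariant).
    spki = float(np.max(mwi[: int(2 * fs)]))
    npki = float(np.mean(mwi[: int(2 * fs)]))
    accepted = []
    for c in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[c] >= thr:
            accepted.append(c)
            spki = 0.125 * mwi[c] + 0.875 * spki
        else:
            npki = 0.125 * mwi[c] + 0.875 * npki
    if not accepted:
        return np.array([], dtype=int)

    # Refine to the local max of |band-passed| signal near each candidate.
    half = int(round(0.075 * fs))
    refined = []
    for c in accepted:
        lo, hi = max(0, c - half), min(signal.size, c + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))

    # Enforce the refractory period after refinement (keep the larger peak).
    refined.sort()
    out = []
    for r in refined:
        if out and r - out[-1] < dist:
            if np.abs(bp[r]) > np.abs(bp[out[-1]]):
                out[-1] = r
        else:
            out.append(r)
    return np.array(out, dtype=int)


def delineate_waves(signal: np.ndarray, fs: float, r_idx: np.ndarray,
                    q_window_s: float = 0.050, s_window_s: float = 0.050,
                    p_window_s: tuple = (0.200, 0.080),
                    t_window_s: tuple = (0.080, 0.400),
                    t_min_window_s: float = 0.040) -> FiducialPoints:
    """Locate Q, S, P, T waves around each detected R peak.

    Window bounds are seconds relative to R (P/T tuples are (far, near) /
    (near, far) edges).  Returns a :class:`FiducialPoints`; absent waves
    carry index -1.
    """
    signal = np.asarray(signal, dtype=float)
    r_idx = np.asarray(r_idx, dtype=int)
    n = signal.size
    if r_idx.size and (r_idx.min() < 0 or r_idx.max() >= n):
        raise ValueError("r_idx out of signal bounds")

    q = np.full(r_idx.size, ABSENT)
    s = np.full(r_idx.size, ABSENT)
    p = np.full(r_idx.size, ABSENT)
    t = np.full(r_idx.size, ABSENT)

    for i, r in enumerate(r_idx):
        lo = max(0, r - int(round(q_window_s * fs)))
        if lo < r:
            q[i] = lo + int(np.argmin(signal[lo:r]))
        hi = min(n, r + int(round(s_window_s * fs)) + 1)
        if r + 1 < hi:
            s[i] = r + 1 + int(np.argmin(signal[r + 1:hi]))

        plo = max(0, r - int(round(p_window_s[0] * fs)))
        phi = max(0, r - int(round(p_window_s[1] * fs)))
        if i > 0:  # keep the window inside this beat
            plo = max(plo, r_idx[i - 1] + 1)
        if plo < phi:
            p[i] = plo + int(np.argmax(signal[plo:phi]))

        tlo = min(n, r + int(round(t_window_s[0] * fs)))
        thi = min(n, r + int(round(t_window_s[1] * fs)) + 1)
        if i + 1 < r_idx.size:
            thi = min(thi, r_idx[i + 1])
        if thi - tlo >= int(round(t_min_window_s * fs)):
            t[i] = tlo + int(np.argmax(signal[tlo:thi]))

        # enforce the ordering invariant; drop any wave breaking it
        if p[i] != ABSENT and q[i] != ABSENT and p[i] >= q[i]:
            p[i] = ABSENT
        if t[i] != ABSENT and s[i] != ABSENT and t[i] <= s[i]:
            t[i] = ABSENT

    return FiducialPoints(r_idx=r_idx, q_idx=q, s_idx=s, p_idx=p, t_idx=t, fs=fs)


def match_peaks(detected, truth, fs: float, tol_s: float = 0.05):
    """Greedy one-to-one matching of detected vs true peak indices.

    Returns (sensitivity, positive_predictivity) at the given time
    tolerance: TP/(TP+FN) and TP/(TP+FP).
    """
    detected = np.asarray(detected, dtype=int)
    truth = np.asarray(truth, dtype=int)
    tol = tol_s * fs
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for t in truth:
        if detected.size == 0:
            break
        d = np.abs(detected - t).astype(float)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            tp += 1
    sens = tp / truth.size if truth.size else 1.0
    ppv = tp / detected.size if detected.size else 1.0
    return sens, ppv


def extract_fiducials(record, lead="II", **kwargs) -> FiducialPoints:
    """Convenience: detect R peaks then delineate, on one configurable lead."""
    sig = record.lead(lead)
    r = detect_r_peaks(sig, record.fs)
    return delineate_waves(sig, record.fs, r, **kwargs)
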
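"""Synthetic multi-label 12-lead ECG generator.

Each heartbeat is a sum of five Gaussian bumps (P, Q, R, S, T) on a
beat-local time axis, repeated at randomly jittered RR intervals and
projected onto 12 leads through a fixed amplitude table.  Rhythm classes
perturb the template in a class-characteristic way:

* ``AF``   — P wave removed, strongly irregular RR intervals
* ``PVC``  — sporadic ectopic beats with a much wider, taller QRS and no P
* ``PAC``  — sporadic premature beats (shortened preceding RR interval)
* ``LBBB`` — widened QRS on every beat, left-type lead polarity pattern
* ``RBBB`` — widened QRS on every beat, right-type lead polarity pattern

The generator stores ground-truth R-peak sample indices alongside the
signal so detection and delineation can be scored without manual
annotation.  Noise is additive white Gaussian; baseline wander and
powerline interference are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CLASS_NAMES = ("Normal", "AF", "PVC", "PAC", "LBBB", "RBBB")

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")

#: Per-lead amplitude multipliers for the whole beat template.  Lead II is
#: the reference (multiplier 1.0); aVR is inverted as in real recordings.
LEAD_PROJECTION = np.array(
    [0.70, 1.00, 0.45, -0.80, 0.30, 0.75, 0.40, 0.65, 0.85, 1.00, 0.90, 0.75]
)

#: QRS polarity overrides (per lead) for the bundle-branch-block classes.
#: Applied to the Q/R/S bumps only, on top of LEAD_PROJECTION.
_BBB_QRS_POLARITY = {
    "LBBB": np.array([1, 1, 1, 1, 1, 1, -1, -1, -1, 1, 1, 1], dtype=float),
    "RBBB": np.array([1, 1, 1, 1, 1, 1, -1, -1, 1, 1, 1, -1], dtype=float),
}

# Template bump parameters: (offset from R in seconds, amplitude in mV,
# Gaussian sigma in seconds).  Offsets respect conventional delineation
# windows: P in [-200, -80] ms, Q/S within 50 ms of R, T in [80, 400] ms.
TEMPLATE = {
    "P": (-0.160, 0.15, 0.022),
    "Q": (-0.030, -0.15, 0.009),
    "R": (0.000, 1.00, 0.011),
    "S": (0.030, -0.25, 0.009),
    "T": (0.250, 0.35, 0.040),
}

_WAVES = ("P", "Q", "R", "S", "T")
_QRS_WAVES = ("Q", "R", "S")


@dataclass(frozen=True)
class RhythmSpec:
    """Generation parameters for one rhythm class.

    ``morphology_params`` maps wave name -> (amplitude multiplier, width
    multiplier, offset shift in seconds); missing waves default to
    (1, 1, 0).  ``ectopic_fraction`` is the per-beat probability that the
    beat is an ectopic (PVC/PAC) rather than a background beat.
    """

    class_name: str
    heart_rate_bpm: float = 72.0
    rr_jitter: float = 0.03
    morphology_params: dict = field(default_factory=dict)
    ectopic_fraction: float = 0.0

    def __post_init__(self):
        if self.class_name not in CLASS_NAMES:
            raise ValueError(
                f"unknown class {self.class_name!r}; expected one of {CLASS_NAMES}"
            )
        if not 30.0 <= self.heart_rate_bpm <= 220.0:
            raise ValueError("heart_rate_bpm must lie in [30, 220]")
        if self.rr_jitter < 0:
            raise ValueError("rr_jitter must be nonnegative")


def default_spec(class_name: str, heart_rate_bpm: float = 72.0) -> RhythmSpec:
    """Canonical RhythmSpec for each of the six classes."""
    if class_name == "Normal":
        return RhythmSpec("Normal", heart_rate_bpm, rr_jitter=0.03)
    if class_name == "AF":
        # absent P wave and strongly irregular ventricular response
        return RhythmSpec("AF", heart_rate_bpm, rr_jitter=0.18,
                          morphology_params={"P": (0.0, 1.0, 0.0)})
    if class_name == "PVC":
        # ectopic beats carry a wide, tall QRS and no preceding P
        return RhythmSpec("PVC", heart_rate_bpm, rr_jitter=0.03,
                          ectopic_fraction=0.25,
                          morphology_params={"P": (0.0, 1.0, 0.0),
                                             "Q": (1.3, 2.2, -0.010),
                                             "R": (1.30, 2.2, 0.0),
                                             "S": (1.5, 2.2, 0.010)})
    if class_name == "PAC":
        # premature atrial beats: early arrival, slightly odd P
        return RhythmSpec("PAC", heart_rate_bpm, rr_jitter=0.03,
                          ectopic_fraction=0.25,
                          morphology_params={"P": (0.6, 0.7, 0.030)})
    if class_name == "LBBB":
        return RhythmSpec("LBBB", heart_rate_bpm, rr_jitter=0.03,
                          morphology_params={"Q": (1.0, 1.9, -0.015),
                                             "R": (0.9, 1.9, 0.0),
                                             "S": (1.2, 1.9, 0.015),
                                             "T": (-0.8, 1.0, 0.0)})
    if class_name == "RBBB":
        return RhythmSpec("RBBB", heart_rate_bpm, rr_jitter=0.03,
                          morphology_params={"Q": (1.0, 1.7, -0.012),
                                             "R": (0.95, 1.7, 0.0),
                                             "S": (1.4, 1.7, 0.012)})
    raise ValueError(f"unknown class {class_name!r}")


@dataclass
class ECGRecord:
    """A multi-lead ECG record with ground truth (synthetic only).

    signal      : (n_leads, n_samples) array, millivolts
    fs          : sampling rate, Hz
    labels      : set of class names
    beat_times  : ground-truth R-peak sample indices, strictly increasing
    beat_classes: per-beat class name (which rhythm spec shaped each beat)
    """

    signal: np.ndarray
    fs: float
    labels: frozenset
    beat_times: np.ndarray
    record_id: str = ""
    lead_names: tuple = LEAD_NAMES
    beat_classes: tuple = ()

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.labels:
            raise ValueError("labels must be nonempty")
        bt = np.asarray(self.beat_times)
        if bt.size and (np.any(np.diff(bt) <= 0) or bt[0] < 0
                        or bt[-1] >= self.signal.shape[1]):
            raise ValueError("beat_times must be strictly increasing and in range")

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs

    def lead(self, name_or_index) -> np.ndarray:
        if isinstance(name_or_index, str):
            return self.signal[self.lead_names.index(name_or_index)]
        return self.signal[name_or_index]


def _beat_waveform(t_local, params, qrs_polarity=None):
    """Evaluate one beat's 12-lead waveform on local times (s from R).

    ``params`` maps wave -> (amp_mult, width_mult, offset_shift).
    Returns (12, len(t_local)).
    """
    out = np.zeros((len(LEAD_NAMES), t_local.size))
    for wave in _WAVES:
        mu, amp, sig = TEMPLATE[wave]
        am, wm, off = params.get(wave, (1.0, 1.0, 0.0))
        if am == 0.0:
            continue
        bump = am * amp * np.exp(-0.5 * ((t_local - (mu + off)) / (sig * wm)) ** 2)
        proj = LEAD_PROJECTION.copy()
        if qrs_polarity is not None and wave in _QRS_WAVES:
            proj = proj * qrs_polarity
        out += proj[:, None] * bump[None, :]
    return out


def _draw_rr(rng, spec):
    rr = 60.0 / spec.heart_rate_bpm
    eps = float(np.clip(rng.standard_normal(), -3.0, 3.0))
    return max(0.30, rr * (1.0 + spec.rr_jitter * eps))


def generate_record(specs, duration_s, fs=500.0, noise_sd=0.0, seed=0,
                    record_id=None):
    """Generate one multi-label 12-lead record.

    Parameters
    ----------
    specs : RhythmSpec or list of RhythmSpec
        Rhythm classes present in the record.  With several specs, beats
        are partitioned among them in alternating blocks so each beat's
        morphology is attributable to exactly one class.
    duration_s : float in [6, 60]
    fs : sampling rate (Hz)
    noise_sd : additive white Gaussian noise SD (mV)
    seed : int, makes the record fully deterministic

    Returns
    -------
    ECGRecord with ground-truth ``beat_times`` and ``labels``.
    """
    if isinstance(specs, RhythmSpec):
        specs = [specs]
    if not specs:
        raise ValueError("specs must be nonempty")
    if not 6.0 <= duration_s <= 60.0:
        raise ValueError("duration_s must lie in [6, 60]")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    signal = np.zeros((len(LEAD_NAMES), n_samples))

    # Background spec drives the RR sequence; ectopic classes overlay
    # sporadic beats onto alternating blocks.
    block = 4  # beats per block when cycling through specs
    beat_times, beat_classes, beat_params, beat_polarity = [], [], [], []

    t = 0.45  # first beat placed clear of the record edge
    beat_i = 0
    while t < duration_s - 0.45:
        spec = specs[(beat_i // block) % len(specs)]
        is_ectopic = (spec.ectopic_fraction > 0
                      and rng.random() < spec.ectopic_fraction)
        if spec.ectopic_fraction > 0 and not is_ectopic:
            # background beats of an ectopic class look normal
            params = {}
        else:
            params = spec.morphology_params
        rr = _draw_rr(rng, spec)
        if is_ectopic and spec.class_name == "PAC":
            rr *= 0.70  # premature arrival
        beat_times.append(t)
        beat_classes.append(spec.class_name if (is_ectopic or spec.ectopic_fraction == 0)
                            else "Normal")
        beat_params.append(params)
        beat_polarity.append(_BBB_QRS_POLARITY.get(spec.class_name))
        t += rr
        beat_i += 1

    # Guarantee at least one morphologically marked beat per ectopic class.
    for s_i, spec in enumerate(specs):
        if spec.ectopic_fraction > 0 and not any(
                c == spec.class_name for c in beat_classes):
            own = [i for i in range(len(beat_times))
                   if (i // block) % len(specs) == s_i]
            if own:
                j = own[len(own) // 2]
                beat_classes[j] = spec.class_name
                beat_params[j] = spec.morphology_params
                if spec.class_name == "PAC" and j > 0:
                    shift = 0.30 * (beat_times[j] - beat_times[j - 1])
                    beat_times[j] -= shift

    half = 0.45  # seconds of template evaluated on each side of R
    for bt, params, pol in zip(beat_times, beat_params, beat_polarity):
        center = int(round(bt * fs))
        lo = max(0, center - int(half * fs))
        hi = min(n_samples, center + int(half * fs))
        t_local = (np.arange(lo, hi) - center) / fs
        signal[:, lo:hi] += _beat_waveform(t_local, params, pol)

    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)

    idx = np.array([int(round(bt * fs)) for bt in beat_times], dtype=int)
    labels = frozenset(s.class_name for s in specs)
    rid = record_id if record_id is not None else f"syn{seed:06d}"
    return ECGRecord(signal=signal, fs=fs, labels=labels, beat_times=idx,
                     record_id=rid, beat_classes=tuple(beat_classes))


#: Empirical per-class prevalence of the six rhythm classes in a
#: multi-label clinical training corpus (record counts / corpus size).
DEFAULT_PREVALENCE = {
    "Normal": 914 / 5078,
    "AF": 1219 / 5078,
    "PVC": 711 / 5078,
    "PAC": 609 / 5078,
    "LBBB": 254 / 5078,
    "RBBB": 1828 / 5078,
}


def generate_dataset(n_records, prevalence=None, seed=0, duration_s=10.0,
                     fs=500.0, noise_sd=0.02, heart_rate_range=(55.0, 95.0)):
    """Generate a multi-label dataset with Bernoulli label co-occurrence.

    Each record's label set is drawn independently per class with the given
    prevalence (resampled until nonempty), then rendered by
    :func:`generate_record` with one RhythmSpec per label.
    """
    if n_records <= 0:
        raise ValueError("n_records must be positive")
    if prevalence is None:
        prevalence = DEFAULT_PREVALENCE
    if not prevalence:
        raise ValueError("prevalence map must be nonempty")
    for c, p in prevalence.items():
        if c not in CLASS_NAMES:
            raise ValueError(f"unknown class {c!r}")
        if not 0.0 <= p <= 1.0:
            raise ValueError("prevalences must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    classes = [c for c in CLASS_NAMES if c in prevalence]
    probs = np.array([prevalence[c] for c in classes])
    records = []
    for i in range(n_records):
        while True:
            mask = rng.random(len(classes)) < probs
            if mask.any():
                break
        labels = [c for c, m in zip(classes, mask) if m]
        hr = float(rng.uniform(*heart_rate_range))
        specs = [default_spec(c, hr) for c in labels]
        rec_seed = int(rng.integers(0, 2**31 - 1))
        records.append(generate_record(specs, duration_s, fs, noise_sd,
                                       seed=rec_seed, record_id=f"rec{i:05d}"))
    return records
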
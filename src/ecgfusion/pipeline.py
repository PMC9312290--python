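"""End-to-end orchestration: simulate -> detect -> extract -> select ->
train -> evaluate, with reproducible multi-label splits.

All training-derived quantities (feature-imputation medians, z-score
parameters, the attribute ranking) are fit on training indices only and
applied frozen to test data, so no test information leaks into feature
scaling or selection.  Splits use iterative stratification to keep
per-label prevalence approximately equal across folds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ecgfusion.catalog import CATALOG_VERSION, FEATURE_NAMES
from ecgfusion.features import ZParams, build_window_matrix, extract_all
from ecgfusion.fiducial import extract_fiducials
from ecgfusion.metrics import evaluate
from ecgfusion.network import FusionGC, NetworkConfig, TrainConfig
from ecgfusion.selection import Hyperparams, select_top_k, solve
from ecgfusion.synthetic import CLASS_NAMES, generate_dataset


@dataclass
class RunConfig:
    # data
    n_records: int = 300
    prevalence: dict | None = None  # None -> corpus-like defaults
    duration_s: float = 10.0
    fs: float = 500.0
    noise_sd: float = 0.02
    lead: str = "II"
    # windows
    window_length_s: float = 2.0
    stride_s: float = 1.0
    # attribute selection
    selection_enabled: bool = True
    top_k: int = 20
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    # model
    network: NetworkConfig = field(default_factory=NetworkConfig)
    # desk-scale training recipe; the clinical-corpus protocol (lr 0.001,
    # batch 150) is TrainConfig's own default and applies at corpus scale
    training: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=120, batch_size=16, learning_rate=0.2, lr_schedule="cosine"))
    threshold: float = 0.5
    # evaluation protocol
    split_policy: str = "holdout"  # 'holdout' (60/40) or 'cv' (k folds)
    train_fraction: float = 0.6
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.split_policy not in ("holdout", "cv"):
            raise ValueError("split_policy must be 'holdout' or 'cv'")

    def hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def iterative_stratification(Y: np.ndarray, fractions, seed: int = 0) -> np.ndarray:
    """Greedy multi-label stratified assignment of instances to folds.

    Repeatedly takes the label with the fewest unassigned positive
    instances and deals its instances to the fold with the largest
    remaining desired count for that label (ties: largest remaining fold
    capacity, then seeded random).  Returns a fold id per instance.
    """
    Y = np.asarray(Y, dtype=int)
    n, m = Y.shape
    fractions = np.asarray(fractions, dtype=float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fold fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n_folds = fractions.size
    fold_of = np.full(n, -1)
    cap = fractions * n                      # remaining fold capacity
    desired = np.outer(fractions, Y.sum(axis=0)).astype(float)  # folds x labels

    unassigned = set(range(n))
    while unassigned:
        counts = np.array([sum(Y[i, l] for i in unassigned) for l in range(m)])
        active = np.where(counts > 0)[0]
        if active.size == 0:
            for i in sorted(unassigned):
                f = int(np.argmax(cap + rng.uniform(0, 1e-9, n_folds)))
                fold_of[i] = f
                cap[f] -= 1
            break
        lab = active[np.argmin(counts[active])]
        members = sorted(i for i in unassigned if Y[i, lab])
        rng.shuffle(members)
        for i in members:
            score = desired[:, lab] + 1e-6 * cap + rng.uniform(0, 1e-9, n_folds)
            score[cap <= 0] = -np.inf  # keep fold sizes exact
            f = int(np.argmax(score))
            fold_of[i] = f
            cap[f] -= 1
            desired[f] -= Y[i]
            unassigned.discard(i)
    return fold_of


def split_dataset(Y: np.ndarray, policy: str = "holdout", seed: int = 0,
                  train_fraction: float = 0.6, cv_folds: int = 5):
    """Return a list of (train_idx, test_idx) pairs.

    'holdout' gives one stratified train/test pair; 'cv' gives
    ``cv_folds`` pairs, each fold serving as the test set once.
    """
    Y = np.asarray(Y, dtype=int)
    n = Y.shape[0]
    if policy == "holdout":
        fold_of = iterative_stratification(
            Y, [train_fraction, 1.0 - train_fraction], seed)
        train = np.where(fold_of == 0)[0]
        test = np.where(fold_of == 1)[0]
        return [(train, test)]
    if policy == "cv":
        if n < cv_folds:
            raise ValueError("need at least as many instances as folds")
        fold_of = iterative_stratification(Y, [1.0 / cv_folds] * cv_folds, seed)
        return [(np.where(fold_of != f)[0], np.where(fold_of == f)[0])
                for f in range(cv_folds)]
    raise ValueError(f"unknown policy {policy!r}")


def labels_to_matrix(records, classes=CLASS_NAMES) -> np.ndarray:
    return np.array([[1 if c in r.labels else 0 for c in classes]
                     for r in records], dtype=int)


def _majority_baseline(Y_train: np.ndarray, n_test: int) -> np.ndarray:
    """Predict each label's training-majority value for every test instance."""
    maj = (Y_train.mean(axis=0) >= 0.5).astype(int)
    return np.tile(maj, (n_test, 1))


def run_pipeline(config: RunConfig | None = None, records=None,
                 verbose: bool = False) -> dict:
    """Execute the full pipeline and return the experiment report.

    ``records`` may be supplied (e.g. read from disk); otherwise a
    synthetic dataset is generated from the config.  The report carries
    per-fold metric dicts, their mean +/- SD, the majority baseline, the
    selected attributes and full provenance.
    """
    cfg = config or RunConfig()

    if records is None:
        records = generate_dataset(cfg.n_records, cfg.prevalence,
                                   seed=cfg.seed, duration_s=cfg.duration_s,
                                   fs=cfg.fs, noise_sd=cfg.noise_sd)
    Y = labels_to_matrix(records)
    n = len(records)

    # -- per-record feature extraction (record-level + windowed) ----------
    if verbose:
        print(f"extracting features from {n} records ...")
    X_rec = np.empty((n, len(FEATURE_NAMES)))
    window_raw = []
    for i, rec in enumerate(records):
        fid = extract_fiducials(rec, lead=cfg.lead)
        X_rec[i] = extract_all(rec, lead=cfg.lead, fiducials=fid).values
        wm = build_window_matrix(rec, FEATURE_NAMES, cfg.window_length_s,
                                 cfg.stride_s, lead=cfg.lead, fiducials=fid)
        window_raw.append(wm.X)  # columns: [rms, *FEATURE_NAMES], raw

    splits = split_dataset(Y, cfg.split_policy, cfg.seed,
                           cfg.train_fraction, cfg.cv_folds)
    fold_reports, baselines, selections = [], [], []
    for fold_i, (train, test) in enumerate(splits):
        # attribute selection on training records only
        if cfg.selection_enabled:
            zrec = ZParams.fit(X_rec[train], FEATURE_NAMES)
            Xs = zrec.transform(X_rec[train])
            sel = solve(Xs, Y[train], cfg.hyperparams, seed=cfg.seed)
            selected = select_top_k(sel.ranking, cfg.top_k, names=FEATURE_NAMES)
        else:
            selected = list(FEATURE_NAMES)
        selections.append(selected)

        cols = [0] + [1 + FEATURE_NAMES.index(nm) for nm in selected]
        colnames = ["signal_rms"] + selected
        train_stack = np.vstack([window_raw[i][:, cols] for i in train])
        zwin = ZParams.fit(train_stack, colnames)
        mats_train = [zwin.transform(window_raw[i][:, cols]) for i in train]
        mats_test = [zwin.transform(window_raw[i][:, cols]) for i in test]

        model = FusionGC(n_cols=len(cols), config=cfg.network,
                         seed=cfg.seed + fold_i)
        model.train(mats_train, Y[train], cfg.training)
        Y_pred = model.predict(mats_test, threshold=cfg.threshold)
        rep = evaluate(Y[test], Y_pred)
        rep["fold"] = fold_i
        rep["n_train"], rep["n_test"] = len(train), len(test)
        fold_reports.append(rep)
        baselines.append(evaluate(Y[test], _majority_baseline(Y[train], len(test))))
        if verbose:
            print(f"fold {fold_i}: f1={rep['f1']:.3f} "
                  f"hamming={rep['hamming_loss']:.3f}")

    scalar_keys = ["accuracy", "subset_accuracy", "hamming_loss", "jaccard",
                   "precision", "recall", "f1"]
    summary = {k: {"mean": float(np.mean([r[k] for r in fold_reports])),
                   "sd": float(np.std([r[k] for r in fold_reports]))}
               for k in scalar_keys}
    baseline_summary = {k: float(np.mean([b[k] for b in baselines]))
                        for k in scalar_keys}

    return {
        "folds": fold_reports,
        "summary": summary,
        "majority_baseline": baseline_summary,
        "selected_features": selections[0],
        "provenance": {
            "seed": cfg.seed,
            "config_hash": cfg.hash(),
            "catalog_version": CATALOG_VERSION,
            "n_records": n,
            "split_policy": cfg.split_policy,
        },
    }
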
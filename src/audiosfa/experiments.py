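"""Pair-discrimination experiments: clean, cluttered, and hold-out conditions.

The task: two sounds are presented once each (random order, silent gap),
the concatenated presentation is passed through the cochlear model, an
unsupervised algorithm (PCA / ICA / lSFA / qSFA) learns a handful of
features from that single presentation, every non-gap time point is
projected into the feature space, and a linear SVM is trained to separate
the two sounds' point clouds under repeated stratified 75/25 splits.
Chance is 50 %. Two linear reference models bracket the algorithms: an
upper bound (SVM on all cochlear channels) and a null (SVM on five random
channels, redrawn per pair).

Clutter conditions embed the pair presentation in a 3-s amplitude-
regularized superposition of other events at a controlled SNR — in the
feature-learning presentation, in the classified presentation, or both
(with fresh clutter tokens each side, the cocktail-party case).
Generalization fits features on 17 held-out exemplars of a class and
classifies a never-seen pair.

Feature learning never sees the classifier's labels; labels enter only at
the SVM stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVC

from . import sfa
from .cochlea import apply_cochlear_model, build_gammatone_bank, \
    temporal_kernel_for_rate
from .seeds import derive
from .stimuli import AudioStimulus, MixSpec, embed_at_snr, make_clutter, \
    make_pair_stimulus

__all__ = [
    "PipelineConfig",
    "ExperimentResult",
    "crossval_svm",
    "run_pair_experiment",
    "feature_count_sweep",
    "upper_bound_and_null",
    "clutter_experiment",
    "generalization_experiment",
    "bootstrap_ci_median",
    "summarize",
]

CHANCE = 0.5


@dataclass
class PipelineConfig:
    """Front-end and classifier settings shared by all experiments.

    ``rate`` is the audio sample rate the stimuli are generated at;
    ``downsample`` decimates the cochleagram before feature learning (the
    slow features of interest live far below the audio rate). Defaults
    reproduce the full-scale front end (50 kHz, 42 channels spanning
    22.9 Hz - 20 208 Hz); `scaled()` gives a band-limited, lower-rate
    configuration for desk-scale runs.
    """

    rate: float = 50_000.0
    n_filters: int = 42
    f_lo: float = 22.9
    f_hi: float = 20_208.0
    downsample: int = 50
    folds: int = 30
    train_frac: float = 0.75
    svm_c: float = 1.0
    repeats: int = 5
    boundary_guard: float = 0.02  # s; frames this close to a label change -> gap
    _bank: object = field(default=None, repr=False, compare=False)

    @classmethod
    def scaled(cls, rate: float = 8000.0, downsample: int = 2) -> "PipelineConfig":
        """Reduced-bandwidth configuration for fast experimentation."""
        return cls(rate=rate, n_filters=42, f_lo=22.9, f_hi=0.95 * rate / 2,
                   downsample=downsample)

    def bank(self):
        if self._bank is None:
            self._bank = build_gammatone_bank(self.n_filters, self.f_lo,
                                              self.f_hi, self.rate)
        return self._bank

    def cochleagram(self, stim: AudioStimulus):
        return apply_cochlear_model(stim, bank=self.bank(),
                                    kernel=temporal_kernel_for_rate(self.rate),
                                    downsample=self.downsample)


@dataclass
class ExperimentResult:
    """Per-pair accuracies for one condition plus summary statistics."""

    condition: dict
    per_pair_accuracy: list[float]
    median: float
    iqr: float
    ci_low: float
    ci_high: float


def bootstrap_ci_median(values, n_boot: int = 10_000, seed: int = 0,
                        alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI of the median over pairs."""
    v = np.asarray(values, dtype=np.float64)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    meds = np.median(v[idx], axis=1)
    return (float(np.quantile(meds, alpha / 2)),
            float(np.quantile(meds, 1 - alpha / 2)))


def summarize(condition: dict, accuracies, seed: int = 0) -> ExperimentResult:
    acc = [float(a) for a in accuracies]
    lo, hi = bootstrap_ci_median(acc, seed=seed)
    q25, q75 = np.percentile(acc, [25, 75])
    return ExperimentResult(condition=condition, per_pair_accuracy=acc,
                            median=float(np.median(acc)), iqr=float(q75 - q25),
                            ci_low=lo, ci_high=hi)


def crossval_svm(points: np.ndarray, labels: np.ndarray, folds: int = 30,
                 train_frac: float = 0.75, seed: int = 0,
                 svm_c: float = 1.0) -> float:
    """Mean held-out accuracy of a linear SVM over random stratified splits.

    Each of ``folds`` splits draws ``train_frac`` of each stimulus's samples
    for training (so both stimuli are represented as evenly as their
    durations allow) and tests on the rest.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim == 1:
        points = points[:, None]
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 label classes, got {classes.size}")
    counts = [int(np.sum(labels == c)) for c in classes]
    if min(counts) < folds:
        raise ValueError(
            f"smallest class has {min(counts)} samples; need >= folds={folds}")
    # standardize features once (affine; label-free)
    mu, sd = points.mean(axis=0), points.std(axis=0)
    sd[sd == 0] = 1.0
    pts = (points - mu) / sd
    rng = np.random.default_rng(seed)
    accs = np.empty(folds)
    for k in range(folds):
        train_idx, test_idx = [], []
        for c in classes:
            idx = np.nonzero(labels == c)[0]
            perm = rng.permutation(idx)
            n_train = int(round(train_frac * idx.size))
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
        tr = np.concatenate(train_idx)
        te = np.concatenate(test_idx)
        clf = LinearSVC(C=svm_c, dual="auto")
        clf.fit(pts[tr], labels[tr])
        accs[k] = float(np.mean(clf.predict(pts[te]) == labels[te]))
    return float(accs.mean())


def _fit_features(X, algorithm: str, n_features: int, seed: int):
    """Unsupervised feature learning; returns a projector(cochleagram)->T x M."""
    algorithm = algorithm.lower()
    if algorithm == "lsfa":
        space = sfa.fit_sfa(X, "identity", n_features)
    elif algorithm == "qsfa":
        space = sfa.fit_sfa(X, "quadratic", n_features)
    elif algorithm == "pca":
        space = sfa.fit_pca(X, n_features)
    elif algorithm == "ica":
        space = sfa.fit_ica(X, min(n_features, 3), seed=seed)
    elif algorithm == "upper_bound":
        return lambda C: np.asarray(C.values, dtype=np.float64)
    elif algorithm == "null":
        rng = np.random.default_rng(seed)
        chans = rng.choice(X.values.shape[1], size=n_features, replace=False)
        return lambda C: np.asarray(C.values, dtype=np.float64)[:, chans]
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return lambda C: sfa.project(space, C)


def _waveform_labels_to_frames(labels: np.ndarray, n_audio: int,
                               n_frames: int,
                               guard_frames: int = 0) -> np.ndarray:
    """Map per-audio-sample labels onto decimated cochleagram frames.

    Frames within ``guard_frames`` of a label transition are relabeled
    "gap": after filtering and decimation a frame's receptive field spans
    several milliseconds of audio, so frames straddling a stimulus boundary
    contain a mixture of both sources and belong to neither class.
    """
    pos = np.minimum((np.arange(n_frames) * n_audio) // n_frames, n_audio - 1)
    fl = labels[pos].copy()
    if guard_frames > 0:
        trans = np.nonzero(fl[1:] != fl[:-1])[0]
        for t in trans:
            lo = max(0, t - guard_frames + 1)
            fl[lo:t + 1 + guard_frames] = "gap"
    return fl


def _pad_labels(labels: np.ndarray, start: int, total: int) -> np.ndarray:
    out = np.full(total, "gap", dtype=labels.dtype)
    out[start:start + len(labels)] = labels
    return out


def _presentation(pair_wave: AudioStimulus, labels: np.ndarray,
                  snr: float | None, clutter_pool, config: PipelineConfig,
                  seed: int):
    """Optionally embed the pair in fresh clutter; return (stimulus, labels)."""
    if snr is None:
        return pair_wave, labels
    clut = make_clutter(clutter_pool, n_components=20,
                        duration=max(3.0, pair_wave.duration + 0.1),
                        seed=derive(seed, "clutter_token"))
    mix = embed_at_snr(pair_wave, clut,
                       MixSpec(snr=snr, clutter_seed=derive(seed, "placement")))
    return mix, _pad_labels(labels, mix.parts["start"], len(mix.samples))


def run_pair_experiment(a: AudioStimulus, b: AudioStimulus, algorithm: str,
                        n_features: int = 5, repeats: int | None = None,
                        seed: int = 0,
                        config: PipelineConfig | None = None,
                        snr_train: float | None = None,
                        snr_test: float | None = None,
                        clutter_pool=None,
                        permute_labels: bool = False) -> float:
    """Mean cross-validated accuracy for one stimulus pair.

    Each repeat redraws presentation order and gap, refits the algorithm on
    the (possibly cluttered, per ``snr_train``) training presentation, and
    classifies the frames of the test presentation (possibly cluttered per
    ``snr_test``, with an independent clutter token). ``permute_labels``
    shuffles the frame labels before classification — the chance control.
    """
    config = config or PipelineConfig.scaled()
    repeats = config.repeats if repeats is None else repeats
    accs = []
    for r in range(repeats):
        pair_wave, labels = make_pair_stimulus(a, b, seed=derive(seed, "pair", r))
        train_stim, _ = _presentation(pair_wave, labels, snr_train,
                                      clutter_pool, config,
                                      derive(seed, "train_clutter", r))
        test_stim, test_labels = _presentation(pair_wave, labels, snr_test,
                                               clutter_pool, config,
                                               derive(seed, "test_clutter", r))
        C_train = config.cochleagram(train_stim)
        projector = _fit_features(C_train, algorithm, n_features,
                                  seed=derive(seed, "algo", r))
        C_test = config.cochleagram(test_stim) if test_stim is not train_stim \
            else C_train
        F = projector(C_test)
        guard = int(round(config.boundary_guard * C_test.rate))
        frame_labels = _waveform_labels_to_frames(test_labels,
                                                  len(test_stim.samples),
                                                  F.shape[0], guard)
        keep = frame_labels != "gap"
        y = frame_labels[keep]
        if permute_labels:
            rng = np.random.default_rng(derive(seed, "permute", r))
            y = rng.permutation(y)
        accs.append(crossval_svm(F[keep], y, folds=config.folds,
                                 train_frac=config.train_frac,
                                 seed=derive(seed, "cv", r),
                                 svm_c=config.svm_c))
    return float(np.mean(accs))


def upper_bound_and_null(a: AudioStimulus, b: AudioStimulus, seed: int = 0,
                         n_null_channels: int = 5,
                         config: PipelineConfig | None = None,
                         repeats: int | None = None) -> tuple[float, float]:
    """Linear-SVM reference models: all channels, and a random channel subset."""
    ub = run_pair_experiment(a, b, "upper_bound", seed=seed, config=config,
                             repeats=repeats)
    null = run_pair_experiment(a, b, "null", n_features=n_null_channels,
                               seed=seed, config=config, repeats=repeats)
    return ub, null


def feature_count_sweep(pairs, k_range, algorithm: str = "qsfa",
                        seed: int = 0, config: PipelineConfig | None = None,
                        repeats: int | None = None) -> list[ExperimentResult]:
    """Accuracy as a function of the number of retained features."""
    results = []
    for k in k_range:
        accs = [run_pair_experiment(a, b, algorithm, n_features=k,
                                    seed=derive(seed, "sweep", k, i),
                                    config=config, repeats=repeats)
                for i, (a, b) in enumerate(pairs)]
        results.append(summarize(
            {"algorithm": algorithm, "n_features": int(k), "seed": seed},
            accs, seed=derive(seed, "boot", k)))
    return results


def clutter_experiment(pairs, algorithm: str, snr_train_levels,
                       snr_test_levels, clutter_pool, seed: int = 0,
                       n_features: int = 5,
                       config: PipelineConfig | None = None,
                       repeats: int | None = None) -> list[ExperimentResult]:
    """Cross train-SNR x test-SNR grid; None means a clean presentation.

    Each pair gets fresh, independent clutter tokens for the training and
    test sides, and a fresh algorithm instantiation per condition.
    """
    results = []
    for snr_tr in snr_train_levels:
        for snr_te in snr_test_levels:
            accs = [run_pair_experiment(
                a, b, algorithm, n_features=n_features,
                seed=derive(seed, "clutter", str(snr_tr), str(snr_te), i),
                config=config, repeats=repeats, snr_train=snr_tr,
                snr_test=snr_te, clutter_pool=clutter_pool)
                for i, (a, b) in enumerate(pairs)]
            results.append(summarize(
                {"algorithm": algorithm, "n_features": n_features,
                 "snr_train": snr_tr, "snr_test": snr_te, "seed": seed},
                accs, seed=derive(seed, "boot", str(snr_tr), str(snr_te))))
    return results


def snr_accuracy_correlation(results: list[ExperimentResult],
                             axis: str = "snr_test") -> tuple[float, float]:
    """Spearman rank correlation between SNR and per-pair accuracy."""
    xs, ys = [], []
    for res in results:
        snr = res.condition[axis]
        for acc in res.per_pair_accuracy:
            xs.append(snr)
            ys.append(acc)
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p)


def _concat_with_gaps(stims, seed: int) -> AudioStimulus:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(stims))
    chunks = []
    for j, idx in enumerate(order):
        s = stims[idx]
        chunks.append(s.samples)
        if j < len(order) - 1:
            gap = rng.uniform(0.05, 0.50) * s.duration
            chunks.append(np.zeros(int(round(gap * s.rate))))
    return AudioStimulus(np.concatenate(chunks), stims[0].rate, "pair",
                         seed=seed)


def generalization_experiment(class_pool: list[AudioStimulus], algorithm: str,
                              n_pairs: int = 20, seed: int = 0,
                              n_features: int = 5,
                              config: PipelineConfig | None = None,
                              repeats: int | None = None) -> ExperimentResult:
    """Hold-out generalization within one stimulus class.

    From a pool of exemplars (19 in the reference design; other sizes are
    accepted with a warning), ``n_pairs`` random test pairs are drawn; for
    each, features are learned from a concatenation of the remaining
    exemplars only, and the never-seen test pair is classified.
    """
    import warnings as _w
    config = config or PipelineConfig.scaled()
    repeats = config.repeats if repeats is None else repeats
    if len(class_pool) != 19:
        _w.warn(f"class pool has {len(class_pool)} exemplars (reference "
                "design uses 19)")
    rng = np.random.default_rng(derive(seed, "pairs"))
    accs = []
    for p in range(n_pairs):
        i, j = rng.choice(len(class_pool), size=2, replace=False)
        a, b = class_pool[i], class_pool[j]
        train_pool = [s for q, s in enumerate(class_pool) if q not in (i, j)]
        pair_accs = []
        for r in range(repeats):
            train_stim = _concat_with_gaps(train_pool,
                                           derive(seed, "train", p, r))
            C_train = config.cochleagram(train_stim)
            projector = _fit_features(C_train, algorithm, n_features,
                                      seed=derive(seed, "algo", p, r))
            pair_wave, labels = make_pair_stimulus(
                a, b, seed=derive(seed, "testpair", p, r))
            C_test = config.cochleagram(pair_wave)
            F = projector(C_test)
            guard = int(round(config.boundary_guard * C_test.rate))
            frame_labels = _waveform_labels_to_frames(
                labels, len(pair_wave.samples), F.shape[0], guard)
            keep = frame_labels != "gap"
            pair_accs.append(crossval_svm(F[keep], frame_labels[keep],
                                          folds=config.folds,
                                          train_frac=config.train_frac,
                                          seed=derive(seed, "cv", p, r),
                                          svm_c=config.svm_c))
        accs.append(float(np.mean(pair_accs)))
    return summarize({"algorithm": algorithm, "n_features": n_features,
                      "task": "generalization", "seed": seed},
                     accs, seed=derive(seed, "boot"))
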
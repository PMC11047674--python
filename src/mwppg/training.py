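"""Data-split protocol, optimisation loop and the three trial layouts.

Protocol: the window-level dataset is split 80/20 into a training portion
and an untouched held-out test set; 10-fold cross-validation runs on the
training portion for model assessment, the model is then refit on the full
training portion and evaluated once on the 20%.  The split is a pure
function of the sample's subject ids and the seed, so the four wavelength
views of the same cohort receive identical index sets.  With
``split_level="record"`` (the default) all windows of a subject land on
the same side of every partition — overlapping 5 s windows of one subject
otherwise leak across the split; ``split_level="window"`` preserves the
permissive alternative.

Trials: 1 — one wavelength's RGB scalograms through the ``single``
variant; 2 — all four wavelengths through four weight-independent conv
branches (``four_branch``); 3 — the depth-fused 12-channel tensor through
a single stack (``fused12``).

Optimisation follows the stated protocol (Adam, learning rate 0.001, MAE
loss); targets are standardised internally and predictions returned in
mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigError, DivergenceError, SplitError
from .evaluation import EvalReport, compute_metrics
from .fusion import (
    DEFAULT_COLORMAP,
    DEFAULT_IMAGE_SIZE,
    DEFAULT_WAVELET,
    fuse_window,
    window_to_rgb,
)
from .model import ACNNBiLSTM, ModelConfig, build_model
from .preprocess import QualityRule, preprocess_record
from .signal_io import MWPPGRecord

TRIAL_VARIANTS = {1: "single", 2: "four_branch", 3: "fused12"}


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol settings (defaults follow the study protocol)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    loss: str = "mae"
    split: tuple[float, float] = (0.8, 0.2)
    cv_folds: int = 10
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    split_level: str = "record"

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ConfigError("only the Adam optimiser is implemented")
        if self.loss != "mae":
            raise ConfigError("only the MAE loss is implemented")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ConfigError("split fractions must sum to 1")
        if not 0 < self.split[1] < 1:
            raise ConfigError("test fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.split_level not in ("record", "window"):
            raise ConfigError("split_level must be 'record' or 'window'")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be positive")


@dataclass
class Splits:
    """An 80/20 partition plus CV fold assignments over the train portion."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]


def make_splits(subject_ids, cfg: TrainConfig) -> Splits:
    """Partition samples 80/20 and assign CV folds, deterministically.

    ``subject_ids`` is the per-sample subject label (length = dataset
    size).  The result depends only on (subject_ids, cfg), so the four
    wavelength views of one cohort — which share subject ids — receive
    identical index sets.  At record level, all of a subject's windows
    stay together in every partition and every fold.
    """
    subject_ids = np.asarray(subject_ids)
    n = subject_ids.size
    if n == 0:
        raise SplitError("empty dataset")
    rng = np.random.default_rng(cfg.seed)

    if cfg.split_level == "record":
        subjects = np.unique(subject_ids)  # sorted, hence order-stable
        if subjects.size < cfg.cv_folds:
            raise SplitError(
                f"{subjects.size} records cannot form {cfg.cv_folds} record-level folds"
            )
        perm = rng.permutation(subjects.size)
        n_test = max(1, int(round(cfg.split[1] * subjects.size)))
        if subjects.size - n_test < cfg.cv_folds:
            raise SplitError(
                f"only {subjects.size - n_test} training records for {cfg.cv_folds} folds"
            )
        test_subjects = set(subjects[perm[:n_test]])
        train_subjects = [subjects[i] for i in perm[n_test:]]
        member = {s: np.flatnonzero(subject_ids == s) for s in subjects}
        train_idx = np.concatenate([member[s] for s in train_subjects])
        test_idx = np.concatenate([member[s] for s in sorted(test_subjects)])
        fold_groups = [
            train_subjects[f :: cfg.cv_folds] for f in range(cfg.cv_folds)
        ]
        folds = []
        for f in range(cfg.cv_folds):
            val = np.concatenate([member[s] for s in fold_groups[f]])
            tr = np.concatenate(
                [member[s] for g in range(cfg.cv_folds) if g != f for s in fold_groups[g]]
            )
            folds.append((tr, val))
    else:
        perm = rng.permutation(n)
        n_test = max(1, int(round(cfg.split[1] * n)))
        if n - n_test < cfg.cv_folds:
            raise SplitError(f"only {n - n_test} training samples for {cfg.cv_folds} folds")
        test_idx = perm[:n_test]
        train_idx = perm[n_test:]
        folds = []
        for f in range(cfg.cv_folds):
            val = train_idx[f :: cfg.cv_folds]
            tr = np.concatenate(
                [train_idx[g :: cfg.cv_folds] for g in range(cfg.cv_folds) if g != f]
            )
            folds.append((tr, val))
    return Splits(train_idx=train_idx, test_idx=test_idx, folds=folds)


@dataclass
class DatasetBundle:
    """Window-level images with labels: X (n, H, W, C), y (n, 2), subjects."""

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.y) != len(self.subjects):
            raise ConfigError("X, y and subjects must have equal length")

    def __len__(self) -> int:
        return len(self.X)


def build_image_dataset(
    records: list[MWPPGRecord],
    kind: str = "fused",
    channel: int | None = None,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    windows_per_subject: int | None = None,
    rule: QualityRule | None = None,
    wavelet: str = DEFAULT_WAVELET,
    colormap: str = DEFAULT_COLORMAP,
) -> DatasetBundle:
    """Preprocess records and render the window-level image dataset.

    ``kind="fused"`` yields H x W x 12 tensors (Trials 2-3);
    ``kind="single"`` yields one wavelength's H x W x 3 images (Trial 1,
    ``channel`` 1-based).  ``windows_per_subject`` evenly subsamples each
    record's retained windows to bound desk-scale training cost.
    """
    if kind not in ("fused", "single"):
        raise ConfigError("kind must be 'fused' or 'single'")
    if kind == "single":
        if channel is None or not 1 <= channel <= 4:
            raise ConfigError("kind='single' requires channel in 1..4")
    X, y, subjects = [], [], []
    for rec in records:
        if not rec.labeled:
            raise ConfigError(f"record {rec.subject_id} has no BP labels")
        ws, _log = preprocess_record(rec, rule=rule)
        if ws.n_windows == 0:
            continue
        take = np.arange(ws.n_windows)
        if windows_per_subject is not None and windows_per_subject < ws.n_windows:
            take = np.unique(
                np.round(np.linspace(0, ws.n_windows - 1, windows_per_subject)).astype(int)
            )
        for i in take:
            if kind == "fused":
                img = fuse_window(
                    ws.windows[:, i], ws.fs, size=image_size,
                    wavelet=wavelet, colormap=colormap,
                ).pixels
            else:
                img = window_to_rgb(
                    ws.windows[channel - 1, i], ws.fs, size=image_size,
                    wavelet=wavelet, colormap=colormap,
                )
            X.append(np.asarray(img, dtype=np.float32))
            y.append((rec.sbp, rec.dbp))
            subjects.append(rec.subject_id)
    if not X:
        raise ConfigError("no windows survived preprocessing")
    return DatasetBundle(
        X=np.stack(X), y=np.asarray(y, dtype=float), subjects=np.asarray(subjects)
    )


@dataclass
class TrainResult:
    model: ACNNBiLSTM
    splits: Splits
    fold_reports: list[dict[str, EvalReport]]
    test_reports: dict[str, EvalReport]
    history: list[float]


def _fit(
    model: ACNNBiLSTM,
    X: np.ndarray,
    y: np.ndarray,
    tcfg: TrainConfig,
    rng: np.random.Generator,
) -> list[float]:
    """Mini-batch Adam/MAE training; returns per-epoch mean loss.

    Targets are standardised with the training-set statistics; the fitted
    affine de-standardisation is stored on the model so predictions come
    out in mmHg.
    """
    y_mean = y.mean(axis=0)
    y_sd = np.where(y.std(axis=0) > 0, y.std(axis=0), 1.0)
    model.set_output_scaling(y_mean, y_sd)
    ys = (y - y_mean) / y_sd
    opt = nn.Adam(model.params(), lr=tcfg.learning_rate)
    n = len(X)
    history = []
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            opt.zero_grad()
            pred = model.forward(X[idx], train=True)
            loss, grad = nn.mae_loss(pred, ys[idx])
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, step {start // tcfg.batch_size} "
                    f"(lr={tcfg.learning_rate}, batch={len(idx)})"
                )
            model.backward(grad)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def _evaluate(model: ACNNBiLSTM, X: np.ndarray, y: np.ndarray) -> dict[str, EvalReport]:
    pred = model.predict(X)
    return {
        "sbp": compute_metrics(y[:, 0], pred[:, 0]),
        "dbp": compute_metrics(y[:, 1], pred[:, 1]),
    }


def train_model(
    data: DatasetBundle,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    run_cv: bool = True,
) -> TrainResult:
    """Run the full protocol: CV on the 80%, refit, evaluate on the 20%.

    Cross-validation serves model assessment only; the reported test
    metrics always come from the untouched held-out portion.  ``run_cv``
    can skip the fold loop when only the held-out evaluation is needed.
    """
    splits = make_splits(data.subjects, tcfg)
    fold_reports = []
    if run_cv:
        for k, (tr, val) in enumerate(splits.folds):
            fold_model = build_model(mcfg)
            rng = np.random.default_rng(np.random.SeedSequence([tcfg.seed, 100 + k]))
            _fit(fold_model, data.X[tr], data.y[tr], tcfg, rng)
            fold_reports.append(_evaluate(fold_model, data.X[val], data.y[val]))
    model = build_model(mcfg)
    rng = np.random.default_rng(np.random.SeedSequence([tcfg.seed, 0]))
    history = _fit(model, data.X[splits.train_idx], data.y[splits.train_idx], tcfg, rng)
    test_reports = _evaluate(model, data.X[splits.test_idx], data.y[splits.test_idx])
    return TrainResult(
        model=model,
        splits=splits,
        fold_reports=fold_reports,
        test_reports=test_reports,
        history=history,
    )


@dataclass
class TrialResult:
    trial: int
    channel: int | None
    result: TrainResult

    @property
    def test_reports(self) -> dict[str, EvalReport]:
        return self.result.test_reports


def run_trial(
    trial: int,
    records: list[MWPPGRecord],
    channel: int | None = None,
    mcfg: ModelConfig | None = None,
    tcfg: TrainConfig | None = None,
    run_cv: bool = True,
    **dataset_kwargs,
) -> TrialResult:
    """Run one of the three experiment layouts end to end.

    Trial 1 requires ``channel`` (1-4) and models one wavelength; Trials
    2-3 consume all four wavelengths (branch-wise and depth-fused
    respectively).  The split depends only on subject ids and the seed, so
    all trials at one seed share identical partitions.
    """
    if trial not in TRIAL_VARIANTS:
        raise ConfigError("trial must be 1, 2 or 3")
    if trial == 1 and channel is None:
        raise ConfigError("trial 1 requires a channel (1-4)")
    variant = TRIAL_VARIANTS[trial]
    mcfg = mcfg if mcfg is not None else ModelConfig(variant=variant)
    if mcfg.variant != variant:
        raise ConfigError(f"trial {trial} needs variant {variant!r}; got {mcfg.variant!r}")
    tcfg = tcfg if tcfg is not None else TrainConfig()
    data = build_image_dataset(
        records,
        kind="single" if trial == 1 else "fused",
        channel=channel if trial == 1 else None,
        **dataset_kwargs,
    )
    result = train_model(data, mcfg, tcfg, run_cv=run_cv)
    return TrialResult(trial=trial, channel=channel, result=result)


# ---------------------------------------------------------------------------
# Desk-scale presets: the problem sizes this package's experiments run at.
# ---------------------------------------------------------------------------
DESK_IMAGE_SIZE = (32, 32)
DESK_WINDOWS_PER_SUBJECT = 14


def desk_scale_model(variant: str) -> ModelConfig:
    """Reduced-width architecture for CPU-scale experiments."""
    return ModelConfig(
        variant=variant,
        conv_channels=(16, 32, 64),
        lstm_hidden=48,
        fc_sizes=(32, 2),
    )


def desk_scale_train(seed: int = 0, epochs: int = 60, cv_folds: int = 2) -> TrainConfig:
    """Desk-scale protocol: same optimiser/loss/split, fewer folds/epochs."""
    return TrainConfig(epochs=epochs, cv_folds=cv_folds, seed=seed)
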
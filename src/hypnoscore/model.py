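"""The DeepConvLSTM sleep scorer: input windows, architecture, training, search.

Each 30-s epoch is scored from a 21-epoch window — the 10 epochs preceding,
the scored epoch, and the 10 following — of C channels (1 activity-count
channel, optionally plus the 17 HRV metrics; record edges are padded by
replicating the terminal epoch).  The classifier is a stack of 1-D
convolutions along the epoch axis, each followed by batch normalization and
ReLU, then LSTM layers whose final hidden state feeds the classification
head: a single sigmoid unit trained with binary cross-entropy for
sleep/wake, or a 3-way softmax for W/NREM/REM.  Convolution kernels carry an
L2 penalty; training checkpoints at the minimum-validation-loss epoch.

Channel standardization statistics are always computed on training subjects
only and reused verbatim at validation/test time; subject-level leakage
between splits is a hard error.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .hrv import FEATURE_COLUMNS, hrv_per_epoch
from .records import SubjectRecord
from .simulate import train_test_split_subjects
from .stages import STAGES3, Hypnogram, collapse_to_3

HALF_WIDTH = 10  # epochs on each side of the scored epoch
WINDOW_EPOCHS = 2 * HALF_WIDTH + 1

#: feature-set names -> HRV window length in seconds (None = activity only)
FEATURE_SETS = {
    "count": None,
    "count+hrv30": 30.0,
    "count+hrv180": 180.0,
    "count+hrv300": 300.0,
}


# ----------------------------------------------------------------- windowing


class ChannelScaler:
    """Per-channel standardization with NaN-aware statistics.

    Fit on training data only; NaN cells (missing HRV sentinels) are imputed
    with the training mean, i.e. zero after scaling.
    """

    def __init__(self):
        self.mean_ = None
        self.std_ = None
        self.channels_ = None

    def fit(self, mat: np.ndarray, channel_names: list[str]) -> "ChannelScaler":
        all_nan = np.all(np.isnan(mat), axis=0)
        if np.any(all_nan):
            bad = [channel_names[i] for i in np.nonzero(all_nan)[0]]
            raise ValueError(f"channel(s) with no finite values: {bad}")
        self.mean_ = np.nanmean(mat, axis=0)
        self.std_ = np.nanstd(mat, axis=0)
        self.std_[self.std_ == 0] = 1.0
        self.channels_ = list(channel_names)
        return self

    def transform(self, mat: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        out = (mat - self.mean_) / self.std_
        return np.where(np.isnan(out), 0.0, out)


def record_channels(rec: SubjectRecord, feature_set: str, align: str = "trailing") -> pd.DataFrame:
    """Per-epoch channel matrix for one record (columns named)."""
    window_len = FEATURE_SETS[feature_set]
    df = pd.DataFrame({"activity": rec.grid.activity})
    if window_len is not None:
        hrv = hrv_per_epoch(rec.rr, rec.grid.n_epochs, window_len, align=align)
        for col in FEATURE_COLUMNS:
            df[col] = hrv[col].to_numpy()
    return df


def build_windows(channels: np.ndarray, half_width: int = HALF_WIDTH) -> np.ndarray:
    """Sliding 21-epoch windows, edge-padded by terminal-epoch replication.

    ``channels`` is (n_epochs, C); returns (n_epochs, 2*half_width+1, C) with
    window *i* centered on epoch *i*.
    """
    c = np.asarray(channels, dtype=float)
    if c.ndim != 2:
        raise ValueError("channels must be 2-D (epochs x channels)")
    padded = np.concatenate(
        [np.repeat(c[:1], half_width, axis=0), c, np.repeat(c[-1:], half_width, axis=0)]
    )
    n = c.shape[0]
    width = 2 * half_width + 1
    return np.stack([padded[i : i + width] for i in range(n)], axis=0)


STAGE_TO_INT3 = {s: i for i, s in enumerate(STAGES3)}  # W=0, NREM=1, REM=2


def labels_to_int(hyp_labels, n_classes: int) -> np.ndarray:
    """3-class codes (W/NREM/REM) or binary sleep codes (wake=0, sleep=1)."""
    lab3 = collapse_to_3(hyp_labels)
    if n_classes == 3:
        return np.array([STAGE_TO_INT3[s] for s in lab3])
    return (lab3 != "W").astype(int)


@dataclass
class Dataset:
    """Windows + labels + subject ids, ready for training."""

    x: np.ndarray  # (N, 21, C)
    y: np.ndarray  # (N,)
    subjects: np.ndarray  # (N,) subject id per window
    channel_names: list


def prepare_dataset(
    records: list[SubjectRecord],
    feature_set: str,
    n_classes: int = 3,
    scaler: ChannelScaler | None = None,
    align: str = "trailing",
) -> tuple[Dataset, ChannelScaler]:
    """Assemble windows for a set of records.

    When ``scaler`` is None, standardization statistics are fitted on these
    records (training); otherwise the provided (training-fitted) scaler is
    reused, as required at validation/test time.
    """
    frames, labels, subjects = [], [], []
    for rec in records:
        if rec.grid.stages is None:
            raise ValueError(f"record {rec.subject} lacks reference stages")
        df = record_channels(rec, feature_set, align=align)
        frames.append(df)
        labels.append(labels_to_int(rec.grid.stages.labels, n_classes))
        subjects.append(np.repeat(rec.subject, len(df)))
    names = list(frames[0].columns)
    stacked = np.concatenate([f.to_numpy(dtype=float) for f in frames])
    if scaler is None:
        scaler = ChannelScaler().fit(stacked, names)
    xs = []
    for f in frames:
        xs.append(build_windows(scaler.transform(f.to_numpy(dtype=float))))
    return (
        Dataset(
            x=np.concatenate(xs),
            y=np.concatenate(labels),
            subjects=np.concatenate(subjects),
            channel_names=names,
        ),
        scaler,
    )


# -------------------------------------------------------------- architecture


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the DeepConvLSTM scorer.

    The published architecture is 9 convolutional layers (each with batch
    normalization) and 4 LSTM layers; per-layer widths were not published,
    so kernel 3 / 32 filters / 32 LSTM units with L2 1e-4 and Adam 1e-3 are
    the defaults, all overridable.  ``desk_scale`` (2 conv / 1 LSTM, width
    16) is the reduced configuration used for CPU-scale experiments.
    """

    n_conv_layers: int = 9
    filters: int = 32
    kernel: int = 3
    n_lstm_layers: int = 4
    lstm_units: int = 32
    l2: float = 1e-4
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 5
    n_classes: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_conv_layers < 1 or self.filters < 1 or self.lstm_units < 1:
            raise ValueError("layer counts and widths must be >= 1")
        if self.n_lstm_layers < 0:
            raise ValueError("n_lstm_layers must be >= 0")
        if self.lr <= 0 or self.l2 < 0:
            raise ValueError("rates must be positive")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")

    @classmethod
    def desk_scale(cls, **kw) -> "ModelConfig":
        base = dict(n_conv_layers=2, filters=16, n_lstm_layers=1, lstm_units=16,
                    max_epochs=30, patience=6)
        base.update(kw)
        return cls(**base)

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)


def build_deepconvlstm(cfg: ModelConfig, n_channels: int) -> nn.Network:
    """Instantiate the network: conv(+BN+ReLU) stack, LSTM stack, class head."""
    rng = np.random.default_rng(cfg.seed)
    layers: list[nn.Layer] = []
    c = n_channels
    for _ in range(cfg.n_conv_layers):
        layers.append(nn.Conv1D(c, cfg.filters, cfg.kernel, rng, l2=cfg.l2))
        layers.append(nn.BatchNorm(cfg.filters))
        layers.append(nn.ReLU())
        c = cfg.filters
    for _ in range(cfg.n_lstm_layers):
        layers.append(nn.LSTM(c, cfg.lstm_units, rng, return_sequences=True))
        c = cfg.lstm_units
    layers.append(nn.LastStep())
    out_dim = 1 if cfg.n_classes == 2 else cfg.n_classes
    layers.append(nn.Dense(c, out_dim, rng))
    return nn.Network(layers, cfg.n_classes)


def expected_n_params(cfg: ModelConfig, n_channels: int) -> int:
    """Closed-form trainable-parameter count of :func:`build_deepconvlstm`."""
    total = 0
    c = n_channels
    for _ in range(cfg.n_conv_layers):
        total += cfg.kernel * c * cfg.filters + cfg.filters  # conv W + b
        total += 2 * cfg.filters  # batch-norm gamma + beta
        c = cfg.filters
    for _ in range(cfg.n_lstm_layers):
        total += 4 * (c * cfg.lstm_units + cfg.lstm_units**2 + cfg.lstm_units)
        c = cfg.lstm_units
    out_dim = 1 if cfg.n_classes == 2 else cfg.n_classes
    total += c * out_dim + out_dim
    return total


# ------------------------------------------------------------------ training


@dataclass
class TrainedModel:
    """A trained scorer: network, config, scaler, history, checkpoint rule."""

    net: nn.Network
    cfg: ModelConfig
    scaler: ChannelScaler
    feature_set: str
    history: list = field(default_factory=list)
    checkpoint_rule: str = "min-validation-loss"

    @property
    def best_epoch(self) -> int:
        return int(np.argmin([v for _, v in self.history]))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(x)


def _check_disjoint(subjects_a, subjects_b, what: str):
    leak = set(subjects_a) & set(subjects_b)
    if leak:
        raise ValueError(f"subject leakage between {what}: {sorted(leak)}")


def class_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    """Inverse-frequency class weights, normalized to mean 1."""
    counts = np.bincount(y, minlength=n_classes).astype(float)
    counts[counts == 0] = 1.0
    w = counts.sum() / (n_classes * counts)
    return w


def train_model(
    train: Dataset,
    val: Dataset,
    cfg: ModelConfig,
    scaler: ChannelScaler,
    feature_set: str,
) -> TrainedModel:
    """Train with Adam + class weights, checkpointing at min validation loss."""
    _check_disjoint(train.subjects, val.subjects, "train/validation")
    net = build_deepconvlstm(cfg, train.x.shape[2])
    cw = class_weights(train.y, cfg.n_classes)
    history, _ = nn.fit(
        net, train.x, train.y, val.x, val.y,
        lr=cfg.lr, batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
        patience=cfg.patience, class_weight=cw, seed=cfg.seed,
    )
    return TrainedModel(net=net, cfg=cfg, scaler=scaler, feature_set=feature_set,
                        history=history)


def predict_stages(model: TrainedModel, x: np.ndarray) -> tuple[Hypnogram, np.ndarray]:
    """Score windows; returns the hypnogram and per-epoch class probabilities.

    3-class models emit W/NREM/REM argmax labels; binary models emit a
    W/sleep hypnogram (sleep mapped to NREM for the binary view).
    """
    if x.shape[2] != len(model.scaler.channels_):
        raise ValueError(
            f"channel mismatch: model expects {len(model.scaler.channels_)}, got {x.shape[2]}"
        )
    probs = model.predict_proba(x)
    if model.cfg.n_classes == 3:
        labels = np.array([STAGES3[i] for i in probs.argmax(axis=1)], dtype=object)
        return Hypnogram(labels), probs
    return Hypnogram.from_sleep_mask(probs[:, 1] >= 0.5), probs


def split_train_val(
    records: list[SubjectRecord], seed: int, val_frac: float = 0.30
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Subject-level train/validation split (70/30 by default)."""
    tr, va = train_test_split_subjects(records, seed=seed, train_frac=1.0 - val_frac)
    if not tr or not va:
        raise ValueError("both train and validation splits must be non-empty")
    return tr, va


def fit_on_records(
    records: list[SubjectRecord],
    feature_set: str,
    cfg: ModelConfig,
    align: str = "trailing",
) -> TrainedModel:
    """Convenience: subject-level 70/30 split, feature building, training."""
    tr_recs, va_recs = split_train_val(records, seed=cfg.seed)
    train, scaler = prepare_dataset(tr_recs, feature_set, cfg.n_classes, align=align)
    val, _ = prepare_dataset(va_recs, feature_set, cfg.n_classes, scaler=scaler, align=align)
    return train_model(train, val, cfg, scaler, feature_set)


def score_record(model: TrainedModel, rec: SubjectRecord, align: str = "trailing") -> Hypnogram:
    """Score one record with a trained model (training-set scaler reused)."""
    df = record_channels(rec, model.feature_set, align=align)
    x = build_windows(model.scaler.transform(df.to_numpy(dtype=float)))
    hyp, _ = predict_stages(model, x)
    return hyp


# ------------------------------------------------------------- random search


DEFAULT_SEARCH_SPACE = {
    "l2": (1e-6, 1e-2),  # log-uniform regularization rate
    "lr": (1e-4, 1e-2),  # log-uniform learning rate
    "n_conv_layers": (1, 4),
    "filters": (8, 32),
    "lstm_units": (8, 32),  # "hidden nodes"
    "n_lstm_layers": (1, 3),  # DeepConvLSTM candidates only
}


def sample_config(space: dict, rng, with_lstm: bool, base: ModelConfig) -> ModelConfig:
    def log_u(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    def int_u(lo, hi):
        return int(rng.integers(lo, hi + 1))

    return base.replace(
        l2=log_u(*space["l2"]),
        lr=log_u(*space["lr"]),
        n_conv_layers=int_u(*space["n_conv_layers"]),
        filters=int_u(*space["filters"]),
        lstm_units=int_u(*space["lstm_units"]),
        n_lstm_layers=int_u(*space["n_lstm_layers"]) if with_lstm else 0,
        seed=int(rng.integers(0, 2**31)),
    )


def subject_kfold(subjects: list, k: int, seed: int) -> list[tuple[list, list]]:
    """Subject-level k-fold partition: folds are disjoint and cover all."""
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(subjects)))
    folds = [order[i::k] for i in range(k)]
    out = []
    for i in range(k):
        test_i = set(folds[i])
        train = [subjects[j] for j in order if j not in test_i]
        test = [subjects[j] for j in folds[i]]
        out.append((train, test))
    return out


def random_search(
    records: list[SubjectRecord],
    feature_set: str,
    n_cnn: int = 5,
    n_dclstm: int = 5,
    seed: int = 0,
    space: dict | None = None,
    base: ModelConfig | None = None,
    top_k: int = 5,
    cv_folds: int = 5,
) -> pd.DataFrame:
    """Random hyperparameter search, ranked by validation loss.

    Samples ``n_cnn`` convolution-only and ``n_dclstm`` conv+LSTM candidates
    from the search space, trains each on a 70/30 subject split, ranks by
    validation loss, then re-scores the top ``top_k`` by subject-level
    ``cv_folds``-fold cross-validation.  Deterministic given the seed.
    """
    if n_cnn + n_dclstm < 1:
        raise ValueError("at least one candidate required")
    space = space or DEFAULT_SEARCH_SPACE
    if not space:
        raise ValueError("empty search space")
    base = base or ModelConfig.desk_scale()
    rng = np.random.default_rng(seed)
    cands = [sample_config(space, rng, False, base) for _ in range(n_cnn)]
    cands += [sample_config(space, rng, True, base) for _ in range(n_dclstm)]
    tr_recs, va_recs = split_train_val(records, seed=seed)
    train, scaler = prepare_dataset(tr_recs, feature_set, base.n_classes)
    val, _ = prepare_dataset(va_recs, feature_set, base.n_classes, scaler=scaler)
    rows = []
    for idx, cfg in enumerate(cands):
        model = train_model(train, val, cfg, scaler, feature_set)
        rows.append(
            {
                "candidate": idx,
                "family": "cnn" if cfg.n_lstm_layers == 0 else "deepconvlstm",
                "val_loss": min(v for _, v in model.history),
                "config": json.dumps(dataclasses.asdict(cfg)),
            }
        )
    table = pd.DataFrame(rows).sort_values("val_loss", kind="stable").reset_index(drop=True)
    # top-k re-evaluation with subject-level k-fold CV
    cv_losses = []
    for _, row in table.head(top_k).iterrows():
        cfg = ModelConfig(**json.loads(row["config"]))
        losses = []
        for fold_train, fold_test in subject_kfold(records, cv_folds, seed):
            ftr, fsc = prepare_dataset(fold_train, feature_set, cfg.n_classes)
            fte, _ = prepare_dataset(fold_test, feature_set, cfg.n_classes, scaler=fsc)
            m = train_model(ftr, fte, cfg, fsc, feature_set)
            losses.append(min(v for _, v in m.history))
        cv_losses.append(float(np.mean(losses)))
    table["cv_loss"] = pd.Series(cv_losses).reindex(table.index)
    return table


# --------------------------------------------------- feature-set comparison


def compare_feature_sets(
    records: list[SubjectRecord],
    feature_sets: list[str] | None = None,
    cfg: ModelConfig | None = None,
    seed: int = 0,
    positive_class: str = "sleep",
) -> pd.DataFrame:
    """Train one model per feature set and summarize test-subject agreement.

    Subjects are split 65/35 into train+validation and test once, shared by
    all feature sets; metrics (accuracy, sensitivity, specificity, kappa,
    plus 3-class kappa) are computed per test subject against the reference
    stages and summarized as mean and 95% CI across subjects.
    """
    from .evaluate import epoch_metrics, kappa_multiclass, summarize_subjects

    feature_sets = feature_sets or list(FEATURE_SETS)
    cfg = cfg or ModelConfig.desk_scale()
    trainval, test = train_test_split_subjects(records, seed=seed)
    _check_disjoint([r.subject for r in trainval], [r.subject for r in test], "train/test")
    rows = []
    for fs in feature_sets:
        model = fit_on_records(trainval, fs, cfg)
        per_subject = []
        for rec in test:
            pred = score_record(model, rec)
            ref = rec.grid.stages.to_hypnogram()
            m = epoch_metrics(ref, pred, positive_class=positive_class)
            m["kappa3"] = kappa_multiclass(ref.labels, pred.labels) * 100.0
            per_subject.append(m)
        df = pd.DataFrame(per_subject)
        summary = summarize_subjects(df)
        row = {"feature_set": fs}
        for _, s in summary.iterrows():
            row[s["metric"]] = s["mean"]
            row[f"{s['metric']}_lo"] = s["ci_lo"]
            row[f"{s['metric']}_hi"] = s["ci_hi"]
        rows.append(row)
    cols = ["feature_set"]
    for m in ("accuracy", "sensitivity", "specificity", "kappa", "kappa3"):
        cols += [m, f"{m}_lo", f"{m}_hi"]
    return pd.DataFrame(rows)[cols]
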
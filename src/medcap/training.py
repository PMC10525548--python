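"""Training loop, experiment grid and family accuracy summaries.

The transcoder is trained with teacher forcing under masked sparse
categorical cross-entropy (padding positions excluded), one of four
gradient optimizers, early stopping on validation loss, and full seeding:
a (config, seed) pair reproduces the history exactly. ``run_grid`` sweeps
backbone x optimizer x {transfer-learning, fine-tuning, augmentation}
switches and records per-cell loss, teacher-forced token accuracy, epochs
and wall-clock times; ``family_summary`` reduces a family's accuracies to
mean, population standard deviation, extremes and mu +/- sigma.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._tensor import Tensor, cross_entropy_logits
from .errors import ConfigurationError, ValidationError
from .optim import OPTIMIZERS, make_optimizer

__all__ = [
    "TrainConfig",
    "ExperimentRecord",
    "FamilySummary",
    "GridSpec",
    "sparse_cce",
    "train",
    "run_grid",
    "best_record",
    "family_summary",
    "records_to_frame",
    "GRID_HEADER",
]

GRID_HEADER = ["ID", "OPTZ", "TL", "TR", "IA", "Loss", "ACC", "Epochs",
               "Training Time (s)", "Test Time (s)"]
SUMMARY_HEADER = ["CNN", "mu", "sigma", "Min", "Max", "mu-sigma", "mu+sigma"]

_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float | None = None  # None -> optimizer's own default
    batch_size: int = 32
    max_epochs: int = 20
    early_stop_patience: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if self.optimizer.lower() not in OPTIMIZERS:
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class ExperimentRecord:
    id: int
    backbone: str
    optimizer: str
    tl: bool
    tr: bool
    ia: bool
    loss: float = float("nan")
    acc: float = float("nan")
    epochs: int = 0
    train_time_s: float = 0.0
    test_time_s: float = 0.0
    error: str | None = None


@dataclass(frozen=True)
class FamilySummary:
    family: str
    mu: float
    sigma: float
    min: float
    max: float

    @property
    def mu_minus_sigma(self) -> float:
        return self.mu - self.sigma

    @property
    def mu_plus_sigma(self) -> float:
        return self.mu + self.sigma

    def rounded(self, ndigits: int = 4) -> dict:
        return {
            "CNN": self.family,
            "mu": round(self.mu, ndigits),
            "sigma": round(self.sigma, ndigits),
            "Min": round(self.min, ndigits),
            "Max": round(self.max, ndigits),
            "mu-sigma": round(self.mu_minus_sigma, ndigits),
            "mu+sigma": round(self.mu_plus_sigma, ndigits),
        }


# ---------------------------------------------------------------------------
# loss and accuracy


def sparse_cce(probabilities, labels, pad_id: int | None = None) -> float:
    """Mean -ln p(true class) over non-padding positions.

    ``probabilities``: rows over C classes (any leading shape); ``labels``:
    matching integer array. Positions whose label equals ``pad_id`` are
    excluded from the mean. Probabilities are clamped at a small epsilon
    before the log.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels)
    C = p.shape[-1]
    if labels.min() < 0 or labels.max() >= C:
        raise ValidationError("label index out of range")
    picked = np.take_along_axis(p, labels[..., None], axis=-1)[..., 0]
    mask = np.ones(labels.shape, dtype=bool) if pad_id is None else labels != pad_id
    if not mask.any():
        raise ValidationError("no non-padding positions to score")
    return float(-(np.log(np.clip(picked, _EPS, None)) * mask).sum() / mask.sum())


def _masked_token_accuracy(logits: np.ndarray, labels: np.ndarray, pad_id: int) -> float:
    mask = labels != pad_id
    pred = logits.argmax(axis=-1)
    return float(((pred == labels) & mask).sum() / max(mask.sum(), 1))


# ---------------------------------------------------------------------------
# training


def _epoch_pass(model, feats, tokens, pad_id, optimizer=None, batch_size=32, order=None):
    """One pass over the data; trains when an optimizer is given."""
    n = feats.shape[0]
    idx = np.arange(n) if order is None else order
    losses, accs, weights = [], [], []
    for lo in range(0, n, batch_size):
        sel = idx[lo : lo + batch_size]
        x, t = feats[sel], tokens[sel]
        inp, lab = t[:, :-1], t[:, 1:]
        logits = model.logits(x, inp)
        mask = lab != pad_id
        loss = cross_entropy_logits(logits, lab, mask)
        if optimizer is not None:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        losses.append(float(loss.data))
        accs.append(_masked_token_accuracy(logits.data, lab, pad_id))
        weights.append(int(mask.sum()))
    w = np.array(weights, dtype=float)
    w /= w.sum()
    return float(np.dot(losses, w)), float(np.dot(accs, w))


def train(model, bundle, targets, config: TrainConfig, val_bundle=None, val_targets=None):
    """Teacher-forced training of a caption model on a feature bundle.

    ``targets`` is the padded token matrix aligned with ``bundle``. Stops at
    ``max_epochs`` or once validation loss has not improved for
    ``early_stop_patience`` consecutive epochs (patience 0 disables early
    stopping); the weights of the best validation epoch are restored.
    Returns ``(model, history)`` where history has per-epoch train/val loss
    and token accuracy.
    """
    feats = np.asarray(bundle.features if hasattr(bundle, "features") else bundle)
    tokens = np.asarray(targets)
    if feats.shape[0] != tokens.shape[0]:
        raise ValidationError("bundle and targets must be aligned")
    pad_id = model.vocabulary.pad_id
    vfeats = feats if val_bundle is None else np.asarray(
        val_bundle.features if hasattr(val_bundle, "features") else val_bundle
    )
    vtokens = tokens if val_targets is None else np.asarray(val_targets)

    optimizer = make_optimizer(config.optimizer, model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_loss, best_state, stale = np.inf, None, 0
    for _ in range(config.max_epochs):
        order = rng.permutation(feats.shape[0])
        tr_loss, tr_acc = _epoch_pass(
            model, feats, tokens, pad_id, optimizer, config.batch_size, order
        )
        va_loss, va_acc = _epoch_pass(model, vfeats, vtokens, pad_id, None, config.batch_size)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)
        if va_loss < best_loss - 1e-12:
            best_loss, best_state, stale = va_loss, model.state_dict(), 0
        else:
            stale += 1
            if config.early_stop_patience and stale >= config.early_stop_patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    history["epochs"] = len(history["train_loss"])
    return model, history


# ---------------------------------------------------------------------------
# experiment grid


@dataclass(frozen=True)
class GridSpec:
    backbones: tuple
    optimizers: tuple = ("adam", "adamw", "adadelta", "adafactor")
    tl_options: tuple = (False,)
    tr_options: tuple = (False,)
    ia_options: tuple = (False,)

    def cells(self):
        i = 0
        for bb in self.backbones:
            for tl in self.tl_options:
                for tr in self.tr_options:
                    for ia in self.ia_options:
                        for opt in self.optimizers:
                            i += 1
                            yield i, bb, opt, tl, tr, ia

    def __len__(self):
        return (len(self.backbones) * len(self.optimizers) * len(self.tl_options)
                * len(self.tr_options) * len(self.ia_options))


def run_grid(grid: GridSpec, corpus_dir, config: TrainConfig, **model_kw) -> list[ExperimentRecord]:
    """Train one model per grid cell on a curated corpus directory.

    Emits records in grid order; a failing cell is recorded with its error
    message rather than aborting the sweep. The best record is the one
    maximizing accuracy (see :func:`best_record`).
    """
    from .pipeline import run_experiment  # late import: pipeline uses train()

    if len(grid) == 0:
        raise ConfigurationError("empty experiment grid")
    records = []
    for cell_id, bb, opt, tl, tr, ia in grid.cells():
        rec = ExperimentRecord(cell_id, bb, opt, tl, tr, ia)
        try:
            out = run_experiment(
                corpus_dir, backbone=bb, optimizer=opt, tl=tl, tr=tr, ia=ia,
                config=config, **model_kw,
            )
            rec.loss = out["val_loss"]
            rec.acc = out["val_acc"]
            rec.epochs = out["epochs"]
            rec.train_time_s = out["train_time_s"]
            rec.test_time_s = out["test_time_s"]
        except Exception as exc:  # per-cell isolation
            rec.error = f"{type(exc).__name__}: {exc}"
        records.append(rec)
    return records


def best_record(records) -> ExperimentRecord:
    """The record with the highest accuracy (first on ties)."""
    scored = [r for r in records if np.isfinite(r.acc)]
    if not scored:
        raise ValidationError("no successful records")
    return max(scored, key=lambda r: (r.acc, -r.id))


def records_to_frame(records) -> pd.DataFrame:
    rows = [
        {
            "ID": r.id, "OPTZ": r.optimizer, "TL": int(r.tl), "TR": int(r.tr),
            "IA": int(r.ia), "Loss": r.loss, "ACC": r.acc, "Epochs": r.epochs,
            "Training Time (s)": r.train_time_s, "Test Time (s)": r.test_time_s,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=GRID_HEADER)


# ---------------------------------------------------------------------------
# summaries


def family_summary(accuracies, family: str = "") -> FamilySummary:
    """Mean, population standard deviation (divisor n) and extremes."""
    a = np.asarray(list(accuracies), dtype=np.float64)
    if a.size == 0:
        raise ValidationError("family_summary requires a non-empty list")
    return FamilySummary(family, float(a.mean()), float(a.std()), float(a.min()), float(a.max()))


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([s.rounded() for s in summaries], columns=SUMMARY_HEADER)
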
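"""Training and evaluation of MIL models.

Optimisation is Adam on the bag-level cross-entropy, one optimisation step
per bag (batch = one bag), with bags visited in seed-shuffled order each
epoch.  After every epoch the model is evaluated (running-statistics mode) on
both splits; the returned model carries the parameters from the epoch with
the strictly highest validation macro-F1, ties resolved to the earliest
epoch.  Data splits are made at the animal level so no mouse contributes
images to both subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score

from .errors import InvalidArgumentError, NumericError
from .mil import Bag, MilAttentionModel, ModelConfig, build_model


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise InvalidArgumentError("learning_rate must be positive")
        if self.epochs < 1:
            raise InvalidArgumentError("epochs must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_f1: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0
    best_val_f1: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "train_f1": self.train_f1,
                "val_f1": self.val_f1,
                "train_acc": self.train_acc,
                "val_acc": self.val_acc,
            }
        )


def split_by_animal(
    manifest: pd.DataFrame, fraction: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort manifest into train/validation at the animal level.

    No animal appears in both subsets.  The split is performed within each
    (class, treatment) group so both subsets see every treatment whenever the
    grouping permits, and class counts stay as balanced as whole-animal
    assignment allows.
    """
    for col in ("animal_id", "class", "treatment"):
        if col not in manifest.columns:
            raise InvalidArgumentError(f"manifest missing column {col!r}")
    if not (0 < fraction < 1):
        raise InvalidArgumentError("fraction must be in (0, 1)")
    for cls, sub in manifest.groupby("class"):
        if sub["animal_id"].nunique() < 2:
            raise InvalidArgumentError(
                f"class {cls!r} has fewer than 2 animals; an animal-level split is impossible"
            )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    train_idx: list[int] = []
    val_idx: list[int] = []
    for _, cls_group in manifest.groupby("class", sort=True):
        # Animals are the assignment unit.  Order them by interleaving the
        # treatment groups (an animal's modal treatment) so both subsets see
        # every treatment whenever the grouping permits, then fill the train
        # subset greedily up to the per-class image target.
        animal_rows = {a: cls_group.index[cls_group["animal_id"] == a]
                       for a in cls_group["animal_id"].unique()}
        by_treatment: dict[str, list[str]] = {}
        for a, rows in animal_rows.items():
            modal = cls_group.loc[rows, "treatment"].mode().iloc[0]
            by_treatment.setdefault(modal, []).append(a)
        queues = []
        for t in sorted(by_treatment):
            group = sorted(by_treatment[t])
            queues.append([group[j] for j in rng.permutation(len(group))])
        queues = [queues[j] for j in rng.permutation(len(queues))]
        ordered: list[str] = []
        while any(queues):
            for q in queues:
                if q:
                    ordered.append(q.pop(0))
        target = fraction * len(cls_group)
        taken = 0
        for a in ordered:
            rows = animal_rows[a]
            if taken + len(rows) <= int(np.ceil(target)) and taken < target:
                train_idx.extend(rows)
                taken += len(rows)
            else:
                val_idx.extend(rows)
    train = manifest.loc[sorted(train_idx)]
    val = manifest.loc[sorted(val_idx)]
    if train.empty or val.empty:
        raise InvalidArgumentError("split produced an empty subset; adjust fraction or cohort")
    assert not set(train["animal_id"]) & set(val["animal_id"])
    return train, val


def _predict(model, bags: list[Bag]):
    losses, preds, labels = [], [], []
    for bag in bags:
        logits, _ = model.forward(bag)
        logits = np.asarray(logits, dtype=float)
        m = logits.max()
        lse = m + np.log(np.exp(logits - m).sum())
        losses.append(float(lse - logits[bag.label]))
        preds.append(int(np.argmax(logits)))
        labels.append(int(bag.label))
    return np.array(losses), np.array(preds), np.array(labels)


def evaluate(model, bags: list[Bag]) -> dict[str, float]:
    """Mean cross-entropy, macro-F1 and accuracy of a model over bags.

    Macro-F1 is the unweighted mean of per-class F1 over the classes present
    in the labels; a class never predicted contributes F1 = 0.
    """
    if not bags:
        raise InvalidArgumentError("evaluate needs at least one bag")
    losses, preds, labels = _predict(model, bags)
    return {
        "loss": float(losses.mean()),
        "macro_f1": float(f1_score(labels, preds, average="macro", zero_division=0.0)),
        "accuracy": float(accuracy_score(labels, preds)),
    }


class Adam:
    """Adam with the standard moment defaults (0.9, 0.999)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    train_bags: list[Bag],
    val_bags: list[Bag],
) -> tuple[MilAttentionModel, TrainingHistory]:
    """Train a model and return the best-validation-F1 checkpoint.

    Fully deterministic given the configs, bags and seed.  A non-finite loss
    aborts with :class:`NumericError`; the exception carries the history so
    far as ``history``.
    """
    if not train_bags or not val_bags:
        raise InvalidArgumentError("train and validation bag sets must be non-empty")
    for bag in train_bags + val_bags:
        if not (0 <= bag.label < model_cfg.n_classes):
            raise InvalidArgumentError(f"bag label {bag.label} outside 0..{model_cfg.n_classes - 1}")

    model = build_model(model_cfg, seed=train_cfg.seed)
    opt = Adam(lr=train_cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([int(train_cfg.seed), 17]))
    history = TrainingHistory()
    best_params = model.copy_params()
    best_f1 = -np.inf
    best_epoch = 0

    for epoch in range(1, train_cfg.epochs + 1):
        order = rng.permutation(len(train_bags))
        for i in order:
            bag = train_bags[i]
            try:
                loss, grads = model.loss_and_grads(bag.instances, bag.label)
            except NumericError as e:
                e.history = history  # type: ignore[attr-defined]
                raise
            opt.step(model.params, grads)

        tr = evaluate(model, train_bags)
        va = evaluate(model, val_bags)
        history.train_loss.append(tr["loss"])
        history.val_loss.append(va["loss"])
        history.train_f1.append(tr["macro_f1"])
        history.val_f1.append(va["macro_f1"])
        history.train_acc.append(tr["accuracy"])
        history.val_acc.append(va["accuracy"])
        if va["macro_f1"] > best_f1:  # strict: earliest epoch wins ties
            best_f1 = va["macro_f1"]
            best_epoch = epoch
            best_params = model.copy_params()

    history.best_epoch = best_epoch
    history.best_val_f1 = float(best_f1)
    return MilAttentionModel(model_cfg, best_params), history
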
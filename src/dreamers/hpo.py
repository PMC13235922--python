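"""Two-stage grid search: architecture first (at a default learning rate),
then the learning rate of the winning architecture.  Every combination is
replicated over several seeds; selection can use the seed-averaged validation
macro-F1 (``mean``) or the single best run (``peak``, the default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .mil import Bag, ModelConfig
from .training import TrainConfig, train

#: Grid-search columns identifying one architecture.
ARCH_COLUMNS = ("n_blocks", "first_hidden", "expansion", "residual")


@dataclass(frozen=True)
class GridSpec:
    """The search grid: all architecture values crossed, three learning rates."""

    n_blocks: tuple[int, ...] = (1, 2, 3)
    first_hidden: tuple[int, ...] = (64, 128, 256)
    expansion: tuple[str, ...] = ("double", "half")
    residual: tuple[bool, ...] = (True, False)
    learning_rates: tuple[float, ...] = (1e-1, 1e-3, 1e-5)
    seeds: tuple[int, ...] = (0, 1, 2)
    epochs_search: int = 20
    epochs_final: int = 50

    def __post_init__(self) -> None:
        for name in ("n_blocks", "first_hidden", "expansion", "residual", "learning_rates"):
            if not getattr(self, name):
                raise InvalidArgumentError(f"grid field {name} must be non-empty")
        if len(self.seeds) < 1:
            raise InvalidArgumentError("at least one seed is required")

    def architectures(self) -> list[dict]:
        return [
            {"n_blocks": nb, "first_hidden": fh, "expansion": ex, "residual": rs}
            for nb, fh, ex, rs in itertools.product(
                self.n_blocks, self.first_hidden, self.expansion, self.residual
            )
        ]


@dataclass
class GridSearchResult:
    """One record per (configuration, seed) with its validation metrics."""

    records: pd.DataFrame
    histories: dict[tuple, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


def _run_one(
    arch: dict, lr: float, seed: int, input_dim: int, epochs: int,
    train_bags: list[Bag], val_bags: list[Bag], n_classes: int,
):
    cfg = ModelConfig(input_dim=input_dim, n_classes=n_classes, **arch)
    tc = TrainConfig(learning_rate=lr, epochs=epochs, seed=seed)
    record = dict(arch, lr=lr, seed=seed)
    try:
        _, history = train(cfg, tc, train_bags, val_bags)
    except Exception as e:  # per-run failures are recorded, not fatal
        record.update(
            best_val_f1=np.nan, final_val_f1=np.nan, final_val_loss=np.nan,
            final_val_acc=np.nan, final_train_f1=np.nan, final_train_loss=np.nan,
            final_train_acc=np.nan, error=str(e),
        )
        return record, None
    record.update(
        best_val_f1=history.best_val_f1,
        final_val_f1=history.val_f1[-1],
        final_val_loss=history.val_loss[-1],
        final_val_acc=history.val_acc[-1],
        final_train_f1=history.train_f1[-1],
        final_train_loss=history.train_loss[-1],
        final_train_acc=history.train_acc[-1],
        error="",
    )
    return record, history


def search_architecture(
    grid: GridSpec,
    train_bags: list[Bag],
    val_bags: list[Bag],
    input_dim: int,
    n_classes: int = 2,
    base_lr: float = 1e-3,
) -> GridSearchResult:
    """Stage 1: train every architecture at the default learning rate."""
    if not train_bags or not val_bags:
        raise InvalidArgumentError("bag sets must be non-empty")
    records, histories = [], {}
    for arch in grid.architectures():
        for seed in grid.seeds:
            rec, hist = _run_one(
                arch, base_lr, seed, input_dim, grid.epochs_search,
                train_bags, val_bags, n_classes,
            )
            records.append(rec)
            if hist is not None:
                histories[tuple(rec[k] for k in ARCH_COLUMNS) + (base_lr, seed)] = hist
    df = pd.DataFrame(records)
    df.attrs.update(input_dim=input_dim, n_classes=n_classes)
    return GridSearchResult(df, histories)


def search_learning_rate(
    best_arch: ModelConfig,
    grid: GridSpec,
    train_bags: list[Bag],
    val_bags: list[Bag],
) -> GridSearchResult:
    """Stage 2: sweep learning rates on the stage-1 winner."""
    arch = {k: getattr(best_arch, k) for k in ARCH_COLUMNS}
    records, histories = [], {}
    for lr in grid.learning_rates:
        for seed in grid.seeds:
            rec, hist = _run_one(
                arch, lr, seed, best_arch.input_dim, grid.epochs_search,
                train_bags, val_bags, best_arch.n_classes,
            )
            records.append(rec)
            if hist is not None:
                histories[tuple(rec[k] for k in ARCH_COLUMNS) + (lr, seed)] = hist
    df = pd.DataFrame(records)
    df.attrs.update(input_dim=best_arch.input_dim, n_classes=best_arch.n_classes)
    return GridSearchResult(df, histories)


def summarize_learning_rates(result: GridSearchResult) -> pd.DataFrame:
    """Mean +/- sd of loss, F1 and accuracy per learning rate (both splits)."""
    cols = [
        "final_val_loss", "final_train_loss", "final_val_f1",
        "final_train_f1", "final_val_acc", "final_train_acc",
    ]
    return result.records.groupby("lr")[cols].agg(["mean", "std"])


def _tie_break_key(row) -> tuple:
    return (
        int(row["n_blocks"]),
        int(row["first_hidden"]),
        bool(row["residual"]),
        str(row["expansion"]),
    )


def select_best(
    result: GridSearchResult, criterion: str = "peak"
) -> tuple[ModelConfig, float]:
    """Pick the winning configuration (and its learning rate).

    ``mean``: argmax of the seed-averaged best validation F1;
    ``peak``: argmax of the single-run maximum.  Ties resolve to fewer
    blocks, then fewer hidden nodes, then no residual, then expansion name.
    """
    if result.records.empty:
        raise InvalidArgumentError("empty grid-search result")
    if criterion not in ("mean", "peak"):
        raise InvalidArgumentError("criterion must be 'mean' or 'peak'")
    keys = list(ARCH_COLUMNS) + ["lr"]
    agg = "mean" if criterion == "mean" else "max"
    scores = result.records.groupby(keys, sort=False)["best_val_f1"].agg(agg).reset_index()
    best_score = scores["best_val_f1"].max()
    tied = scores[scores["best_val_f1"] == best_score]
    row = min(tied.to_dict("records"), key=_tie_break_key)
    # input_dim / n_classes are data properties, not searched: take any record's model
    cfg = ModelConfig(
        n_blocks=int(row["n_blocks"]),
        first_hidden=int(row["first_hidden"]),
        expansion=str(row["expansion"]),
        residual=bool(row["residual"]),
        input_dim=result.records.attrs.get("input_dim", ModelConfig().input_dim),
        n_classes=result.records.attrs.get("n_classes", ModelConfig().n_classes),
    )
    return cfg, float(row["lr"])


def landscape(
    result: GridSearchResult, expansion: str, residual: bool | None = None
) -> pd.DataFrame:
    """Seed-averaged validation-F1 table (n_blocks x first_hidden).

    Cells absent from the result are NaN (reported as missing, never zero).
    """
    sub = result.records[result.records["expansion"] == expansion]
    if residual is not None:
        sub = sub[sub["residual"] == residual]
    if sub.empty:
        raise InvalidArgumentError(f"result has no records for expansion={expansion!r}")
    return sub.pivot_table(
        index="n_blocks", columns="first_hidden", values="best_val_f1", aggfunc="mean"
    )
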
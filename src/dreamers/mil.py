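"""Bag data model and the attention-pooling MIL network.

A hyperspectral image is a *bag* of per-pixel spectra (*instances*); only the
bag carries a class label.  Each instance is embedded by a stack of
linear / batch-norm / ReLU blocks (ResNet-flavoured, with an optional skip
connection per block), the bag is pooled with gated-softmax attention

    a_k = exp(w^T tanh(V h_k)) / sum_j exp(w^T tanh(V h_j)),
    z   = sum_k a_k h_k,

and a final linear layer maps the pooled embedding z to class logits.  The
attention weights a_k are the per-pixel saliency used throughout the
interpretability stages.

The network is implemented directly on NumPy arrays with hand-written
reverse-mode gradients; parameters live in a flat name -> array mapping so the
optimiser, checkpointing and serialisation stay trivial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .errors import InvalidArgumentError, NumericError

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class Bag:
    """K spectral instances from one image, with the bag-level label."""

    instances: np.ndarray          # (K, B)
    label: int
    index_map: np.ndarray          # (K, 2) int (row, col), 0-based
    source_id: str = ""

    def __post_init__(self) -> None:
        inst = np.asarray(self.instances, dtype=float)
        if inst.ndim != 2 or inst.shape[0] < 1:
            raise InvalidArgumentError("instances must be a K x B matrix with K >= 1")
        idx = np.asarray(self.index_map, dtype=int)
        if idx.shape != (inst.shape[0], 2):
            raise InvalidArgumentError("index_map must be K pairs (row, col)")
        if np.unique(idx, axis=0).shape[0] != idx.shape[0]:
            raise InvalidArgumentError("index_map entries must be unique")
        self.instances = inst
        self.index_map = idx

    @property
    def n_instances(self) -> int:
        return int(self.instances.shape[0])


def bag_from_cube(pre, label: int = -1, source_id: str | None = None) -> Bag:
    """Flatten all H*W pixels of a (preprocessed) cube into a bag.

    Row-major order; background zero-vectors are kept so the bag maps back to
    the full spatial grid.  Accepts a PreprocessedCube (``spectra``) or a raw
    HyperCube (``absorbance``).
    """
    arr = getattr(pre, "spectra", None)
    if arr is None:
        arr = pre.absorbance
    H, W, B = arr.shape
    instances = arr.reshape(H * W, B)
    rows, cols = np.divmod(np.arange(H * W), W)
    index_map = np.stack([rows, cols], axis=1)
    if source_id is None:
        source_id = str(getattr(pre, "meta", {}).get("image_id", ""))
    return Bag(instances=instances, label=int(label), index_map=index_map, source_id=source_id)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the block network + attention head."""

    input_dim: int = 213
    n_blocks: int = 2
    first_hidden: int = 64
    expansion: str = "half"        # "half" or "double"
    residual: bool = False
    attention_dim: int = 128       # L; never stated upstream, common default
    n_classes: int = 2
    activation: str = "relu"       # "identity" is a linear-model test hook
    #: How batch norm normalises during optimisation.  "running" (default)
    #: normalises with the running statistics (still updated as an EMA of the
    #: bag statistics), so training and evaluation share one geometry and the
    #: label cannot leak through per-bag normalisation constants.  "batch"
    #: is the classic mode: normalise each bag by its own statistics.
    bn_train_mode: str = "running"

    def __post_init__(self) -> None:
        if self.n_blocks not in (1, 2, 3):
            raise InvalidArgumentError("n_blocks must be 1, 2 or 3")
        if self.expansion not in ("half", "double"):
            raise InvalidArgumentError("expansion must be 'half' or 'double'")
        if self.activation not in ("relu", "identity"):
            raise InvalidArgumentError("activation must be 'relu' or 'identity'")
        if self.bn_train_mode not in ("running", "batch"):
            raise InvalidArgumentError("bn_train_mode must be 'running' or 'batch'")
        if self.first_hidden < 1 or self.attention_dim < 1 or self.n_classes < 1:
            raise InvalidArgumentError("widths must be >= 1")
        if self.input_dim < 1:
            raise InvalidArgumentError("input_dim must be >= 1")
        layer_widths(self)  # validates derived widths

    @property
    def embedding_dim(self) -> int:
        """Width M of the final block output (the attention input)."""
        return layer_widths(self)[-1]


def layer_widths(config: ModelConfig) -> list[int]:
    """Output width of each block: doubling or (floor) halving per block."""
    widths = []
    for b in range(config.n_blocks):
        if config.expansion == "double":
            w = config.first_hidden * (2**b)
        else:
            w = config.first_hidden // (2**b)
        if w < 1:
            raise InvalidArgumentError(
                f"block {b + 1} width {w} < 1 for first_hidden={config.first_hidden}"
            )
        widths.append(int(w))
    return widths


@dataclass(frozen=True)
class AttentionParams:
    """Learnable attention-network weights: V (L x M) and w (L)."""

    V: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        w = np.asarray(self.w, dtype=float)
        if V.ndim != 2 or w.ndim != 1 or V.shape[0] != w.shape[0]:
            raise InvalidArgumentError("V must be L x M and w length L")
        if not (np.all(np.isfinite(V)) and np.all(np.isfinite(w))):
            raise InvalidArgumentError("attention parameters must be finite")
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "w", w)


def attention_pool(H_embed: np.ndarray, params: AttentionParams) -> tuple[np.ndarray, np.ndarray]:
    """Gated-softmax attention pooling of K instance embeddings.

    Returns the bag embedding z = sum_k a_k h_k and the weights a (simplex:
    non-negative, summing to 1).  Permuting rows of ``H_embed`` permutes ``a``
    identically and leaves ``z`` unchanged.
    """
    H = np.asarray(H_embed, dtype=float)
    if H.ndim != 2 or H.shape[0] < 1:
        raise InvalidArgumentError("embeddings must be K x M with K >= 1")
    if not np.all(np.isfinite(H)):
        raise NumericError("non-finite instance embeddings")
    if H.shape[1] != params.V.shape[1]:
        raise InvalidArgumentError("embedding width does not match attention V")
    scores = np.tanh(H @ params.V.T) @ params.w
    scores -= scores.max()  # softmax stability
    e = np.exp(scores)
    a = e / e.sum()
    z = a @ H
    return z, a


class MilAttentionModel:
    """Block network + attention pooling + linear classifier.

    Parameters (and batch-norm running statistics) live in ``self.params``, a
    flat ``name -> ndarray`` dict.  Batch norm treats the K instances of a bag
    as the normalisation batch during training and uses running statistics in
    evaluation mode, which makes evaluation exactly row-wise (so K=1 bags and
    instance permutations behave as the pooling algebra dictates).
    """

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params

    # ---------------------------------------------------------------- shapes

    @property
    def block_shapes(self) -> list[tuple[int, int]]:
        """(in, out) widths of each block's linear layer."""
        widths = layer_widths(self.config)
        ins = [widths[0]] + widths[:-1]
        return list(zip(ins, widths))

    @property
    def trainable_keys(self) -> list[str]:
        return [k for k in self.params if "running" not in k]

    @property
    def n_parameters(self) -> int:
        return sum(self.params[k].size for k in self.trainable_keys)

    # ------------------------------------------------------------- forward

    def _act(self, x: np.ndarray) -> np.ndarray:
        if self.config.activation == "identity":
            return x
        return np.maximum(x, 0.0)

    def _embed(self, X: np.ndarray, training: bool, cache: dict | None = None) -> np.ndarray:
        p = self.params
        cur = X @ p["input.W"].T + p["input.b"]
        if cache is not None:
            cache["X"] = X
            cache["blocks"] = []
        for i, (win, wout) in enumerate(self.block_shapes):
            pre = f"block{i}"
            U = cur @ p[f"{pre}.W"].T + p[f"{pre}.b"]
            K = U.shape[0]
            batch_stats = False
            if training:
                mu_b = U.mean(axis=0)
                var_b = U.var(axis=0)
                if self.config.bn_train_mode == "batch":
                    mu, var = mu_b, var_b
                    batch_stats = True
                else:
                    # normalise with the pre-update running statistics so the
                    # constants do not depend on this bag's parameters
                    mu = p[f"{pre}.bn.running_mean"].copy()
                    var = p[f"{pre}.bn.running_var"].copy()
                # running stats track the unbiased variance, per convention
                unbiased = var_b * (K / (K - 1)) if K > 1 else var_b
                p[f"{pre}.bn.running_mean"] *= 1 - _BN_MOMENTUM
                p[f"{pre}.bn.running_mean"] += _BN_MOMENTUM * mu_b
                p[f"{pre}.bn.running_var"] *= 1 - _BN_MOMENTUM
                p[f"{pre}.bn.running_var"] += _BN_MOMENTUM * unbiased
            else:
                mu = p[f"{pre}.bn.running_mean"]
                var = p[f"{pre}.bn.running_var"]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (U - mu) * inv_std
            Y = p[f"{pre}.bn.gamma"] * xhat + p[f"{pre}.bn.beta"]
            A = self._act(Y)
            if self.config.residual:
                skip_key = f"{pre}.skip.W"
                skip = cur @ p[skip_key].T if skip_key in p else cur
                out = A + skip
            else:
                out = A
            if cache is not None:
                cache["blocks"].append(
                    {
                        "cur_in": cur, "xhat": xhat, "inv_std": inv_std,
                        "Y": Y, "A": A, "batch_stats": batch_stats,
                    }
                )
            cur = out
        if cache is not None:
            cache["H"] = cur
        return cur

    def forward(self, bag: Bag | np.ndarray, training: bool = False):
        """Run one bag through the network.

        Returns ``(logits, attention_weights)``.
        """
        X = bag.instances if isinstance(bag, Bag) else np.asarray(bag, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.input_dim:
            raise InvalidArgumentError(
                f"bag instance width {X.shape[-1] if X.ndim == 2 else '?'} "
                f"does not match model input_dim {self.config.input_dim}"
            )
        H = self._embed(X, training=training)
        z, a = attention_pool(H, self.attention)
        logits = self.params["clf.W"] @ z + self.params["clf.b"]
        return logits, a

    @property
    def attention(self) -> AttentionParams:
        return AttentionParams(self.params["attn.V"], self.params["attn.w"])

    # ---------------------------------------------------- loss and gradients

    def loss_and_grads(self, X: np.ndarray, label: int):
        """Cross-entropy loss of one bag and gradients w.r.t. all trainables.

        Training mode: batch norm uses bag statistics (and updates the running
        buffers).
        """
        p = self.params
        cache: dict = {}
        H = self._embed(X, training=True, cache=cache)

        V, w = p["attn.V"], p["attn.w"]
        T = np.tanh(H @ V.T)
        s = T @ w
        s_shift = s - s.max()
        e = np.exp(s_shift)
        a = e / e.sum()
        z = a @ H
        logits = p["clf.W"] @ z + p["clf.b"]

        m = logits.max()
        lse = m + np.log(np.exp(logits - m).sum())
        loss = float(lse - logits[label])
        if not np.isfinite(loss):
            raise NumericError("non-finite loss")

        probs = np.exp(logits - lse)
        dlogits = probs.copy()
        dlogits[label] -= 1.0

        grads: dict[str, np.ndarray] = {}
        grads["clf.W"] = np.outer(dlogits, z)
        grads["clf.b"] = dlogits
        dz = p["clf.W"].T @ dlogits

        da = H @ dz
        dH = np.outer(a, dz)
        ds = a * (da - float(a @ da))
        grads["attn.w"] = T.T @ ds
        dT = np.outer(ds, w)
        dpre = dT * (1.0 - T**2)
        grads["attn.V"] = dpre.T @ H
        dH += dpre @ V

        dcur = dH
        for i in reversed(range(len(cache["blocks"]))):
            blk = cache["blocks"][i]
            pre = f"block{i}"
            dA = dcur
            if self.config.residual:
                skip_key = f"{pre}.skip.W"
                if skip_key in p:
                    grads[skip_key] = dcur.T @ blk["cur_in"]
                    dskip = dcur @ p[skip_key]
                else:
                    dskip = dcur
            else:
                dskip = 0.0
            if self.config.activation == "relu":
                dY = dA * (blk["Y"] > 0)
            else:
                dY = dA
            xhat, inv_std = blk["xhat"], blk["inv_std"]
            grads[f"{pre}.bn.gamma"] = (dY * xhat).sum(axis=0)
            grads[f"{pre}.bn.beta"] = dY.sum(axis=0)
            K = dY.shape[0]
            dxhat = dY * p[f"{pre}.bn.gamma"]
            if blk["batch_stats"]:
                dU = (inv_std / K) * (
                    K * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
                )
            else:
                # normalisation constants are not functions of this bag
                dU = dxhat * inv_std
            grads[f"{pre}.W"] = dU.T @ blk["cur_in"]
            grads[f"{pre}.b"] = dU.sum(axis=0)
            dcur = dU @ p[f"{pre}.W"] + dskip
        grads["input.W"] = dcur.T @ cache["X"]
        grads["input.b"] = dcur.sum(axis=0)
        return loss, grads

    # -------------------------------------------------- instance-level view

    def instance_logits(self, X: np.ndarray) -> np.ndarray:
        """Per-instance class scores (eval mode): classifier(embedding(x))."""
        H = self._embed(np.asarray(X, dtype=float), training=False)
        return H @ self.params["clf.W"].T + self.params["clf.b"]

    def instance_input_gradients(self, X: np.ndarray, class_idx: int) -> np.ndarray:
        """d score_c / d x for each row of X, in evaluation mode.

        Evaluation-mode batch norm is a per-feature affine map, so rows are
        independent and the gradient is exact per instance.
        """
        p = self.params
        cache: dict = {}
        self._embed(np.asarray(X, dtype=float), training=False, cache=cache)
        dH = np.broadcast_to(p["clf.W"][class_idx], cache["H"].shape).copy()
        dcur = dH
        for i in reversed(range(len(cache["blocks"]))):
            blk = cache["blocks"][i]
            pre = f"block{i}"
            if self.config.residual:
                skip_key = f"{pre}.skip.W"
                dskip = dcur @ p[skip_key] if skip_key in p else dcur
            else:
                dskip = 0.0
            dY = dcur * (blk["Y"] > 0) if self.config.activation == "relu" else dcur
            dU = dY * p[f"{pre}.bn.gamma"] * blk["inv_std"]
            dcur = dU @ p[f"{pre}.W"] + dskip
        return dcur @ p["input.W"]

    # ------------------------------------------------------- serialisation

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint with the config embedded as JSON."""
        cfg = json.dumps(self.config.__dict__)
        np.savez(path, __config__=np.array(cfg), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "MilAttentionModel":
        with np.load(path, allow_pickle=False) as f:
            cfg = ModelConfig(**json.loads(str(f["__config__"])))
            params = {k: np.array(f[k]) for k in f.files if k != "__config__"}
        return cls(cfg, params)


#: Serialisable alias used in type hints across the package.
TrainedModel = MilAttentionModel


def build_model(config: ModelConfig, seed: int = 0) -> MilAttentionModel:
    """Initialise an (untrained) model deterministically from ``seed``.

    He initialisation for the ReLU block linears, Xavier for the attention
    network and classifier; batch-norm gamma = 1, beta = 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    p: dict[str, np.ndarray] = {}

    def he(shape):
        return rng.normal(0.0, np.sqrt(2.0 / shape[1]), size=shape)

    def xavier(shape):
        return rng.normal(0.0, np.sqrt(2.0 / (shape[0] + shape[1])), size=shape)

    widths = layer_widths(config)
    p["input.W"] = he((widths[0], config.input_dim))
    p["input.b"] = np.zeros(widths[0])
    ins = [widths[0]] + widths[:-1]
    for i, (win, wout) in enumerate(zip(ins, widths)):
        pre = f"block{i}"
        p[f"{pre}.W"] = he((wout, win))
        p[f"{pre}.b"] = np.zeros(wout)
        p[f"{pre}.bn.gamma"] = np.ones(wout)
        p[f"{pre}.bn.beta"] = np.zeros(wout)
        p[f"{pre}.bn.running_mean"] = np.zeros(wout)
        p[f"{pre}.bn.running_var"] = np.ones(wout)
        if config.residual and win != wout:
            # learned linear projection on the skip path across width changes
            p[f"{pre}.skip.W"] = xavier((wout, win))
    M = widths[-1]
    L = config.attention_dim
    p["attn.V"] = xavier((L, M))
    p["attn.w"] = xavier((1, L))[0]
    p["clf.W"] = xavier((config.n_classes, M))
    p["clf.b"] = np.zeros(config.n_classes)
    return MilAttentionModel(config, p)
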
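"""Binary tree-LSTM classifier: forward recursion, analytic backward
pass, weighted softmax cross-entropy, recurrent dropout, Adam training
loop, checkpointing and logit-sum ensembling.

The recursion at node ``j`` with children ``k`` in ``B(j)`` (|B(j)| = 2
after binarization; leaves have no children) is::

    h~   = sum_k h_k
    i    = sigmoid(W_i [x, h~] + b_i)
    f_k  = sigmoid(W_f [x, h_k] + b_f)      # one forget gate per child,
    o    = sigmoid(W_o [x, h~] + b_o)       # shared W_f
    u    = tanh(W_u [x, h~] + b_u)
    c    = i * drop(u) + sum_k f_k * c_k
    h    = o * tanh(c)

Only the root hidden state is scored: ``logits = W_fc h_root + b_fc``.
Dropout masks the candidate update ``u`` during training and is the
identity at evaluation time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from .features import INPUT_DIM, EmbeddingTable, PositionCodec, assemble_input
from .parse_trees import ParseNode, TreeError

__all__ = [
    "TreeLSTMParams",
    "NodeState",
    "DropoutSpec",
    "TrainConfig",
    "CompiledTree",
    "compile_tree",
    "node_forward",
    "forward_tree",
    "classify_root",
    "predict",
    "predict_logits",
    "loss",
    "loss_and_grads",
    "train",
    "ensemble_logits",
    "ensemble_predict",
]

@dataclass
class NodeState:
    """Hidden state and memory cell of one node."""

    h: np.ndarray
    c: np.ndarray


class TreeLSTMParams:
    """All trainable tensors of the tree-LSTM and its output layer.

    ``W_i``, ``W_o``, ``W_u`` map the concatenation ``[x, h~]`` to the
    hidden size; ``W_f`` maps ``[x, h_k]`` and is shared across both
    children's forget gates.  ``W_fc``/``b_fc`` form the fully-connected
    output layer over the root hidden state.
    """

    def __init__(self, hidden_size: int, n_classes: int, input_size: int = INPUT_DIM):
        self.hidden_size = hidden_size
        self.n_classes = n_classes
        self.input_size = input_size
        z = input_size + hidden_size
        self.W_i = np.zeros((hidden_size, z))
        self.W_f = np.zeros((hidden_size, z))
        self.W_o = np.zeros((hidden_size, z))
        self.W_u = np.zeros((hidden_size, z))
        self.b_i = np.zeros(hidden_size)
        self.b_f = np.zeros(hidden_size)
        self.b_o = np.zeros(hidden_size)
        self.b_u = np.zeros(hidden_size)
        self.W_fc = np.zeros((n_classes, hidden_size))
        self.b_fc = np.zeros(n_classes)

    _TENSORS = ("W_i", "W_f", "W_o", "W_u", "b_i", "b_f", "b_o", "b_u", "W_fc", "b_fc")

    @classmethod
    def initialize(
        cls,
        hidden_size: int,
        n_classes: int,
        input_size: int = INPUT_DIM,
        seed: int = 0,
        init_scale: float = 0.05,
    ) -> "TreeLSTMParams":
        """Seeded uniform(-scale, scale) weights, zero biases."""
        params = cls(hidden_size, n_classes, input_size)
        rng = np.random.default_rng(seed)
        for name in ("W_i", "W_f", "W_o", "W_u", "W_fc"):
            mat = getattr(params, name)
            setattr(params, name, rng.uniform(-init_scale, init_scale, mat.shape))
        return params

    def tensors(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self._TENSORS}

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {name: np.zeros_like(getattr(self, name)) for name in self._TENSORS}

    def copy(self) -> "TreeLSTMParams":
        out = TreeLSTMParams(self.hidden_size, self.n_classes, self.input_size)
        for name in self._TENSORS:
            setattr(out, name, getattr(self, name).copy())
        return out

    def save(self, path) -> None:
        """Single-archive checkpoint: named tensors + shape config."""
        meta = json.dumps(
            {
                "hidden_size": self.hidden_size,
                "n_classes": self.n_classes,
                "input_size": self.input_size,
            }
        )
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.tensors())

    @classmethod
    def load(cls, path) -> "TreeLSTMParams":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"]).decode())
            params = cls(meta["hidden_size"], meta["n_classes"], meta["input_size"])
            for name in cls._TENSORS:
                setattr(params, name, data[name].copy())
        return params

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TreeLSTMParams):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, n), getattr(other, n)) for n in self._TENSORS
        )


@dataclass
class DropoutSpec:
    """Recurrent-dropout configuration.

    ``variant="inverted"`` scales kept activations by 1/keep_p during
    training so evaluation needs no rescaling; ``variant="paper"``
    applies the raw Bernoulli mask in training and the identity at test
    time.  ``scope`` controls whether one mask is shared by every node of
    a tree or redrawn per node.  Evaluation mode is always the identity.
    """

    keep_p: float = 1.0
    mode: str = "eval"
    seed: int = 0
    variant: str = "inverted"
    scope: str = "tree"
    _rng: Optional[np.random.Generator] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.keep_p <= 1.0):
            raise ValueError("keep_p must be in (0, 1]")
        if self.mode not in ("train", "eval"):
            raise ValueError(f"unknown dropout mode {self.mode!r}")
        if self.variant not in ("inverted", "paper"):
            raise ValueError(f"unknown dropout variant {self.variant!r}")
        if self.scope not in ("tree", "node"):
            raise ValueError(f"unknown mask scope {self.scope!r}")
        if self._rng is None:
            self._rng = np.random.default_rng(self.seed)

    @property
    def active(self) -> bool:
        return self.mode == "train" and self.keep_p < 1.0

    def sample_mask(self, size: int) -> np.ndarray:
        """Multiplier applied to the candidate update ``u``."""
        if not self.active:
            return np.ones(size)
        mask = (self._rng.random(size) < self.keep_p).astype(np.float64)
        if self.variant == "inverted":
            mask /= self.keep_p
        return mask


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the detection task)."""

    hidden_size: int = 128
    batch_size: int = 100
    learning_rate: float = 0.0008
    keep_p: float = 0.75
    epochs: int = 100
    positive_weight: float = 3.0
    n_classes: int = 2
    seed: int = 0
    input_size: int = INPUT_DIM
    dropout_variant: str = "inverted"
    mask_scope: str = "tree"
    init_scale: float = 0.05
    l2_lambda: float = 0.0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Tree compilation: freeze per-node input vectors once (embeddings are
# static, so inputs never change during training).


@dataclass
class CompiledTree:
    """Post-order flattened tree with per-node input vectors.

    ``children[j]`` is ``None`` for leaves, else the post-order indices
    of the two children (both < j).
    """

    xs: list[np.ndarray]
    children: list[Optional[tuple[int, int]]]

    def __len__(self) -> int:
        return len(self.xs)

    @property
    def root(self) -> int:
        return len(self.xs) - 1


def compile_tree(
    root: ParseNode,
    table: EmbeddingTable,
    codec: Optional[PositionCodec] = None,
    tree_key: str = "",
) -> CompiledTree:
    """Assemble and cache the input vector of every node, post-order."""
    xs: list[np.ndarray] = []
    children: list[Optional[tuple[int, int]]] = []
    index: dict[int, int] = {}
    for node in root.iter_nodes():
        if node.is_leaf:
            kids = None
        else:
            if len(node.children) != 2:
                raise TreeError(
                    f"node {node.label!r} has {len(node.children)} children; "
                    "binarize before compiling"
                )
            kids = (index[id(node.children[0])], index[id(node.children[1])])
        node_key = f"{tree_key}#{len(xs)}"
        xs.append(assemble_input(node, table, codec, node_key=node_key))
        children.append(kids)
        index[id(node)] = len(xs) - 1
    return CompiledTree(xs=xs, children=children)


# ---------------------------------------------------------------------------
# Forward


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def node_forward(
    params: TreeLSTMParams,
    x: np.ndarray,
    children: Sequence[NodeState] = (),
    dropout: Optional[DropoutSpec] = None,
    mask: Optional[np.ndarray] = None,
) -> NodeState:
    """One tree-LSTM cell update from an input vector and 0 or 2 child
    states."""
    if len(children) not in (0, 2):
        raise TreeError(f"node_forward requires 0 or 2 children, got {len(children)}")
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (params.input_size,):
        raise ValueError(f"input shape {x.shape}, expected ({params.input_size},)")
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite values in node input")
    H = params.hidden_size
    h_tilde = np.zeros(H)
    for child in children:
        h_tilde = h_tilde + child.h
    a = np.concatenate([x, h_tilde])
    i = _sigmoid(params.W_i @ a + params.b_i)
    o = _sigmoid(params.W_o @ a + params.b_o)
    u = np.tanh(params.W_u @ a + params.b_u)
    if mask is None:
        mask = dropout.sample_mask(H) if dropout is not None else np.ones(H)
    c = i * (mask * u)
    for child in children:
        a_k = np.concatenate([x, child.h])
        f_k = _sigmoid(params.W_f @ a_k + params.b_f)
        c = c + f_k * child.c
    h = o * np.tanh(c)
    return NodeState(h=h, c=c)


class _ForwardCache:
    """Per-node intermediates retained for the backward pass."""

    __slots__ = ("a", "i", "o", "u", "mask", "f", "c", "t", "h")

    def __init__(self) -> None:
        self.f: list[np.ndarray] = []


def forward_tree(
    params: TreeLSTMParams,
    tree: CompiledTree,
    dropout: Optional[DropoutSpec] = None,
) -> tuple[NodeState, list[_ForwardCache]]:
    """Post-order forward pass over a compiled tree."""
    H = params.hidden_size
    caches: list[_ForwardCache] = []
    if dropout is not None and dropout.active and dropout.scope == "tree":
        shared_mask: Optional[np.ndarray] = dropout.sample_mask(H)
    else:
        shared_mask = None
    hs = np.empty((len(tree), H))
    cs = np.empty((len(tree), H))
    for j in range(len(tree)):
        cache = _ForwardCache()
        kids = tree.children[j]
        if kids is None:
            h_tilde = np.zeros(H)
        else:
            h_tilde = hs[kids[0]] + hs[kids[1]]
        a = np.concatenate([tree.xs[j], h_tilde])
        cache.a = a
        cache.i = _sigmoid(params.W_i @ a + params.b_i)
        cache.o = _sigmoid(params.W_o @ a + params.b_o)
        cache.u = np.tanh(params.W_u @ a + params.b_u)
        if shared_mask is not None:
            cache.mask = shared_mask
        elif dropout is not None:
            cache.mask = dropout.sample_mask(H)
        else:
            cache.mask = np.ones(H)
        c = cache.i * (cache.mask * cache.u)
        if kids is not None:
            for k in kids:
                a_k = np.concatenate([tree.xs[j], hs[k]])
                f_k = _sigmoid(params.W_f @ a_k + params.b_f)
                cache.f.append(f_k)
                c = c + f_k * cs[k]
        cache.c = c
        cache.t = np.tanh(c)
        cache.h = cache.o * cache.t
        hs[j] = cache.h
        cs[j] = c
        caches.append(cache)
    root = tree.root
    return NodeState(h=hs[root], c=cs[root]), caches


def classify_root(params: TreeLSTMParams, root_state: NodeState) -> np.ndarray:
    """Affine output layer over the root hidden state only."""
    return params.W_fc @ root_state.h + params.b_fc


def predict(logits: np.ndarray) -> int:
    """Argmax with ties broken toward the lower class index."""
    logits = np.asarray(logits)
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits")
    return int(np.argmax(logits))


def predict_logits(params: TreeLSTMParams, tree: CompiledTree) -> np.ndarray:
    """Evaluation-mode logits for one compiled tree."""
    state, _ = forward_tree(params, tree, dropout=None)
    return classify_root(params, state)


# ---------------------------------------------------------------------------
# Loss


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - np.max(logits)
    return shifted - np.log(np.sum(np.exp(shifted)))


def _instance_weight(label: int, positive_weight: float) -> float:
    # Class 0 is the negative / "no DDI" class by convention.
    return positive_weight if label != 0 else 1.0


def loss(
    logits_batch: Sequence[np.ndarray],
    labels: Sequence[int],
    positive_weight: float = 1.0,
) -> float:
    """Mean weighted softmax cross-entropy over a batch.

    Instances with a non-zero (positive) label contribute
    ``positive_weight`` times the negative log-probability of their gold
    class; type classifiers use ``positive_weight=1`` (uniform weights).
    """
    if len(logits_batch) == 0:
        raise ValueError("empty batch")
    if len(logits_batch) != len(labels):
        raise ValueError("batch size mismatch between logits and labels")
    total = 0.0
    for logits, label in zip(logits_batch, labels):
        logits = np.asarray(logits, dtype=np.float64)
        if not (0 <= label < logits.shape[0]):
            raise ValueError(f"label {label} outside class range")
        total += -_instance_weight(label, positive_weight) * _log_softmax(logits)[label]
    return total / len(logits_batch)


# ---------------------------------------------------------------------------
# Backward


def loss_and_grads(
    params: TreeLSTMParams,
    tree: CompiledTree,
    label: int,
    positive_weight: float = 1.0,
    dropout: Optional[DropoutSpec] = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Per-instance weighted cross-entropy and analytic gradients.

    Backpropagates through the output layer and the full tree recursion
    (reverse post-order), reusing the dropout masks sampled in the
    forward pass.
    """
    if not (0 <= label < params.n_classes):
        raise ValueError(f"label {label} outside class range")
    root_state, caches = forward_tree(params, tree, dropout=dropout)
    logits = classify_root(params, root_state)
    logp = _log_softmax(logits)
    weight = _instance_weight(label, positive_weight)
    value = -weight * logp[label]

    grads = params.zero_grads()
    glogits = np.exp(logp)
    glogits[label] -= 1.0
    glogits *= weight
    grads["W_fc"] += np.outer(glogits, root_state.h)
    grads["b_fc"] += glogits

    n = len(tree)
    X = params.input_size
    gh = [None] * n
    gc = [None] * n
    gh[tree.root] = params.W_fc.T @ glogits
    gc[tree.root] = np.zeros(params.hidden_size)

    for j in range(n - 1, -1, -1):
        if gh[j] is None:  # unreachable for connected trees
            continue
        cache = caches[j]
        gh_j, gc_j = gh[j], gc[j]
        go = gh_j * cache.t
        gc_j = gc_j + gh_j * cache.o * (1.0 - cache.t**2)
        gz_o = go * cache.o * (1.0 - cache.o)
        gi = gc_j * (cache.mask * cache.u)
        gz_i = gi * cache.i * (1.0 - cache.i)
        gu = gc_j * cache.i * cache.mask
        gz_u = gu * (1.0 - cache.u**2)

        a = cache.a
        grads["W_i"] += np.outer(gz_i, a)
        grads["W_o"] += np.outer(gz_o, a)
        grads["W_u"] += np.outer(gz_u, a)
        grads["b_i"] += gz_i
        grads["b_o"] += gz_o
        grads["b_u"] += gz_u
        ga = params.W_i.T @ gz_i + params.W_o.T @ gz_o + params.W_u.T @ gz_u
        gh_tilde = ga[X:]

        kids = tree.children[j]
        if kids is not None:
            for idx, k in enumerate(kids):
                f_k = cache.f[idx]
                gf = gc_j * caches[k].c
                gz_f = gf * f_k * (1.0 - f_k)
                a_k = np.concatenate([tree.xs[j], caches[k].h])
                grads["W_f"] += np.outer(gz_f, a_k)
                grads["b_f"] += gz_f
                ga_k = params.W_f.T @ gz_f
                child_gh = gh_tilde + ga_k[X:]
                child_gc = gc_j * f_k
                if gh[k] is None:
                    gh[k] = child_gh
                    gc[k] = child_gc
                else:
                    gh[k] = gh[k] + child_gh
                    gc[k] = gc[k] + child_gc
    return value, grads


# ---------------------------------------------------------------------------
# Training


class _Adam:
    def __init__(self, params: TreeLSTMParams, config: TrainConfig) -> None:
        self.lr = config.learning_rate
        self.b1 = config.adam_beta1
        self.b2 = config.adam_beta2
        self.eps = config.adam_eps
        self.t = 0
        self.m = params.zero_grads()
        self.v = params.zero_grads()

    def step(self, params: TreeLSTMParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        correction1 = 1.0 - self.b1**self.t
        correction2 = 1.0 - self.b2**self.t
        for name, g in grads.items():
            self.m[name] = self.b1 * self.m[name] + (1.0 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1.0 - self.b2) * g * g
            m_hat = self.m[name] / correction1
            v_hat = self.v[name] / correction2
            tensor = getattr(params, name)
            tensor -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    trees: Sequence[CompiledTree],
    labels: Sequence[int],
    config: TrainConfig,
    params: Optional[TreeLSTMParams] = None,
) -> tuple[TreeLSTMParams, list[float]]:
    """Mini-batch Adam over shuffled instances.

    Word embeddings are static (inputs are frozen at compile time); only
    the tree-LSTM and output-layer tensors are updated.  Returns the
    final parameters and the per-epoch mean training loss.
    """
    if len(trees) == 0:
        raise ValueError("empty training set")
    if len(trees) != len(labels):
        raise ValueError("trees and labels length mismatch")
    if params is None:
        params = TreeLSTMParams.initialize(
            config.hidden_size,
            config.n_classes,
            input_size=config.input_size,
            seed=config.seed,
            init_scale=config.init_scale,
        )
    rng = np.random.default_rng(config.seed + 1)
    dropout = DropoutSpec(
        keep_p=config.keep_p,
        mode="train",
        seed=config.seed + 2,
        variant=config.dropout_variant,
        scope=config.mask_scope,
    )
    optimizer = _Adam(params, config)
    order = np.arange(len(trees))
    epoch_losses: list[float] = []
    for _ in range(config.epochs):
        rng.shuffle(order)
        total = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            grads = params.zero_grads()
            batch_loss = 0.0
            for idx in batch:
                value, g = loss_and_grads(
                    params,
                    trees[idx],
                    labels[idx],
                    positive_weight=config.positive_weight,
                    dropout=dropout,
                )
                batch_loss += value
                for name in grads:
                    grads[name] += g[name]
            scale = 1.0 / len(batch)
            for name in grads:
                grads[name] *= scale
                if config.l2_lambda > 0.0 and name.startswith("W"):
                    grads[name] += config.l2_lambda * getattr(params, name)
            optimizer.step(params, grads)
            total += batch_loss
        epoch_losses.append(total / len(order))
    return params, epoch_losses


# ---------------------------------------------------------------------------
# Ensemble


def ensemble_logits(
    members: Sequence[TreeLSTMParams], tree: CompiledTree
) -> np.ndarray:
    """Element-wise sum of the members' root logits."""
    if len(members) == 0:
        raise ValueError("ensemble requires at least one member")
    n_classes = members[0].n_classes
    for member in members:
        if member.n_classes != n_classes:
            raise ValueError("ensemble members disagree on class count")
    total = np.zeros(n_classes)
    for member in members:
        total += predict_logits(member, tree)
    return total


def ensemble_predict(members: Sequence[TreeLSTMParams], tree: CompiledTree) -> int:
    """Sum members' logits, then argmax."""
    return predict(ensemble_logits(members, tree))
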
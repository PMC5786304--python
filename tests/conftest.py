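"""Shared fixtures: hand-built sentences, random compiled trees, and a
naive scalar tree-LSTM reference used as the independent oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from treeddi.corpus_io import EntityMention, SentenceRecord
from treeddi.features import EmbeddingTable
from treeddi.model import CompiledTree, TreeLSTMParams


CALCIUM_TEXT = (
    "Calcium is the only known component in the diet that may affect "
    "absorption of both nonheme and heme iron."
)

CALCIUM_ANONYMIZED = (
    "Ddrug0 is the only known component in the diet that may affect "
    "absorption of both Ddrug1 and Ddrug2."
)


@pytest.fixture
def calcium_record() -> SentenceRecord:
    """The three-drug sentence with a discontinuous second mention
    ('nonheme ... iron' shares its head noun with 'heme iron')."""
    text = CALCIUM_TEXT
    span_cal = (0, len("Calcium"))
    span_non = (text.find("nonheme"), text.find("nonheme") + len("nonheme"))
    span_heme = (text.find("heme iron"), text.find("heme iron") + len("heme iron"))
    span_iron = (text.rfind("iron"), text.rfind("iron") + len("iron"))
    return SentenceRecord(
        id="doc0.s0",
        text=text,
        entities=[
            EntityMention(id="doc0.s0.e0", text="Calcium", spans=(span_cal,)),
            EntityMention(
                id="doc0.s0.e1", text="nonheme iron", spans=(span_non, span_iron)
            ),
            EntityMention(id="doc0.s0.e2", text="heme iron", spans=(span_heme,)),
        ],
    )


@pytest.fixture
def embedding_table() -> EmbeddingTable:
    return EmbeddingTable(seed=0)


def random_compiled_tree(
    rng: np.random.Generator, n_leaves: int, input_size: int
) -> CompiledTree:
    """A random binary tree shape with random input vectors, in the
    post-order layout the model consumes."""
    xs: list[np.ndarray] = []
    children: list = []
    stack: list[int] = []
    for _ in range(n_leaves):
        xs.append(rng.normal(size=input_size))
        children.append(None)
        stack.append(len(xs) - 1)
    while len(stack) > 1:
        i = int(rng.integers(len(stack) - 1))
        left = stack.pop(i)
        right = stack.pop(i)
        xs.append(rng.normal(size=input_size))
        children.append((left, right))
        stack.append(len(xs) - 1)
    return CompiledTree(xs=xs, children=children)


# ---------------------------------------------------------------------------
# Naive scalar reference (independent of the vectorized implementation:
# plain Python floats, explicit loops, recursion over the tree).


def _sig(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def _matvec(mat, vec):
    return [sum(mat[r][c] * vec[c] for c in range(len(vec))) for r in range(len(mat))]


def naive_forward(params: TreeLSTMParams, tree: CompiledTree, node: int | None = None):
    """Recursive scalar evaluation of the tree-LSTM equations; returns
    (h, c) as Python lists."""
    if node is None:
        node = tree.root
    H = params.hidden_size
    kids = tree.children[node]
    child_states = [] if kids is None else [naive_forward(params, tree, k) for k in kids]
    x = [float(v) for v in tree.xs[node]]
    h_tilde = [0.0] * H
    for h_k, _ in child_states:
        for r in range(H):
            h_tilde[r] += h_k[r]
    a = x + h_tilde
    Wi, Wo, Wu, Wf = params.W_i.tolist(), params.W_o.tolist(), params.W_u.tolist(), params.W_f.tolist()
    i = [_sig(z + b) for z, b in zip(_matvec(Wi, a), params.b_i.tolist())]
    o = [_sig(z + b) for z, b in zip(_matvec(Wo, a), params.b_o.tolist())]
    u = [math.tanh(z + b) for z, b in zip(_matvec(Wu, a), params.b_u.tolist())]
    c = [i[r] * u[r] for r in range(H)]
    for h_k, c_k in child_states:
        a_k = x + h_k
        f_k = [_sig(z + b) for z, b in zip(_matvec(Wf, a_k), params.b_f.tolist())]
        for r in range(H):
            c[r] += f_k[r] * c_k[r]
    h = [o[r] * math.tanh(c[r]) for r in range(H)]
    return h, c


def naive_logits(params: TreeLSTMParams, tree: CompiledTree):
    h, _ = naive_forward(params, tree)
    Wfc, bfc = params.W_fc.tolist(), params.b_fc.tolist()
    return [
        sum(Wfc[r][c] * h[c] for c in range(len(h))) + bfc[r]
        for r in range(len(bfc))
    ]
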
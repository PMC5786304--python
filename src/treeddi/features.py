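"""Per-node input features: position encoding, subtree-containment
vector, word-embedding lookup, and assembly of the 230-dimensional node
input (10 containment + 2x10 position + 200 word embedding)."""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = [
    "EMBEDDING_DIM",
    "POSITION_DIM",
    "CONTAINMENT_DIM",
    "INPUT_DIM",
    "relative_distance",
    "encode_distance",
    "containment_vector",
    "PositionCodec",
    "EmbeddingTable",
    "assemble_input",
]

EMBEDDING_DIM = 200
POSITION_DIM = 10
CONTAINMENT_DIM = 10
INPUT_DIM = CONTAINMENT_DIM + 2 * POSITION_DIM + EMBEDDING_DIM


def relative_distance(current: int, target: int) -> int:
    """Signed distance to a target token: positive when the target lies
    after the current token (a word two tokens after the first target has
    d1 = -2)."""
    return target - current


def encode_distance(d: int) -> np.ndarray:
    """Encode a signed relative distance as a 10-component binary vector.

    Component 1 flags a strictly positive distance; components 2-10 form
    a thermometer over |d| with thresholds 21, 16, 11, 6, 5, 4, 3, 2, 1.
    Distances of magnitude above 5 share one code per bucket of 5 (6-10,
    11-15, 16-20, 21 and beyond); d = 0 is the all-zero vector.
    """
    a = abs(d)
    return np.array(
        [
            d >= 1,
            a >= 21,
            a >= 16,
            a >= 11,
            a >= 6,
            a >= 5,
            a >= 4,
            a >= 3,
            a >= 2,
            a >= 1,
        ],
        dtype=np.float64,
    )


def containment_vector(flag: bool) -> np.ndarray:
    """All-ones vector when a target drug is under the node, else all
    zeros."""
    return np.full(CONTAINMENT_DIM, 1.0 if flag else 0.0)


class PositionCodec:
    """Cached integer-distance -> binary-vector lookup."""

    def __init__(self) -> None:
        self._cache: dict[int, np.ndarray] = {}

    def __call__(self, d: int) -> np.ndarray:
        key = int(d)
        vec = self._cache.get(key)
        if vec is None:
            vec = encode_distance(key)
            vec.setflags(write=False)
            self._cache[key] = vec
        return vec


class EmbeddingTable:
    """Static word-embedding lookup with seeded out-of-vocabulary randoms.

    Unknown words draw a random vector once and keep it (lookups are
    reproducible across runs for the same seed).  Internal tree nodes are
    not words; they get a random vector per constituent label by default
    (``internal_policy="label"``) or per individual node
    (``internal_policy="node"``, keyed by a caller-supplied node key).
    """

    def __init__(
        self,
        vectors: Optional[dict[str, np.ndarray]] = None,
        dim: int = EMBEDDING_DIM,
        seed: int = 0,
        internal_policy: str = "label",
        scale: float = 0.25,
    ) -> None:
        if internal_policy not in ("label", "node"):
            raise ValueError(f"unknown internal vector policy {internal_policy!r}")
        self.dim = dim
        self.seed = seed
        self.internal_policy = internal_policy
        self.scale = scale
        self._vectors: dict[str, np.ndarray] = {}
        if vectors:
            for word, vec in vectors.items():
                arr = np.asarray(vec, dtype=np.float64)
                if arr.shape != (dim,):
                    raise ValueError(
                        f"embedding for {word!r} has dimension {arr.shape}, "
                        f"expected ({dim},)"
                    )
                self._vectors[word] = arr
        self._random_cache: dict[str, np.ndarray] = {}

    @classmethod
    def from_text_file(cls, path, dim: int = EMBEDDING_DIM, **kwargs) -> "EmbeddingTable":
        """Read a whitespace-separated embedding file (word + floats)."""
        vectors: dict[str, np.ndarray] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) == 2 and lineno == 1:
                    continue  # optional word2vec-style header "count dim"
                word, values = parts[0], parts[1:]
                if len(values) != dim:
                    raise ValueError(
                        f"{path} line {lineno}: {len(values)} components, "
                        f"expected {dim}"
                    )
                vectors[word] = np.array(values, dtype=np.float64)
        return cls(vectors=vectors, dim=dim, **kwargs)

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    def _random_vector(self, key: str) -> np.ndarray:
        vec = self._random_cache.get(key)
        if vec is None:
            entropy = [self.seed] + list(key.encode("utf-8"))
            rng = np.random.default_rng(entropy)
            vec = rng.uniform(-self.scale, self.scale, self.dim)
            vec.setflags(write=False)
            self._random_cache[key] = vec
        return vec

    def lookup_word(self, word: str) -> np.ndarray:
        vec = self._vectors.get(word)
        if vec is not None:
            return vec
        return self._random_vector("w\x00" + word)

    def lookup_internal(self, label: str, node_key: Optional[str] = None) -> np.ndarray:
        if self.internal_policy == "node":
            if node_key is None:
                raise ValueError("internal_policy='node' requires a node_key")
            return self._random_vector("n\x00" + node_key)
        return self._random_vector("l\x00" + label)


def assemble_input(
    node,
    table: EmbeddingTable,
    codec: Optional[PositionCodec] = None,
    node_key: Optional[str] = None,
) -> np.ndarray:
    """Concatenate containment, position, and word vectors for one
    annotated parse node (length 230)."""
    if not node.is_annotated:
        raise ValueError("node must be annotated before input assembly")
    encode = codec if codec is not None else encode_distance
    if node.is_leaf:
        word_vec = table.lookup_word(node.token)
    else:
        word_vec = table.lookup_internal(node.label, node_key=node_key)
    return np.concatenate(
        [
            containment_vector(node.containment),
            encode(node.d1),
            encode(node.d2),
            word_vec,
        ]
    )
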
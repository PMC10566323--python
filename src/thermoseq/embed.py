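"""Per-residue embedding providers and length pooling.

A provider maps an amino-acid sequence to an l x d matrix of per-residue
representations. Three providers share one interface:

* ``MockEmbedder`` — a deterministic seeded hash-to-Gaussian stand-in used
  for testing and desk-scale experiments; injects no label signal.
* ``PrecomputedEmbedder`` — loads matrices from a cache directory (flat
  float32 binary + JSON sidecar, one pair per sequence hash), e.g. matrices
  exported from a language-model encoder elsewhere.
* ``PretrainedEmbedder`` — adapter around a frozen pretrained protein
  language-model encoder (1024-wide per-residue states, pooled over residue
  positions only). Inference-only; raises an explicit error when the
  optional ``transformers`` dependency is absent, never falls back silently.

Pooling over the sequence length is the arithmetic mean of the residue rows,
yielding a fixed d-dimensional vector per protein.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .descriptors import ordinal_encode

__all__ = [
    "EmbeddingMatrix",
    "mean_pool",
    "MockEmbedder",
    "PrecomputedEmbedder",
    "PretrainedEmbedder",
    "get_embedder",
    "save_matrix",
    "load_matrix",
]


@dataclass(frozen=True)
class EmbeddingMatrix:
    """l x d per-residue representation with its provider tag."""

    values: np.ndarray
    provider_tag: str

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError(f"embedding matrix must be l x d with l >= 1, got {self.values.shape}")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def mean_pool(phi: EmbeddingMatrix | np.ndarray) -> np.ndarray:
    """Average pooling over the sequence length: mu = (1/l) sum_k phi_k."""
    values = phi.values if isinstance(phi, EmbeddingMatrix) else np.asarray(phi)
    if values.ndim != 2 or values.shape[0] == 0:
        raise ValueError("mean_pool requires a nonempty l x d matrix")
    return values.mean(axis=0)


# ---------------------------------------------------------------------------
# cache format: <hash>.bin (float32 row-major) + <hash>.json sidecar
# ---------------------------------------------------------------------------

def _seq_hash(seq: str) -> str:
    return hashlib.sha1(seq.encode()).hexdigest()


def save_matrix(cache_dir: str | Path, seq: str, matrix: np.ndarray, provider_tag: str) -> Path:
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = _seq_hash(seq)
    data = np.asarray(matrix, dtype=np.float32)
    (cache_dir / f"{key}.bin").write_bytes(data.tobytes())
    sidecar = {"shape": list(data.shape), "dtype": "float32", "provider": provider_tag}
    (cache_dir / f"{key}.json").write_text(json.dumps(sidecar))
    return cache_dir / f"{key}.bin"


def load_matrix(cache_dir: str | Path, seq: str) -> EmbeddingMatrix | None:
    cache_dir = Path(cache_dir)
    key = _seq_hash(seq)
    bin_path = cache_dir / f"{key}.bin"
    json_path = cache_dir / f"{key}.json"
    if not (bin_path.exists() and json_path.exists()):
        return None
    sidecar = json.loads(json_path.read_text())
    data = np.frombuffer(bin_path.read_bytes(), dtype=np.float32).reshape(sidecar["shape"])
    return EmbeddingMatrix(np.array(data, dtype=np.float64), sidecar["provider"])


# ---------------------------------------------------------------------------
# providers
# ---------------------------------------------------------------------------

class MockEmbedder:
    """Deterministic seeded stand-in for a per-residue encoder.

    Row j is ``e[a_j] + positional_scale * p[j]`` where ``e`` is a seeded
    20 x d Gaussian residue table and ``p`` a seeded positional Gaussian
    stream; identical (sequence, seed) inputs give identical matrices. The
    construction carries residue-identity and position structure but no
    label information.
    """

    def __init__(self, d: int = 64, seed: int = 0, positional_scale: float = 0.25):
        self.d = int(d)
        self.seed = int(seed)
        self.positional_scale = float(positional_scale)
        self._residue_table = np.random.RandomState(seed).standard_normal((20, self.d))
        self._positional = np.zeros((0, self.d))

    @property
    def tag(self) -> str:
        return f"mock:d={self.d}:seed={self.seed}"

    def _positions(self, n: int) -> np.ndarray:
        if n > self._positional.shape[0]:
            # the RandomState stream fills row-major, so regenerating a longer
            # table reproduces the leading rows exactly
            self._positional = np.random.RandomState(self.seed + 1).standard_normal((n, self.d))
        return self._positional[:n]

    def embed(self, seq: str) -> EmbeddingMatrix:
        idx = ordinal_encode(seq) - 1
        rows = self._residue_table[idx] + self.positional_scale * self._positions(len(idx))
        return EmbeddingMatrix(rows, self.tag)


class PrecomputedEmbedder:
    """Serve matrices from a cache directory; missing sequences are errors."""

    def __init__(self, cache_dir: str | Path):
        self.cache_dir = Path(cache_dir)
        if not self.cache_dir.is_dir():
            raise FileNotFoundError(f"embedding cache directory not found: {cache_dir}")

    @property
    def tag(self) -> str:
        return f"precomputed:{self.cache_dir}"

    def embed(self, seq: str) -> EmbeddingMatrix:
        matrix = load_matrix(self.cache_dir, seq)
        if matrix is None:
            raise KeyError(f"no precomputed embedding for sequence hash {_seq_hash(seq)}")
        return matrix


class PretrainedEmbedder:
    """Frozen pretrained protein language-model encoder adapter (d = 1024).

    Requires the optional ``transformers``/``torch`` stack. Matrices are
    cached to disk keyed by (model reference, sequence hash); cache hits are
    bitwise identical. Residue positions only are returned (special tokens
    stripped before pooling).
    """

    D = 1024

    def __init__(self, model_ref: str, cache_dir: str | Path | None = None):
        self.model_ref = model_ref
        self.cache_dir = Path(cache_dir) if cache_dir else None
        self._model = None
        self._tokenizer = None

    @property
    def tag(self) -> str:
        return f"pretrained:{self.model_ref}"

    def _load(self):
        if self._model is not None:
            return
        try:
            import torch  # noqa: F401
            from transformers import T5EncoderModel, T5Tokenizer
        except ImportError as exc:
            raise RuntimeError(
                "embedder not installed: the pretrained provider needs the optional "
                "'transformers' and 'torch' packages; use the mock or precomputed "
                "provider instead"
            ) from exc
        self._tokenizer = T5Tokenizer.from_pretrained(self.model_ref, do_lower_case=False)
        self._model = T5EncoderModel.from_pretrained(self.model_ref).eval()

    def embed(self, seq: str) -> EmbeddingMatrix:
        if self.cache_dir is not None:
            cached = load_matrix(self.cache_dir, seq)
            if cached is not None:
                return cached
        self._load()
        import torch

        spaced = " ".join(seq)
        tokens = self._tokenizer(spaced, return_tensors="pt")
        with torch.no_grad():
            states = self._model(**tokens).last_hidden_state[0]
        matrix = states[: len(seq)].numpy().astype(np.float64)  # strip special tokens
        if self.cache_dir is not None:
            save_matrix(self.cache_dir, seq, matrix, self.tag)
        return EmbeddingMatrix(matrix, self.tag)


def get_embedder(spec: str, seed: int = 0, d: int = 64):
    """Resolve a provider config key.

    ``mock`` | ``pretrained:<model-ref>`` | ``precomputed:<dir>``.
    """
    if spec == "mock":
        return MockEmbedder(d=d, seed=seed)
    if spec.startswith("pretrained:"):
        return PretrainedEmbedder(spec.split(":", 1)[1])
    if spec.startswith("precomputed:"):
        return PrecomputedEmbedder(spec.split(":", 1)[1])
    raise ValueError(f"unknown embedder spec {spec!r}")
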
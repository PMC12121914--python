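"""TF-vs-non-TF screening: tokenization, CLS-embedding head, BCE loss.

This stage mirrors the protein-language-model workflow: each sequence is
tokenized residue-wise over the 20 canonical amino acids plus ``X`` for
anything non-standard, framed as ``[CLS] r1 ... rm [SEP]`` and padded to a
fixed token budget (default 1000 tokens, so 998 residues — the budget
includes the CLS and SEP tokens, standard BERT accounting).  Truncation
keeps the N-terminal prefix.  A backend maps the token sequence to a fixed
CLS summary vector; a linear layer plus sigmoid converts that vector into
the probability of being a transcription factor, with the inclusive rule
that probability >= 0.5 labels positive.

The head is trained by full-batch gradient descent on binary cross-entropy,

    L(y, p) = -(1/N) * sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ].

The :class:`StubEmbeddingBackend` is a deterministic, dependency-free
embedding based on fixed per-token random vectors; it exercises the full
tokenize -> embed -> head pipeline at test scale.  A transformer-based
protein language model can be dropped in through the same
:class:`EmbeddingBackend` contract (declared dimension + ``embed``), the
real backend emitting 1024-dimensional CLS vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from methylpref.io import CANONICAL_RESIDUES, LabeledDataset, ProteinRecord
from methylpref.metrics import MetricsReport, compute_metrics, confusion, roc_auc
from methylpref.tfpm import Prediction

CLS, SEP, PAD, UNK = "[CLS]", "[SEP]", "[PAD]", "X"

#: token vocabulary: residues + X + specials (index order is fixed)
VOCAB = tuple(sorted(CANONICAL_RESIDUES)) + (UNK, CLS, SEP, PAD)
_TOKEN_INDEX = {t: i for i, t in enumerate(VOCAB)}


@dataclass(frozen=True)
class TokenizerConfig:
    """Fixed token budget; the budget includes the CLS and SEP tokens."""

    max_len: int = 1000

    def __post_init__(self):
        if self.max_len < 3:
            raise ValueError("max_len must be >= 3 (CLS + SEP + >=1 residue)")


@dataclass(frozen=True)
class TokenizedSequence:
    """Token list of length exactly ``max_len`` with a parallel attention mask."""

    tokens: tuple[str, ...]
    attention_mask: tuple[int, ...]

    @property
    def n_real(self) -> int:
        return sum(self.attention_mask)


def tokenize(record: ProteinRecord, cfg: TokenizerConfig = TokenizerConfig()) -> TokenizedSequence:
    """Frame a sequence as [CLS, r1..rm, SEP, PAD...] with m = min(L, max_len-2).

    Non-canonical residues are mapped to ``X``; truncation keeps the
    N-terminal prefix.
    """
    budget = cfg.max_len - 2
    residues = [
        (ch if ch in CANONICAL_RESIDUES else UNK) for ch in record.sequence[:budget]
    ]
    tokens = [CLS] + residues + [SEP]
    mask = [1] * len(tokens)
    n_pad = cfg.max_len - len(tokens)
    tokens += [PAD] * n_pad
    mask += [0] * n_pad
    return TokenizedSequence(tokens=tuple(tokens), attention_mask=tuple(mask))


@dataclass(frozen=True)
class HeadParams:
    """Linear + sigmoid classification head: probability = sigmoid(w.e + b)."""

    weights: np.ndarray
    bias: float

    @property
    def dim(self) -> int:
        return len(self.weights)


class EmbeddingBackend(Protocol):
    """Contract: a declared dimension and a deterministic tokens -> CLS vector map."""

    dim: int

    def embed(self, tokenized: TokenizedSequence) -> np.ndarray: ...


class StubEmbeddingBackend:
    """Deterministic composition-style embedding for testing the pipeline.

    Each vocabulary token gets a fixed random vector (drawn once from
    ``seed``); a sequence embeds as the mean of its real (non-PAD) token
    vectors.  Same tokens always give the same vector, so the full screen is
    reproducible and runs in milliseconds per thousand records.
    """

    def __init__(self, dim: int = 32, seed: int = 0):
        self.dim = dim
        rng = np.random.default_rng(seed)
        self._table = rng.standard_normal((len(VOCAB), dim))

    def embed(self, tokenized: TokenizedSequence) -> np.ndarray:
        idx = [
            _TOKEN_INDEX[t]
            for t, m in zip(tokenized.tokens, tokenized.attention_mask)
            if m
        ]
        return self._table[idx].mean(axis=0)

    def embed_batch(self, tokenized: Sequence[TokenizedSequence]) -> np.ndarray:
        return np.vstack([self.embed(t) for t in tokenized])


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=float)))


def classify_head(
    embedding: np.ndarray, params: HeadParams, threshold: float = 0.5
) -> tuple[float, int]:
    """probability = sigmoid(w.e + b); label = 1 iff probability >= threshold."""
    e = np.asarray(embedding, dtype=float)
    if e.shape != (params.dim,):
        raise ValueError(f"embedding dim {e.shape} != head dim ({params.dim},)")
    p = float(_sigmoid(params.weights @ e + params.bias))
    return p, int(p >= threshold)


def bce_loss(labels, probabilities, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy; probabilities clipped to [eps, 1-eps]."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if y.size == 0:
        raise ValueError("bce_loss on empty input")
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def train_head(
    embeddings: np.ndarray,
    labels,
    lr: float = 0.5,
    n_iter: int = 500,
    seed: int = 0,
) -> tuple[HeadParams, list[float]]:
    """Fit the linear+sigmoid head by full-batch gradient descent on BCE.

    Weights start from a small seeded Gaussian; returns the fitted params
    and the per-iteration loss trace.
    """
    X = np.asarray(embeddings, dtype=float)
    y = np.asarray(labels, dtype=float)
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(X.shape[1]) * 0.01
    b = 0.0
    trace = []
    n = len(y)
    for _ in range(n_iter):
        p = _sigmoid(X @ w + b)
        trace.append(bce_loss(y, p))
        grad = p - y  # dL/dz for BCE with sigmoid
        w -= lr * (X.T @ grad) / n
        b -= lr * float(grad.mean())
    return HeadParams(weights=w, bias=b), trace


def screen(
    records: Sequence[ProteinRecord],
    backend: EmbeddingBackend,
    params: HeadParams,
    cfg: TokenizerConfig = TokenizerConfig(),
    threshold: float = 0.5,
) -> list[Prediction]:
    """tokenize -> embed -> classify each record, order preserved.

    Backend failures in batch mode yield flagged null predictions rather
    than aborting the screen.
    """
    out: list[Prediction] = []
    for rec in records:
        try:
            emb = backend.embed(tokenize(rec, cfg))
            p, label = classify_head(emb, params, threshold)
            logit = float(params.weights @ emb + params.bias)
            out.append(Prediction(rec.id, logit, p, label))
        except Exception:
            out.append(Prediction(rec.id, 0.0, 0.0, 0, flagged=True))
    return out


class TfScreenModel:
    """TF-vs-non-TF screening head specification: dataset + backend + tokenizer."""

    def __init__(
        self,
        dataset: LabeledDataset,
        backend: EmbeddingBackend | None = None,
        cfg: TokenizerConfig = TokenizerConfig(),
    ):
        self.dataset = dataset
        self.backend = backend or StubEmbeddingBackend()
        self.cfg = cfg

    def fit(self, lr: float = 0.5, n_iter: int = 500, seed: int = 0) -> "TfScreenResults":
        """Embed the training set and fit the head by gradient descent on BCE."""
        if len(self.dataset) == 0:
            raise ValueError("cannot fit on an empty dataset")
        emb = np.vstack(
            [self.backend.embed(tokenize(r, self.cfg)) for r in self.dataset.records]
        )
        params, trace = train_head(emb, self.dataset.labels, lr=lr, n_iter=n_iter, seed=seed)
        return TfScreenResults(self, params, trace)


class TfScreenResults:
    """Fitted screening head: per-record screening, evaluation, summary."""

    def __init__(self, model: TfScreenModel, params: HeadParams, loss_trace: list[float]):
        self.model = model
        self.params = params
        self.loss_trace = loss_trace

    @property
    def final_loss(self) -> float:
        return self.loss_trace[-1]

    def screen(self, records, threshold: float = 0.5) -> list[Prediction]:
        return screen(records, self.model.backend, self.params, self.model.cfg, threshold)

    def evaluate(self, dataset: LabeledDataset, threshold: float = 0.5) -> MetricsReport:
        preds = self.screen(dataset.records, threshold)
        labels = np.asarray(dataset.labels)
        return compute_metrics(
            confusion(labels, [p.label for p in preds]),
            auc=roc_auc(labels, [p.score for p in preds]),
        )

    def summary(self) -> str:
        return "\n".join(
            [
                "TF screening head (linear + sigmoid on CLS embedding)",
                "=" * 52,
                f"embedding dim:   {self.params.dim}",
                f"token budget:    {self.model.cfg.max_len}",
                f"training set:    {self.model.dataset.n_pos} TFs, "
                f"{self.model.dataset.n_neg} non-TFs",
                f"final BCE loss:  {self.final_loss:.4f}",
            ]
        )
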
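"""Sentence features from a language model, and decoding in feature space.

The extraction contract: per sentence, the per-token hidden states of one
transformer layer (default layer 8, width 768) are right-padded with zeros
to ``max_tokens`` (default 21) and flattened, so every sentence becomes a
vector of max_tokens * width = 16 128 elements.  The backend is pluggable:
a deterministic stub (hash-seeded Gaussian states, no downloads) is the
default for testing; a HuggingFace transformer backend is available when
the `transformers` package is installed.

Feature-space decoding uses leave-a-pair-of-words-out cross-validation: one
fold per (low-class item, high-class item) pair, training a linear SVM on
the remaining 34 sentences and scoring the held-out pair by ROC AUC.
Significance comes from a label-shuffle permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from hashlib import sha256
from typing import NamedTuple, Protocol

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .synth import EmbeddingMatrix

__all__ = [
    "Backend",
    "StubBackend",
    "HuggingFaceBackend",
    "extract_lm_features",
    "pair_holdout_decode",
    "label_permutation_pvalue",
    "PermutationResult",
]


class Backend(Protocol):
    """Supplies per-token hidden states of a requested layer."""

    width: int

    def layer_states(self, sentence: str, layer: int) -> np.ndarray:
        """(n_tokens, width) hidden states for one sentence."""
        ...


@dataclass
class StubBackend:
    """Deterministic stand-in backend (synthetic states, no model weights).

    Tokenizes on whitespace; each token's state vector is Gaussian noise
    seeded from a SHA-256 of (sentence, token index, layer), so extraction
    is pure: the same sentence always yields the same states, and different
    sentences yield (almost surely) different ones.
    """

    width: int = 768

    def layer_states(self, sentence: str, layer: int) -> np.ndarray:
        tokens = sentence.split()
        states = np.empty((len(tokens), self.width))
        for i in range(len(tokens)):
            digest = sha256(f"{sentence}\x00{i}\x00{layer}".encode()).digest()
            seed = int.from_bytes(digest[:4], "big")
            states[i] = np.random.default_rng(seed).standard_normal(self.width)
        return states


class HuggingFaceBackend:
    """Real transformer backend; requires the optional `transformers` package."""

    def __init__(self, model_name: str, width: int = 768):
        try:
            from transformers import AutoModel, AutoTokenizer  # noqa: PLC0415
        except ImportError as err:  # pragma: no cover - optional dependency
            raise ImportError(
                "HuggingFaceBackend needs the optional 'transformers' package; "
                "install it or use StubBackend"
            ) from err
        self.tokenizer = AutoTokenizer.from_pretrained(model_name)
        self.model = AutoModel.from_pretrained(model_name, output_hidden_states=True)
        self.width = width

    def layer_states(self, sentence: str, layer: int) -> np.ndarray:  # pragma: no cover
        import torch  # noqa: PLC0415

        enc = self.tokenizer(sentence, return_tensors="pt")
        with torch.no_grad():
            out = self.model(**enc)
        return out.hidden_states[layer][0].numpy()


def extract_lm_features(
    sentences: list[str],
    backend: Backend | None = None,
    layer: int = 8,
    max_tokens: int = 21,
) -> EmbeddingMatrix:
    """Layer states per sentence, zero-padded and flattened to one row each.

    Refuses sentences that tokenize to more than ``max_tokens`` tokens,
    reporting the offending count.
    """
    backend = backend or StubBackend()
    width = backend.width
    mat = np.zeros((len(sentences), max_tokens * width))
    counts = np.empty(len(sentences), dtype=int)
    for i, sent in enumerate(sentences):
        states = np.asarray(backend.layer_states(sent, layer), dtype=float)
        n_tok = states.shape[0]
        if n_tok > max_tokens:
            raise ValueError(
                f"sentence {i} tokenizes to {n_tok} tokens > max_tokens={max_tokens}"
            )
        counts[i] = n_tok
        mat[i, : n_tok * width] = states.ravel()
    return EmbeddingMatrix(matrix=mat, token_counts=counts, max_tokens=max_tokens, width=width)


def _pair_folds(labels: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    lo = np.nonzero(labels == 0)[0]
    hi = np.nonzero(labels == 1)[0]
    folds = []
    for a in lo:
        for b in hi:
            te = np.array([a, b])
            tr = np.setdiff1d(np.arange(len(labels)), te)
            folds.append((tr, te))
    return folds


def pair_holdout_decode(
    embeddings: np.ndarray | EmbeddingMatrix,
    labels: np.ndarray,
    seed: int = 0,
) -> float:
    """Mean pair-holdout ROC AUC of a linear SVM in feature space.

    One fold per (low, high) item pair (18 x 18 = 324 folds for the full
    design); features are standardized on each fold's training items, and
    the held-out pair is scored by the SVM decision function, giving AUC 1
    when the high item outranks the low item, 0.5 on a tie, 0 otherwise.
    """
    X = embeddings.matrix if isinstance(embeddings, EmbeddingMatrix) else np.asarray(embeddings)
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must be binary 0/1 with both classes present")
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise ValueError("need at least 2 items per class")
    aucs = []
    for tr, te in _pair_folds(labels):
        scaler = StandardScaler().fit(X[tr])
        clf = LinearSVC(C=1.0, random_state=seed).fit(scaler.transform(X[tr]), labels[tr])
        scores = clf.decision_function(scaler.transform(X[te]))
        aucs.append(roc_auc_score(labels[te], scores))
    return float(np.mean(aucs))


class PermutationResult(NamedTuple):
    p: float
    observed_auc: float
    null_aucs: np.ndarray


def label_permutation_pvalue(
    embeddings: np.ndarray | EmbeddingMatrix,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Shuffle-labels permutation test on the pair-holdout mean AUC.

    p = (1 + #{permuted AUC >= observed}) / (1 + n_perm), so p is always in
    (0, 1] with minimum 1/(1+n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    observed = pair_holdout_decode(embeddings, labels, seed=seed)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = pair_holdout_decode(embeddings, rng.permutation(labels), seed=seed)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(p=float(p), observed_auc=observed, null_aucs=null)
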
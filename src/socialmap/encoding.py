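"""Encoding-based RSA: ridge regression from sentence features to voxels.

A voxelwise L2-regularized linear model maps the 16 128-dimensional sentence
features to brain patterns.  Training leaves one subject out entirely; the
regularization strength is chosen by an inner leave-one-subject-out grid
search within the training subjects (scored by mean per-voxel Pearson
correlation between predicted and held-out values).  Because the full
feature-to-voxel weight matrix is large, voxels are split into contiguous
chunks fit independently — ridge is separable across targets, so chunked and
unchunked predictions are numerically identical.  The held-out subject's
predicted patterns are then compared to their observed patterns
sphere-by-sphere via Spearman-correlated RDMs, exactly as in standard RSA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.linear_model import Ridge
from sklearn.preprocessing import StandardScaler

from .rsa import ConceptPatterns, compute_rdm, upper_triangle, _iter_spheres, RHO_CLIP
from .volume import StatMap

__all__ = [
    "EncoderSpec",
    "chunk_slices",
    "fit_ridge_encoder",
    "chunked_predict",
    "encoding_rsa_map",
    "encoding_rsa_chance",
]

DEFAULT_LAMBDA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


def chunk_slices(n_voxels: int, n_chunks: int) -> list[slice]:
    """Equal contiguous blocks partitioning ``range(n_voxels)``."""
    n_chunks = min(n_chunks, n_voxels)
    bounds = np.linspace(0, n_voxels, n_chunks + 1).astype(int)
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


@dataclass
class EncoderSpec:
    """A fitted chunked ridge encoder and its provenance."""

    models: list[Ridge]
    slices: list[slice]
    scaler: StandardScaler
    alpha: float
    n_features: int
    n_voxels: int
    train_subjects: list
    holdout_subject: object
    grid_scores: dict

    def __post_init__(self) -> None:
        covered = np.zeros(self.n_voxels, dtype=int)
        for s in self.slices:
            covered[s] += 1
        if not np.all(covered == 1):
            raise ValueError("chunks must partition the voxel set exactly once")


def _stack_training(
    features: np.ndarray, targets_by_subject: dict, subjects: list
) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([features for _ in subjects])
    Y = np.vstack([targets_by_subject[s] for s in subjects])
    return X, Y


def _cv_score(pred: np.ndarray, obs: np.ndarray) -> float:
    """Mean per-voxel product-moment correlation, ignoring flat voxels."""
    pc = pred - pred.mean(0)
    oc = obs - obs.mean(0)
    denom = np.sqrt((pc**2).sum(0) * (oc**2).sum(0))
    ok = denom > 1e-12
    if not ok.any():
        return -1.0
    return float(((pc * oc).sum(0)[ok] / denom[ok]).mean())


def fit_ridge_encoder(
    features: np.ndarray,
    targets_by_subject: dict,
    holdout_subject,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    n_chunks: int = 20,
) -> EncoderSpec:
    """Leave-one-subject-out ridge with inner-LOSO grid search for lambda.

    ``features`` is the shared (n_concepts x n_features) sentence matrix;
    ``targets_by_subject`` maps subject id to that subject's
    (n_concepts x n_voxels) patterns.  The holdout subject's data never
    enters standardization, lambda selection, or fitting.
    """
    if len(lambda_grid) == 0:
        raise ValueError("lambda grid must be non-empty")
    train_subjects = [s for s in targets_by_subject if s != holdout_subject]
    if len(train_subjects) < 2:
        raise ValueError("need at least 2 training subjects for the inner CV")
    features = np.asarray(features, dtype=float)
    n_voxels = next(iter(targets_by_subject.values())).shape[1]

    # inner leave-one-subject-out over training subjects
    grid_scores: dict[float, float] = {}
    for lam in lambda_grid:
        scores = []
        for inner in train_subjects:
            inner_train = [s for s in train_subjects if s != inner]
            X, Y = _stack_training(features, targets_by_subject, inner_train)
            scaler = StandardScaler().fit(X)
            model = Ridge(alpha=lam).fit(scaler.transform(X), Y)
            pred = model.predict(scaler.transform(features)).reshape(len(features), -1)
            scores.append(_cv_score(pred, targets_by_subject[inner]))
        grid_scores[lam] = float(np.mean(scores))
    best = max(grid_scores, key=grid_scores.get)

    X, Y = _stack_training(features, targets_by_subject, train_subjects)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    slices = chunk_slices(n_voxels, n_chunks)
    models = [Ridge(alpha=best).fit(Xs, Y[:, s]) for s in slices]
    return EncoderSpec(
        models=models,
        slices=slices,
        scaler=scaler,
        alpha=best,
        n_features=features.shape[1],
        n_voxels=n_voxels,
        train_subjects=train_subjects,
        holdout_subject=holdout_subject,
        grid_scores=grid_scores,
    )


def chunked_predict(encoder: EncoderSpec, features: np.ndarray) -> np.ndarray:
    """Predictions concatenated in original voxel order."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != encoder.n_features:
        raise ValueError(
            f"feature dimension {features.shape[1]} != fitted {encoder.n_features}"
        )
    Xs = encoder.scaler.transform(features)
    out = np.empty((features.shape[0], encoder.n_voxels))
    for model, s in zip(encoder.models, encoder.slices):
        out[:, s] = model.predict(Xs).reshape(features.shape[0], -1)
    return out


def encoding_rsa_map(
    predicted: ConceptPatterns,
    observed: ConceptPatterns,
    radius_mm: float = 4.0,
    centers: np.ndarray | None = None,
) -> StatMap:
    """Fisher-z Spearman between predicted-RDM and observed-RDM per sphere."""
    if predicted.grid != observed.grid or not np.array_equal(
        predicted.voxel_ijk, observed.voxel_ijk
    ):
        raise ValueError("predicted and observed patterns must share geometry")
    data = np.full(observed.grid.shape, np.nan)
    for center, cols in _iter_spheres(observed, radius_mm, centers):
        if len(cols) < 2:
            continue
        p, o = predicted.data[:, cols], observed.data[:, cols]
        if np.any(p.std(axis=1) < 1e-300) or np.any(o.std(axis=1) < 1e-300):
            continue
        rho = spearmanr(
            upper_triangle(compute_rdm(p)), upper_triangle(compute_rdm(o))
        ).statistic
        data[tuple(center)] = float(np.arctanh(np.clip(rho, -RHO_CLIP, RHO_CLIP)))
    return StatMap(data=data, grid=observed.grid, tag="z", meta={"radius_mm": radius_mm})


def encoding_rsa_chance(
    predicted: ConceptPatterns,
    observed: ConceptPatterns,
    n_shuffles: int = 100,
    seed: int = 0,
    radius_mm: float = 4.0,
    centers: np.ndarray | None = None,
) -> StatMap:
    """Chance map from shuffling the observed concept-row assignment."""
    rng = np.random.default_rng(seed)
    acc = np.zeros(observed.grid.shape)
    cnt = np.zeros(observed.grid.shape, dtype=int)
    for _ in range(n_shuffles):
        perm = rng.permutation(len(observed.concept_ids))
        shuf = ConceptPatterns(
            data=observed.data[perm],
            concept_ids=observed.concept_ids,
            voxel_ijk=observed.voxel_ijk,
            grid=observed.grid,
        )
        m = encoding_rsa_map(predicted, shuf, radius_mm=radius_mm, centers=centers)
        ok = np.isfinite(m.data)
        acc[ok] += m.data[ok]
        cnt[ok] += 1
    data = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return StatMap(data=data, grid=observed.grid, tag="z_chance", meta={"n_shuffles": n_shuffles, "seed": seed})
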
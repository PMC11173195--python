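"""Whole-brain searchlight decoding of affect and social desirability.

A 4-mm sphere slides over every in-mask voxel; the sphere's voxel values are
the features of a calibrated linear SVM that predicts the binary condition.
Performance is ROC AUC on held-out data under one of three cross-validation
schemes (100x stratified 80/20 shuffle, leave-one-run-out, or
leave-two-concepts-out), minus the AUC of a feature-blind dummy that emits
random probabilities under the identical protocol.  The difference map,
centered on zero under the null, is the input to group inference.

Seed policy: a master seed is fanned out per sphere through
``numpy.random.SeedSequence`` so serial and parallel traversals agree, and
the dummy's random scores are paired fold-for-fold with the real
classifier's splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .dataprep import ExampleSet
from .volume import StatMap, VolumeGrid

__all__ = [
    "SphereIndex",
    "sphere_offsets",
    "sphere_members",
    "make_cv_splits",
    "decode_auc",
    "chance_auc",
    "run_searchlight",
]

SCHEMES = ("stratified_shuffle", "leave_one_run_out", "leave_two_concepts_out")


@dataclass
class SphereIndex:
    center_ijk: np.ndarray
    member_columns: np.ndarray  # indices into ExampleSet columns


def sphere_offsets(affine: np.ndarray, radius_mm: float) -> np.ndarray:
    """Integer voxel offsets whose mm displacement is within the radius."""
    A = np.asarray(affine, dtype=float)[:3, :3]
    # bound the search box by the smallest voxel dimension
    step = np.min(np.linalg.norm(A, axis=0))
    r = int(np.ceil(radius_mm / step)) + 1
    offs = np.array(np.meshgrid(*([range(-r, r + 1)] * 3), indexing="ij")).reshape(3, -1).T
    d = np.linalg.norm(offs @ A.T, axis=1)
    return offs[d <= radius_mm]


def sphere_members(
    center_ijk: np.ndarray,
    grid: VolumeGrid,
    radius_mm: float = 4.0,
    column_lookup: dict | None = None,
) -> SphereIndex:
    """All in-mask voxels within ``radius_mm`` (center-to-center, via affine).

    ``column_lookup`` maps (i, j, k) tuples to ExampleSet column indices;
    when omitted, members are returned in grid-mask order over
    ``grid.mask_indices()``.
    """
    center_ijk = np.asarray(center_ijk, dtype=int)
    if not grid.mask[tuple(center_ijk)]:
        raise ValueError("sphere center outside the brain mask")
    cand = center_ijk + sphere_offsets(grid.affine, radius_mm)
    inside = np.all((cand >= 0) & (cand < np.array(grid.shape)), axis=1)
    cand = cand[inside]
    cand = cand[grid.mask[tuple(cand.T)]]
    if column_lookup is None:
        column_lookup = {tuple(ijk): i for i, ijk in enumerate(grid.mask_indices())}
    cols = np.array(
        sorted(column_lookup[tuple(c)] for c in cand if tuple(c) in column_lookup),
        dtype=int,
    )
    return SphereIndex(center_ijk=center_ijk, member_columns=cols)


def make_cv_splits(
    scheme: str,
    labels: np.ndarray,
    run_ids: np.ndarray | None = None,
    concept_ids: np.ndarray | None = None,
    seed: int = 0,
    n_splits: int = 100,
    test_size: float = 0.2,
    max_folds: int | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Folds for the three schemes; train and test are always disjoint.

    stratified_shuffle: ``n_splits`` random stratified 80/20 splits (ignores
    run structure, as in the original protocol).  leave_one_run_out: one fold
    per run.  leave_two_concepts_out: one fold per (low-class concept,
    high-class concept) pair, testing on every trial of the two held-out
    concepts; ``max_folds`` subsamples the pair list reproducibly.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must be binary")
    if scheme == "stratified_shuffle":
        sss = StratifiedShuffleSplit(n_splits=n_splits, test_size=test_size, random_state=seed)
        return [(tr, te) for tr, te in sss.split(np.zeros_like(labels), labels)]
    if scheme == "leave_one_run_out":
        if run_ids is None:
            raise ValueError("leave_one_run_out needs run_ids")
        run_ids = np.asarray(run_ids)
        return [
            (np.nonzero(run_ids != r)[0], np.nonzero(run_ids == r)[0])
            for r in np.unique(run_ids)
        ]
    if scheme == "leave_two_concepts_out":
        if concept_ids is None:
            raise ValueError("leave_two_concepts_out needs concept_ids")
        concept_ids = np.asarray(concept_ids)
        hi = np.unique(concept_ids[labels == 1])
        lo = np.unique(concept_ids[labels == 0])
        pairs = [(a, b) for a in lo for b in hi]
        if max_folds is not None and max_folds < len(pairs):
            rng = np.random.default_rng(seed)
            pairs = [pairs[i] for i in rng.choice(len(pairs), max_folds, replace=False)]
        folds = []
        for a, b in pairs:
            te = np.nonzero((concept_ids == a) | (concept_ids == b))[0]
            tr = np.nonzero((concept_ids != a) & (concept_ids != b))[0]
            folds.append((tr, te))
        return folds
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def sphere_seed(master_seed: int, center_ijk: np.ndarray, shape: tuple[int, int, int]) -> int:
    """Deterministic per-sphere sub-seed from the master seed and center."""
    flat = int(np.ravel_multi_index(tuple(np.asarray(center_ijk, dtype=int)), shape))
    return int(np.random.SeedSequence([master_seed, flat]).generate_state(1)[0] % (2**31))


def _calibrated_svc(seed: int, calibration_folds: int = 3) -> CalibratedClassifierCV:
    return CalibratedClassifierCV(
        LinearSVC(C=1.0, random_state=seed),
        method="sigmoid",
        cv=calibration_folds,
    )


def decode_auc(
    X: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
) -> float:
    """Mean held-out ROC AUC of a calibrated linear SVM over folds.

    Per fold: features standardized on the training set (then applied to
    test), linear SVM with default margin penalty wrapped in sigmoid
    probability calibration, AUC of the test-set class probabilities.
    Folds with a single training class are skipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    aucs = []
    for tr, te in folds:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            warnings.warn("fold with a single class skipped", stacklevel=2)
            continue
        scaler = StandardScaler().fit(X[tr])
        cal_cv = min(3, int(np.bincount(y[tr]).min()))
        clf = _calibrated_svc(seed, calibration_folds=max(2, cal_cv))
        clf.fit(scaler.transform(X[tr]), y[tr])
        proba = clf.predict_proba(scaler.transform(X[te]))[:, 1]
        aucs.append(roc_auc_score(y[te], proba))
    if not aucs:
        raise ValueError("no usable folds")
    return float(np.mean(aucs))


def chance_auc(
    X: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
) -> float:
    """Identical protocol but label-independent random test probabilities.

    The features are never read, so two datasets with the same labels,
    folds and seed give the same value; over seeds the distribution is
    centered on 0.5.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    aucs = []
    for tr, te in folds:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            warnings.warn("fold with a single class skipped", stacklevel=2)
            continue
        proba = rng.random(len(te))
        aucs.append(roc_auc_score(y[te], proba))
    if not aucs:
        raise ValueError("no usable folds")
    return float(np.mean(aucs))


def _sphere_value(
    X: np.ndarray,
    y: np.ndarray,
    run_ids: np.ndarray,
    concept_ids: np.ndarray,
    cols: np.ndarray,
    scheme: str,
    n_reps: int,
    sub_seed: int,
    max_folds: int | None,
) -> float:
    folds = make_cv_splits(
        scheme, y, run_ids, concept_ids, seed=sub_seed, n_splits=n_reps, max_folds=max_folds
    )
    real = decode_auc(X[:, cols], y, folds, seed=sub_seed)
    dummy = chance_auc(X[:, cols], y, folds, seed=sub_seed)
    return real - dummy


def run_searchlight(
    example_set: ExampleSet,
    dimension: str,
    scheme: str = "stratified_shuffle",
    radius_mm: float = 4.0,
    seed: int = 0,
    n_reps: int = 100,
    centers: np.ndarray | None = None,
    max_folds: int | None = None,
    n_jobs: int = 1,
) -> StatMap:
    """AUC-minus-chance map; each sphere's value sits at its center voxel.

    ``centers`` restricts evaluation to a subset of in-mask voxel
    coordinates (rows of (i, j, k)); unevaluated voxels are NaN.  The
    per-sphere sub-seed is SeedSequence(seed, center_rank), so results do
    not depend on traversal order or parallelism.
    """
    y = example_set.binary_labels(dimension)
    run_ids = example_set.labels["run_id"].to_numpy()
    concept_ids = example_set.labels["concept_id"].to_numpy()
    grid = example_set.grid
    lookup = {tuple(ijk): i for i, ijk in enumerate(example_set.voxel_ijk)}
    all_centers = example_set.voxel_ijk if centers is None else np.asarray(centers, dtype=int)

    spheres = [
        sphere_members(c, grid, radius_mm, column_lookup=lookup) for c in all_centers
    ]
    # sub-seed keyed to the center's flat grid index, not traversal rank,
    # so reordering or parallelizing the centers cannot change any value
    sub_seeds = [sphere_seed(seed, s.center_ijk, grid.shape) for s in spheres]
    jobs = (
        delayed(_sphere_value)(
            example_set.X, y, run_ids, concept_ids, s.member_columns, scheme,
            n_reps, ss, max_folds,
        )
        for s, ss in zip(spheres, sub_seeds)
        if len(s.member_columns) > 0
    )
    values = Parallel(n_jobs=n_jobs)(jobs)
    data = np.full(grid.shape, np.nan)
    vi = iter(values)
    for s in spheres:
        if len(s.member_columns) > 0:
            data[tuple(s.center_ijk)] = next(vi)
    return StatMap(
        data=data,
        grid=grid,
        tag="auc_minus_chance",
        meta={
            "dimension": dimension,
            "scheme": scheme,
            "radius_mm": radius_mm,
            "n_reps": n_reps,
            "seed": seed,
        },
    )
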
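"""Model-based representational similarity analysis with noise ceilings.

Per-concept activity patterns (36 x n_voxels, trials averaged within
concept) are compared to a model RDM — typically 1 - Pearson dissimilarities
among sentence embeddings — by Spearman-correlating the strict upper
triangles of the sphere RDM and the model RDM at every searchlight sphere.
Correlations are Fisher-z (arctanh) transformed, with |rho| clipped just
below 1 to keep z finite.  The empirical chance map repeats the procedure
with the concept-to-pattern assignment shuffled; observed minus chance is
the group-inference input.  Noise ceilings bound attainable model
performance: lower = each subject's RDM vs the mean RDM of the remaining
subjects, upper = vs the mean including the subject itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .dataprep import ExampleSet
from .searchlight import sphere_members
from .volume import StatMap, VolumeGrid

__all__ = [
    "ConceptPatterns",
    "NoiseCeilingMap",
    "average_per_concept",
    "compute_rdm",
    "upper_triangle",
    "searchlight_rsa",
    "rsa_chance",
    "noise_ceiling",
]

RHO_CLIP = 1.0 - 1e-7


@dataclass
class ConceptPatterns:
    """Concept x voxel matrix with voxel geometry (rows sorted by concept)."""

    data: np.ndarray  # (n_concepts, n_voxels)
    concept_ids: np.ndarray
    voxel_ijk: np.ndarray
    grid: VolumeGrid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.concept_ids = np.asarray(self.concept_ids, dtype=int)
        self.voxel_ijk = np.asarray(self.voxel_ijk, dtype=int)
        if self.data.shape != (len(self.concept_ids), len(self.voxel_ijk)):
            raise ValueError("data must be (n_concepts, n_voxels)")


def average_per_concept(example_set: ExampleSet) -> ConceptPatterns:
    """Mean pattern per concept across its trials; rows ordered by concept id."""
    df = example_set.labels
    concept_ids = np.sort(df["concept_id"].unique())
    rows = []
    for cid in concept_ids:
        idx = np.nonzero((df["concept_id"] == cid).to_numpy())[0]
        if len(idx) == 0:
            raise ValueError(f"concept {cid} has no examples")
        rows.append(example_set.X[idx].mean(axis=0))
    return ConceptPatterns(
        data=np.vstack(rows),
        concept_ids=concept_ids,
        voxel_ijk=example_set.voxel_ijk,
        grid=example_set.grid,
    )


def compute_rdm(patterns: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation among rows; symmetric, zero diagonal."""
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[0] < 2:
        raise ValueError("need at least 2 items")
    if np.any(patterns.std(axis=1) < 1e-300):
        raise ValueError("constant row: Pearson correlation undefined")
    rdm = 1.0 - np.corrcoef(patterns)
    np.fill_diagonal(rdm, 0.0)
    return rdm


def upper_triangle(rdm: np.ndarray) -> np.ndarray:
    """Strict upper triangle, row-major."""
    rdm = np.asarray(rdm)
    return rdm[np.triu_indices(rdm.shape[0], k=1)]


def _rdm_spearman_z(sphere_patterns: np.ndarray, model_vec: np.ndarray) -> float:
    rho = spearmanr(upper_triangle(compute_rdm(sphere_patterns)), model_vec).statistic
    return float(np.arctanh(np.clip(rho, -RHO_CLIP, RHO_CLIP)))


def _iter_spheres(patterns: ConceptPatterns, radius_mm: float, centers: np.ndarray | None):
    lookup = {tuple(ijk): i for i, ijk in enumerate(patterns.voxel_ijk)}
    cs = patterns.voxel_ijk if centers is None else np.asarray(centers, dtype=int)
    for c in cs:
        s = sphere_members(c, patterns.grid, radius_mm, column_lookup=lookup)
        yield c, s.member_columns


def searchlight_rsa(
    patterns: ConceptPatterns,
    model_rdm: np.ndarray,
    radius_mm: float = 4.0,
    centers: np.ndarray | None = None,
) -> StatMap:
    """Fisher-z Spearman between sphere RDM and model RDM at every center.

    Spheres with fewer than 2 voxels (or a constant pattern) are masked out.
    """
    model_rdm = np.asarray(model_rdm, dtype=float)
    if model_rdm.shape != (len(patterns.concept_ids),) * 2:
        raise ValueError("model RDM dimension must match concept count")
    model_vec = upper_triangle(model_rdm)
    data = np.full(patterns.grid.shape, np.nan)
    for center, cols in _iter_spheres(patterns, radius_mm, centers):
        if len(cols) < 2:
            continue
        sub = patterns.data[:, cols]
        if np.any(sub.std(axis=1) < 1e-300):
            continue
        data[tuple(center)] = _rdm_spearman_z(sub, model_vec)
    return StatMap(data=data, grid=patterns.grid, tag="z", meta={"radius_mm": radius_mm})


def rsa_chance(
    patterns: ConceptPatterns,
    model_rdm: np.ndarray,
    n_shuffles: int = 100,
    seed: int = 0,
    radius_mm: float = 4.0,
    centers: np.ndarray | None = None,
) -> StatMap:
    """Empirical chance map: mean z over concept-row shuffles.

    Shuffling the concept-to-pattern assignment destroys the correspondence
    with the model RDM while preserving the data's spatial structure.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    acc = np.zeros(patterns.grid.shape)
    cnt = np.zeros(patterns.grid.shape, dtype=int)
    for _ in range(n_shuffles):
        perm = rng.permutation(len(patterns.concept_ids))
        shuffled = ConceptPatterns(
            data=patterns.data[perm],
            concept_ids=patterns.concept_ids,
            voxel_ijk=patterns.voxel_ijk,
            grid=patterns.grid,
        )
        m = searchlight_rsa(shuffled, model_rdm, radius_mm=radius_mm, centers=centers)
        ok = np.isfinite(m.data)
        acc[ok] += m.data[ok]
        cnt[ok] += 1
    data = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return StatMap(data=data, grid=patterns.grid, tag="z_chance", meta={"n_shuffles": n_shuffles, "seed": seed})


@dataclass
class NoiseCeilingMap:
    lower: StatMap
    upper: StatMap

    def __post_init__(self) -> None:
        # rank correlation does not make lower <= upper a theorem, but any
        # violation beyond numerical noise indicates mismatched inputs
        ok = np.isfinite(self.lower.data) & np.isfinite(self.upper.data)
        bad = int(np.sum(self.lower.data[ok] > self.upper.data[ok] + 1e-9))
        if bad:
            import warnings

            warnings.warn(
                f"lower noise ceiling exceeds upper at {bad} voxels", stacklevel=2
            )


def noise_ceiling(
    subject_patterns: list[ConceptPatterns],
    radius_mm: float = 4.0,
    centers: np.ndarray | None = None,
) -> NoiseCeilingMap:
    """Leave-one-out (lower) and all-subject (upper) RDM agreement per sphere.

    Per sphere: each subject's RDM is Spearman-correlated with the
    element-wise mean RDM of the other subjects (lower) and of all subjects
    (upper); the subject-mean correlations are assigned to the center.
    """
    if len(subject_patterns) < 3:
        raise ValueError("noise ceiling needs at least 3 subjects")
    ref = subject_patterns[0]
    for p in subject_patterns[1:]:
        if p.grid != ref.grid or not np.array_equal(p.voxel_ijk, ref.voxel_ijk):
            raise ValueError("subjects must share grid and voxel set")
    n_sub = len(subject_patterns)
    lower = np.full(ref.grid.shape, np.nan)
    upper = np.full(ref.grid.shape, np.nan)
    for center, cols in _iter_spheres(ref, radius_mm, centers):
        if len(cols) < 2:
            continue
        try:
            rdms = np.stack(
                [upper_triangle(compute_rdm(p.data[:, cols])) for p in subject_patterns]
            )
        except ValueError:  # constant pattern in some subject
            continue
        mean_all = rdms.mean(axis=0)
        lo, up = [], []
        for s in range(n_sub):
            others = (mean_all * n_sub - rdms[s]) / (n_sub - 1)
            lo.append(spearmanr(rdms[s], others).statistic)
            up.append(spearmanr(rdms[s], mean_all).statistic)
        lower[tuple(center)] = float(np.mean(lo))
        upper[tuple(center)] = float(np.mean(up))
    return NoiseCeilingMap(
        lower=StatMap(data=lower, grid=ref.grid, tag="noise_ceiling_lower"),
        upper=StatMap(data=upper, grid=ref.grid, tag="noise_ceiling_upper"),
    )


def model_rdm_from_embeddings(matrix: np.ndarray) -> np.ndarray:
    """Convenience: 1 - Pearson RDM of an embedding matrix's rows."""
    return compute_rdm(np.asarray(matrix, dtype=float))


def read_model_rdm(path) -> np.ndarray:
    rdm = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    if rdm.shape[0] != rdm.shape[1] or not np.allclose(rdm, rdm.T):
        raise ValueError("model RDM must be square and symmetric")
    return rdm
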
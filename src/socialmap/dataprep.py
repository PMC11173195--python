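"""From preprocessed runs to labeled MVPA examples.

Order of operations: trim initial volumes -> drop invariant voxels ->
per-voxel linear detrend + z-score per run -> stack runs -> one example per
trial by averaging volumes whose acquisition midpoint falls in the 5.5-10.5 s
post-onset window (the HRF peak for a ~3.5 s stimulus).  Detrending and
scaling are a single combined linear model per voxel: the least-squares line
is removed and the residual standardized.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import BoldRun, VolumeGrid

__all__ = [
    "ExampleSet",
    "trim_initial_volumes",
    "remove_invariant_voxels",
    "normalize_run",
    "extract_examples",
    "prepare_examples",
]

DEFAULT_WINDOW = (5.5, 10.5)


@dataclass
class ExampleSet:
    """Examples x voxels matrix with labels and voxel geometry.

    One row per (run, concept) trial.  ``voxel_ijk`` maps each column to its
    grid coordinate, so searchlights can gather sphere features by geometry.
    """

    X: np.ndarray
    labels: pd.DataFrame  # columns: affect, desirability, run_id, concept_id
    voxel_ijk: np.ndarray  # (n_voxels, 3) int
    grid: VolumeGrid

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.voxel_ijk = np.asarray(self.voxel_ijk, dtype=int)
        if self.X.shape != (len(self.labels), len(self.voxel_ijk)):
            raise ValueError("X shape must be (n_examples, n_voxels)")
        dup = self.labels.duplicated(subset=["run_id", "concept_id"])
        if dup.any():
            raise ValueError("more than one example per (run, concept)")

    @property
    def n_examples(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def binary_labels(self, dimension: str) -> np.ndarray:
        """0/1 vector for 'affect' or 'desirability' (1 = high)."""
        if dimension not in ("affect", "desirability"):
            raise ValueError("dimension must be 'affect' or 'desirability'")
        return (self.labels[dimension].to_numpy() == "high").astype(int)

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.save(outdir / "X.npy", self.X)
        self.labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
        header = {
            "voxel_ijk": self.voxel_ijk.tolist(),
            "grid_shape": list(self.grid.shape),
            "affine": self.grid.affine.tolist(),
            "mask_ijk": self.grid.mask_indices().tolist(),
        }
        (outdir / "header.json").write_text(json.dumps(header))
        return outdir

    @classmethod
    def load(cls, outdir: str | Path) -> "ExampleSet":
        outdir = Path(outdir)
        header = json.loads((outdir / "header.json").read_text())
        shape = tuple(header["grid_shape"])
        mask = np.zeros(shape, dtype=bool)
        mi = np.array(header["mask_ijk"], dtype=int)
        mask[tuple(mi.T)] = True
        grid = VolumeGrid(shape=shape, affine=np.array(header["affine"]), mask=mask)
        return cls(
            X=np.load(outdir / "X.npy"),
            labels=pd.read_csv(outdir / "labels.tsv", sep="\t"),
            voxel_ijk=np.array(header["voxel_ijk"], dtype=int),
            grid=grid,
        )


def trim_initial_volumes(
    run: BoldRun, n: int, events: pd.DataFrame | None = None
) -> BoldRun | tuple[BoldRun, pd.DataFrame]:
    """Drop the first ``n`` volumes; re-reference event onsets by -n*TR."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= run.n_volumes:
        raise ValueError(f"cannot trim {n} of {run.n_volumes} volumes")
    trimmed = BoldRun(run_id=run.run_id, data=run.data[..., n:], tr=run.tr, grid=run.grid)
    if events is None:
        return trimmed
    ev = events.copy()
    ev["onset"] = ev["onset"] - n * run.tr
    return trimmed, ev


def remove_invariant_voxels(runs: list[BoldRun], tol: float = 1e-10) -> np.ndarray:
    """Boolean keep-mask: voxels whose signal varies in EVERY run.

    A voxel constant (variance <= tol) in any single run is dropped
    everywhere, since its pattern carries no information for that run and
    z-scoring it is undefined.  Restricted to the grid's brain mask.
    """
    if not runs:
        raise ValueError("need at least one run")
    keep = runs[0].grid.mask.copy()
    for run in runs:
        keep &= run.data.var(axis=3) > tol
    if not keep.any():
        raise ValueError("all voxels are invariant; nothing to analyze")
    return keep


def normalize_run(run: BoldRun, voxel_mask: np.ndarray | None = None) -> BoldRun:
    """Per-voxel linear detrend + z-score (single least-squares pass).

    For each voxel the best-fit line a + b*t is removed and the residual
    scaled to unit variance (its mean is zero by construction).  Voxels
    whose residual variance is ~0 are set to all-zeros and flagged with a
    warning.  Voxels outside ``voxel_mask`` (default: grid mask) are zeroed.
    """
    nt = run.n_volumes
    if nt < 3:
        raise ValueError("need at least 3 time points to detrend")
    mask = run.grid.mask if voxel_mask is None else np.asarray(voxel_mask, dtype=bool)
    Y = run.data[mask, :]  # (n_vox, t)
    t = np.arange(nt, dtype=float)
    A = np.stack([np.ones(nt), t], axis=1)  # (t, 2)
    coef, *_ = np.linalg.lstsq(A, Y.T, rcond=None)
    resid = Y - (A @ coef).T
    sd = resid.std(axis=1)
    degenerate = sd < 1e-12
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} voxels had no variance after detrending; "
            "set to zero",
            stacklevel=2,
        )
    sd_safe = np.where(degenerate, 1.0, sd)
    Z = resid / sd_safe[:, None]
    Z[degenerate] = 0.0
    out = np.zeros_like(run.data)
    out[mask, :] = Z
    return BoldRun(run_id=run.run_id, data=out, tr=run.tr, grid=run.grid)


def window_volume_indices(
    onset: float, tr: float, n_volumes: int, window: tuple[float, float] = DEFAULT_WINDOW
) -> np.ndarray:
    """Volumes whose acquisition midpoint (i+0.5)*TR lies in [onset+lo, onset+hi)."""
    mid = (np.arange(n_volumes) + 0.5) * tr
    lo, hi = window
    return np.nonzero((mid >= onset + lo) & (mid < onset + hi))[0]


def extract_examples(
    runs: list[BoldRun],
    events_list: list[pd.DataFrame],
    window: tuple[float, float] = DEFAULT_WINDOW,
    voxel_mask: np.ndarray | None = None,
) -> ExampleSet:
    """Average the post-onset window per trial and stack runs.

    Runs are assumed normalized per run; stacking then simply concatenates
    examples.  Trials whose window extends past the end of the run are
    dropped with a warning.
    """
    if len(runs) != len(events_list):
        raise ValueError("need one event table per run")
    mask = runs[0].grid.mask if voxel_mask is None else np.asarray(voxel_mask, dtype=bool)
    voxel_ijk = np.argwhere(mask)
    rows, labels = [], []
    for run, events in zip(runs, events_list):
        flat = run.data[mask, :]
        for _, ev in events.iterrows():
            idx = window_volume_indices(float(ev["onset"]), run.tr, run.n_volumes, window)
            full = window_volume_indices(float(ev["onset"]), run.tr, run.n_volumes + 10_000, window)
            if len(idx) < len(full):
                warnings.warn(
                    f"run {run.run_id}: trial at {ev['onset']:.1f} s extends past "
                    "the end of the run; dropped",
                    stacklevel=2,
                )
                continue
            rows.append(flat[:, idx].mean(axis=1))
            labels.append(
                {
                    "affect": ev["affect"],
                    "desirability": ev["desirability"],
                    "run_id": int(ev["run_id"]),
                    "concept_id": int(ev["concept_id"]),
                }
            )
    if not rows:
        raise ValueError("no usable trials")
    return ExampleSet(
        X=np.vstack(rows),
        labels=pd.DataFrame(labels),
        voxel_ijk=voxel_ijk,
        grid=runs[0].grid,
    )


def prepare_examples(
    runs: list[BoldRun],
    events_list: list[pd.DataFrame],
    n_trim: int = 10,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> ExampleSet:
    """Full preparation chain: trim, invariant removal, normalize, extract."""
    trimmed, ev_out = [], []
    for run, ev in zip(runs, events_list):
        r, e = trim_initial_volumes(run, n_trim, ev)
        trimmed.append(r)
        ev_out.append(e)
    keep = remove_invariant_voxels(trimmed)
    normed = [normalize_run(r, keep) for r in trimmed]
    return extract_examples(normed, ev_out, window=window, voxel_mask=keep)
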
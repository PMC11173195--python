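"""Synthetic social-concept experiments with known ground truth.

Emulates the study design this package analyses: 36 personality-trait
concepts in a 2x2 (affect x social desirability) factorial, presented once
per run in a jittered event-related design (8 runs, TR 0.85 s, 537 volumes,
2.4 mm voxels), plus sentence-embedding matrices (21 tokens x 768 = 16 128
features) and 0-100 behavioral ratings.  Every generated dataset carries a
manifest of its ground truth (ROI voxels, class patterns, effect scale) so
downstream decoding, RSA and group inference can be tested as recovery
problems rather than against unavailable scanner data.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical seed and configuration give
bit-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import gamma as gamma_dist

from .volume import BoldRun, VolumeGrid, default_grid

__all__ = [
    "AFFECT_LEVELS",
    "DESIRABILITY_LEVELS",
    "TrialTiming",
    "RoiPattern",
    "SignalSpec",
    "EmbeddingMatrix",
    "make_concept_set",
    "default_iti_spec",
    "draw_itis",
    "make_event_schedule",
    "required_volumes",
    "double_gamma_hrf",
    "simulate_bold",
    "make_signal_spec",
    "simulate_embeddings",
    "simulate_ratings",
    "simulate_subject",
]

AFFECT_LEVELS = ("high", "low")
DESIRABILITY_LEVELS = ("high", "low")

N_CONCEPTS = 36
PER_CELL = 9


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

def make_concept_set(seed: int = 0) -> pd.DataFrame:
    """36 concepts, 9 per (affect x desirability) cell, placeholder text.

    Columns: concept_id (0-35), affect, desirability, definition.  The
    concept-to-cell assignment is fixed (blocks of 9); the seed only
    shuffles nothing here and is kept for interface symmetry.
    """
    rows = []
    cid = 0
    for aff in AFFECT_LEVELS:
        for des in DESIRABILITY_LEVELS:
            for i in range(PER_CELL):
                rows.append(
                    {
                        "concept_id": cid,
                        "affect": aff,
                        "desirability": des,
                        "definition": f"synthetic definition {cid} "
                        f"({aff}-affect, {des}-desirability, exemplar {i})",
                    }
                )
                cid += 1
    df = pd.DataFrame(rows)
    _validate_concept_set(df)
    return df


def _validate_concept_set(df: pd.DataFrame) -> None:
    if len(df) != N_CONCEPTS or df["concept_id"].nunique() != N_CONCEPTS:
        raise ValueError("concept set must contain 36 unique concepts")
    cells = df.groupby(["affect", "desirability"]).size()
    if len(cells) != 4 or not (cells == PER_CELL).all():
        raise ValueError("concept set must have 9 concepts per 2x2 cell")


@dataclass(frozen=True)
class TrialTiming:
    """Within-trial timing, seconds.

    A trial is 0.25 s fixation + 0.5 s blank + 3.5 s audio definition +
    2.0 s mental simulation.  Event onsets refer to AUDIO onset and event
    duration to the audio stimulus; the jittered 6-8 s intertrial interval
    runs from audio offset to the next trial's audio onset, so the 2.0 s
    simulation and the next trial's fixation/blank fall inside it.
    """

    fixation_s: float = 0.25
    blank_s: float = 0.5
    audio_s: float = 3.5
    simulation_s: float = 2.0

    @property
    def stimulus_s(self) -> float:
        return self.audio_s


def default_iti_spec() -> dict[float, float]:
    """Pseudo-exponential jitter: mass halves per 0.5 s step from 6 s.

    50% at 6.0 s, 25% at 6.5 s, 12.5% at 7.0 s, 6.25% at 7.5 s; the
    remaining 6.25% goes to the final 8.0 s bin so the distribution sums
    to one over the stated 6-8 s range.
    """
    return {6.0: 0.5, 6.5: 0.25, 7.0: 0.125, 7.5: 0.0625, 8.0: 0.0625}


def draw_itis(
    n: int,
    iti_spec: dict[float, float] | None = None,
    seed: int | np.random.Generator = 0,
    mode: str = "sampled",
) -> np.ndarray:
    """Draw ``n`` intertrial intervals from a discrete jitter distribution.

    mode="sampled": i.i.d. draws.  mode="deterministic": largest-remainder
    allocation of exact counts (shuffled order), so empirical proportions
    match the spec as closely as integer counts allow.
    """
    spec = default_iti_spec() if iti_spec is None else dict(iti_spec)
    values = np.array(sorted(spec))
    probs = np.array([spec[v] for v in values], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("ITI probabilities must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "sampled":
        return rng.choice(values, size=n, p=probs)
    if mode == "deterministic":
        ideal = probs * n
        counts = np.floor(ideal).astype(int)
        rem = ideal - counts
        # hand out leftover trials to the largest fractional remainders
        for idx in np.argsort(-rem)[: n - counts.sum()]:
            counts[idx] += 1
        itis = np.repeat(values, counts)
        rng.shuffle(itis)
        return itis
    raise ValueError(f"unknown ITI mode {mode!r}")


def make_event_schedule(
    concept_set: pd.DataFrame,
    n_runs: int = 8,
    timing: TrialTiming | None = None,
    iti_spec: dict[float, float] | None = None,
    seed: int = 0,
    first_onset: float = 12.0,
    run_duration: float | None = None,
    iti_mode: str = "sampled",
) -> list[pd.DataFrame]:
    """One event table per run; every concept once per run, random order.

    Columns: onset, duration, trial_type, concept_id, affect, desirability,
    run_id.  Onset is audio onset (seconds from run start), duration the
    3.5 s stimulus.  If ``run_duration`` is given, a schedule whose last
    trial (plus the 10.5 s post-onset analysis window) would overrun it is
    refused with a diagnostic.
    """
    _validate_concept_set(concept_set)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    timing = timing or TrialTiming()
    rng = np.random.default_rng(seed)
    runs = []
    for run_id in range(n_runs):
        order = rng.permutation(len(concept_set))
        itis = draw_itis(len(concept_set) - 1, iti_spec, rng, mode=iti_mode)
        onsets = first_onset + np.concatenate(
            [[0.0], np.cumsum(timing.stimulus_s + itis)]
        )
        if run_duration is not None:
            t_end = onsets[-1] + 10.5
            if t_end > run_duration:
                raise ValueError(
                    f"run {run_id}: schedule needs {t_end:.1f} s "
                    f"(last onset {onsets[-1]:.1f} s + 10.5 s window) but the "
                    f"run lasts {run_duration:.1f} s; reduce trials or ITIs"
                )
        sub = concept_set.iloc[order].reset_index(drop=True)
        runs.append(
            pd.DataFrame(
                {
                    "onset": onsets,
                    "duration": timing.stimulus_s,
                    "trial_type": sub["affect"] + "_" + sub["desirability"],
                    "concept_id": sub["concept_id"].to_numpy(),
                    "affect": sub["affect"].to_numpy(),
                    "desirability": sub["desirability"].to_numpy(),
                    "run_id": run_id,
                }
            )
        )
    return runs


def required_volumes(events: pd.DataFrame, tr: float, tail_s: float = 12.0) -> int:
    """Smallest volume count covering the last trial plus analysis window."""
    t_end = float(events["onset"].max()) + 10.5 + tail_s
    return int(np.ceil(t_end / tr))


# --------------------------------------------------------------------------
# BOLD synthesis
# --------------------------------------------------------------------------

def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak.

    Positive gamma peaking at ~6 s minus an undershoot peaking at ~16 s with
    one sixth the amplitude — the standard parameterization used across
    neuroimaging GLM software.
    """
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    h = h - gamma_dist.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp) / undershoot_ratio
    h[t < 0] = 0.0
    m = h.max()
    return h / m if m > 0 else h


@dataclass
class RoiPattern:
    """Ground-truth multivoxel patterns for one region.

    ``voxel_ijk`` are the region's voxel coordinates; ``patterns`` holds one
    amplitude vector per concept (36 x n_roi_voxels) so any labeling of the
    36 concepts (binary class or full concept identity) is recoverable.
    """

    name: str
    voxel_ijk: np.ndarray  # (k, 3) int
    patterns: np.ndarray  # (36, k) float
    dimension: str = ""  # which factor the class structure follows, if any

    def __post_init__(self) -> None:
        self.voxel_ijk = np.asarray(self.voxel_ijk, dtype=int)
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.shape != (N_CONCEPTS, len(self.voxel_ijk)):
            raise ValueError("patterns must be (36, n_roi_voxels)")


@dataclass
class SignalSpec:
    """Everything that turns a schedule into signal: ROIs, noise, drift."""

    rois: list[RoiPattern] = field(default_factory=list)
    effect_scale: float = 1.0
    noise_sd: float = 1.0
    drift_amplitude: float = 0.0  # peak-to-peak linear drift over the run
    baseline: float = 100.0
    smoothing_fwhm_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.effect_scale < 0 or self.noise_sd < 0:
            raise ValueError("effect_scale and noise_sd must be >= 0")

    def manifest(self) -> dict:
        return {
            "effect_scale": self.effect_scale,
            "noise_sd": self.noise_sd,
            "drift_amplitude": self.drift_amplitude,
            "baseline": self.baseline,
            "smoothing_fwhm_mm": self.smoothing_fwhm_mm,
            "rois": [
                {
                    "name": r.name,
                    "dimension": r.dimension,
                    "voxel_ijk": r.voxel_ijk.tolist(),
                }
                for r in self.rois
            ],
        }

    def save_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.manifest(), indent=1))
        return path


def _ball_voxels(grid: VolumeGrid, center_ijk: np.ndarray, radius_mm: float) -> np.ndarray:
    """In-mask voxels within ``radius_mm`` of a voxel center (mm distance)."""
    ijk = grid.mask_indices()
    d = np.linalg.norm(grid.voxels_to_mm(ijk) - grid.voxels_to_mm(center_ijk), axis=1)
    return ijk[d <= radius_mm]


def make_signal_spec(
    grid: VolumeGrid,
    concept_set: pd.DataFrame,
    seed: int = 0,
    effect_scale: float = 1.0,
    noise_sd: float = 1.0,
    drift_amplitude: float = 0.0,
    smoothing_fwhm_mm: float = 0.0,
    roi_radius_mm: float = 6.0,
    concept_sd: float = 0.25,
    embeddings: "EmbeddingMatrix | None" = None,
    n_rsa_voxels_from_embedding: int = 40,
) -> SignalSpec:
    """Default ground truth: one ROI per factor, optionally one RSA ROI.

    The affect ROI's concept patterns are a class mean (+v for high, -v for
    low affect) plus concept-specific jitter of relative size ``concept_sd``;
    likewise for desirability at a spatially distinct location.  If an
    embedding matrix is supplied, a third ROI's 36 concept patterns are a
    random linear projection of the embeddings, so searchlight RDMs there
    correlate with the embedding model RDM (RSA/encoding recovery), and the
    feature-to-voxel map is shared by all subjects built from the same spec.
    """
    _validate_concept_set(concept_set)
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid.shape
    c = np.array(grid.shape) / 2.0
    offsets = {
        "affect": np.array([-0.22 * nx, 0.0, 0.0]),
        "desirability": np.array([0.22 * nx, 0.0, 0.0]),
    }
    rois: list[RoiPattern] = []
    for dim, off in offsets.items():
        center = np.round(c + off).astype(int)
        vox = _ball_voxels(grid, center, roi_radius_mm)
        if len(vox) == 0:
            raise ValueError(f"{dim} ROI fell outside the brain mask")
        v = rng.standard_normal(len(vox))
        v /= np.linalg.norm(v) / np.sqrt(len(vox))  # unit RMS amplitude
        sign = np.where(concept_set[dim].to_numpy() == "high", 1.0, -1.0)
        pats = sign[:, None] * v[None, :]
        pats = pats + concept_sd * rng.standard_normal(pats.shape)
        rois.append(RoiPattern(name=f"{dim}_roi", voxel_ijk=vox, patterns=pats, dimension=dim))
    if embeddings is not None:
        center = np.round(c + np.array([0.0, 0.22 * ny, 0.0])).astype(int)
        vox = _ball_voxels(grid, center, roi_radius_mm)
        emb = embeddings.matrix
        emb = (emb - emb.mean(0)) / (emb.std(0) + 1e-12)
        proj = rng.standard_normal((emb.shape[1], min(len(vox), n_rsa_voxels_from_embedding)))
        pats = emb @ proj / np.sqrt(emb.shape[1])
        pats = pats / (np.abs(pats).mean() + 1e-12)
        k = pats.shape[1]
        rois.append(
            RoiPattern(name="rsa_roi", voxel_ijk=vox[:k], patterns=pats, dimension="concept")
        )
    return SignalSpec(
        rois=rois,
        effect_scale=effect_scale,
        noise_sd=noise_sd,
        drift_amplitude=drift_amplitude,
        smoothing_fwhm_mm=smoothing_fwhm_mm,
    )


def simulate_bold(
    events: pd.DataFrame,
    grid: VolumeGrid,
    spec: SignalSpec,
    n_volumes: int = 537,
    tr: float = 0.85,
    seed: int = 0,
    oversample: int = 10,
) -> BoldRun:
    """Baseline + HRF-convolved event signal + drift + Gaussian noise.

    Each event contributes its concept's ROI pattern scaled by
    ``effect_scale`` and by a boxcar (event duration) convolved with the
    double-gamma HRF; the regressor is built on a grid ``oversample`` times
    finer than the TR and sampled at volume onsets (``oversample=1``
    reproduces plain discrete convolution at TR resolution).  Optional
    isotropic Gaussian smoothing is applied volume-wise last.
    """
    run_len = n_volumes * tr
    if float(events["onset"].max()) + float(events["duration"].max()) > run_len:
        raise ValueError(
            f"schedule extends past the run: last trial ends after {run_len:.1f} s"
        )
    for roi in spec.rois:
        if not grid.mask[tuple(roi.voxel_ijk.T)].all():
            raise ValueError(f"ROI {roi.name!r} has voxels outside the brain mask")
    rng = np.random.default_rng(seed)
    dt = tr / oversample
    hires_n = n_volumes * oversample
    hrf = double_gamma_hrf(np.arange(0, 32.0, dt))
    vol_idx = np.arange(n_volumes) * oversample  # sample at volume onsets

    # per-concept regressor: concepts occurring in this run
    data = np.zeros((*grid.shape, n_volumes))
    run_id = int(events["run_id"].iloc[0]) if "run_id" in events else 0
    for concept_id, ev in events.groupby("concept_id"):
        box = np.zeros(hires_n)
        for _, row in ev.iterrows():
            i0 = int(round(row["onset"] / dt))
            i1 = int(round((row["onset"] + row["duration"]) / dt))
            box[i0 : max(i1, i0 + 1)] = 1.0
        reg = np.convolve(box, hrf)[:hires_n][vol_idx]
        for roi in spec.rois:
            amp = spec.effect_scale * roi.patterns[int(concept_id)]
            xs, ys, zs = roi.voxel_ijk.T
            data[xs, ys, zs, :] += amp[:, None] * reg[None, :]

    data += spec.baseline
    if spec.drift_amplitude:
        drift = spec.drift_amplitude * (np.linspace(0, 1, n_volumes) - 0.5)
        data += drift
    if spec.noise_sd:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    if spec.smoothing_fwhm_mm:
        sigma_mm = spec.smoothing_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        spacing = np.abs(np.diag(grid.affine)[:3])
        sig = sigma_mm / spacing
        for t in range(n_volumes):
            data[..., t] = gaussian_filter(data[..., t], sigma=sig)
    data[~grid.mask, :] = 0.0
    return BoldRun(run_id=run_id, data=data, tr=tr, grid=grid)


def simulate_subject(
    concept_set: pd.DataFrame,
    grid: VolumeGrid | None = None,
    spec: SignalSpec | None = None,
    n_runs: int = 8,
    n_volumes: int | None = None,
    tr: float = 0.85,
    seed: int = 0,
) -> tuple[list[BoldRun], list[pd.DataFrame]]:
    """Schedule + BOLD for one subject; returns (runs, event tables)."""
    grid = grid or default_grid()
    spec = spec or make_signal_spec(grid, concept_set, seed=seed)
    schedule = make_event_schedule(concept_set, n_runs=n_runs, seed=seed)
    if n_volumes is None:
        n_volumes = max(required_volumes(ev, tr) for ev in schedule)
    runs = [
        simulate_bold(ev, grid, spec, n_volumes=n_volumes, tr=tr, seed=seed * 1000 + r)
        for r, ev in enumerate(schedule)
    ]
    return runs, schedule


# --------------------------------------------------------------------------
# sentence embeddings
# --------------------------------------------------------------------------

@dataclass
class EmbeddingMatrix:
    """Flattened per-sentence token features, zero-padded to max_tokens.

    ``matrix`` is 36 x (max_tokens * width); row i holds sentence i's
    token states concatenated in order, with positions beyond
    ``token_counts[i] * width`` exactly zero.
    """

    matrix: np.ndarray
    token_counts: np.ndarray
    max_tokens: int = 21
    width: int = 768
    padding: str = "zero"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.token_counts = np.asarray(self.token_counts, dtype=int)
        if self.matrix.shape[1] != self.max_tokens * self.width:
            raise ValueError("row length must equal max_tokens * width")
        for i, c in enumerate(self.token_counts):
            if c > self.max_tokens:
                raise ValueError(f"sentence {i} has {c} tokens > max {self.max_tokens}")
            if np.any(self.matrix[i, c * self.width :] != 0.0):
                raise ValueError(f"sentence {i}: padded tail is not zero")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.matrix).to_csv(path, sep="\t", header=False, index=False)
        meta = {
            "max_tokens": self.max_tokens,
            "width": self.width,
            "padding": self.padding,
            "token_counts": self.token_counts.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(meta))
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EmbeddingMatrix":
        path = Path(path)
        mat = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            matrix=mat,
            token_counts=np.array(meta["token_counts"]),
            max_tokens=meta["max_tokens"],
            width=meta["width"],
            padding=meta.get("padding", "zero"),
        )


def simulate_embeddings(
    concept_set: pd.DataFrame,
    max_tokens: int = 21,
    width: int = 768,
    class_effect: float = 0.0,
    seed: int = 0,
    min_tokens: int = 5,
) -> EmbeddingMatrix:
    """Gaussian token features plus class-dependent mean shifts.

    Per sentence: ``k`` tokens (k uniform on [min_tokens, max_tokens]) of
    N(0, 1) features; each binary factor (affect, desirability) adds a shift
    of magnitude ``class_effect`` along its own random unit direction in the
    token-feature space (+ for high, - for low), applied to every real
    token.  Tails beyond the token count are exactly zero.
    """
    if max_tokens < 1 or width < 1:
        raise ValueError("max_tokens and width must be >= 1")
    _validate_concept_set(concept_set)
    rng = np.random.default_rng(seed)
    dirs = {}
    for dim in ("affect", "desirability"):
        u = rng.standard_normal(width)
        dirs[dim] = u / np.linalg.norm(u)
    lo = min(min_tokens, max_tokens)
    counts = rng.integers(lo, max_tokens + 1, size=N_CONCEPTS)
    mat = np.zeros((N_CONCEPTS, max_tokens * width))
    for i in range(N_CONCEPTS):
        k = int(counts[i])
        tok = rng.standard_normal((k, width))
        for dim in ("affect", "desirability"):
            sgn = 1.0 if concept_set[dim].iloc[i] == "high" else -1.0
            tok += sgn * class_effect * dirs[dim] / 2.0
        mat[i, : k * width] = tok.ravel()
    return EmbeddingMatrix(matrix=mat, token_counts=counts, max_tokens=max_tokens, width=width)


# --------------------------------------------------------------------------
# behavioral ratings
# --------------------------------------------------------------------------

DEFAULT_CELL_MEANS = {
    # rated dimension -> concept level on that dimension -> mean rating
    "affect": {"high": 68.5, "low": 45.8},
    "desirability": {"high": 84.5, "low": 15.4},
}


def simulate_ratings(
    concept_set: pd.DataFrame,
    n_subjects: int = 30,
    mean_by_cell: dict | None = None,
    between_subject_sd: float = 8.0,
    noise_sd: float = 6.0,
    seed: int = 0,
) -> pd.DataFrame:
    """0-100 ratings, pre and post sessions sharing true scores.

    Long format: subject_id, concept_id, dimension, session, rating.  The
    true score of (subject, concept, dimension) is the cell mean plus a
    N(0, between_subject_sd) offset shared by both sessions; each session
    adds independent N(0, noise_sd) measurement noise.  Values are clipped
    to [0, 100]; the number of clipped entries is recorded in
    ``df.attrs["n_clipped"]``.  Test-retest reliability is therefore
    between_subject_sd^2 / (between_subject_sd^2 + noise_sd^2) before
    clipping.
    """
    means = DEFAULT_CELL_MEANS if mean_by_cell is None else mean_by_cell
    for dim in means:
        for v in means[dim].values():
            if not 0 <= v <= 100:
                raise ValueError("cell means must lie within [0, 100]")
    rng = np.random.default_rng(seed)
    rows = []
    n_clipped = 0
    for subj in range(n_subjects):
        for _, con in concept_set.iterrows():
            for dim in ("affect", "desirability"):
                true = means[dim][con[dim]] + rng.normal(0.0, between_subject_sd)
                for session in ("pre", "post"):
                    r = true + rng.normal(0.0, noise_sd)
                    clipped = min(max(r, 0.0), 100.0)
                    n_clipped += clipped != r
                    rows.append(
                        {
                            "subject_id": subj,
                            "concept_id": int(con["concept_id"]),
                            "dimension": dim,
                            "session": session,
                            "rating": clipped,
                        }
                    )
    df = pd.DataFrame(rows)
    df.attrs["n_clipped"] = int(n_clipped)
    if n_clipped:
        warnings.warn(f"{n_clipped} ratings clipped to [0, 100]", stacklevel=2)
    return df


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> Path:
    """BIDS-style events table (onset, duration, trial_type, ...)."""
    path = Path(path)
    events.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
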
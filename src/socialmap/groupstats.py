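"""Group inference: TFCE with sign-flip permutations.

One-sample ("is decoding greater than chance across subjects?") and paired
difference ("is desirability decoded better than affect?") tests over
subject maps.  The observed statistic is the threshold-free cluster
enhancement of the group mean map; the null is the distribution of the
maximum TFCE score under random per-subject sign flips, giving family-wise
corrected p values by the max-statistic argument.

TFCE integrates cluster support across all heights: for voxel v with value
h_v, score(v) = sum over thresholds h = dh, 2dh, ... <= h_v of
e(h)^E * h^H * dh, where e(h) is the extent of the supra-threshold connected
component containing v.  Defaults E = 0.5, H = 2, dh = max/100,
26-connectivity — the standard published parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import StatMap, VolumeGrid

__all__ = ["GroupResult", "tfce", "one_sample_signflip", "paired_difference_inference"]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def tfce(
    data: np.ndarray,
    mask: np.ndarray,
    height_power: float = 2.0,
    extent_power: float = 0.5,
    dh: float | None = None,
    connectivity: int = 26,
    n_steps: int = 100,
) -> np.ndarray:
    """TFCE of a 3D map, one-sided (positive values only).

    ``dh`` defaults to max(map)/n_steps.  Values outside the mask are
    ignored; the returned array is zero outside the mask.
    """
    if dh is not None and dh <= 0:
        raise ValueError("dh must be > 0")
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    work = np.where(mask, np.nan_to_num(data, nan=0.0), 0.0)
    vmax = work.max()
    out = np.zeros_like(work)
    if vmax <= 0:
        return out
    if dh is None:
        dh = vmax / n_steps
    structure = _STRUCTURES[connectivity]
    h = dh
    while h <= vmax + 1e-12:
        supra = work >= h
        lab, n = ndimage.label(supra, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(lab.ravel())
        contrib = (sizes.astype(float) ** extent_power) * (h**height_power) * dh
        contrib[0] = 0.0
        out += contrib[lab]
        h += dh
    return out


@dataclass
class GroupResult:
    """Mean, TFCE, corrected-p maps plus the significant-voxel mask."""

    mean_map: StatMap
    tfce_map: StatMap
    p_map: StatMap
    sig_mask: np.ndarray
    alpha: float
    n_perm: int
    seed: int
    null_max: np.ndarray = field(repr=False, default=None)

    def cluster_table(self) -> list[dict]:
        """Connected significant clusters: peak voxel/mm, extent, min p."""
        lab, n = ndimage.label(self.sig_mask, structure=_STRUCTURES[26])
        grid = self.mean_map.grid
        rows = []
        for c in range(1, n + 1):
            vox = np.argwhere(lab == c)
            vals = self.tfce_map.data[lab == c]
            peak = vox[np.argmax(vals)]
            rows.append(
                {
                    "cluster": c,
                    "extent_voxels": int(len(vox)),
                    "peak_ijk": peak.tolist(),
                    "peak_mm": grid.voxels_to_mm(peak)[0].tolist(),
                    "min_corrected_p": float(self.p_map.data[lab == c].min()),
                }
            )
        return rows


def one_sample_signflip(
    subject_maps: list[StatMap],
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    variance_normalize: bool = False,
    **tfce_kwargs,
) -> GroupResult:
    """One-sided test that the group mean exceeds zero, FWER-corrected.

    Corrected p(v) = (1 + #{perm max-TFCE >= TFCE_obs(v)}) / (1 + n_perm);
    the +1 convention keeps p above zero and the minimum attainable p at
    1/(1+n_perm).  ``variance_normalize`` replaces the mean map with the
    one-sample t map before TFCE (off by default: the difference-from-chance
    maps are fed directly).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(subject_maps) < 2:
        raise ValueError("need at least 2 subject maps")
    grid = subject_maps[0].grid
    for m in subject_maps[1:]:
        if m.grid != grid:
            raise ValueError("all subject maps must share one grid")
    stack = np.stack([np.nan_to_num(m.data, nan=0.0) for m in subject_maps])
    mask = grid.mask

    def group_stat(arr: np.ndarray) -> np.ndarray:
        mean = arr.mean(axis=0)
        if variance_normalize:
            sd = arr.std(axis=0, ddof=1)
            return np.divide(mean, sd / np.sqrt(len(arr)), out=np.zeros_like(mean), where=sd > 0)
        return mean

    obs_tfce = tfce(group_stat(stack), mask, **tfce_kwargs)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=len(stack))
        null_max[p] = tfce(group_stat(stack * signs[:, None, None, None]), mask, **tfce_kwargs).max()
    exceed = (null_max[None, :] >= obs_tfce[mask][:, None]).sum(axis=1)
    p_in = (1.0 + exceed) / (1.0 + n_perm)
    p_map = StatMap.from_masked(p_in, grid, tag="p")
    sig = np.zeros(grid.shape, dtype=bool)
    sig[mask] = p_in < alpha
    mean_map = StatMap(data=np.where(mask, stack.mean(axis=0), np.nan), grid=grid, tag="mean")
    return GroupResult(
        mean_map=mean_map,
        tfce_map=StatMap(data=np.where(mask, obs_tfce, np.nan), grid=grid, tag="tfce"),
        p_map=p_map,
        sig_mask=sig,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
        null_max=null_max,
    )


def paired_difference_inference(
    maps_a: list[StatMap],
    maps_b: list[StatMap],
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    **kwargs,
) -> GroupResult:
    """Test a > b via per-subject difference maps (same subjects, paired)."""
    if len(maps_a) != len(maps_b):
        raise ValueError("paired inference needs matching subject lists")
    diffs = []
    for a, b in zip(maps_a, maps_b):
        if a.grid != b.grid:
            raise ValueError("paired maps must share a grid")
        diffs.append(StatMap(data=a.data - b.data, grid=a.grid, tag="difference"))
    return one_sample_signflip(diffs, n_perm=n_perm, alpha=alpha, seed=seed, **kwargs)
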
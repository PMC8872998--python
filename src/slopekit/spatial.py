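"""Voxelwise one-sample t-test across a stack of per-gene maps, with
BH-FDR thresholding restricted to in-mask voxels."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .enrichment import bh_fdr

__all__ = ["MapStack", "TMapResult", "voxelwise_one_sample_t", "load_map_stack"]


@dataclass
class MapStack:
    """G per-gene maps over a common voxel grid plus a boolean mask."""

    gene_ids: Sequence[str]
    data: np.ndarray  # shape (G, *spatial)
    mask: np.ndarray  # shape (*spatial), bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape[0] != len(self.gene_ids):
            raise ValueError("number of maps does not match number of gene ids")
        if self.data.shape[1:] != self.mask.shape:
            raise ValueError("maps and mask have different spatial shapes")
        in_mask = self.data[:, self.mask]
        if not np.isfinite(in_mask).all():
            raise ValueError("non-finite values inside the mask")

    @property
    def n_maps(self) -> int:
        return self.data.shape[0]


@dataclass
class TMapResult:
    t: np.ndarray
    df: int
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray  # bool, q < threshold
    excluded: np.ndarray  # bool, in-mask voxels with zero across-map SD
    q_threshold: float


def voxelwise_one_sample_t(
    stack: MapStack,
    q_threshold: float = 0.05,
    alternative: str = "two-sided",
    standardize_maps: bool = False,
) -> TMapResult:
    """Per-voxel one-sample t against 0 across maps, df = G-1, FDR in-mask.

    Voxels with zero across-map SD are excluded from testing (flagged in
    ``excluded``, with a warning).  ``standardize_maps`` z-scores each map
    over its in-mask voxels first.  ``alternative`` is ``'two-sided'`` or
    ``'greater'``.  Out-of-mask voxels carry NaN.
    """
    if stack.n_maps < 3:
        raise ValueError("need at least 3 maps for a one-sample t-test")
    mask = stack.mask
    vals = stack.data[:, mask].astype(float)  # G x V
    if standardize_maps:
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError("cannot standardize a constant map")
        vals = (vals - mu) / sd
    g = vals.shape[0]
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    valid = sd > 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} in-mask voxel(s) have zero across-map SD; excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    df = g - 1
    t_flat = np.full(mask.sum(), np.nan)
    t_flat[valid] = mean[valid] / (sd[valid] / np.sqrt(g))
    if alternative == "two-sided":
        p_flat_valid = 2.0 * stats.t.sf(np.abs(t_flat[valid]), df)
    elif alternative == "greater":
        p_flat_valid = stats.t.sf(t_flat[valid], df)
    else:
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    p_flat = np.full_like(t_flat, np.nan)
    p_flat[valid] = p_flat_valid
    q_flat = np.full_like(t_flat, np.nan)
    q_flat[valid] = bh_fdr(p_flat_valid)

    def unflatten(flat: np.ndarray, fill=np.nan) -> np.ndarray:
        out = np.full(mask.shape, fill, dtype=float)
        out[mask] = flat
        return out

    sig = np.zeros(mask.shape, dtype=bool)
    sig[mask] = np.where(valid, q_flat < q_threshold, False)
    excluded = np.zeros(mask.shape, dtype=bool)
    excluded[mask] = ~valid
    return TMapResult(
        t=unflatten(t_flat),
        df=df,
        p=unflatten(p_flat),
        q=unflatten(q_flat),
        significant=sig,
        excluded=excluded,
        q_threshold=q_threshold,
    )


def load_map_stack(map_dir: str, mask_path: str) -> MapStack:
    """Load a stack from a directory of NIfTI volumes plus a mask volume."""
    import nibabel as nib

    paths = sorted(Path(map_dir).glob("*.nii*"))
    if not paths:
        raise ValueError(f"no NIfTI volumes found in {map_dir}")
    mask = np.asanyarray(nib.load(mask_path).dataobj) > 0
    data = np.stack([np.asanyarray(nib.load(p).dataobj, dtype=float) for p in paths])
    return MapStack([p.name.split(".")[0] for p in paths], data, mask)
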
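"""Voxel-level fractional anisotropy reduced to per-ROI means.

Only voxels with FA strictly greater than the threshold (default 0.2)
enter the mean — the strict inequality is deliberate.  An ROI with no
qualifying voxel is kept with ``mean_fa = NaN`` and ``n_voxels_used = 0``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["FA_THRESHOLD", "roi_mean_fa", "roi_mean_fa_from_nifti"]

FA_THRESHOLD = 0.2


def roi_mean_fa(fa_voxels, roi_labels, threshold: float = FA_THRESHOLD) -> pd.DataFrame:
    """Mean FA per ROI over voxels with ``FA > threshold``.

    Parameters
    ----------
    fa_voxels, roi_labels
        Parallel arrays: FA value in [0, 1] and ROI label per voxel.
    threshold
        Strict lower bound for a voxel to qualify.

    Returns a DataFrame with columns ``roi``, ``mean_fa``,
    ``n_voxels_used`` (one row per ROI present in the labels, in first
    appearance order).
    """
    fa = np.asarray(fa_voxels, dtype=float)
    labels = np.asarray(roi_labels)
    if fa.shape != labels.shape:
        raise ValueError("fa_voxels and roi_labels must have equal length")
    bad = (fa < 0.0) | (fa > 1.0)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} voxel(s) have FA outside [0, 1]")
    rows = []
    for roi in dict.fromkeys(labels.tolist()):
        vals = fa[(labels == roi) & (fa > threshold)]
        rows.append({
            "roi": roi,
            "mean_fa": float(vals.mean()) if vals.size else float("nan"),
            "n_voxels_used": int(vals.size),
        })
    return pd.DataFrame(rows, columns=["roi", "mean_fa", "n_voxels_used"])


def roi_mean_fa_from_nifti(fa_path, label_path, label_names: dict | None = None,
                           threshold: float = FA_THRESHOLD) -> pd.DataFrame:
    """Optional NIfTI adapter: FA volume + integer ROI-label volume.

    ``label_names`` maps integer label -> ROI name; label 0 is background
    and is skipped.  Requires :mod:`nibabel`.
    """
    import nibabel as nib

    fa_img = np.asarray(nib.load(str(fa_path)).dataobj, dtype=float)
    lab_img = np.asarray(nib.load(str(label_path)).dataobj)
    if fa_img.shape != lab_img.shape:
        raise ValueError("FA and label volumes have different shapes")
    mask = lab_img != 0
    labels = lab_img[mask].astype(int)
    if label_names:
        named = np.array([label_names.get(int(v), f"roi_{int(v)}")
                          for v in labels])
    else:
        named = np.array([f"roi_{int(v)}" for v in labels])
    return roi_mean_fa(fa_img[mask], named, threshold)
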
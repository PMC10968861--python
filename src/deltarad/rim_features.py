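"""Radial intensity mean (RIM) shell features.

The lesion mask is peeled one voxel layer at a time by iterated 3D binary
erosion; shell k is the set difference between the k-th and (k+1)-th eroded
masks, so the shells partition the ROI from its outer envelope (shell 0) to
its core.  Six statistics are recorded per shell: min, mean, SD and max of
intensity, voxel count (with its volume in ml) and the intensity sum.

Erosion uses the 6-connected (face-adjacency) structuring element by
default so each peeled layer is one voxel of face thickness; 26-connectivity
is available.  Feature vectors are emitted under two indexings — from the
outermost shell inwards (``RIM_*``) and from the innermost shell outwards
(``RIMcore_*``) — because core-anchored names stay comparable across lesions
of different depth.  Lesions with fewer shells than the fixed feature length
are padded with missing values (mean-imputed downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_core import EmptyROIError

SHELL_STATS = ("min", "mean", "std", "max", "count", "volume_ml", "sum")


def peel_shells(mask: np.ndarray, connectivity: int = 1) -> list[np.ndarray]:
    """Successive one-voxel erosion shells, outermost first.

    ``connectivity`` 1 = 6-connected faces (default), 3 = 26-connected.
    The returned boolean shells are disjoint and their union is the mask.
    """
    m = np.asarray(mask) > 0
    if not m.any():
        raise EmptyROIError("peel_shells on empty mask")
    structure = ndimage.generate_binary_structure(3, connectivity)
    shells = []
    current = m
    while current.any():
        inner = ndimage.binary_erosion(current, structure=structure, border_value=0)
        shells.append(current & ~inner)
        current = inner
    return shells


@dataclass
class ShellProfile:
    """Ordered per-shell statistics; row 0 is the outermost shell."""

    table: pd.DataFrame  # columns SHELL_STATS, one row per shell

    @property
    def n_shells(self) -> int:
        return len(self.table)


def shell_statistics(
    intensities: np.ndarray, shells: list[np.ndarray], spacing: tuple[float, float, float]
) -> ShellProfile:
    img = np.asarray(intensities, dtype=float)
    voxel_ml = float(np.prod(spacing)) / 1000.0
    rows = []
    for sh in shells:
        vals = img[sh]
        rows.append(
            {
                "min": float(vals.min()),
                "mean": float(vals.mean()),
                "std": float(vals.std()),
                "max": float(vals.max()),
                "count": float(vals.size),
                "volume_ml": vals.size * voxel_ml,
                "sum": float(vals.sum()),
            }
        )
    return ShellProfile(pd.DataFrame(rows, columns=list(SHELL_STATS)))


def rim_feature_vector(profile: ShellProfile, k_fixed: int = 6, prefix: str = "RIM") -> pd.Series:
    """Named shell features under outer- and core-based indexing.

    ``{prefix}_{stat}_{k}`` counts shells from the outside (k = 0 is the
    envelope); ``{prefix}core_{stat}_{k}`` counts from the innermost shell.
    Profiles shorter than ``k_fixed`` yield NaN for the missing shells;
    longer profiles are truncated.
    """
    tab = profile.table
    out: dict[str, float] = {}
    for k in range(k_fixed):
        for stat in SHELL_STATS:
            out[f"{prefix}_{stat}_{k}"] = float(tab.iloc[k][stat]) if k < len(tab) else np.nan
    inner = tab.iloc[::-1].reset_index(drop=True)  # row 0 = innermost
    for k in range(k_fixed):
        for stat in SHELL_STATS:
            out[f"{prefix}core_{stat}_{k}"] = float(inner.iloc[k][stat]) if k < len(inner) else np.nan
    return pd.Series(out)


def extract_rim_features(
    pet: np.ndarray,
    ct: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    k_fixed: int = 6,
    connectivity: int = 1,
) -> pd.Series:
    """PET- and CT-prefixed RIM features for one scan pair."""
    shells = peel_shells(mask, connectivity=connectivity)
    parts = []
    for prefix, img in (("PET_RIM", pet), ("CT_RIM", ct)):
        profile = shell_statistics(img, shells, spacing)
        parts.append(rim_feature_vector(profile, k_fixed=k_fixed, prefix=prefix))
    return pd.concat(parts)
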
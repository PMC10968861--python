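"""Single-time-point radiomic features from one PET/CT scan pair.

First-order SUV/HU statistics (max, mean, metabolic tumor volume, total
lesion glycolysis, intensity entropy), the cumulative SUV-volume histogram
area (AUC-CSH), tumor dissemination (Dmax), and two texture families on
discretized intensities: the grey-level run-length matrix (GLRLM,
non-uniformity features) and the neighbourhood grey-tone difference matrix
(NGTDM, Amadasun-style busyness/coarseness/complexity/contrast/strength).

Discretization uses a fixed bin width per modality (0.3125 SUV for PET,
10 HU for CT) with a capped number of grey levels (64 for PET, 400 for CT);
the anchor of the first bin is the ROI minimum by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_core import EmptyROIError, ScanPair

#: guard value for NGTDM coarseness on homogeneous ROIs (also its cap)
COARSENESS_GUARD = 1.0e6

#: the 13 unique 3D run directions (one per axis/diagonal pair)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13


@dataclass
class DiscretizationConfig:
    pet_bin_width: float = 0.3125
    pet_levels: int = 64
    ct_bin_width: float = 10.0
    ct_levels: int = 400
    anchor: str = "roi_min"  # or "zero"
    n_csh_thresholds: int = 101

    def __post_init__(self) -> None:
        if self.pet_bin_width <= 0 or self.ct_bin_width <= 0:
            raise ValueError("bin widths must be positive")
        if self.pet_levels < 2 or self.ct_levels < 2:
            raise ValueError("need at least 2 grey levels")
        if self.anchor not in ("roi_min", "zero"):
            raise ValueError(f"unknown anchor {self.anchor!r}")

    def params_for(self, modality: str) -> tuple[float, int]:
        if modality == "pet":
            return self.pet_bin_width, self.pet_levels
        if modality == "ct":
            return self.ct_bin_width, self.ct_levels
        raise ValueError(f"unknown modality {modality!r}")


def discretize(
    intensities: np.ndarray,
    bin_width: float,
    n_levels: int,
    anchor: str = "roi_min",
    roi_values: np.ndarray | None = None,
) -> np.ndarray:
    """Map intensities to integer grey levels 1..n_levels.

    ``level(v) = clip(floor((v - anchor_value) / bin_width) + 1, 1, n_levels)``
    with ``anchor_value`` the ROI minimum (``roi_min``) or 0 (``zero``).
    ``roi_values`` supplies the ROI for the minimum when ``intensities`` spans
    the whole grid.
    """
    vals = np.asarray(intensities, dtype=float)
    if anchor == "roi_min":
        ref = roi_values if roi_values is not None else vals
        if ref.size == 0:
            raise EmptyROIError("cannot anchor discretization on an empty ROI")
        anchor_value = float(np.min(ref))
    else:
        anchor_value = 0.0
    levels = np.floor((vals - anchor_value) / bin_width).astype(np.int64) + 1
    return np.clip(levels, 1, n_levels)


def first_order(
    image: np.ndarray, mask: np.ndarray, spacing: tuple[float, float, float],
    levels: np.ndarray | None = None,
) -> dict[str, float]:
    """Max, mean, volume (ml), TLG and discretized-histogram entropy (bits).

    ``levels`` is the discretized grey-level array used for the entropy
    histogram; when omitted, entropy is reported as NaN.
    """
    m = np.asarray(mask) > 0
    if not m.any():
        raise EmptyROIError("first_order on empty mask")
    vals = np.asarray(image, dtype=float)[m]
    voxel_ml = float(np.prod(spacing)) / 1000.0
    mtv = vals.size * voxel_ml
    mean = float(vals.mean())
    if levels is not None:
        _, counts = np.unique(np.asarray(levels)[m], return_counts=True)
        p = counts / counts.sum()
        entropy = float(-(p * np.log2(p)).sum())
    else:
        entropy = float("nan")
    return {
        "max": float(vals.max()),
        "mean": mean,
        "MTV_ml": mtv,
        "TLG": mean * mtv,
        "entropy": entropy,
    }


def auc_csh(pet: np.ndarray, mask: np.ndarray, n_thresholds: int = 101) -> float:
    """Area under the cumulative SUV-volume histogram.

    ``CSH(t)`` is the fraction of ROI volume with SUV >= ``t * SUVmax`` for
    ``t`` on a uniform grid in [0, 1]; the area is the trapezoidal integral.
    Values near 1 indicate homogeneous uptake, lower values more heterogeneity.
    """
    m = np.asarray(mask) > 0
    if not m.any():
        raise EmptyROIError("auc_csh on empty mask")
    vals = np.asarray(pet, dtype=float)[m]
    vmax = vals.max()
    if vmax <= 0:
        raise ValueError("auc_csh requires SUVmax > 0")
    t = np.linspace(0.0, 1.0, n_thresholds)
    csh = (vals[None, :] >= t[:, None] * vmax).mean(axis=1)
    return float(np.trapezoid(csh, t))


def dmax(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Tumor dissemination: largest centroid-to-centroid distance (mm) between
    26-connected lesion components; 0 for a single component."""
    m = np.asarray(mask) > 0
    if not m.any():
        raise EmptyROIError("dmax on empty mask")
    labels, n = ndimage.label(m, structure=np.ones((3, 3, 3)))
    if n < 2:
        return 0.0
    centroids = np.array(ndimage.center_of_mass(m, labels, range(1, n + 1)))
    centroids = centroids * np.asarray(spacing)
    diffs = centroids[:, None, :] - centroids[None, :, :]
    return float(np.sqrt((diffs**2).sum(-1)).max())


# ---------------------------------------------------------------------------
# GLRLM


def _shift(a: np.ndarray, offset: tuple[int, int, int], fill=0) -> np.ndarray:
    """out[v] = a[v + offset], filled with ``fill`` outside the grid."""
    out = np.full_like(a, fill)
    src, dst = [], []
    for n, o in zip(a.shape, offset):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = a[tuple(src)]
    return out


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray,
                 directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13) -> np.ndarray:
    """Run-length matrix r(i, j): runs of grey level i and length j, summed
    over the given directions.  Out-of-mask voxels break runs.

    Runs are enumerated by boolean shift algebra: a link exists from voxel v
    to v+d when both are in-mask with equal level; run starts are voxels with
    no incoming link, and the remaining chain length is accumulated by
    AND-ing progressively shifted link arrays.
    """
    lv = np.asarray(levels, dtype=np.int64)
    m = np.asarray(mask) > 0
    if not m.any():
        raise EmptyROIError("glrlm on empty mask")
    max_level = int(lv[m].max())
    counts: dict[tuple[int, int], int] = {}
    max_run_seen = 1
    for d in directions:
        link = m & _shift(m, d, False) & (lv == _shift(lv, d, fill=-1))
        start = m & ~_shift(link, tuple(-c for c in d), False)
        # chain[v] = number of consecutive links starting at v
        chain = np.zeros(m.shape, dtype=np.int64)
        prefix = link.copy()
        k = 1
        while prefix.any():
            chain += prefix
            koff = tuple(k * c for c in d)
            prefix &= _shift(link, koff, False)
            k += 1
        run_len = chain[start] + 1
        run_lev = lv[start]
        pairs, cnt = np.unique(np.stack([run_lev, run_len]), axis=1, return_counts=True)
        for (le, ln), c in zip(pairs.T, cnt):
            counts[(int(le), int(ln))] = counts.get((int(le), int(ln)), 0) + int(c)
            max_run_seen = max(max_run_seen, int(ln))
    mat = np.zeros((max_level, max_run_seen), dtype=np.int64)
    for (le, ln), c in counts.items():
        mat[le - 1, ln - 1] = mat[le - 1, ln - 1] + c
    return mat


def glrlm_features(levels: np.ndarray, mask: np.ndarray,
                   directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13) -> dict[str, float]:
    """Grey-level non-uniformity (GLN) and run-length non-uniformity (RLN)."""
    mat = glrlm_matrix(levels, mask, directions)
    n_runs = mat.sum()
    gln = float((mat.sum(axis=1) ** 2).sum() / n_runs)
    rln = float((mat.sum(axis=0) ** 2).sum() / n_runs)
    return {"GLN": gln, "RLN": rln}


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-level (n_i, p_i, s_i) over ROI voxels with >= 1 in-mask neighbour
    in the 26-neighbourhood; returns (n, p, s, N) indexed by level-1."""
    lv = np.asarray(levels, dtype=np.int64)
    m = np.asarray(mask) > 0
    if not m.any():
        raise EmptyROIError("ngtdm on empty mask")
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    msk = m.astype(float)
    nbr_cnt = ndimage.convolve(msk, kernel, mode="constant", cval=0.0)
    nbr_sum = ndimage.convolve(lv * msk, kernel, mode="constant", cval=0.0)
    valid = m & (np.round(nbr_cnt) > 0)
    n_levels = int(lv[m].max())
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    if valid.any():
        abar = nbr_sum[valid] / nbr_cnt[valid]
        vlev = lv[valid]
        diffs = np.abs(vlev - abar)
        for i in range(1, n_levels + 1):
            sel = vlev == i
            n[i - 1] = sel.sum()
            s[i - 1] = diffs[sel].sum()
    total = int(n.sum())
    p = n / total if total else n
    return n, p, s, total


def ngtdm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Amadasun texture features with zero-denominator guards.

    Homogeneous ROIs (all ``s_i = 0``) return coarseness = 1e6 (also used as
    a cap), strength = 0 and contrast = 0; busyness returns 0 when its
    denominator vanishes.
    """
    _, p, s, total = ngtdm_table(levels, mask)
    nz = np.flatnonzero(p > 0)
    lev = nz + 1.0  # grey-level values i with p_i > 0
    pi, si = p[nz], s[nz]
    n_gp = nz.size

    sum_ps = float((pi * si).sum())
    sum_s = float(si.sum())

    coarseness = COARSENESS_GUARD if sum_ps == 0 else min(1.0 / sum_ps, COARSENESS_GUARD)

    if n_gp > 1 and total > 0:
        pij = pi[:, None] * pi[None, :]
        d2 = (lev[:, None] - lev[None, :]) ** 2
        contrast = float((pij * d2).sum()) / (n_gp * (n_gp - 1)) * (sum_s / total)
    else:
        contrast = 0.0

    ipi = lev * pi
    busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    busyness = 0.0 if busy_den == 0 else sum_ps / busy_den

    if total > 0 and n_gp > 1:
        dl = np.abs(lev[:, None] - lev[None, :])
        num = pi[:, None] * si[:, None] + pi[None, :] * si[None, :]
        den = pi[:, None] + pi[None, :]
        complexity = float((dl * num / den).sum()) / total
    else:
        complexity = 0.0

    if sum_s == 0:
        strength = 0.0
    else:
        d2 = (lev[:, None] - lev[None, :]) ** 2
        strength = float(((pi[:, None] + pi[None, :]) * d2).sum()) / sum_s

    return {
        "busyness": busyness,
        "coarseness": coarseness,
        "complexity": complexity,
        "contrast": contrast,
        "strength": strength,
    }


# ---------------------------------------------------------------------------
# Full per-scan feature vector


def extract_features(scan: ScanPair, config: DiscretizationConfig | None = None) -> pd.Series:
    """All single-time-point features for one scan, PET- and CT-prefixed."""
    config = config or DiscretizationConfig()
    scan.require_roi()
    m = scan.mask > 0
    out: dict[str, float] = {}

    for modality, image in (("pet", scan.pet), ("ct", scan.ct)):
        width, nlev = config.params_for(modality)
        lv = discretize(image, width, nlev, anchor=config.anchor, roi_values=image[m])
        fo = first_order(image, m, scan.spacing, levels=lv)
        prefix = "PET" if modality == "pet" else "CT"
        if modality == "pet":
            out["PET_SUVmax"] = fo["max"]
            out["PET_SUVmean"] = fo["mean"]
            out["PET_MTV_ml"] = fo["MTV_ml"]
            out["PET_TLG"] = fo["TLG"]
            out["PET_entropy"] = fo["entropy"]
            out["PET_AUC_CSH"] = auc_csh(scan.pet, m, config.n_csh_thresholds)
            out["PET_Dmax_mm"] = dmax(m, scan.spacing)
        else:
            out["CT_HUmax"] = fo["max"]
            out["CT_HUmean"] = fo["mean"]
            out["CT_entropy"] = fo["entropy"]
        for k, v in ngtdm_features(lv, m).items():
            out[f"{prefix}_NGTDM_{k}"] = v
        for k, v in glrlm_features(lv, m).items():
            out[f"{prefix}_GLRLM_{k}"] = v
    return pd.Series(out, name=scan.subject_id)
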
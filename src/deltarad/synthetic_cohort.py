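"""Synthetic two-time-point PET/CT cohort with known ground truth.

The real study cohort (lymphoma patients with paired staging and
end-of-treatment FDG PET/CT) is private, so every downstream stage is
exercised on simulated scans instead.  Each subject receives:

* a baseline scan with one or two spherical lesions whose uptake falls off
  radially as ``peak * (1 - (r/R)**g)`` above a soft-tissue background,
* an end-of-treatment (EoT) scan in which the lesion volume is multiplied by
  a response-dependent shrinkage factor and the radial exponent / peak uptake
  change (treated lesions become smaller, colder and more homogeneous),
* a binary progression label drawn from a logistic model on the latent
  response score (the noise-free relative change in total lesion glycolysis
  plus a heterogeneity-change term),
* a time to progression drawn from a Weibull whose scale shrinks with the
  response score, with optional independent uniform censoring,
* optional per-scanner additive (SUV shift) and multiplicative (noise
  inflation) effects.

Spheres are used because they admit analytic oracles for volume and radial
profiles; an ``irregularity`` knob perturbs the radius directionally to
exercise irregular-shape code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_core import OutcomeRecord, ScanPair


@dataclass
class CohortSpec:
    """Generator parameters; the defaults emulate the study's design.

    Sizes and rates: 31 subjects with both time points, ~24% progression,
    follow-up on the order of five years, two scanners.  Uptake and lesion
    geometry are typical of bulky mediastinal lymphoma on FDG PET (peak SUV
    roughly 8-20, lesion radii 8-20 mm on a 2 mm grid).
    """

    n_subjects: int = 31
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # lesion model
    lesion_count_probs: tuple[float, ...] = (0.8, 0.2)  # P(1 lesion), P(2 lesions)
    radius_range_mm: tuple[float, float] = (8.0, 20.0)
    peak_suv_range: tuple[float, float] = (8.0, 20.0)
    gradient_exponent: float = 1.5
    irregularity: float = 0.0
    background_suv: float = 1.0
    pet_noise_sd: float = 0.2
    tissue_hu: float = 40.0
    lesion_hu_offset: float = 25.0
    ct_noise_sd: float = 10.0
    # response model
    responder_fraction: float = 0.75
    shrinkage_responders: tuple[float, float] = (0.02, 0.15)
    shrinkage_nonresponders: tuple[float, float] = (0.4, 0.9)
    peak_decline_responders: tuple[float, float] = (0.2, 0.4)
    peak_decline_nonresponders: tuple[float, float] = (0.7, 1.0)
    exponent_factor_responders: float = 2.0
    exponent_factor_nonresponders: float = 1.0
    het_weight: float = 0.5
    # outcome model: P(progression) = logistic(beta0 + beta1 * score)
    beta0: float = 2.0
    beta1: float = 4.0
    # TTP ~ Weibull(shape k, scale lambda0 * exp(-score_coef * score)) months
    weibull_shape: float = 1.5
    lambda0_months: float = 40.0
    score_coef: float = 2.0
    censoring_rate: float = 0.3
    max_followup_months: float = 60.0
    # scanner model
    scanner_ids: tuple[str, str] = ("D690", "D600")
    scanner_probs: tuple[float, float] = (0.5, 0.5)
    scanner_additive_suv: dict = field(default_factory=dict)
    scanner_noise_inflation: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if abs(sum(self.lesion_count_probs) - 1) > 1e-9 or abs(sum(self.scanner_probs) - 1) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        min_vox = self.radius_range_mm[0] / max(self.spacing)
        if min_vox < 2:
            raise ValueError("minimum lesion radius must be >= 2 voxels")


class GroundTruth(NamedTuple):
    """Per-subject latent quantities, reproducible from the seed."""

    table: pd.DataFrame  # score, prob, responder, shrinkage, radii, ttp params


class CohortSample(NamedTuple):
    scans: list[tuple[ScanPair, ScanPair]]  # (baseline, eot) per subject
    outcomes: list[OutcomeRecord]
    ground_truth: GroundTruth


def _sphere_volume(
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: np.ndarray,
    radius_mm: float,
    peak: float,
    exponent: float,
    irregularity: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free lesion uptake above background and its boolean support."""
    coords = [np.arange(n) * s for n, s in zip(grid_shape, spacing)]
    dx = coords[0][:, None, None] - center_mm[0]
    dy = coords[1][None, :, None] - center_mm[1]
    dz = coords[2][None, None, :] - center_mm[2]
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    if irregularity:
        theta = np.arctan2(np.sqrt(dx**2 + dy**2), dz + 1e-12)
        phi = np.arctan2(dy, dx + 1e-12)
        r_eff = radius_mm * (1.0 + irregularity * np.sin(2 * theta) * np.cos(2 * phi))
    else:
        r_eff = radius_mm
    inside = r <= r_eff
    frac = np.zeros_like(r)
    frac[inside] = 1.0 - (r[inside] / np.maximum(r_eff if np.isscalar(r_eff) else r_eff[inside], 1e-12)) ** exponent
    return peak * frac, inside


def _lesion_centers(
    n_lesions: int, grid_shape: tuple[int, int, int], spacing: tuple[float, float, float],
    radius_mm: float, rng: np.random.Generator,
) -> list[np.ndarray]:
    extent = np.array(grid_shape) * np.array(spacing)
    margin = radius_mm * 1.3 + max(spacing)
    if np.any(extent / 2 < margin):
        raise ValueError(f"lesion of radius {radius_mm} mm does not fit in grid of extent {extent} mm")
    centers = [extent / 2]
    if n_lesions == 2:
        # second smaller lesion offset along x, kept inside the grid
        offset = np.array([min(2.5 * radius_mm, extent[0] / 2 - margin), 0.0, 0.0])
        centers = [extent / 2 - offset / 2, extent / 2 + offset / 2]
    return centers


def simulate_cohort(spec: CohortSpec) -> CohortSample:
    """Generate paired baseline/EoT scans, outcomes, and latent ground truth."""
    rng = np.random.default_rng(spec.seed)
    voxel_ml = float(np.prod(spec.spacing)) / 1000.0
    scans: list[tuple[ScanPair, ScanPair]] = []
    outcomes: list[OutcomeRecord] = []
    rows = []

    for i in range(spec.n_subjects):
        sid = f"S{i:03d}"
        n_lesions = int(rng.choice(len(spec.lesion_count_probs), p=spec.lesion_count_probs)) + 1
        radius = float(rng.uniform(*spec.radius_range_mm))
        peak = float(rng.uniform(*spec.peak_suv_range))
        responder = bool(rng.random() < spec.responder_fraction)
        shrink_rng = spec.shrinkage_responders if responder else spec.shrinkage_nonresponders
        shrinkage = float(rng.uniform(*shrink_rng))
        peak_rng = spec.peak_decline_responders if responder else spec.peak_decline_nonresponders
        peak_decline = float(rng.uniform(*peak_rng))
        g_base = spec.gradient_exponent
        g_eot = g_base * (spec.exponent_factor_responders if responder else spec.exponent_factor_nonresponders)

        centers = _lesion_centers(n_lesions, spec.grid_shape, spec.spacing, radius, rng)
        radii = [radius] + [radius * 0.6] * (n_lesions - 1)

        pair = {}
        tlg, cv = {}, {}
        scanners = {}
        for tp, g, pk, rad_scale in (
            ("baseline", g_base, peak, 1.0),
            ("eot", g_eot, peak * peak_decline, shrinkage ** (1.0 / 3.0)),
        ):
            lesion = np.zeros(spec.grid_shape)
            support = np.zeros(spec.grid_shape, dtype=bool)
            for c, rad in zip(centers, radii):
                up, ins = _sphere_volume(
                    spec.grid_shape, spec.spacing, c, rad * rad_scale, pk, g, spec.irregularity
                )
                lesion = np.maximum(lesion, up)
                support |= ins
            clean_pet = spec.background_suv + lesion
            vals = clean_pet[support]
            tlg[tp] = float(vals.mean()) * support.sum() * voxel_ml
            cv[tp] = float(vals.std() / max(vals.mean(), 1e-12))

            scanner = str(rng.choice(spec.scanner_ids, p=spec.scanner_probs))
            scanners[tp] = scanner
            shift = float(spec.scanner_additive_suv.get(scanner, 0.0))
            inflate = float(spec.scanner_noise_inflation.get(scanner, 1.0))
            pet = clean_pet + shift + rng.normal(0.0, spec.pet_noise_sd * inflate, spec.grid_shape)
            pet = np.maximum(pet, 0.0)
            ct = spec.tissue_hu + spec.lesion_hu_offset * support + rng.normal(
                0.0, spec.ct_noise_sd, spec.grid_shape
            )
            pair[tp] = ScanPair(
                subject_id=sid, timepoint=tp, pet=pet, ct=ct,
                mask=support.astype(np.uint8), spacing=spec.spacing, scanner_id=scanner,
            )

        rel_dtlg = (tlg["eot"] - tlg["baseline"]) / tlg["baseline"]
        rel_dcv = (cv["eot"] - cv["baseline"]) / max(cv["baseline"], 1e-12)
        score = rel_dtlg + spec.het_weight * rel_dcv
        prob = 1.0 / (1.0 + np.exp(-(spec.beta0 + spec.beta1 * score)))
        progression = int(rng.random() < prob)

        lam = spec.lambda0_months * np.exp(-spec.score_coef * score)
        t_prog = float(lam * rng.weibull(spec.weibull_shape))
        if spec.censoring_rate > 0 and rng.random() < spec.censoring_rate:
            c_time = float(rng.uniform(0.0, spec.max_followup_months))
        else:
            c_time = np.inf
        event = int(t_prog <= c_time)
        ttp = t_prog if event else c_time

        scans.append((pair["baseline"], pair["eot"]))
        outcomes.append(
            OutcomeRecord(
                subject_id=sid, progression=progression, ttp_months=float(ttp),
                event=event, scanner_id=scanners["eot"],
            )
        )
        rows.append(
            {
                "subject_id": sid, "responder": responder, "shrinkage": shrinkage,
                "radius_mm": radius, "n_lesions": n_lesions, "peak_suv": peak,
                "tlg_baseline": tlg["baseline"], "tlg_eot": tlg["eot"],
                "rel_delta_tlg": rel_dtlg, "rel_delta_cv": rel_dcv,
                "score": score, "prob": prob, "weibull_scale": lam,
                "scanner_baseline": scanners["baseline"], "scanner_eot": scanners["eot"],
            }
        )

    gt = GroundTruth(pd.DataFrame(rows).set_index("subject_id"))
    return CohortSample(scans, outcomes, gt)


class FeatureBatch(NamedTuple):
    features: pd.DataFrame
    labels: np.ndarray
    scanner_ids: np.ndarray


def simulate_feature_batch(
    n: int,
    n_features: int,
    effect_spec: dict | None = None,
    rng: np.random.Generator | int | None = None,
) -> FeatureBatch:
    """Tabular generator: Gaussian features with optional scanner and class effects.

    ``effect_spec`` keys (all optional):

    * ``scanner_shift`` — additive mean shift (in SD units) applied to scanner
      "B" rows, either a scalar (all features) or per-feature array;
    * ``scanner_var_inflation`` — multiplicative SD factor on scanner "B";
    * ``class_effect`` — Cohen's d separating class 1 from class 0;
    * ``n_informative`` — number of leading features carrying the class effect;
    * ``class_balance`` — P(label = 1), default 0.5.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    spec = effect_spec or {}
    rng = np.random.default_rng(rng)
    y = (rng.random(n) < spec.get("class_balance", 0.5)).astype(int)
    scanner = np.where(rng.random(n) < 0.5, "A", "B")
    X = rng.standard_normal((n, n_features))

    shift = np.asarray(spec.get("scanner_shift", 0.0), dtype=float)
    inflate = float(spec.get("scanner_var_inflation", 1.0))
    b = scanner == "B"
    if inflate != 1.0:
        X[b] *= inflate  # noise inflation, applied before any class effect
    X[b] += shift

    d = spec.get("class_effect", 0.0)
    k = int(spec.get("n_informative", 0))
    if d and k:
        X[:, :k] += d * y[:, None]

    cols = [f"f{j:03d}" for j in range(n_features)]
    idx = [f"S{i:03d}" for i in range(n)]
    return FeatureBatch(pd.DataFrame(X, index=idx, columns=cols), y, scanner)
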
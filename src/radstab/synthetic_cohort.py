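"""Synthetic CT lesion cohorts with simulated inter-rater segmentation noise.

Real multi-rater lesion datasets are scarce; this module generates the two
ingredients a segmentation-robustness analysis needs:

* CT-like 2D lesion images: a star-convex lesion of controllable size,
  boundary irregularity, contrast and intratumoral texture on a noisy
  background, with Gaussian partial-volume blur at the edge. Two presets
  bracket the clinically relevant contrast regimes: a lung nodule on air
  (huge contrast) and an abdominal lesion on soft tissue (low contrast).

* Rater populations: plausible alternative segmentations produced by
  perturbing the signed Euclidean distance field of a mask with a smooth
  random field and re-thresholding. The perturbation amplitude is calibrated
  by bisection so the median pairwise Dice of a rater set matches a target
  (e.g. the 0.87 observed between expert readers on lung nodules), and each
  sample is rejection-filtered against a Dice > 0.3 floor with respect to a
  reference mask, mimicking the acceptance rule used when sampling from a
  probabilistic segmentation network.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label

from .agreement import dice
from .grids import BinaryMask, ImageGrid, save_nifti

__all__ = [
    "LesionSpec", "PerturbationParams", "SyntheticLesionCase",
    "LUNG_PRESET", "ABDOMEN_PRESET", "make_lesion", "perturb_mask",
    "sample_rater_set", "calibrate_amplitude", "make_cohort",
    "default_spec_sampler", "save_cohort", "load_cohort",
]


@dataclass(frozen=True)
class LesionSpec:
    """Geometry, contrast and texture of one synthetic lesion.

    HU values describe CT intensity; lengths are in mm. radius_irregularity
    in [0, 1) modulates the boundary radius with smooth periodic noise,
    turning the disc into a star-convex blob.
    """

    background_hu: float = -800.0
    background_noise_sd: float = 20.0
    lesion_hu: float = 40.0
    texture_sd: float = 30.0
    texture_corr_len: float = 2.0
    edge_blur_sigma: float = 0.7
    radius_mean: float = 10.0
    radius_irregularity: float = 0.25
    image_size: int = 64
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be positive")
        if not (0 <= self.radius_irregularity < 1):
            raise ValueError("radius_irregularity must be in [0, 1)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


# Lung nodule on aerated parenchyma: lesion/background contrast ~ 840 HU.
LUNG_PRESET = LesionSpec()

# Abdominal (kidney/liver) lesion on soft tissue: contrast ~ 45 HU.
ABDOMEN_PRESET = LesionSpec(
    background_hu=45.0, background_noise_sd=12.0, lesion_hu=90.0,
    texture_sd=18.0, texture_corr_len=3.0, edge_blur_sigma=1.0)


@dataclass(frozen=True)
class PerturbationParams:
    """Boundary-perturbation and acceptance settings for rater simulation.

    amplitude        : mm standard deviation of the boundary displacement field.
    corr_len         : mm correlation length (smoothness) of that field.
    accept_threshold : Dice floor for rejection sampling; a draw is kept only
                       if its Dice with a reference mask strictly exceeds it.
    max_attempts     : draws tried per accepted sample before giving up.
    min_volume_mm3   : volume floor (1 mm extrusion) a draw must keep so the
                       downstream eligibility filter cannot reject it;
                       set to 0 to disable.
    """

    amplitude: float = 1.0
    corr_len: float = 4.0
    accept_threshold: float = 0.3
    max_attempts: int = 50
    min_volume_mm3: float = 30.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not (0 <= self.accept_threshold < 1):
            raise ValueError("accept_threshold must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticLesionCase:
    """One lesion: image, ground-truth mask and its simulated rater masks."""

    lesion_id: str
    image: ImageGrid
    truth_mask: BinaryMask
    expert_masks: tuple[BinaryMask, ...]
    sample_masks: tuple[BinaryMask, ...]
    seed: int


def _smooth_periodic_noise(theta: np.ndarray, rng: np.random.Generator,
                           n_harmonics: int = 6) -> np.ndarray:
    """Band-limited periodic field on [0, 2pi), normalised to max |f| = 1."""
    f = np.zeros_like(theta)
    amps = rng.normal(size=n_harmonics) / np.arange(1, n_harmonics + 1)
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
    for m, (a, p) in enumerate(zip(amps, phases), start=2):
        f += a * np.cos(m * theta + p)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def make_lesion(spec: LesionSpec, seed: int) -> tuple[ImageGrid, BinaryMask]:
    """Render one lesion image and its ground-truth mask.

    The mask is star-convex: boundary radius r(theta) = radius_mean *
    (1 + radius_irregularity * f(theta)) with f a smooth periodic field.
    Lesion pixels carry correlated Gaussian texture, the background white
    noise, and the transition is blurred by edge_blur_sigma to mimic the
    partial-volume effect. Identical (spec, seed) gives identical output.
    """
    rng = np.random.default_rng(seed)
    n = spec.image_size
    sp = spec.spacing
    r_max = spec.radius_mean * (1 + spec.radius_irregularity)
    half_extent_px = min((n / 2 - 2) * sp[0], (n / 2 - 2) * sp[1])
    if r_max > half_extent_px:
        raise ValueError(
            f"lesion radius {r_max:.1f} mm does not fit in a {n} px image "
            f"at spacing {sp} (needs <= {half_extent_px:.1f} mm)")

    centre = ((n - 1) / 2.0, (n - 1) / 2.0)
    rows, cols = np.mgrid[0:n, 0:n]
    dy = (rows - centre[0]) * sp[0]
    dx = (cols - centre[1]) * sp[1]
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    f = _smooth_periodic_noise(theta, rng)
    r_theta = spec.radius_mean * (1 + spec.radius_irregularity * f)
    mask = dist <= r_theta

    bg = spec.background_hu + rng.normal(size=(n, n)) * spec.background_noise_sd
    texture = rng.normal(size=(n, n))
    if spec.texture_sd > 0:
        sig = (spec.texture_corr_len / sp[0], spec.texture_corr_len / sp[1])
        texture = ndimage.gaussian_filter(texture, sig)
        std = texture.std()
        if std > 0:
            texture = texture / std
    lesion = spec.lesion_hu + spec.texture_sd * texture

    if spec.edge_blur_sigma > 0:
        sig = (spec.edge_blur_sigma / sp[0], spec.edge_blur_sigma / sp[1])
        alpha = ndimage.gaussian_filter(mask.astype(np.float64), sig)
    else:
        alpha = mask.astype(np.float64)
    img = alpha * lesion + (1 - alpha) * bg
    return ImageGrid(img, sp), BinaryMask(mask, sp)


def _signed_distance(mask: np.ndarray,
                     spacing: tuple[float, float]) -> np.ndarray:
    """Signed Euclidean distance field in mm, positive inside the mask.

    Distances are taken to the mask boundary (half a pixel beyond the
    nearest opposite-class pixel centre), so boundary-adjacent pixels sit
    at about +/-0.5 px rather than +/-1 px and sub-pixel displacement
    fields can actually move the contour.
    """
    half = 0.5 * min(spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing) - half
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing) - half
    return np.where(mask, inside, -outside)


def perturb_mask(mask: BinaryMask, params: PerturbationParams,
                 seed: int) -> BinaryMask:
    """One plausible alternative segmentation of `mask`.

    Adds a smooth random field (white noise blurred over corr_len, scaled to
    std = amplitude mm) to the signed distance field and re-thresholds at
    zero; the largest connected component is kept so a rater's contour is
    always a single body. amplitude = 0 returns the input unchanged.
    """
    m = mask.values
    if not m.any():
        raise ValueError("cannot perturb an empty mask")
    if label(m, connectivity=2).max() != 1:
        raise ValueError("input mask must be a single connected component")
    if params.amplitude == 0:
        return mask
    sdf = _signed_distance(m, mask.spacing)
    rng = np.random.default_rng(seed)
    sig = (params.corr_len / mask.spacing[0], params.corr_len / mask.spacing[1])
    for _ in range(max(params.max_attempts, 1)):
        field = ndimage.gaussian_filter(rng.normal(size=m.shape), sig)
        std = field.std()
        if std == 0:
            continue
        field *= params.amplitude / std
        new = (sdf + field) > 0
        if not new.any():
            continue
        lab = label(new, connectivity=2)
        if lab.max() > 1:
            counts = np.bincount(lab.ravel())[1:]
            new = lab == (np.argmax(counts) + 1)
        return BinaryMask(new, mask.spacing)
    raise RuntimeError(
        f"no non-empty perturbation in {params.max_attempts} attempts "
        f"(amplitude={params.amplitude} mm)")


def sample_rater_set(truth: BinaryMask, params: PerturbationParams, k: int,
                     seed: int,
                     reference_masks: Sequence[BinaryMask] | None = None
                     ) -> list[BinaryMask]:
    """Sample k accepted rater masks for one lesion.

    Each draw is perturb_mask applied to `truth`; it is accepted only if its
    Dice with at least one reference mask strictly exceeds
    params.accept_threshold. References default to the ground truth alone;
    passing the simulated expert set reproduces the any-expert acceptance
    variant used for multi-rater datasets.
    """
    if k < 2:
        raise ValueError("a rater set needs k >= 2")
    refs = list(reference_masks) if reference_masks else [truth]
    ss = np.random.SeedSequence(seed)
    out: list[BinaryMask] = []
    for slot, child in enumerate(ss.spawn(k)):
        draw_seeds = child.generate_state(params.max_attempts)
        accepted = None
        for s in draw_seeds:
            cand = perturb_mask(truth, params, seed=int(s))
            if cand.area_mm2 < params.min_volume_mm3:
                continue
            if any(dice(cand, r) > params.accept_threshold for r in refs):
                accepted = cand
                break
        if accepted is None:
            raise RuntimeError(
                f"rater slot {slot}: no draw with Dice > "
                f"{params.accept_threshold} in {params.max_attempts} attempts")
        out.append(accepted)
    return out


def _median_pairwise_dice(truth: BinaryMask, params: PerturbationParams,
                          n_draws: int, seed: int,
                          n_repeats: int = 1) -> float:
    """Median pairwise Dice of an n_draws rater set, averaged over
    n_repeats independent sets to tame sampling noise."""
    meds = []
    for rep_seed in np.random.SeedSequence(seed).generate_state(n_repeats):
        masks = sample_rater_set(truth, params, k=n_draws, seed=int(rep_seed))
        vals = [dice(masks[i], masks[j])
                for i in range(n_draws) for j in range(i + 1, n_draws)]
        meds.append(np.median(vals))
    return float(np.mean(meds))


def calibrate_amplitude(truth: BinaryMask, target_median_dice: float,
                        params: PerturbationParams, seed: int,
                        n_draws: int = 20, tol: float = 0.02,
                        amplitude_bounds: tuple[float, float] = (1e-3, 12.0),
                        max_iter: int = 40) -> PerturbationParams:
    """Bisection on amplitude until the median pairwise Dice of an n_draws
    rater set is within +/- tol of the target.

    The Dice objective is evaluated with a fixed seed per amplitude, making
    it a deterministic, monotonically decreasing function of amplitude, so
    plain bisection applies. Raises if the target lies outside the Dice
    range achievable within amplitude_bounds.
    """
    if not (0 < target_median_dice < 1):
        raise ValueError("target_median_dice must be in (0, 1)")
    lo, hi = amplitude_bounds

    def objective(a: float) -> float:
        return _median_pairwise_dice(truth, replace(params, amplitude=a),
                                     n_draws, seed, n_repeats=3)

    d_lo, d_hi = objective(lo), objective(hi)
    if not (d_hi - tol <= target_median_dice <= d_lo + tol):
        raise ValueError(
            f"target median Dice {target_median_dice} outside achievable "
            f"range [{d_hi:.3f}, {d_lo:.3f}] for amplitudes in "
            f"[{lo}, {hi}] mm")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d_mid = objective(mid)
        if abs(d_mid - target_median_dice) <= tol:
            return replace(params, amplitude=mid)
        if d_mid > target_median_dice:
            lo = mid
        else:
            hi = mid
    return replace(params, amplitude=0.5 * (lo + hi))


def default_spec_sampler(preset: LesionSpec = LUNG_PRESET,
                         radius_range: tuple[float, float] = (4.0, 15.0),
                         irregularity_range: tuple[float, float] = (0.05, 0.45),
                         lesion_hu_sd: float = 60.0,
                         texture_scale_range: tuple[float, float] = (0.4, 1.8),
                         ) -> Callable[[np.random.Generator], LesionSpec]:
    """Distribution over LesionSpec emulating cohort heterogeneity: lesion
    radii spanning small nodules to large tumours, variable boundary
    irregularity, a wide attenuation range (e.g. ground-glass to solid for
    lung nodules, hypo- to hyperdense for abdominal lesions) and variable
    intratumoral texture strength."""

    def sample(rng: np.random.Generator) -> LesionSpec:
        return replace(
            preset,
            radius_mean=rng.uniform(*radius_range),
            radius_irregularity=rng.uniform(*irregularity_range),
            lesion_hu=preset.lesion_hu + rng.normal(scale=lesion_hu_sd),
            texture_sd=preset.texture_sd * rng.uniform(*texture_scale_range),
        )

    return sample


def make_cohort(n_lesions: int,
                params: PerturbationParams,
                k_experts: int = 4,
                k_samples: int = 25,
                spec_sampler: Callable[[np.random.Generator], LesionSpec]
                | None = None,
                seed: int = 0,
                expert_params: PerturbationParams | None = None,
                ) -> list[SyntheticLesionCase]:
    """Seeded, reproducible cohort of synthetic lesions with two rater
    populations per lesion: a small "expert" panel and a large sampled set
    (defaults k=4 and k=25). Expert masks double as acceptance references
    for the sampled population."""
    if n_lesions < 2:
        raise ValueError("a cohort needs at least 2 lesions")
    sampler = spec_sampler or default_spec_sampler()
    e_params = expert_params or params
    ss = np.random.SeedSequence(seed)
    cases: list[SyntheticLesionCase] = []
    for i, child in enumerate(ss.spawn(n_lesions)):
        s_spec, s_img, s_exp, s_smp = (int(x) for x in child.generate_state(4))
        rng = np.random.default_rng(s_spec)
        spec = sampler(rng)
        image, truth = make_lesion(spec, seed=s_img)
        experts = sample_rater_set(truth, e_params, k=k_experts, seed=s_exp)
        samples = sample_rater_set(truth, params, k=k_samples, seed=s_smp,
                                   reference_masks=experts)
        cases.append(SyntheticLesionCase(
            lesion_id=f"lesion_{i:04d}", image=image, truth_mask=truth,
            expert_masks=tuple(experts), sample_masks=tuple(samples),
            seed=s_img))
    return cases


def save_cohort(cases: Sequence[SyntheticLesionCase],
                out_dir: str | Path) -> None:
    """Write a cohort as NIfTI files, one directory per lesion:
    cohort/<lesion_id>/{image, truth, expert_<j>, rater_<j>}.nii.gz"""
    out = Path(out_dir)
    for case in cases:
        d = out / case.lesion_id
        d.mkdir(parents=True, exist_ok=True)
        save_nifti(case.image, d / "image.nii.gz")
        save_nifti(case.truth_mask, d / "truth.nii.gz")
        for j, m in enumerate(case.expert_masks):
            save_nifti(m, d / f"expert_{j}.nii.gz")
        for j, m in enumerate(case.sample_masks):
            save_nifti(m, d / f"rater_{j}.nii.gz")


def load_cohort(in_dir: str | Path) -> list[SyntheticLesionCase]:
    """Read a cohort written by save_cohort back into memory."""
    from .grids import load_nifti_image, load_nifti_mask

    root = Path(in_dir)
    cases = []
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        def _idx(p: Path) -> int:
            return int(p.name.split("_")[1].split(".")[0])

        experts = sorted(d.glob("expert_*.nii.gz"), key=_idx)
        raters = sorted(d.glob("rater_*.nii.gz"), key=_idx)
        cases.append(SyntheticLesionCase(
            lesion_id=d.name,
            image=load_nifti_image(d / "image.nii.gz"),
            truth_mask=load_nifti_mask(d / "truth.nii.gz"),
            expert_masks=tuple(load_nifti_mask(p) for p in experts),
            sample_masks=tuple(load_nifti_mask(p) for p in raters),
            seed=-1))
    if not cases:
        raise FileNotFoundError(f"no lesion directories under {root}")
    return cases
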
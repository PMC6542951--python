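"""Seeded synthetic FLAIR-like phantoms for end-to-end testing.

The phantom is schematic rather than physics-based: an ellipsoidal
brain with a CSF rim, a central CSF "ventricle", a cortical GM shell
and a WM interior, on the standardized [0, 1] intensity scale with the
FLAIR-like class ordering CSF < GM < WM < lesion.  Stroke lesions are
irregular hyperintense blobs carrying an oriented sinusoidal texture,
so Gabor features are discriminative by construction; white-matter
hyperintensity confounders share the lesion intensity but not its
texture.  A smooth multiplicative bias field and additive noise emulate
scanner non-uniformity and thermal noise.

Tissue priors are derived from the smoothed, lesion-free truth, so the
lesion region has WM-dominant priors — mimicking a registered atlas
that knows nothing of the lesion.

The geometry is a scaled-down brain (a few hundred mL) so that full
leave-one-out experiments run in minutes; voxel spacing (2, 2, 6) mm
keeps the in-plane / through-plane anisotropy of clinical FLAIR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import BACKGROUND, CSF, GM, LES, WM, LabelMap, PriorMaps, Volume


@dataclass
class PhantomConfig:
    """Study conditions of the synthetic cohort."""

    shape: tuple[int, int, int] = (48, 48, 16)
    spacing: tuple[float, float, float] = (2.0, 2.0, 6.0)
    #: per-class intensity means on the standardized scale (CSF, GM, WM, Les)
    class_means: tuple[float, ...] = (0.12, 0.42, 0.55, 0.85)
    #: per-class intensity SDs
    class_sds: tuple[float, ...] = (0.03, 0.03, 0.03, 0.03)
    lesion_count: int = 1
    lesion_volume_ml: float = 15.0
    lesion_irregularity: float = 0.4
    texture_orientation_deg: float = 45.0
    texture_frequency_cpv: float = math.sqrt(2.0) / 8.0  # cycles per voxel
    texture_contrast: float = 0.10
    confounder_count: int = 3
    confounder_volume_ml: float = 0.35
    confounder_edge_mm: float = 2.5
    bias_amplitude: float = 0.10
    bias_length_mm: float = 40.0
    noise_sd: float = 0.02
    prior_smooth_mm: float = 6.0
    seed: int = 0

    def __post_init__(self):
        means = self.class_means
        if not (means[CSF] < means[GM] < means[WM] < means[LES]):
            raise ValueError("class means must be ordered CSF < GM < WM < Les")
        if any(s <= 0 for s in self.class_sds):
            raise ValueError("class SDs must be > 0")


@dataclass
class PhantomCase:
    """One synthetic subject: image, ground truth, and atlas-like priors."""

    flair: Volume
    truth: LabelMap  # quaternary, -1 outside the brain
    lesion_mask: LabelMap
    priors: PriorMaps  # CSF/GM/WM channels; Les channel zero
    config: PhantomConfig
    clean: Volume | None = None  # class means + texture, before bias/noise

    @property
    def brain_mask(self) -> LabelMap:
        return LabelMap(
            (self.truth.labels >= 0).astype(np.int16), "binary", self.truth.spacing
        )


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _smooth_noise(rng, shape, sigma_vox) -> np.ndarray:
    g = gaussian_filter(rng.standard_normal(shape), sigma_vox, mode="nearest")
    sd = g.std()
    return g / sd if sd > 0 else g


def _tissue_geometry(config: PhantomConfig) -> np.ndarray:
    """Layered CSF/GM/WM truth (lesion-free), -1 outside the brain."""
    nx, ny, nz = config.shape
    center = ((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2)
    semi = (0.88 * nx / 2, 0.88 * ny / 2, 0.88 * nz / 2)
    brain = _ellipsoid(config.shape, center, semi)
    shrink = lambda f: _ellipsoid(
        config.shape, center, tuple(a * f for a in semi)
    )
    truth = np.full(config.shape, BACKGROUND, dtype=np.int16)
    truth[brain] = CSF  # outer rim
    truth[shrink(0.93)] = GM  # cortical shell
    truth[shrink(0.78)] = WM  # interior
    ventricle = _ellipsoid(
        config.shape, center, (0.16 * nx / 2, 0.16 * ny / 2, 0.35 * nz / 2)
    )
    truth[ventricle & brain] = CSF
    return truth


def _place_blob(
    rng, truth: np.ndarray, allowed: np.ndarray, n_target: int,
    irregularity: float, spacing,
) -> np.ndarray:
    """Irregular blob of ~n_target voxels grown inside the allowed region.

    A perturbed radial field from a random seed point is thresholded at
    the n-th smallest value, giving exact voxel-count control.
    """
    n_avail = int(allowed.sum())
    if n_avail < n_target:
        raise ValueError(
            f"requested blob of {n_target} voxels exceeds the available "
            f"region ({n_avail} voxels)"
        )
    seeds = np.argwhere(allowed)
    cx, cy, cz = seeds[rng.integers(len(seeds))]
    grids = np.ogrid[tuple(slice(0, n) for n in truth.shape)]
    dist = np.sqrt(
        sum(((g - c) * s) ** 2 for g, c, s in zip(grids, (cx, cy, cz), spacing))
    )
    mean_radius = (3.0 * n_target * np.prod(spacing) / (4.0 * np.pi)) ** (1 / 3)
    bumps = _smooth_noise(rng, truth.shape, (2.0, 2.0, 1.0))
    fld = dist + irregularity * mean_radius * bumps
    fld = np.where(allowed, fld, np.inf)
    thr = np.partition(fld.ravel(), n_target - 1)[n_target - 1]
    return fld <= thr


def generate_phantom(config: PhantomConfig) -> PhantomCase:
    """Generate one phantom case, fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    spacing = config.spacing
    vox_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    truth = _tissue_geometry(config)
    brain = truth >= 0

    lesion = np.zeros(config.shape, dtype=bool)
    for _ in range(config.lesion_count):
        n_target = max(1, int(round(config.lesion_volume_ml / vox_ml)))
        allowed = (truth == WM) & ~lesion
        blob = _place_blob(
            rng, truth, allowed, n_target, config.lesion_irregularity, spacing
        )
        lesion |= blob

    confounder = np.zeros(config.shape, dtype=bool)
    for _ in range(config.confounder_count):
        n_target = max(1, int(round(config.confounder_volume_ml / vox_ml)))
        allowed = (truth == WM) & ~lesion & ~confounder
        blob = _place_blob(rng, truth, allowed, n_target, 0.3, spacing)
        confounder |= blob

    truth_full = truth.copy()
    truth_full[lesion] = LES  # confounders stay labelled WM

    # clean image: class means plus oriented lesion texture
    means = np.asarray(config.class_means)
    clean = np.zeros(config.shape)
    clean[brain] = means[truth_full[brain]]
    theta = math.radians(config.texture_orientation_deg)
    fx = config.texture_frequency_cpv * math.cos(theta)
    fy = config.texture_frequency_cpv * math.sin(theta)
    gx, gy = np.meshgrid(
        np.arange(config.shape[0]), np.arange(config.shape[1]), indexing="ij"
    )
    grating = config.texture_contrast * np.cos(2 * np.pi * (fx * gx + fy * gy))
    clean += lesion * grating[:, :, None]
    # Confounders are hyperintense like the lesion but, by definition, carry
    # no oriented texture: a soft-shouldered profile (fuzzy WMH border, peak
    # at the lesion intensity) keeps them free of the broadband content a
    # hard-edged blob would inject into the oriented Gabor channels.
    if confounder.any():
        sigma_c = tuple(config.confounder_edge_mm / s for s in spacing)
        profile = gaussian_filter(confounder.astype(np.float64), sigma_c,
                                  mode="nearest")
        profile /= profile.max()
        clean += (means[LES] - means[WM]) * profile * (truth_full == WM)

    sigma_bias = tuple(config.bias_length_mm / s for s in spacing)
    bias = np.exp(config.bias_amplitude * _smooth_noise(rng, config.shape, sigma_bias))
    bias /= bias[brain].mean()

    sds = np.asarray(config.class_sds)
    noise = np.zeros(config.shape)
    noise[brain] = sds[truth_full[brain]] * rng.standard_normal(int(brain.sum()))
    noise += config.noise_sd * rng.standard_normal(config.shape)

    img = clean * bias + noise
    img[~brain] = 0.0
    img = np.clip(img, 0.0, 1.0)

    # atlas-like priors from the smoothed lesion-free tissue truth
    tissue = truth.copy()
    tissue[confounder] = WM
    sigma_p = tuple(config.prior_smooth_mm / s for s in spacing)
    probs = np.zeros((4,) + tuple(config.shape))
    for c in (CSF, GM, WM):
        probs[c] = gaussian_filter((tissue == c).astype(np.float64), sigma_p,
                                   mode="nearest")
    total = probs[:3].sum(axis=0)
    inside = brain & (total > 0)
    for c in (CSF, GM, WM):
        probs[c][inside] /= total[inside]
        probs[c][~brain] = 0.0
    # voxels where smoothing left no mass: fall back to WM
    fallback = brain & (total <= 0)
    probs[WM][fallback] = 1.0

    return PhantomCase(
        flair=Volume(img, spacing),
        truth=LabelMap(truth_full, "quaternary", spacing),
        lesion_mask=LabelMap(lesion.astype(np.int16), "binary", spacing),
        priors=PriorMaps(probs, spacing),
        config=config,
        clean=Volume(clean, spacing),
    )


def generate_cohort(n: int, base: PhantomConfig, seed: int = 0) -> list[PhantomCase]:
    """Generate ``n`` cases with jittered lesion size/position.

    Per-case seeds derive deterministically from the master ``seed``;
    lesion target volumes are jittered by a uniform factor in
    [0.6, 1.4] around the base configuration.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 cases")
    cases = []
    for i in range(n):
        child = np.random.SeedSequence([int(seed), i])
        rng = np.random.default_rng(child)
        factor = rng.uniform(0.6, 1.4)
        case_seed = int(child.generate_state(1, np.uint32)[0] % (2**31))
        cfg = replace(
            base,
            lesion_volume_ml=base.lesion_volume_ml * factor,
            seed=case_seed,
        )
        cases.append(generate_phantom(cfg))
    return cases
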
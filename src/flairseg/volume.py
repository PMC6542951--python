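"""Volume and label-map data model with NIfTI I/O.

Conventions shared by every module in the package:

* axes 0 and 1 are the in-plane axes of an axial slice, axis 2 indexes
  slices; all 2-D operations (Gabor filtering, 8-neighborhoods) act on
  axes 0 and 1;
* voxel indexing is 0-based and volumes are processed in stored voxel
  order — no resampling or reorientation is performed;
* spacing is (dx, dy, dz) in millimetres per voxel along axes 0, 1, 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

#: Tissue class codes used throughout the package.
CSF, GM, WM, LES = 0, 1, 2, 3
CLASS_NAMES = ("CSF", "GM", "WM", "Les")

#: Sentinel for voxels outside the brain in quaternary label maps.
BACKGROUND = -1

_SCHEMES = {
    "binary": frozenset({0, 1}),
    "quaternary": frozenset({BACKGROUND, CSF, GM, WM, LES}),
}


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive components, got {spacing}")
    return spacing


@dataclass
class Volume:
    """A 3-D scalar image with anisotropic voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)
        n_bad = int(np.count_nonzero(~np.isfinite(self.data)))
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]


@dataclass
class LabelMap:
    """A 3-D integer label image under a declared labelling scheme.

    ``binary`` maps use {0: non-lesion, 1: lesion}; ``quaternary`` maps use
    {0: CSF, 1: GM, 2: WM, 3: Les} plus the out-of-brain sentinel -1.
    """

    labels: np.ndarray
    scheme: str
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int16)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("label map values must be integers")
            self.labels = as_int
        if self.labels.ndim != 3:
            raise ValueError(f"label map must be 3-D, got shape {self.labels.shape}")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        allowed = _SCHEMES[self.scheme]
        present = set(np.unique(self.labels).tolist())
        stray = present - allowed
        if stray:
            raise ValueError(
                f"label values {sorted(stray)} are outside the {self.scheme} scheme"
            )
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class PriorMaps:
    """Per-voxel tissue prior probabilities (CSF, GM, WM, Les channels).

    ``data`` has shape (4, X, Y, Z) in the class order of ``CLASS_NAMES``.
    A registered atlas carries no lesion channel; such priors store zeros
    in the Les channel and a constant lesion prior is mixed in with
    :meth:`with_lesion_prior` before MRF inference.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[0] != 4:
            raise ValueError(
                f"priors must have shape (4, X, Y, Z), got {self.data.shape}"
            )
        self.spacing = _check_spacing(self.spacing)
        if np.any(self.data < -1e-9):
            raise ValueError("prior probabilities must be non-negative")
        total = self.data.sum(axis=0)
        inside = total > 0.5
        if inside.any() and not np.allclose(total[inside], 1.0, atol=1e-6):
            raise ValueError("priors must sum to 1 inside the brain mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def brain_mask(self) -> np.ndarray:
        """Boolean in-brain mask derived from where the priors are defined."""
        return self.data.sum(axis=0) > 0.5

    def with_lesion_prior(self, pi_les: float) -> "PriorMaps":
        """Mix a constant lesion prior into lesion-free atlas priors.

        Tissue (CSF/GM/WM) probabilities are rescaled by ``1 - pi_les`` and
        the Les channel is set to ``pi_les`` inside the brain.
        """
        if not 0.0 <= pi_les < 1.0:
            raise ValueError("pi_les must be in [0, 1)")
        mixed = self.data.copy()
        inside = self.brain_mask()
        tissue = mixed[:3, inside]
        tissue_total = tissue.sum(axis=0)
        tissue_total[tissue_total == 0] = 1.0
        mixed[:3, inside] = tissue / tissue_total * (1.0 - pi_les)
        mixed[3, inside] = pi_les
        return PriorMaps(mixed, self.spacing)


def _affine_from_spacing(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def read_volume(path) -> Volume:
    """Read a 3-D single-channel NIfTI image as a :class:`Volume`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"expected a 3-D single-channel image, got shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(data, dtype=np.float64)
    n_bad = int(np.count_nonzero(~np.isfinite(data)))
    if n_bad:
        raise ValueError(f"{path}: volume contains {n_bad} non-finite voxel(s)")
    return Volume(data, spacing)


def write_volume(volume: Volume, path) -> None:
    img = nib.Nifti1Image(
        volume.data.astype(np.float32), _affine_from_spacing(volume.spacing)
    )
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_labelmap(path, scheme: str) -> LabelMap:
    """Read an integer NIfTI label image under the declared scheme."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D label image, got shape {data.shape}")
    labels = np.rint(np.asarray(data)).astype(np.int16)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(labels, scheme, spacing)


def write_labelmap(labels: LabelMap, path) -> None:
    img = nib.Nifti1Image(
        labels.labels.astype(np.int16), _affine_from_spacing(labels.spacing)
    )
    img.header.set_zooms(labels.spacing)
    nib.save(img, str(path))
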
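"""Multi-window 2-D discrete Gabor filter bank and its optimization.

Each axial slice is decomposed with a bank of R Gaussian windows
modulated by complex exponentials,

    g_r[x, y] = exp(-(x^2 / sigma_x_r^2 + y^2 / sigma_y_r^2))
                * exp(-j 2 pi (m1 b x / L1 + m2 b y / L2)),

evaluated on a truncated support and convolved with the slice at every
voxel (spatial shift a = 1, dense evaluation).  2-D rather than 3-D
filtering is used because FLAIR slice thickness is much coarser than the
in-plane resolution.  The per-voxel feature is the modulus of the
complex coefficient, one channel per (window, frequency-shift) pair.

Window spreads are chosen to maximize the total pairwise distance
between lesion and non-lesion coefficient vectors on labelled training
data; the search is an exhaustive scan of a spread grid with seeded
subsampling of voxel pairs, which is exact on the declared grid and
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import yaml
from scipy.signal import fftconvolve

from .volume import LabelMap, Volume

#: Frequency-shift sets of the default 3-window bank, one set per window
#: (octave-matched: each window carries the orientations of its own octave,
#: so the oriented channels are nearly DC-free; the finest window keeps only
#: the local-mean channel because its octave would sit at the Nyquist rate).
DEFAULT_FREQUENCY_SHIFTS = (
    ((0, 0),),
    ((0, 0), (2, 0), (0, 2), (2, 2), (2, -2)),
    ((0, 0), (1, 0), (0, 1), (1, 1), (1, -1)),
)


def _per_window_shifts(freq, R):
    """Accept one shared shift set or one set per window; normalize to per-window."""
    freq = tuple(freq)
    if freq and isinstance(freq[0][0], (int, np.integer)):
        freq = (freq,) * R
    if len(freq) != R:
        raise ValueError("provide one frequency-shift set per window")
    out = []
    for shifts in freq:
        shifts = tuple((int(m1), int(m2)) for m1, m2 in shifts)
        if (0, 0) not in shifts:
            raise ValueError("every window's frequency shifts must include (0, 0)")
        out.append(shifts)
    return tuple(out)


@dataclass
class GaborBankSpec:
    """Parameters of the multi-window Gabor bank.

    ``sigma_x``/``sigma_y`` hold one spatial spread per window (voxels);
    ``a`` and ``b`` are the spatial and frequency shift magnitudes; the
    frequency of channel (m1, m2) on an L1 x L2 slice is
    (m1 * b / L1, m2 * b / L2) cycles per voxel.  ``frequency_shifts`` is
    either one shared set of (m1, m2) pairs or one set per window.
    ``L1``/``L2`` are bound to the slice dimensions at transform time
    when left unset.
    """

    sigma_x: tuple[float, ...] = (1.5, 3.0, 6.0)
    sigma_y: tuple[float, ...] = (1.5, 3.0, 6.0)
    frequency_shifts: tuple = DEFAULT_FREQUENCY_SHIFTS
    a: int = 1
    b: float = 6.0
    kernel_halfwidth: int | None = None
    L1: int | None = None
    L2: int | None = None

    def __post_init__(self):
        self.sigma_x = tuple(float(s) for s in self.sigma_x)
        self.sigma_y = tuple(float(s) for s in self.sigma_y)
        if len(self.sigma_x) != len(self.sigma_y) or not self.sigma_x:
            raise ValueError("sigma_x and sigma_y must be nonempty and equal length")
        if any(s <= 0 for s in self.sigma_x + self.sigma_y):
            raise ValueError("all window spreads must be > 0")
        self.frequency_shifts = _per_window_shifts(self.frequency_shifts, self.R)
        hw = self.kernel_halfwidth
        if hw is None:
            hw = int(math.ceil(3.0 * max(self.sigma_x + self.sigma_y)))
        if hw < math.ceil(3.0 * max(self.sigma_x + self.sigma_y)):
            raise ValueError("kernel_halfwidth must cover 3x the largest spread")
        self.kernel_halfwidth = int(hw)

    @property
    def R(self) -> int:
        return len(self.sigma_x)

    @property
    def channels(self) -> tuple[tuple[int, int, int], ...]:
        """Fixed feature ordering: (r, m1, m2), windows outer, shifts inner."""
        return tuple(
            (r, m1, m2)
            for r in range(self.R)
            for (m1, m2) in self.frequency_shifts[r]
        )

    @property
    def n_features(self) -> int:
        return len(self.channels)

    def bind(self, L1: int, L2: int) -> "GaborBankSpec":
        return replace(self, L1=int(L1), L2=int(L2))

    def to_yaml(self, path) -> None:
        payload = {
            "sigma_x": list(self.sigma_x),
            "sigma_y": list(self.sigma_y),
            "frequency_shifts": [[list(p) for p in w] for w in self.frequency_shifts],
            "a": self.a,
            "b": self.b,
            "kernel_halfwidth": self.kernel_halfwidth,
            "L1": self.L1,
            "L2": self.L2,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "GaborBankSpec":
        with open(path) as fh:
            p = yaml.safe_load(fh)
        return cls(
            sigma_x=tuple(p["sigma_x"]),
            sigma_y=tuple(p["sigma_y"]),
            frequency_shifts=tuple(
                tuple(tuple(q) for q in w) for w in p["frequency_shifts"]
            ),
            a=p.get("a", 1),
            b=p.get("b", 6.0),
            kernel_halfwidth=p.get("kernel_halfwidth"),
            L1=p.get("L1"),
            L2=p.get("L2"),
        )


@dataclass
class FeatureVolume:
    """Per-voxel Gabor coefficient vectors on the source grid.

    ``data`` has shape (X, Y, Z, D); ``channels`` records the (r, m1, m2)
    identity of each of the D features in order.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    channels: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("feature volume must have shape (X, Y, Z, D)")
        if self.data.shape[3] != len(self.channels):
            raise ValueError("channel list does not match feature dimension")
        if not np.isfinite(self.data).all():
            raise ValueError("feature coefficients must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_features(self) -> int:
        return self.data.shape[3]


def build_kernels(spec: GaborBankSpec, shape: tuple[int, int] | None = None):
    """Sample the complex Gabor kernels on their truncated support.

    Returns a dict mapping (r, m1, m2) to a (2H+1, 2H+1) complex array
    centred on the window origin.  Kernels with (m1, m2) = (0, 0) are
    purely real Gaussians.
    """
    if shape is not None:
        spec = spec.bind(shape[0], shape[1])
    if spec.L1 is None or spec.L2 is None:
        raise ValueError("slice dimensions L1, L2 must be bound before kernel build")
    hw = spec.kernel_halfwidth
    if 2 * hw + 1 > min(spec.L1, spec.L2):
        raise ValueError(
            f"kernel support {2 * hw + 1} exceeds slice size ({spec.L1}, {spec.L2})"
        )
    x = np.arange(-hw, hw + 1, dtype=np.float64)[:, None]
    y = np.arange(-hw, hw + 1, dtype=np.float64)[None, :]
    kernels = {}
    for r in range(spec.R):
        env = np.exp(-(x**2 / spec.sigma_x[r] ** 2 + y**2 / spec.sigma_y[r] ** 2))
        for m1, m2 in spec.frequency_shifts[r]:
            phase = -2j * np.pi * (m1 * spec.b * x / spec.L1 + m2 * spec.b * y / spec.L2)
            k = env * np.exp(phase)
            if (m1, m2) == (0, 0):
                k = k.real.astype(np.complex128)
            kernels[(r, m1, m2)] = k
    return kernels


def transform_slice(
    slice2d: np.ndarray, spec: GaborBankSpec, modulus: bool = True
) -> np.ndarray:
    """Convolve one slice with every kernel (reflection-padded boundaries).

    Returns (L1, L2, D) moduli, or the complex coefficients when
    ``modulus=False`` (on which the transform is strictly linear).
    """
    slice2d = np.asarray(slice2d, dtype=np.float64)
    spec = spec.bind(slice2d.shape[0], slice2d.shape[1])
    kernels = build_kernels(spec)
    hw = spec.kernel_halfwidth
    padded = np.pad(slice2d, hw, mode="reflect")
    dtype = np.float64 if modulus else np.complex128
    out = np.empty(slice2d.shape + (spec.n_features,), dtype=dtype)
    for d, key in enumerate(spec.channels):
        conv = fftconvolve(padded, kernels[key], mode="same")
        conv = conv[hw:-hw, hw:-hw]
        out[..., d] = np.abs(conv) if modulus else conv
    return out


def transform_volume(volume: Volume, spec: GaborBankSpec) -> FeatureVolume:
    """Slice-by-slice multi-window Gabor transform of a volume."""
    L1, L2, nz = volume.shape
    bound = spec.bind(L1, L2)
    feats = np.empty((L1, L2, nz, bound.n_features), dtype=np.float64)
    for z in range(nz):
        feats[:, :, z, :] = transform_slice(volume.data[:, :, z], bound)
    return FeatureVolume(feats, volume.spacing, bound.channels)


def separation_objective(
    features_lesion: np.ndarray, features_nonlesion: np.ndarray, norm: str = "l2"
) -> float:
    """Total pairwise distance between lesion and non-lesion coefficients.

    Sums ||c_j - c_k|| over every cross pair, with c_j drawn from the
    lesion set and c_k from the non-lesion set.  ``norm`` selects the
    Euclidean (default) or L1 vector norm.
    """
    a = np.atleast_2d(np.asarray(features_lesion, dtype=np.float64))
    b = np.atleast_2d(np.asarray(features_nonlesion, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("both feature sets must be nonempty")
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    diff = a[:, None, :] - b[None, :, :]
    if norm == "l2":
        dist = np.sqrt((diff**2).sum(axis=-1))
    elif norm == "l1":
        dist = np.abs(diff).sum(axis=-1)
    else:
        raise ValueError("norm must be 'l2' or 'l1'")
    return float(dist.sum())


def _sample_voxels(rng, selector: np.ndarray, n: int):
    idx = np.flatnonzero(selector)
    if idx.size > n:
        idx = rng.choice(idx, size=n, replace=False)
    return np.sort(idx)


def bank_separation(
    volumes: list[Volume],
    lesion_labels: list[LabelMap],
    spec: GaborBankSpec,
    pairs_budget: int = 4000,
    seed: int = 0,
) -> float:
    """Evaluate the class-separation objective of a bank on labelled data.

    At most ``pairs_budget`` lesion/non-lesion voxel pairs per volume are
    used, subsampled reproducibly from ``seed``; non-lesion voxels are
    restricted to nonzero-intensity (in-brain) voxels.
    """
    n_each = max(2, int(math.isqrt(pairs_budget)))
    total = 0.0
    for v, (vol, lab) in enumerate(zip(volumes, lesion_labels)):
        rng = np.random.default_rng(np.random.SeedSequence([seed, v]))
        les = lab.labels.ravel() > 0
        non = (lab.labels.ravel() == 0) & (vol.data.ravel() > 0)
        if not les.any():
            raise ValueError(f"volume {v} has no lesion voxels")
        if not non.any():
            raise ValueError(f"volume {v} has no non-lesion foreground voxels")
        i_les = _sample_voxels(rng, les, n_each)
        i_non = _sample_voxels(rng, non, n_each)
        feats = transform_volume(vol, spec).data.reshape(-1, spec.n_features)
        total += separation_objective(feats[i_les], feats[i_non])
    return total


def octave_bank(base_sigma: float, spec: GaborBankSpec) -> GaborBankSpec:
    """Bank with octave-spaced isotropic spreads (s, 2s, 4s, ...)."""
    sig = tuple(base_sigma * 2.0**k for k in range(spec.R))
    return replace(spec, sigma_x=sig, sigma_y=sig, kernel_halfwidth=None)


def optimize_bank(
    volumes: list[Volume],
    lesion_labels: list[LabelMap],
    sigma_grid: list[float],
    pairs_budget: int = 4000,
    seed: int = 0,
    base_spec: GaborBankSpec | None = None,
) -> GaborBankSpec:
    """Choose the window spreads maximizing lesion/non-lesion separation.

    The analysis-window spreads vary over ``sigma_grid`` (each candidate
    scales the octave ladder of the bank) while the remapping lattice
    (``a``, ``b``, frequency shifts) stays fixed.  The search is an
    exhaustive scan over the grid with the same seeded voxel subsample for
    every candidate; ties resolve to the earlier grid entry.
    """
    if not sigma_grid:
        raise ValueError("sigma_grid must be nonempty")
    if base_spec is None:
        base_spec = GaborBankSpec()
    best_spec, best_val = None, -np.inf
    for s in sigma_grid:
        cand = octave_bank(float(s), base_spec)
        val = bank_separation(volumes, lesion_labels, cand, pairs_budget, seed)
        if val > best_val:
            best_spec, best_val = cand, val
    return best_spec
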
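"""Customized 4-class Markov random field over CSF/GM/WM/lesion labels.

The label field couples three kinds of observation at each voxel —
its intensity, its Gabor texture vector, and the intensity differences
to its neighbors — with learned clique label-configuration potentials.
The per-voxel energy is

    U(C_i | I) = -log P(I_i | C_i) - log P(T_i | C_i) - log P(C_i)
                 - sum_{j in N_i} log P(dI_ij | C_i, C_j)
                 + alpha * sum_{cliques k containing i} m(C_k),

where the neighborhood intensity-difference likelihood factorizes into
one pairwise Gaussian per neighbor (each neighbor counted once — it is
a single factor of the per-voxel observation model, not replicated per
clique), ``m`` is the negative log frequency of the clique's label
configuration in training data, and ``alpha`` weights the spatial
clique term by the in-plane / through-plane distance ratio,
compensating the anisotropic acquisition grid.

Neighborhood: the 8 in-plane neighbors plus the same-position voxels in
the slices above and below (a full 26-neighborhood is available as a
config option).  Cliques are all mutually adjacent subsets of sizes
2-4 containing the voxel; under the default reading the through-plane
neighbors are adjacent to the center only, so mixed in-plane /
through-plane 3- and 4-cliques do not arise.

Two modelling conventions keep asynchronous ICM a true coordinate
descent on a single well-defined objective:

* the intensity-difference Gaussians are exactly antisymmetric in the
  ordered class pair (they are fitted over both directions of every
  neighbor relation), so the pairwise term looks identical from either
  endpoint;
* the clique potential ``m`` is a function of the clique's label
  multiset (center included), identical from every member's viewpoint.

The tracked total energy counts each shared term once: per-voxel unary
terms, each in-brain neighbor pair once, and each clique
potential exactly once.  The per-voxel conditional energy above is then
precisely the part of the total that depends on C_i, so every accepted
ICM update strictly decreases the total.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.linalg import cho_factor, cho_solve

from .gabor import FeatureVolume
from .volume import BACKGROUND, CLASS_NAMES, CSF, GM, LES, WM, LabelMap, PriorMaps, Volume

_LOG2PI = float(np.log(2.0 * np.pi))
_M = 4  # number of classes

IN_PLANE_OFFSETS = tuple(
    (dx, dy, 0) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)
)
AXIAL_OFFSETS = ((0, 0, -1), (0, 0, 1))


def compute_alpha(spacing) -> float:
    """Anisotropy weight: ratio of in-plane to through-plane voxel distance."""
    dx, dy, dz = (float(s) for s in spacing)
    if min(dx, dy, dz) <= 0:
        raise ValueError("spacing components must be > 0")
    if abs(dx - dy) > 0.05 * max(dx, dy):
        raise ValueError(
            f"in-plane spacing must be isotropic within 5%, got ({dx}, {dy})"
        )
    return dx / dz


@dataclass
class NeighborhoodSpec:
    """Neighborhood and clique structure of the MRF.

    ``through_plane='axial'`` adds the two same-(x, y) voxels in the
    adjacent slices; ``'full'`` extends to the complete 26-neighborhood.
    """

    through_plane: str = "axial"
    clique_sizes: tuple[int, ...] = (2, 3, 4)
    alpha: float | None = None

    def __post_init__(self):
        if self.through_plane not in ("axial", "full", "none"):
            raise ValueError("through_plane must be 'axial', 'full' or 'none'")
        self.clique_sizes = tuple(sorted(int(k) for k in self.clique_sizes))
        if not set(self.clique_sizes) <= {2, 3, 4}:
            raise ValueError("clique sizes must be within {2, 3, 4}")

    def offsets(self) -> tuple[tuple[int, int, int], ...]:
        if self.through_plane == "axial":
            return IN_PLANE_OFFSETS + AXIAL_OFFSETS
        if self.through_plane == "full":
            return IN_PLANE_OFFSETS + tuple(
                (dx, dy, dz)
                for dz in (-1, 1)
                for dx in (-1, 0, 1)
                for dy in (-1, 0, 1)
            )
        return IN_PLANE_OFFSETS

    def adjacent(self, u, v) -> bool:
        """Mutual adjacency of two neighbor offsets (edge or vertex shared)."""
        if u == v:
            return False
        if self.through_plane == "full":
            return max(abs(a - b) for a, b in zip(u, v)) <= 1
        # minimal reading: through-plane voxels touch the center only
        if u[2] != 0 or v[2] != 0:
            return False
        return max(abs(u[0] - v[0]), abs(u[1] - v[1])) <= 1

    def resolve_alpha(self, spacing) -> float:
        return self.alpha if self.alpha is not None else compute_alpha(spacing)


@dataclass
class CliqueSet:
    """Cliques containing the center voxel, as member-offset tuples.

    ``by_size[k]`` lists the size-k cliques; each entry is the sorted
    tuple of the k-1 member offsets (the center offset (0,0,0) is
    implicit in every clique).
    """

    by_size: dict[int, list[tuple[tuple[int, int, int], ...]]]

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(sorted(self.by_size))

    def count(self, k: int | None = None) -> int:
        if k is not None:
            return len(self.by_size.get(k, []))
        return sum(len(v) for v in self.by_size.values())

    def canonical_by_size(self) -> dict[int, list[tuple]]:
        """Cliques whose center is the lexicographically smallest voxel.

        Every physical clique in the volume appears in the pattern list of
        each of its members; restricting to patterns where all member
        offsets are lex-greater than the origin counts it exactly once.
        """
        out = {}
        for k, cl in self.by_size.items():
            out[k] = [c for c in cl if all(m > (0, 0, 0) for m in c)]
        return out


def enumerate_cliques(spec: NeighborhoodSpec) -> CliqueSet:
    """All cliques of sizes 2-4 containing the center voxel.

    A clique is a set of mutually adjacent voxels; candidates are subsets
    of the neighborhood, checked for pairwise adjacency.
    """
    nbrs = spec.offsets()
    by_size: dict[int, list] = {}
    for k in spec.clique_sizes:
        found = []
        for members in itertools.combinations(nbrs, k - 1):
            ok = all(
                spec.adjacent(u, v) for u, v in itertools.combinations(members, 2)
            )
            if ok:
                found.append(tuple(sorted(members)))
        by_size[k] = found
    return CliqueSet(by_size)


@dataclass
class MRFModel:
    """Learned observation models and clique statistics of the MRF.

    * ``intensity_mean/var``: per-class 1-D Gaussians for P(I|C);
    * ``texture_mean/cov``: per-class multivariate Gaussians for P(T|C);
    * ``delta_mean/var``: Gaussians for the center-minus-neighbor
      intensity difference per ordered class pair (antisymmetric means);
    * ``config_tables[k]``: Laplace-smoothed frequency of each size-k
      clique label multiset; the potential is m = -log frequency;
    * ``priors``: subject tissue priors (atlas has no lesion channel, a
      constant ``pi_les`` is mixed in at inference time).
    """

    intensity_mean: np.ndarray
    intensity_var: np.ndarray
    texture_mean: np.ndarray
    texture_cov: np.ndarray
    delta_mean: np.ndarray
    delta_var: np.ndarray
    config_tables: dict[int, dict[tuple[int, ...], float]]
    neighborhood: NeighborhoodSpec
    cliques: CliqueSet
    pi_les: float = 0.05
    priors: PriorMaps | None = None
    prob_floor: float = 1e-12

    def __post_init__(self):
        self.intensity_mean = np.asarray(self.intensity_mean, dtype=np.float64)
        self.intensity_var = np.asarray(self.intensity_var, dtype=np.float64)
        self.texture_mean = np.asarray(self.texture_mean, dtype=np.float64)
        self.texture_cov = np.asarray(self.texture_cov, dtype=np.float64)
        self.delta_mean = np.asarray(self.delta_mean, dtype=np.float64)
        self.delta_var = np.asarray(self.delta_var, dtype=np.float64)
        if np.any(self.intensity_var <= 0) or np.any(self.delta_var <= 0):
            raise ValueError("all variances must be > 0")
        # role symmetry: dI(i,j) = -dI(j,i) must see mirrored parameters,
        # otherwise ICM is not a descent on any well-defined total energy
        if not np.allclose(self.delta_mean, -self.delta_mean.T, atol=1e-8):
            raise ValueError("delta means must be antisymmetric in the class pair")
        if not np.allclose(self.delta_var, self.delta_var.T, atol=1e-8):
            raise ValueError("delta variances must be symmetric in the class pair")
        for c in range(_M):
            np.linalg.cholesky(self.texture_cov[c])  # raises if not PD
        for k, table in self.config_tables.items():
            total = sum(table.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ValueError(f"size-{k} configuration table is not normalized")

    @property
    def D(self) -> int:
        return self.texture_mean.shape[1]

    def potential(self, config: tuple[int, ...]) -> float:
        """m(C_k): negative log frequency of a clique label multiset."""
        table = self.config_tables[len(config)]
        return -math.log(max(table[tuple(sorted(config))], self.prob_floor))

    def dense_potentials(self, k: int, member_count: int) -> np.ndarray:
        """Potential lookup m[member_code, center_class] with positional codes.

        ``member_code`` encodes the member labels base-4 in clique member
        order; the potential itself depends only on the label multiset.
        """
        n = member_count
        out = np.empty((_M**n, _M))
        for code in range(_M**n):
            mem = tuple((code // _M**t) % _M for t in range(n))
            for c in range(_M):
                out[code, c] = self.potential(mem + (c,))
        return out

    def with_priors(self, priors: PriorMaps) -> "MRFModel":
        return replace(self, priors=priors)

    def to_yaml(self, path) -> None:
        payload = {
            "intensity_mean": self.intensity_mean.tolist(),
            "intensity_var": self.intensity_var.tolist(),
            "texture_mean": self.texture_mean.tolist(),
            "texture_cov": self.texture_cov.tolist(),
            "delta_mean": self.delta_mean.tolist(),
            "delta_var": self.delta_var.tolist(),
            "config_tables": {
                int(k): {",".join(map(str, cfg)): float(p) for cfg, p in tab.items()}
                for k, tab in self.config_tables.items()
            },
            "neighborhood": {
                "through_plane": self.neighborhood.through_plane,
                "clique_sizes": list(self.neighborhood.clique_sizes),
                "alpha": self.neighborhood.alpha,
            },
            "pi_les": self.pi_les,
            "prob_floor": self.prob_floor,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "MRFModel":
        with open(path) as fh:
            p = yaml.safe_load(fh)
        spec = NeighborhoodSpec(
            through_plane=p["neighborhood"]["through_plane"],
            clique_sizes=tuple(p["neighborhood"]["clique_sizes"]),
            alpha=p["neighborhood"]["alpha"],
        )
        tables = {
            int(k): {
                tuple(int(x) for x in cfg.split(",")): float(prob)
                for cfg, prob in tab.items()
            }
            for k, tab in p["config_tables"].items()
        }
        return cls(
            np.array(p["intensity_mean"]),
            np.array(p["intensity_var"]),
            np.array(p["texture_mean"]),
            np.array(p["texture_cov"]),
            np.array(p["delta_mean"]),
            np.array(p["delta_var"]),
            tables,
            spec,
            enumerate_cliques(spec),
            pi_les=p.get("pi_les", 0.05),
            prob_floor=p.get("prob_floor", 1e-12),
        )


def _shifted(arr: np.ndarray, off, fill):
    """arr sampled at voxel + off, with ``fill`` where the shift leaves the grid."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for d, o in enumerate(off):
        n = arr.shape[d]
        lo, hi = max(0, -o), min(n, n - o)
        if lo >= hi:
            return out
        dst.append(slice(lo, hi))
        src.append(slice(lo + o, hi + o))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def clique_config_counts(
    labels_list: list[np.ndarray], cliques: CliqueSet
) -> dict[int, dict[tuple[int, ...], int]]:
    """Empirical counts of clique label multisets, each physical clique once.

    Cliques touching the background sentinel or the volume border are
    skipped.  Returns {k: {sorted label tuple: count}} with every multiset
    present (zero counts included).
    """
    out: dict[int, dict[tuple, int]] = {}
    canonical = cliques.canonical_by_size()
    for k in cliques.sizes:
        counts = np.zeros(_M**k, dtype=np.int64)
        for lab in labels_list:
            for members in canonical[k]:
                stack = [lab] + [_shifted(lab, off, BACKGROUND) for off in members]
                stacked = np.stack([s.ravel() for s in stack])
                ok = (stacked >= 0).all(axis=0)
                if not ok.any():
                    continue
                cfg = np.sort(stacked[:, ok], axis=0).astype(np.int64)
                codes = sum(cfg[t] * _M**t for t in range(k))
                counts += np.bincount(codes, minlength=_M**k)
        table = {}
        for ms in itertools.combinations_with_replacement(range(_M), k):
            code = sum(ms[t] * _M**t for t in range(k))
            table[ms] = int(counts[code])
        out[k] = table
    return out


def train_mrf(
    volumes: list[Volume],
    features: list[FeatureVolume],
    labels: list[LabelMap],
    priors: PriorMaps | None = None,
    spec: NeighborhoodSpec | None = None,
    ridge: float = 1e-6,
    pi_les: float = 0.05,
) -> MRFModel:
    """Fit all MRF observation models and clique statistics from training data.

    Labels are quaternary ground truth with the -1 sentinel outside the
    brain.  Intensity-difference Gaussians are fitted over both directions
    of every neighbor relation (hence exactly antisymmetric); clique
    configuration tables are Laplace-smoothed multiset frequencies, each
    physical clique counted once.
    """
    if spec is None:
        spec = NeighborhoodSpec()
    if not (len(volumes) == len(features) == len(labels)):
        raise ValueError("volumes, features and labels must align")
    cliques = enumerate_cliques(spec)

    all_labels = np.concatenate([lm.labels.ravel() for lm in labels])
    present = set(np.unique(all_labels).tolist()) - {BACKGROUND}
    missing = [CLASS_NAMES[c] for c in range(_M) if c not in present]
    if missing:
        raise ValueError(f"training labels are missing class(es): {', '.join(missing)}")

    D = features[0].n_features
    intensity_mean = np.empty(_M)
    intensity_var = np.empty(_M)
    texture_mean = np.empty((_M, D))
    texture_cov = np.empty((_M, D, D))
    for c in range(_M):
        ivals = np.concatenate(
            [v.data[lm.labels == c] for v, lm in zip(volumes, labels)]
        )
        intensity_mean[c] = ivals.mean()
        intensity_var[c] = ivals.var() + max(ridge, 1e-12)
        tvals = np.concatenate(
            [fv.data[lm.labels == c] for fv, lm in zip(features, labels)]
        )
        texture_mean[c] = tvals.mean(axis=0)
        cov = np.cov(tvals, rowvar=False).reshape(D, D)
        cov_ridge = max(ridge, 1e-6 * float(np.trace(cov)) / D, 1e-12)
        texture_cov[c] = cov + cov_ridge * np.eye(D)

    # intensity-difference Gaussians over ordered class pairs
    n_pair = np.zeros((_M, _M))
    s_pair = np.zeros((_M, _M))
    ss_pair = np.zeros((_M, _M))
    for vol, lm in zip(volumes, labels):
        lab = lm.labels
        brain = lab >= 0
        for off in spec.offsets():
            lab_n = _shifted(lab, off, BACKGROUND)
            int_n = _shifted(vol.data, off, np.nan)
            ok = brain & (lab_n >= 0)
            ci = lab[ok].astype(np.int64)
            cj = lab_n[ok].astype(np.int64)
            d = vol.data[ok] - int_n[ok]
            idx = ci * _M + cj
            np.add.at(n_pair.ravel(), idx, 1.0)
            np.add.at(s_pair.ravel(), idx, d)
            np.add.at(ss_pair.ravel(), idx, d * d)
    with np.errstate(invalid="ignore", divide="ignore"):
        delta_mean = np.where(n_pair > 0, s_pair / np.maximum(n_pair, 1), 0.0)
        delta_var = np.where(
            n_pair > 1,
            ss_pair / np.maximum(n_pair, 1) - delta_mean**2,
            np.nan,
        )
    unseen = ~(n_pair > 1)
    if unseen.any():
        if ridge == 0:
            bad = np.argwhere(unseen)[0]
            raise ValueError(
                f"class pair ({CLASS_NAMES[bad[0]]}, {CLASS_NAMES[bad[1]]}) "
                "never co-occurs in training data and ridge is 0"
            )
        global_var = float(
            (ss_pair.sum() / max(n_pair.sum(), 1))
            - (s_pair.sum() / max(n_pair.sum(), 1)) ** 2
        )
        delta_var = np.where(unseen, max(global_var, ridge), delta_var)
    delta_var = np.maximum(delta_var, 1e-12) + ridge

    # clique label-configuration tables (multisets, Laplace smoothed)
    raw = clique_config_counts([lm.labels for lm in labels], cliques)
    config_tables: dict[int, dict[tuple, float]] = {}
    for k in spec.clique_sizes:
        counts = raw[k]
        total = sum(counts.values()) + len(counts)
        config_tables[k] = {
            ms: (counts[ms] + 1.0) / total for ms in counts
        }

    return MRFModel(
        intensity_mean,
        intensity_var,
        texture_mean,
        texture_cov,
        delta_mean,
        delta_var,
        config_tables,
        spec,
        cliques,
        pi_les=pi_les,
        priors=priors,
    )


def initial_labels(
    lesion_binary: LabelMap, priors: PriorMaps, brain_mask: LabelMap
) -> LabelMap:
    """Bridge the two-class initial estimate to the 4-class label field.

    Lesion voxels become Les; other brain voxels take the argmax of the
    CSF/GM/WM priors (exact ties break by fixed class order CSF < GM < WM);
    voxels outside the brain get the background sentinel.
    """
    if lesion_binary.shape != priors.shape or lesion_binary.shape != brain_mask.shape:
        raise ValueError("grids of lesion map, priors and brain mask must match")
    out = np.full(brain_mask.shape, BACKGROUND, dtype=np.int16)
    brain = brain_mask.labels > 0
    tissue = np.argmax(priors.data[:3], axis=0).astype(np.int16)
    out[brain] = tissue[brain]
    out[brain & (lesion_binary.labels > 0)] = LES
    return LabelMap(out, "quaternary", brain_mask.spacing)


@dataclass
class EnergyTrace:
    """Per-sweep record of ICM: total energy and label-change counts."""

    initial_energy: float
    energies: list[float] = field(default_factory=list)
    changes: list[int] = field(default_factory=list)
    max_iter: int = 10

    @property
    def n_sweeps(self) -> int:
        return len(self.energies)

    @property
    def converged(self) -> bool:
        return bool(self.changes) and self.changes[-1] == 0

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"sweep": range(1, self.n_sweeps + 1), "energy": self.energies,
             "label_changes": self.changes}
        ).to_csv(path, index=False)


class EnergyModel:
    """Precomputed energy machinery for one (volume, features, model) triple.

    Exposes the per-voxel conditional energy (the operative quantity of
    ICM) and the total field energy, in which unary terms are summed per
    voxel, every in-brain neighbor pair is counted once, and
    every clique potential is counted once.
    """

    def __init__(
        self,
        volume: Volume,
        features: FeatureVolume,
        model: MRFModel,
        priors: PriorMaps | None = None,
        brain_mask: np.ndarray | None = None,
    ):
        priors = priors if priors is not None else model.priors
        if priors is None:
            raise ValueError("tissue priors are required (model.priors or argument)")
        if np.all(priors.data[LES] == 0):
            priors = priors.with_lesion_prior(model.pi_les)
        self.model = model
        self.shape = volume.shape
        self.spacing = volume.spacing
        self.alpha = model.neighborhood.resolve_alpha(volume.spacing)
        brain = (
            priors.brain_mask() if brain_mask is None else np.asarray(brain_mask, bool)
        )
        self.brain_flat = brain.ravel()
        Q = self.brain_flat.size
        I = volume.data.ravel()

        # unary energies (Q, 4)
        unary = np.empty((Q, _M))
        F = features.data.reshape(Q, -1)
        for c in range(_M):
            v = model.intensity_var[c]
            unary[:, c] = 0.5 * (np.log(2 * np.pi * v) + (I - model.intensity_mean[c]) ** 2 / v)
            chol = cho_factor(model.texture_cov[c], lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
            diff = F - model.texture_mean[c]
            quad = np.einsum("nd,nd->n", diff, cho_solve(chol, diff.T).T)
            unary[:, c] += 0.5 * (model.D * _LOG2PI + logdet + quad)
            pc = priors.data[c].ravel()
            unary[:, c] += -np.log(np.clip(pc, model.prob_floor, None))
        self.unary = unary

        # neighbor slots
        offsets = model.neighborhood.offsets()
        self.n_slots = len(offsets)
        flat_idx = np.arange(Q).reshape(self.shape)
        nbr = np.empty((Q, self.n_slots), dtype=np.int64)
        dI = np.zeros((Q, self.n_slots))
        for s, off in enumerate(offsets):
            sh = _shifted(flat_idx, off, -1).ravel()
            valid = (sh >= 0) & self.brain_flat & self.brain_flat[sh.clip(min=0)]
            nbr[:, s] = np.where(valid, sh, -1)
            dI[:, s] = np.where(valid, I - I[sh.clip(min=0)], 0.0)
        self.nbr = nbr
        self.nbr_clipped = nbr.clip(min=0)
        self.valid_slot = nbr >= 0
        self.dI = dI

        # each in-brain neighbor pair carries exactly one dI factor
        self.w = self.valid_slot.astype(np.float64)

        # clique groups (for the configuration potentials m)
        slot_of = {off: s for s, off in enumerate(offsets)}
        groups = []
        for k in sorted(model.cliques.by_size):
            patterns = model.cliques.by_size[k]
            if not patterns:
                continue
            mem = np.array(
                [[slot_of[off] for off in pat] for pat in patterns], dtype=np.int64
            )
            valid = self.valid_slot[:, mem].all(axis=2)  # (Q, n_cliques_k)
            pow4 = _M ** np.arange(k - 1, dtype=np.int64)
            m_dense = model.dense_potentials(k, k - 1)
            groups.append((k, mem, pow4, valid, m_dense))
        self.cliq_groups = groups

        # pairwise Gaussian parameters
        self.c0 = 0.5 * np.log(2 * np.pi * model.delta_var)
        self.mu = model.delta_mean
        self.inv2 = 1.0 / (2.0 * model.delta_var)

    # -- per-voxel conditional ------------------------------------------------

    def energies4(self, q: int, labels_flat: np.ndarray) -> np.ndarray:
        """Conditional energy of voxel ``q`` for each of the 4 candidate labels."""
        Ls = labels_flat[self.nbr_clipped[q]]
        np.maximum(Ls, 0, out=Ls)
        d = self.dI[q]
        nld = self.c0[:, Ls] + (d - self.mu[:, Ls]) ** 2 * self.inv2[:, Ls]
        E = self.unary[q] + nld @ self.w[q]
        if self.alpha != 0.0:
            for k, mem, pow4, valid, m_dense in self.cliq_groups:
                vm = valid[q]
                if vm.any():
                    codes = (Ls[mem[vm]] * pow4).sum(axis=1)
                    E = E + self.alpha * m_dense[codes].sum(axis=0)
        return E

    def voxel_energy(self, index, labels_flat: np.ndarray) -> float:
        q = int(np.ravel_multi_index(index, self.shape)) if not np.isscalar(index) else int(index)
        if not self.brain_flat[q]:
            raise ValueError("voxel is outside the brain mask")
        c = int(labels_flat[q])
        return float(self.energies4(q, labels_flat)[c])

    # -- total field energy ---------------------------------------------------

    def total_energy(self, labels_flat: np.ndarray) -> float:
        brain = self.brain_flat
        lab = labels_flat.clip(min=0)
        total = float(self.unary[brain, lab[brain]].sum())
        ci = lab[:, None].repeat(self.n_slots, axis=1)
        cj = lab[self.nbr_clipped]
        nld = (
            self.c0[ci, cj] + (self.dI - self.mu[ci, cj]) ** 2 * self.inv2[ci, cj]
        )
        total += 0.5 * float((self.w * nld).sum())
        if self.alpha != 0.0:
            for k, mem, pow4, valid, m_dense in self.cliq_groups:
                codes = (lab[self.nbr_clipped[:, mem]] * pow4).sum(axis=2)
                vals = m_dense[codes, lab[:, None]]
                total += self.alpha / k * float(vals[valid].sum())
        return total

    def energies4_batch(self, q: int, labels_batch: np.ndarray) -> np.ndarray:
        """Conditional energies of voxel ``q`` under many labelings at once.

        ``labels_batch`` has shape (N, Q); returns (N, 4).  Intended for
        exhaustive scans of small problems.
        """
        lab = labels_batch.clip(min=0)
        Ls = lab[:, self.nbr_clipped[q]]  # (N, S)
        nld = (
            self.c0[:, Ls] + (self.dI[q] - self.mu[:, Ls]) ** 2 * self.inv2[:, Ls]
        )  # (4, N, S)
        E = self.unary[q][None, :] + np.einsum("cns,s->nc", nld, self.w[q])
        if self.alpha != 0.0:
            for k, mem, pow4, valid, m_dense in self.cliq_groups:
                vm = valid[q]
                if vm.any():
                    codes = (Ls[:, mem[vm]] * pow4).sum(axis=2)  # (N, nv)
                    E = E + self.alpha * m_dense[codes].sum(axis=1)
        return E

    def total_energy_batch(self, labels_batch: np.ndarray) -> np.ndarray:
        """Total field energy of many labelings at once ((N, Q) -> (N,))."""
        lab = labels_batch.clip(min=0)
        idx = np.flatnonzero(self.brain_flat)
        total = np.sum(
            self.unary[idx, :][np.arange(idx.size)[None, :], lab[:, idx]], axis=1
        )
        # pairwise (each in-brain pair once: sum both directions, halve)
        ci = lab[:, :, None]
        cj = lab[:, self.nbr_clipped]
        nld = self.c0[ci, cj] + (self.dI - self.mu[ci, cj]) ** 2 * self.inv2[ci, cj]
        total = total + 0.5 * (self.w * nld).sum(axis=(1, 2))
        if self.alpha != 0.0:
            for k, mem, pow4, valid, m_dense in self.cliq_groups:
                codes = (lab[:, self.nbr_clipped[:, mem]] * pow4).sum(axis=3)
                vals = m_dense[codes, lab[:, :, None]]
                total = total + self.alpha / k * (vals * valid).sum(axis=(1, 2))
        return total

    # -- inference ------------------------------------------------------------

    def icm(
        self, init_flat: np.ndarray, max_iter: int = 10, seed: int = 0
    ) -> tuple[np.ndarray, EnergyTrace]:
        labels = init_flat.copy()
        rng = np.random.default_rng(seed)
        brain_idx = np.flatnonzero(self.brain_flat)
        trace = EnergyTrace(self.total_energy(labels), max_iter=max_iter)
        for _ in range(max_iter):
            order = rng.permutation(brain_idx)
            changed = 0
            for q in order:
                E = self.energies4(q, labels)
                cur = labels[q]
                new = int(np.argmin(E))
                if E[new] < E[cur]:
                    labels[q] = new
                    changed += 1
            trace.energies.append(self.total_energy(labels))
            trace.changes.append(changed)
            if changed == 0:
                break
        return labels, trace


# small cache so the module-level energy functions can be called repeatedly
# (e.g. when scanning labelings) without rebuilding the workspace
_WORKSPACE_CACHE: list[tuple[tuple, EnergyModel]] = []


def _workspace(volume, features, model) -> EnergyModel:
    for (v, f, m), ws in _WORKSPACE_CACHE:
        if v is volume and f is features and m is model:
            return ws
    ws = EnergyModel(volume, features, model)
    _WORKSPACE_CACHE.append(((volume, features, model), ws))
    del _WORKSPACE_CACHE[:-4]
    return ws


def _labels_flat(labels) -> np.ndarray:
    arr = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    return arr.reshape(-1).astype(np.int64)


def voxel_energy(i, labels, volume, features, model, cliques=None) -> float:
    """Conditional MRF energy of voxel ``i`` under the current label field."""
    ws = _workspace(volume, features, model)
    return ws.voxel_energy(i, _labels_flat(labels))


def total_energy(labels, volume, features, model) -> float:
    """Total field energy (unary per voxel, shared clique terms counted once)."""
    ws = _workspace(volume, features, model)
    return ws.total_energy(_labels_flat(labels))


def icm_segment(
    volume: Volume,
    features: FeatureVolume,
    model: MRFModel,
    init: LabelMap,
    max_iter: int = 10,
    seed: int = 0,
    priors: PriorMaps | None = None,
) -> tuple[LabelMap, EnergyTrace]:
    """Asynchronous iterated conditional modes from the initial labelling.

    Brain voxels are visited in a fresh seeded random order each sweep and
    set to the label minimizing the conditional energy given the current
    neighbors (current label kept on exact ties).  Stops after a sweep
    with no change or after ``max_iter`` sweeps.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    brain = init.labels >= 0
    ws = EnergyModel(volume, features, model, priors=priors, brain_mask=brain)
    labels, trace = ws.icm(_labels_flat(init), max_iter=max_iter, seed=seed)
    out = labels.reshape(init.shape).astype(np.int16)
    out[~brain] = BACKGROUND
    return LabelMap(out, "quaternary", init.spacing), trace


def segment(
    volume: Volume,
    priors: PriorMaps,
    bank,
    bayes_model,
    model: MRFModel,
    brain_mask: LabelMap | None = None,
    max_iter: int = 10,
    seed: int = 0,
) -> LabelMap:
    """Full second-stage pipeline: Gabor transform, Bayesian initial estimate,
    4-class ICM refinement; returns the binary lesion mask."""
    result = segment_full(
        volume, priors, bank, bayes_model, model,
        brain_mask=brain_mask, max_iter=max_iter, seed=seed,
    )
    return result["lesion_mask"]


def segment_full(
    volume: Volume,
    priors: PriorMaps,
    bank,
    bayes_model,
    model: MRFModel,
    brain_mask: LabelMap | None = None,
    max_iter: int = 10,
    seed: int = 0,
) -> dict:
    from .bayes import classify_bayes
    from .gabor import transform_volume

    if brain_mask is None:
        brain_mask = LabelMap(
            priors.brain_mask().astype(np.int16), "binary", volume.spacing
        )
    features = transform_volume(volume, bank)
    bayes_mask, posterior = classify_bayes(features, bayes_model, brain_mask)
    init = initial_labels(bayes_mask, priors, brain_mask)
    labels, trace = icm_segment(
        volume, features, model, init, max_iter=max_iter, seed=seed, priors=priors
    )
    lesion = LabelMap(
        (labels.labels == LES).astype(np.int16), "binary", volume.spacing
    )
    return {
        "lesion_mask": lesion,
        "labels": labels,
        "init": init,
        "bayes_mask": bayes_mask,
        "posterior": posterior,
        "trace": trace,
        "features": features,
    }
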
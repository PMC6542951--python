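"""Independent brute-force oracles used by the test suite.

Every function here is a deliberately naive re-implementation (literal
loops, exhaustive enumeration) of an operation in the package, coded
against the mathematical definition rather than against the package
internals, so agreement is evidence of correctness.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# ---------------------------------------------------------------------------
# Gabor


def direct_convolution(slice2d: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """O(N^2 K^2) direct-sum 2-D convolution with reflection padding.

    Computes c[p] = sum_q s[p - q] k[q] over the kernel support, with the
    slice reflected at its borders, kernel centred on the output pixel.
    """
    hw = kernel.shape[0] // 2
    padded = np.pad(slice2d, hw, mode="reflect")
    out = np.zeros(slice2d.shape, dtype=np.complex128)
    n1, n2 = slice2d.shape
    for x in range(n1):
        for y in range(n2):
            acc = 0.0 + 0.0j
            for u in range(-hw, hw + 1):
                for v in range(-hw, hw + 1):
                    acc += padded[x - u + hw, y - v + hw] * kernel[u + hw, v + hw]
            out[x, y] = acc
    return out


def pairwise_separation(lesion: np.ndarray, nonlesion: np.ndarray) -> float:
    """Exhaustive double loop over all cross pairs of feature vectors."""
    dists = np.empty((len(lesion), len(nonlesion)))
    for j, cj in enumerate(lesion):
        for k, ck in enumerate(nonlesion):
            dists[j, k] = np.sqrt(((np.asarray(cj) - np.asarray(ck)) ** 2).sum())
    return float(dists.sum())


# ---------------------------------------------------------------------------
# Bayes


def two_gaussian_posterior(x, mu0, var0, mu1, var1, prior1):
    """Closed-form lesion posterior for scalar features, two Gaussian classes."""
    l0 = math.exp(-0.5 * (x - mu0) ** 2 / var0) / math.sqrt(2 * math.pi * var0)
    l1 = math.exp(-0.5 * (x - mu1) ** 2 / var1) / math.sqrt(2 * math.pi * var1)
    return prior1 * l1 / (prior1 * l1 + (1 - prior1) * l0)


# ---------------------------------------------------------------------------
# cliques


def cliques_bruteforce(offsets, adjacent, sizes=(2, 3, 4)):
    """All center-containing cliques by brute-force subset enumeration.

    ``offsets`` are the neighbor offsets, ``adjacent(u, v)`` the mutual
    adjacency predicate between neighbors (the center is adjacent to every
    neighbor by construction).  Returns {k: set of frozensets of offsets}.
    """
    out = {k: set() for k in sizes}
    for k in sizes:
        for members in itertools.combinations(offsets, k - 1):
            if all(adjacent(u, v) for u, v in itertools.combinations(members, 2)):
                out[k].add(frozenset(members))
    return out


# ---------------------------------------------------------------------------
# MRF energy (literal re-implementation of the per-voxel energy equation)


def _gauss_nll(x, mean, var):
    return 0.5 * math.log(2 * math.pi * var) + 0.5 * (x - mean) ** 2 / var


def _mvn_nll(x, mean, cov):
    d = np.asarray(x, dtype=float) - np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    k = len(d)
    sign, logdet = np.linalg.slogdet(cov)
    quad = float(d @ np.linalg.solve(cov, d))
    return 0.5 * (k * math.log(2 * math.pi) + logdet + quad)


def _in_bounds(idx, shape):
    return all(0 <= i < n for i, n in zip(idx, shape))


def voxel_cliques(i, shape, brain, cliques_by_size):
    """Cliques containing voxel ``i`` whose members all lie in the brain."""
    result = []
    for k, patterns in cliques_by_size.items():
        for members in patterns:
            abs_members = [tuple(np.add(i, off)) for off in members]
            if all(_in_bounds(m, shape) and brain[m] for m in abs_members):
                result.append((k, abs_members))
    return result


def literal_voxel_energy(i, c_i, labels, intensity, features, model, priors, alpha):
    """Literal per-voxel energy: unary terms, one pairwise intensity-difference
    likelihood per in-brain neighbor, and the clique potential sum.

    ``model`` is the package MRFModel (only its fitted parameters are
    used); everything is recomputed with plain loops and numpy solves.
    """
    shape = intensity.shape
    brain = labels >= 0
    u = _gauss_nll(intensity[i], model.intensity_mean[c_i], model.intensity_var[c_i])
    u += _mvn_nll(features[i], model.texture_mean[c_i], model.texture_cov[c_i])
    p_c = max(priors[(c_i,) + tuple(i)], model.prob_floor)
    u += -math.log(p_c)
    for off in model.neighborhood.offsets():
        j = tuple(np.add(i, off))
        if not _in_bounds(j, shape) or not brain[j]:
            continue
        c_j = labels[j]
        dI = intensity[i] - intensity[j]
        u += _gauss_nll(dI, model.delta_mean[c_i, c_j], model.delta_var[c_i, c_j])
    for k, members in voxel_cliques(i, shape, brain, model.cliques.by_size):
        config = tuple(sorted([c_i] + [labels[m] for m in members]))
        u += alpha * -math.log(max(model.config_tables[k][config], model.prob_floor))
    return u


def literal_total_energy(labels, intensity, features, model, priors, alpha):
    """Total field energy: unary per voxel; each in-brain neighbor pair and
    each clique potential counted once."""
    shape = intensity.shape
    brain = labels >= 0
    total = 0.0
    for i in np.argwhere(brain):
        i = tuple(i)
        c_i = labels[i]
        total += _gauss_nll(
            intensity[i], model.intensity_mean[c_i], model.intensity_var[c_i]
        )
        total += _mvn_nll(features[i], model.texture_mean[c_i], model.texture_cov[c_i])
        total += -math.log(max(priors[(c_i,) + i], model.prob_floor))
        for off in model.neighborhood.offsets():
            j = tuple(np.add(i, off))
            if not _in_bounds(j, shape) or not brain[j]:
                continue
            c_j = labels[j]
            dI = intensity[i] - intensity[j]
            total += 0.5 * _gauss_nll(
                dI, model.delta_mean[c_i, c_j], model.delta_var[c_i, c_j]
            )
        for k, members in voxel_cliques(i, shape, brain, model.cliques.by_size):
            config = tuple(sorted([c_i] + [labels[m] for m in members]))
            m_pot = -math.log(max(model.config_tables[k][config], model.prob_floor))
            total += alpha * m_pot / k  # clique seen from each of its k members
    return total


# ---------------------------------------------------------------------------
# random MRF instances (valid under the model's symmetry requirements)


def random_mrf_model(rng, D=2, spec=None):
    """A random but internally consistent MRFModel for energy/ICM stress tests."""
    from flairseg.mrf import MRFModel, NeighborhoodSpec, enumerate_cliques

    spec = spec or NeighborhoodSpec()
    intensity_mean = np.sort(rng.uniform(0.0, 1.0, 4))
    intensity_var = rng.uniform(0.005, 0.05, 4)
    texture_mean = rng.uniform(0.0, 3.0, (4, D))
    covs = []
    for _ in range(4):
        a = rng.normal(size=(D, D))
        covs.append(a @ a.T / D + 0.2 * np.eye(D))
    r = rng.normal(scale=0.2, size=(4, 4))
    delta_mean = r - r.T
    v = rng.uniform(0.01, 0.1, (4, 4))
    delta_var = (v + v.T) / 2
    tables = {}
    for k in spec.clique_sizes:
        ms = list(itertools.combinations_with_replacement(range(4), k))
        p = rng.uniform(0.2, 1.0, len(ms))
        p /= p.sum()
        tables[k] = dict(zip(ms, p))
    return MRFModel(
        intensity_mean, intensity_var, texture_mean, np.array(covs),
        delta_mean, delta_var, tables, spec, enumerate_cliques(spec),
    )


def random_problem(rng, shape, D=2, spacing=(1.0, 1.0, 2.0)):
    """Random volume, features and normalized priors on a small grid."""
    from flairseg import FeatureVolume, PriorMaps, Volume

    vol = Volume(rng.uniform(0, 1, shape), spacing)
    channels = tuple(("r", 0, d) for d in range(D))
    feats = FeatureVolume(rng.uniform(0, 3, shape + (D,)), spacing, channels)
    p = rng.uniform(0.1, 1.0, (4,) + shape)
    priors = PriorMaps(p / p.sum(axis=0), spacing)
    return vol, feats, priors


class CachedEnergyOracle:
    """Literal-structure energy oracle with precomputed scalar terms.

    Enumerates voxels, neighbors and cliques explicitly like
    :func:`literal_voxel_energy`, but computes every Gaussian log density and
    clique potential once up front so that exhaustive sweeps over all
    labelings of tiny problems stay cheap.  Shares no code with the
    package's vectorized energy implementation.
    """

    def __init__(self, intensity, features, model, priors, alpha):
        shape = intensity.shape
        self.alpha = alpha
        self.voxels = [tuple(v) for v in np.argwhere(np.ones(shape, bool))]
        self.index = {v: n for n, v in enumerate(self.voxels)}
        # unary[v][c]
        self.unary = [
            [
                _gauss_nll(intensity[v], model.intensity_mean[c], model.intensity_var[c])
                + _mvn_nll(features[v], model.texture_mean[c], model.texture_cov[c])
                - math.log(max(priors[(c,) + v], model.prob_floor))
                for c in range(4)
            ]
            for v in self.voxels
        ]
        # neighbor lists and pairwise tables: pair_nll[v][j][ci][cj]
        offsets = model.neighborhood.offsets()
        self.neighbors = []
        self.pair_nll = []
        for v in self.voxels:
            nbrs, tables = [], []
            for off in offsets:
                j = tuple(np.add(v, off))
                if not _in_bounds(j, shape):
                    continue
                nbrs.append(self.index[j])
                d = intensity[v] - intensity[j]
                tables.append(
                    [
                        [
                            _gauss_nll(d, model.delta_mean[ci, cj], model.delta_var[ci, cj])
                            for cj in range(4)
                        ]
                        for ci in range(4)
                    ]
                )
            self.neighbors.append(nbrs)
            self.pair_nll.append(tables)
        # clique member lists (voxel indices) and potential-by-multiset
        self.m_pot = {
            k: {cfg: -math.log(max(p, model.prob_floor)) for cfg, p in tab.items()}
            for k, tab in model.config_tables.items()
        }
        brain = np.ones(shape, bool)
        self.voxel_cliqs = []
        for v in self.voxels:
            entries = []
            for k, members in voxel_cliques(v, shape, brain, model.cliques.by_size):
                entries.append((k, [self.index[m] for m in members]))
            self.voxel_cliqs.append(entries)

    def voxel_energy(self, n, labels_flat):
        c = labels_flat[n]
        u = self.unary[n][c]
        for j, tab in zip(self.neighbors[n], self.pair_nll[n]):
            u += tab[c][labels_flat[j]]
        for k, members in self.voxel_cliqs[n]:
            config = tuple(sorted([c] + [labels_flat[m] for m in members]))
            u += self.alpha * self.m_pot[k][config]
        return u

    def total_energy(self, labels_flat):
        total = 0.0
        for n in range(len(self.voxels)):
            c = labels_flat[n]
            total += self.unary[n][c]
            for j, tab in zip(self.neighbors[n], self.pair_nll[n]):
                total += 0.5 * tab[c][labels_flat[j]]
            for k, members in self.voxel_cliqs[n]:
                config = tuple(sorted([c] + [labels_flat[m] for m in members]))
                total += self.alpha * self.m_pot[k][config] / k
        return total


# ---------------------------------------------------------------------------
# clique configuration counting


def clique_config_counts_bruteforce(labels, cliques_by_size):
    """Count each physical clique's label multiset once, by explicit loops."""
    shape = labels.shape
    brain = labels >= 0
    counts = {k: {} for k in cliques_by_size}
    seen = set()
    for i in np.argwhere(brain):
        i = tuple(i)
        for k, members in voxel_cliques(i, shape, brain, cliques_by_size):
            voxels = frozenset([i] + [tuple(m) for m in members])
            if voxels in seen:
                continue
            seen.add(voxels)
            config = tuple(sorted(labels[v] for v in voxels))
            counts[k][config] = counts[k].get(config, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# evaluation


def border_voxels(mask: np.ndarray):
    """Mask voxels with at least one non-mask face neighbor (or at the edge)."""
    out = []
    for p in np.argwhere(mask):
        p = tuple(p)
        for d in range(3):
            for s in (-1, 1):
                q = list(p)
                q[d] += s
                q = tuple(q)
                if not _in_bounds(q, mask.shape) or not mask[q]:
                    out.append(p)
                    break
            else:
                continue
            break
    return out


def surface_distances_bruteforce(a: np.ndarray, m: np.ndarray, spacing):
    """All-pairs border-to-border ASD and Hausdorff distance."""
    pa = border_voxels(a)
    pm = border_voxels(m)
    sp = np.asarray(spacing, dtype=float)

    def directed(src, dst):
        mins = []
        for p in src:
            best = math.inf
            for q in dst:
                d = math.sqrt((((np.array(p) - np.array(q)) * sp) ** 2).sum())
                best = min(best, d)
            mins.append(best)
        return mins

    d_am = directed(pa, pm)
    d_ma = directed(pm, pa)
    asd = 0.5 * (sum(d_am) / len(d_am) + sum(d_ma) / len(d_ma))
    hd = max(max(d_am), max(d_ma))
    return asd, hd


def flood_fill_components(mask: np.ndarray):
    """Connected components under 26-connectivity by explicit flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        comp = []
        stack = [start]
        seen[start] = True
        while stack:
            p = stack.pop()
            comp.append(p)
            for off in itertools.product((-1, 0, 1), repeat=3):
                if off == (0, 0, 0):
                    continue
                q = tuple(np.add(p, off))
                if _in_bounds(q, mask.shape) and mask[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
        comps.append(comp)
    return comps
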
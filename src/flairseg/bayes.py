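"""Two-class Bayesian MAP classification of Gabor feature vectors.

The initial lesion estimate treats every brain voxel as a draw from one
of two multivariate Gaussians (lesion / non-lesion) over the Gabor
coefficient vector; the posterior is likelihood x prior, normalized over
the two classes.  Priors are the training class frequencies (the
registered atlas carries no lesion channel).  All computation is done in
the log domain; ties resolve to non-lesion so the initialization stays
conservative and the MRF stage refines upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy.linalg import cho_factor, cho_solve

from .gabor import FeatureVolume
from .volume import LabelMap, Volume

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class GaussianClassModel:
    """Gaussian class-conditional models for (non-lesion, lesion)."""

    means: np.ndarray  # (2, D)
    covariances: np.ndarray  # (2, D, D)
    priors: np.ndarray  # (2,)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=np.float64)
        self.covariances = np.asarray(self.covariances, dtype=np.float64)
        self.priors = np.asarray(self.priors, dtype=np.float64)
        if self.means.shape != (2, self.D) or self.covariances.shape != (2, self.D, self.D):
            raise ValueError("model shapes are inconsistent")
        if self.priors.shape != (2,) or np.any(self.priors <= 0) or np.any(self.priors >= 1):
            raise ValueError("priors must lie in (0, 1)")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        for c in range(2):
            cov = self.covariances[c]
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise ValueError("covariances must be symmetric")
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as err:
                raise ValueError(
                    f"class {c} covariance is not positive-definite; "
                    "increase the ridge or use more training voxels"
                ) from err

    @property
    def D(self) -> int:
        return self.means.shape[1]

    def log_likelihoods(self, x: np.ndarray) -> np.ndarray:
        """Per-class Gaussian log densities for feature rows ``x`` (N, D)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        out = np.empty((x.shape[0], 2))
        for c in range(2):
            chol = cho_factor(self.covariances[c], lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
            diff = x - self.means[c]
            quad = np.einsum("nd,nd->n", diff, cho_solve(chol, diff.T).T)
            out[:, c] = -0.5 * (self.D * _LOG2PI + logdet + quad)
        return out

    def to_yaml(self, path) -> None:
        payload = {
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "priors": self.priors.tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "GaussianClassModel":
        with open(path) as fh:
            p = yaml.safe_load(fh)
        return cls(np.array(p["means"]), np.array(p["covariances"]), np.array(p["priors"]))


def fit_bayes(
    features: list[FeatureVolume],
    labels: list[LabelMap],
    ridge: float = 1e-6,
    brain_masks: list[np.ndarray] | None = None,
) -> GaussianClassModel:
    """Fit the two-class Gaussian model from labelled feature volumes.

    Class means and covariances are sample statistics over in-mask voxels
    (``covariance += ridge * I``); priors are the class voxel frequencies.
    """
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if len(features) != len(labels):
        raise ValueError("one label map per feature volume is required")
    rows = {0: [], 1: []}
    for i, (fv, lm) in enumerate(zip(features, labels)):
        if lm.scheme != "binary":
            raise ValueError("fit_bayes expects binary lesion label maps")
        mask = np.ones(fv.shape, dtype=bool) if brain_masks is None else brain_masks[i].astype(bool)
        flat = fv.data.reshape(-1, fv.n_features)
        lab = lm.labels.ravel()
        sel = mask.ravel()
        rows[1].append(flat[sel & (lab > 0)])
        rows[0].append(flat[sel & (lab == 0)])
    D = features[0].n_features
    means = np.empty((2, D))
    covs = np.empty((2, D, D))
    counts = np.empty(2)
    for c in (0, 1):
        x = np.concatenate(rows[c], axis=0)
        counts[c] = x.shape[0]
        if x.shape[0] == 0:
            raise ValueError(f"no training voxels for class {c}: both classes are required")
        if x.shape[0] < D + 1:
            raise ValueError(
                f"class {c} has {x.shape[0]} voxels for D={D} features; "
                "use a larger ridge or a diagonal covariance"
            )
        means[c] = x.mean(axis=0)
        covs[c] = np.cov(x, rowvar=False) + ridge * np.eye(D)
    return GaussianClassModel(means, covs, counts / counts.sum())


def classify_bayes(
    features: FeatureVolume, model: GaussianClassModel, brain_mask: LabelMap
) -> tuple[LabelMap, Volume]:
    """MAP-classify every brain voxel; ties resolve to non-lesion.

    Returns the binary lesion map and the per-voxel lesion posterior
    (zero outside the brain mask).
    """
    if model.D != features.n_features:
        raise ValueError(
            f"model dimension {model.D} does not match features ({features.n_features})"
        )
    mask = brain_mask.labels.ravel() > 0
    flat = features.data.reshape(-1, features.n_features)
    post = np.zeros(flat.shape[0])
    if mask.any():
        logp = model.log_likelihoods(flat[mask]) + np.log(model.priors)
        # log-sum-exp normalization over the two classes
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        post[mask] = p[:, 1] / p.sum(axis=1)
    lesion = (post > 0.5).astype(np.int16).reshape(features.shape)
    lesion[brain_mask.labels == 0] = 0
    return (
        LabelMap(lesion, "binary", features.spacing),
        Volume(post.reshape(features.shape), features.spacing),
    )
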
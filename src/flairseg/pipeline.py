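"""Orchestration of the full segmentation flow and the leave-one-out harness.

The per-case flow is: intensity standardization and bias handling, the
multi-window Gabor transform, two-class Bayesian initialization, and
4-class MRF refinement by asynchronous ICM.  ``run_loocv`` wraps it in a
leave-one-case-out loop: for every held-out case the Bayesian and MRF
models are trained on the remaining cases only, the held-out case is
segmented, and the result is scored against its ground truth.  The Gabor
window parameters are deliberately NOT re-optimized inside the loop —
they are either supplied (optimized on disjoint data) or left at the
bank defaults — mirroring how texture parameters are transferred
between databases rather than tuned per fold.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bayes import fit_bayes
from .evaluation import CaseMetrics, spearman_rho
from .gabor import GaborBankSpec, transform_volume
from .mrf import NeighborhoodSpec, segment_full, train_mrf
from .phantom import PhantomCase
from .preprocessing import compute_standard_scale, preprocess
from .volume import LabelMap, Volume


@dataclass
class RunConfig:
    """Configuration of a leave-one-out run."""

    bank: GaborBankSpec = field(default_factory=GaborBankSpec)
    neighborhood: NeighborhoodSpec = field(default_factory=NeighborhoodSpec)
    seed: int = 0
    max_iter: int = 10
    pi_les: float = 0.05
    ridge: float = 1e-6
    bayes_ridge: float = 1e-6
    standardize: bool = True
    bias: str = "internal"
    smoothness_mm: float = 20.0
    output_dir: str | None = None


@dataclass
class LoocvResult:
    """Per-case and aggregate outcome of a leave-one-out evaluation."""

    per_case: pd.DataFrame
    aggregate: pd.Series
    traces: list
    fold_hashes: list[str]

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.per_case.to_csv(out_dir / "per_case.csv", index=False)
        self.aggregate.to_frame().T.to_csv(out_dir / "aggregate.csv", index=False)
        for i, trace in enumerate(self.traces):
            trace.to_csv(out_dir / f"energy_trace_case{i}.csv")


def _fold_hash(cases: list[PhantomCase]) -> str:
    """Hash of the training inputs of one fold (guards against leakage)."""
    h = hashlib.sha256()
    for case in cases:
        h.update(np.ascontiguousarray(case.flair.data).tobytes())
        h.update(np.ascontiguousarray(case.truth.labels).tobytes())
    return h.hexdigest()[:16]


def _preprocessed_volumes(cases, config: RunConfig, train_idx) -> list[Volume]:
    """Standardize every case on a scale learned from the training cases."""
    if not config.standardize:
        return [c.flair for c in cases]
    scale = compute_standard_scale(
        [cases[i].flair for i in train_idx],
        [cases[i].brain_mask for i in train_idx],
    )
    return [
        preprocess(c.flair, c.brain_mask, scale, bias=config.bias,
                   smoothness_mm=config.smoothness_mm)
        for c in cases
    ]


def run_loocv(cases: list[PhantomCase], config: RunConfig | None = None) -> LoocvResult:
    """Leave-one-case-out evaluation of the full pipeline.

    For each fold, preprocessing statistics and both classifiers are fit
    on the training cases only; the held-out case is segmented end to end
    and scored.  Per-case metrics, the aggregate (mean over cases plus
    the Spearman correlation of automatic vs. true lesion volumes), the
    ICM energy traces and a hash of each fold's training inputs are
    returned; ``config.output_dir`` additionally writes them as CSV.
    """
    if config is None:
        config = RunConfig()
    if len(cases) < 3:
        raise ValueError("leave-one-out needs at least 3 cases")

    rows, traces, hashes = [], [], []
    for test_idx in range(len(cases)):
        train_idx = [i for i in range(len(cases)) if i != test_idx]
        hashes.append(_fold_hash([cases[i] for i in train_idx]))

        volumes = _preprocessed_volumes(cases, config, train_idx)
        train_feats = [transform_volume(volumes[i], config.bank) for i in train_idx]
        train_lesions = [cases[i].lesion_mask for i in train_idx]
        train_truths = [cases[i].truth for i in train_idx]
        train_brains = [cases[i].truth.labels >= 0 for i in train_idx]

        bayes_model = fit_bayes(
            train_feats, train_lesions, ridge=config.bayes_ridge,
            brain_masks=train_brains,
        )
        mrf_model = train_mrf(
            [volumes[i] for i in train_idx],
            train_feats,
            train_truths,
            spec=config.neighborhood,
            ridge=config.ridge,
            pi_les=config.pi_les,
        )

        case = cases[test_idx]
        result = segment_full(
            volumes[test_idx],
            case.priors,
            config.bank,
            bayes_model,
            mrf_model,
            brain_mask=case.brain_mask,
            max_iter=config.max_iter,
            seed=config.seed + test_idx,
        )
        metrics = CaseMetrics.compute(
            f"case{test_idx}", result["lesion_mask"], case.lesion_mask
        )
        rows.append(vars(metrics))
        traces.append(result["trace"])

    per_case = pd.DataFrame(rows)
    agg = per_case.drop(columns=["case"]).mean(numeric_only=True)
    agg["dice_sd"] = per_case["dice"].std()
    agg["n_cases"] = len(cases)
    try:
        agg["spearman_volumes"] = spearman_rho(
            per_case["vol_auto_ml"].to_numpy(), per_case["vol_manual_ml"].to_numpy()
        )
    except ValueError:  # degenerate volume ranks
        agg["spearman_volumes"] = float("nan")
    result = LoocvResult(per_case, agg, traces, hashes)
    if config.output_dir:
        result.write(config.output_dir)
        manifest = {
            "seed": config.seed,
            "max_iter": config.max_iter,
            "fold_hashes": hashes,
            "n_cases": len(cases),
        }
        with open(Path(config.output_dir) / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return result
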
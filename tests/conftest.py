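import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import flairseg as fs


@pytest.fixture(scope="session")
def default_phantom() -> fs.PhantomCase:
    """One phantom case at the default study conditions (shared, read-only)."""
    return fs.generate_phantom(fs.PhantomConfig(seed=11))


@pytest.fixture(scope="session")
def mini_config() -> fs.PhantomConfig:
    """Small, fast phantom configuration for plumbing tests."""
    return fs.PhantomConfig(
        shape=(32, 32, 10),
        lesion_volume_ml=5.0,
        confounder_count=1,
        seed=0,
    )


@pytest.fixture(scope="session")
def mini_cohort(mini_config) -> list[fs.PhantomCase]:
    return fs.generate_cohort(3, mini_config, seed=5)


@pytest.fixture(scope="session")
def mini_bank() -> fs.GaborBankSpec:
    """A small Gabor bank whose kernels fit the mini phantom slices."""
    return fs.GaborBankSpec(
        sigma_x=(1.5, 3.0),
        sigma_y=(1.5, 3.0),
        frequency_shifts=(
            ((0, 0),),
            ((0, 0), (1, 0), (0, 1), (1, 1), (1, -1)),
        ),
    )


@pytest.fixture(scope="session")
def trained_mini(mini_cohort, mini_bank):
    """Bayes + MRF models trained on the mini cohort (features included)."""
    feats = [fs.transform_volume(c.flair, mini_bank) for c in mini_cohort]
    brains = [c.truth.labels >= 0 for c in mini_cohort]
    bayes = fs.fit_bayes(
        feats, [c.lesion_mask for c in mini_cohort], brain_masks=brains
    )
    mrf = fs.train_mrf(
        [c.flair for c in mini_cohort], feats, [c.truth for c in mini_cohort]
    )
    return {"features": feats, "bayes": bayes, "mrf": mrf}
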
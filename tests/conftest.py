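import numpy as np
import pytest

from sorptherm.data_model import Branch, FitStatistics, SorptionDataset, SorptionPoint
from sorptherm.isotherm_models import ModelParams, evaluate_raw
from sorptherm.model_fitting import IsothermFit


def make_group(model_id, values, T=298.15, branch=Branch.ADSORPTION, n=15,
               aw_lo=0.09, aw_hi=0.83, noise_sd=0.0, seed=0):
    """Noiseless (or noisy) single-(branch, T) dataset generated from a model."""
    aw = np.linspace(aw_lo, aw_hi, n)
    xe = np.asarray(evaluate_raw(model_id, values, aw, T=T), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        xe = np.clip(xe + rng.normal(0, noise_sd, xe.size), 0, None)
    pts = [SorptionPoint(float(a), float(x), T, branch) for a, x in zip(aw, xe)]
    return SorptionDataset(points=pts)


def make_fit(model_id, values, T, branch=Branch.ADSORPTION):
    """IsothermFit wrapper around known-true parameters (stats are dummies)."""
    stats = FitStatistics(
        r2_regression=1.0, r2_standard=1.0, sse=0.0, e_percent=0.0, n_points=3
    )
    return IsothermFit(
        model_id=model_id,
        branch=branch,
        T=T,
        params=ModelParams(model_id, tuple(values), T_for_eval=T),
        stats=stats,
        converged=True,
        n_starts_used=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
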
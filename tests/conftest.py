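import numpy as np
import pytest

from earlyonset import (
    McmcSettings,
    ScenarioConfig,
    StandardCurve,
    fit_standard_curve,
    generate_reference_pairs,
)

#: short chains for desk-scale tests; long enough for stable summaries
SHORT = McmcSettings(chains=2, burn_in=400, samples=1500, seed=11)


def make_degenerate_curve(alpha=50.0, beta=0.5, sigma=0.0, n_draws=20_000,
                          sex="male", seed=0) -> StandardCurve:
    """Curve whose posterior is a point mass at (alpha, beta) with noise sd sigma."""
    tau = 1.0 / sigma**2 if sigma > 0 else 1e12
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=(1, n_draws)) if sigma > 0 else np.zeros((1, n_draws))
    return StandardCurve(
        alpha=np.full((1, n_draws), float(alpha)),
        beta=np.full((1, n_draws), float(beta)),
        tau=np.full((1, n_draws), tau),
        eps=eps,
        reference_ids=("R0", "R1", "R2"),
        sex=sex,
        x_ref=np.array([40.0, 45.0, 50.0]),
        y_ref=np.array([alpha + beta * x for x in (40.0, 45.0, 50.0)]),
    )


@pytest.fixture(scope="session")
def reference_pairs():
    pairs, _ = generate_reference_pairs(ScenarioConfig(seed=42))
    return pairs


@pytest.fixture(scope="session")
def fitted_curve(reference_pairs):
    return fit_standard_curve(reference_pairs, settings=SHORT)
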
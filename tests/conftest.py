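import numpy as np
import pytest

from activetravel.model import PosteriorDraws
from activetravel.schema import CITY_COVARIATES, COUNTRY_COVARIATES
from activetravel.simulate import PRESETS, generate_dataset


def manual_draws(
    beta: np.ndarray,
    alpha: np.ndarray | None = None,
    delta: np.ndarray | None = None,
    Z: np.ndarray | None = None,
    phi: float = 50.0,
    outcome: str = "walk",
    registry: dict | None = None,
) -> PosteriorDraws:
    """Build a PosteriorDraws object with fully specified parameter values.

    ``beta`` has shape (D, J, K). Everything unspecified defaults to zero,
    so predictions reduce to inverse-logit of the chosen pieces.
    """
    beta = np.asarray(beta, dtype=float)
    D, J, K = beta.shape
    alpha = np.zeros((D, J)) if alpha is None else np.asarray(alpha, dtype=float)
    M = len(COUNTRY_COVARIATES)
    delta = np.zeros((D, M)) if delta is None else np.asarray(delta, dtype=float)
    Z = np.zeros((J, M)) if Z is None else np.asarray(Z, dtype=float)
    reg = {k: (0.0, 1.0) for k in CITY_COVARIATES + COUNTRY_COVARIATES}
    if registry:
        reg.update(registry)
    return PosteriorDraws(
        outcome=outcome,
        alpha=alpha,
        beta=beta,
        gamma0=beta.mean(axis=1),
        gamma1=np.zeros((D, K, 1)),
        delta=delta,
        tau=np.zeros((D, K)),
        phi=np.full(D, phi),
        a=alpha.mean(axis=1),
        sigma_alpha=np.full(D, 0.1),
        Z=Z,
        city_covariates=CITY_COVARIATES[:K],
        country_covariates=COUNTRY_COVARIATES,
        moderators=("ln_gdp_pc",),
        country_ids=[f"C{j:03d}" for j in range(J)],
        registry=reg,
        diagnostics={"max_rhat": 1.0, "min_ess": float("inf")},
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(PRESETS["tiny"])


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(PRESETS["small"])


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A quick (reduced-draw) posterior fit of the small synthetic dataset,
    shared by effect- and scenario-level tests that need realistic draws."""
    from activetravel.model import ModelSpec, fit
    from activetravel.schema import prepare_model_inputs

    cities, countries, truth = small_dataset
    design, shares, modeled = prepare_model_inputs(cities, countries)
    posts = {}
    for i, outcome in enumerate(("walk", "cycle")):
        spec = ModelSpec(outcome=outcome, chains=2, warmup=400, draws=300,
                         seed=100 + i, check_convergence=False)
        posts[outcome] = fit(spec, design, shares[outcome])
    return {"design": design, "shares": shares, "modeled": modeled,
            "draws": posts, "truth": truth, "cities": cities, "countries": countries}
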
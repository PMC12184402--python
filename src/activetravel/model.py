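"""Hierarchical Bayesian beta regression for city mode shares.

One model per outcome (walk or cycle km share on the transit-excluded
denominator). For city i in country j with standardized city covariates
x_i and country covariates z_j:

    y_i   ~ Beta(mu_i * phi, (1 - mu_i) * phi)
    logit(mu_i) = alpha_j + sum_k beta_jk x_ik + sum_m delta_m z_jm
    alpha_j ~ Normal(a, sigma_alpha^2)
    beta_jk ~ Normal(gamma0_k + sum_m gamma1_km z_jm', tau_k^2)

where the moderators z' (by default only standardized ln GDP per capita)
shift the expected country slope: the cross-level interaction. phi is a
global precision; larger phi concentrates shares around mu.

Priors (all overridable through :class:`ModelSpec`): Normal(0, 2) on the
global intercept a and on delta, Normal(0, 1) on gamma0 and gamma1,
half-Normal(0, 1) on tau and sigma_alpha, Exponential(rate 0.1) on phi.

Posterior sampling is by an adaptive Metropolis-within-Gibbs scheme:
country intercepts and slopes update by vectorized random-walk Metropolis
(countries are conditionally independent given the hyperparameters),
gamma0/gamma1 and the global intercept by exact conjugate Normal draws,
the scale parameters by univariate slice sampling, and delta/phi by
random-walk Metropolis. Proposal scales adapt during warmup only, so the
kept draws form a valid Markov chain. Split-chain R-hat and effective
sample size are computed with arviz and gate the fit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
from scipy.special import expit, gammaln, logit

from .schema import CITY_COVARIATES, COUNTRY_COVARIATES, DesignMatrix

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when the sampler fails the R-hat / effective-sample-size gate."""


def beta_logpdf(y, mu, phi):
    """Log-density of Beta(mu*phi, (1-mu)*phi) — the mean–precision form.

    ``y`` and ``mu`` must lie in the open interval (0, 1) and ``phi`` must
    be positive. Vectorizes over any argument.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("y must lie strictly inside (0, 1)")
    if np.any((mu <= 0) | (mu >= 1)):
        raise ValueError("mu must lie strictly inside (0, 1)")
    if np.any(phi <= 0):
        raise ValueError("phi must be > 0")
    a = mu * phi
    b = (1.0 - mu) * phi
    out = (gammaln(phi) - gammaln(a) - gammaln(b)
           + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))
    return out if out.shape else float(out)


@dataclass
class ModelSpec:
    """Configuration of one outcome's hierarchical beta regression."""

    outcome: str = "walk"
    city_covariates: tuple[str, ...] = CITY_COVARIATES
    country_covariates: tuple[str, ...] = COUNTRY_COVARIATES
    moderators: tuple[str, ...] = ("ln_gdp_pc",)
    prior_scales: dict[str, float] = field(default_factory=lambda: {
        "intercept": 2.0, "delta": 2.0, "gamma0": 1.0, "gamma1": 1.0,
        "tau": 1.0, "sigma_alpha": 1.0, "phi_rate": 0.1,
    })
    chains: int = 2
    warmup: int = 1000
    draws: int = 3000
    seed: int = 0
    rhat_threshold: float = 1.05
    ess_threshold: float = 100.0
    check_convergence: bool = True

    def validate(self) -> None:
        for name, lst in (("city_covariates", self.city_covariates),
                          ("country_covariates", self.country_covariates)):
            if not lst:
                raise ValueError(f"{name} must be nonempty")
            if len(set(lst)) != len(lst):
                raise ValueError(f"{name} contains duplicates")
        for m in self.moderators:
            if m not in self.country_covariates:
                raise ValueError(f"moderator {m!r} not among country covariates")
        if any(s <= 0 for s in self.prior_scales.values()):
            raise ValueError("prior scales must be > 0")


@dataclass
class PosteriorDraws:
    """Joint posterior draws of all model parameters for one outcome.

    Arrays are flattened over chains: the first axis has
    ``chains * draws`` entries. ``diagnostics`` carries max split R-hat and
    min bulk ESS over all monitored parameters.
    """

    outcome: str
    alpha: np.ndarray        # (D, J) country intercepts, logit scale
    beta: np.ndarray         # (D, J, K) country slopes per city covariate
    gamma0: np.ndarray       # (D, K) slope hyper-means
    gamma1: np.ndarray       # (D, K, M') moderation coefficients
    delta: np.ndarray        # (D, M) country-covariate main effects
    tau: np.ndarray          # (D, K) between-country slope SDs
    phi: np.ndarray          # (D,) beta precision
    a: np.ndarray            # (D,) global intercept
    sigma_alpha: np.ndarray  # (D,) country-intercept SD
    Z: np.ndarray            # (J, M) standardized country covariates used in the fit
    city_covariates: tuple[str, ...]
    country_covariates: tuple[str, ...]
    moderators: tuple[str, ...]
    country_ids: list[str]
    registry: dict[str, tuple[float, float]]
    diagnostics: dict
    seed: int

    @property
    def n_draws(self) -> int:
        return self.phi.shape[0]

    @property
    def z_terms(self) -> np.ndarray:
        """(D, J) country fixed-effect contribution delta @ Z per draw."""
        return self.delta @ self.Z.T

    def moderator_values(self, moderator: str) -> np.ndarray:
        """Standardized values of one country covariate, per country."""
        try:
            m = self.country_covariates.index(moderator)
        except ValueError:
            raise KeyError(f"{moderator!r} not among fitted country covariates") from None
        return self.Z[:, m]

    def country_pos(self, country_id: str) -> int:
        try:
            return self.country_ids.index(country_id)
        except ValueError:
            raise KeyError(f"country {country_id!r} not in fitted model") from None

    def save(self, store_dir) -> None:
        """Persist draws (npz) plus a JSON manifest to a directory."""
        d = Path(store_dir)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / f"{self.outcome}_draws.npz",
                 alpha=self.alpha, beta=self.beta, gamma0=self.gamma0,
                 gamma1=self.gamma1, delta=self.delta, tau=self.tau,
                 phi=self.phi, a=self.a, sigma_alpha=self.sigma_alpha,
                 Z=self.Z)
        manifest = {
            "outcome": self.outcome,
            "city_covariates": list(self.city_covariates),
            "country_covariates": list(self.country_covariates),
            "moderators": list(self.moderators),
            "country_ids": self.country_ids,
            "registry": {k: list(v) for k, v in self.registry.items()},
            "diagnostics": self.diagnostics,
            "seed": self.seed,
            "n_draws": self.n_draws,
        }
        (d / f"{self.outcome}_manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=1))

    @classmethod
    def load(cls, store_dir, outcome: str) -> "PosteriorDraws":
        d = Path(store_dir)
        manifest = json.loads((d / f"{outcome}_manifest.json").read_text())
        arrays = np.load(d / f"{outcome}_draws.npz")
        return cls(
            outcome=outcome,
            alpha=arrays["alpha"], beta=arrays["beta"], gamma0=arrays["gamma0"],
            gamma1=arrays["gamma1"], delta=arrays["delta"], tau=arrays["tau"],
            phi=arrays["phi"], a=arrays["a"], sigma_alpha=arrays["sigma_alpha"],
            Z=arrays["Z"],
            city_covariates=tuple(manifest["city_covariates"]),
            country_covariates=tuple(manifest["country_covariates"]),
            moderators=tuple(manifest["moderators"]),
            country_ids=manifest["country_ids"],
            registry={k: tuple(v) for k, v in manifest["registry"].items()},
            diagnostics=manifest["diagnostics"],
            seed=manifest["seed"],
        )


def linear_predictor(draws: PosteriorDraws, x_row: np.ndarray, country_id: str) -> np.ndarray:
    """Logit-scale predictor for one design row, per posterior draw.

    ``x_row`` holds the standardized city covariates in the fitted order.
    The country's own covariate values (from the fit) enter through the
    stored delta coefficients.
    """
    j = draws.country_pos(country_id)
    x_row = np.asarray(x_row, dtype=float)
    return (draws.alpha[:, j]
            + draws.beta[:, j, :] @ x_row
            + draws.z_terms[:, j])


def posterior_predict(
    draws: PosteriorDraws, x_row: np.ndarray, country_id: str,
    sample_observation: bool = False, rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Predicted mean share mu per draw (optionally with beta noise)."""
    mu = expit(linear_predictor(draws, x_row, country_id))
    if not sample_observation:
        return mu
    rng = rng or np.random.default_rng()
    return rng.beta(mu * draws.phi, (1.0 - mu) * draws.phi)


# ---------------------------------------------------------------------------
# Sampler internals


def _slice_sample_positive(logp, x0: float, rng: np.random.Generator,
                           w: float = 0.5, max_steps: int = 50) -> float:
    """One slice-sampling update of a positive scalar (stepping-out + shrink)."""
    logy = logp(x0) + np.log(rng.random())
    u = rng.random() * w
    lo, hi = x0 - u, x0 + (w - u)
    lo = max(lo, 1e-12)
    for _ in range(max_steps):
        if lo <= 1e-12 or logp(lo) < logy:
            break
        lo = max(lo - w, 1e-12)
    for _ in range(max_steps):
        if logp(hi) < logy:
            break
        hi += w
    for _ in range(max_steps):
        x1 = rng.uniform(lo, hi)
        if logp(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


class _GibbsState:
    """Mutable sampler state for one chain."""

    def __init__(self, y, X, Z, cidx, W, spec, rng):
        self.y, self.X, self.Z, self.cidx, self.W = y, X, Z, cidx, W
        self.spec = spec
        self.rng = rng
        self.n, self.K = X.shape
        self.J = Z.shape[0]
        self.Mm = W.shape[1] - 1  # moderator count (W has a leading 1s column)
        self.M = Z.shape[1]
        self.log_y = np.log(y)
        self.log1m_y = np.log1p(-y)
        self.counts = np.bincount(cidx, minlength=self.J)

        # initialization from empirical logits
        ly = logit(y)
        self.a = float(ly.mean())
        sums = np.bincount(cidx, weights=ly, minlength=self.J)
        self.alpha = sums / np.maximum(self.counts, 1)
        self.alpha[self.counts == 0] = self.a
        self.sigma_alpha = max(float(self.alpha.std()), 0.05)
        self.beta = np.zeros((self.J, self.K))
        self.gamma0 = np.zeros(self.K)
        self.gamma1 = np.zeros((self.K, self.Mm))
        self.delta = np.zeros(self.M)
        self.tau = np.full(self.K, 0.1)
        mu0 = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
        v = max(float(y.var()), 1e-6)
        self.phi = float(np.clip(mu0 * (1 - mu0) / v - 1.0, 2.0, 500.0))

        # strongly correlated covariate pairs (e.g. tmin and tmin^2) define
        # ridge directions the per-coordinate walks traverse slowly; they
        # get dedicated joint moves along the low-information direction
        corr = np.corrcoef(X.T) if self.K > 1 else np.ones((1, 1))
        self.pairs = [
            (k1, k2, np.array([1.0, -np.sign(corr[k1, k2])]) / np.sqrt(2.0))
            for k1 in range(self.K) for k2 in range(k1 + 1, self.K)
            if abs(corr[k1, k2]) > 0.8
        ]

        # adaptive proposal scales
        self.s_alpha = np.full(self.J, 0.1)
        self.s_beta = np.full((self.J, self.K), 0.1)
        self.s_delta = 0.05
        self.s_phi = 0.1
        self.s_pair = np.full((len(self.pairs), self.J), 0.2)
        self.s_pair_hyper = np.full(len(self.pairs), 0.1)
        self.acc_pair = np.zeros((len(self.pairs), self.J))
        self.acc_pair_hyper = np.zeros(len(self.pairs))
        self.s_gamma0 = np.full(self.K, 0.05)
        self.s_gamma1 = np.full((self.K, self.Mm), 0.05)
        self.s_a = 0.05
        self.acc_alpha = np.zeros(self.J)
        self.acc_beta = np.zeros((self.J, self.K))
        self.acc_delta = 0.0
        self.acc_phi = 0.0
        self.acc_gamma0 = np.zeros(self.K)
        self.acc_gamma1 = np.zeros((self.K, self.Mm))
        self.acc_a = 0.0

    # -- likelihood helpers -------------------------------------------------

    def eta(self, alpha=None, beta=None, delta=None):
        alpha = self.alpha if alpha is None else alpha
        beta = self.beta if beta is None else beta
        delta = self.delta if delta is None else delta
        return (alpha[self.cidx]
                + np.einsum("ik,ik->i", self.X, beta[self.cidx])
                + (self.Z @ delta)[self.cidx])

    def loglik_rows(self, eta, phi=None):
        phi = self.phi if phi is None else phi
        mu = expit(eta)
        a = mu * phi
        b = phi - a
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (gammaln(phi) - gammaln(a) - gammaln(b)
                  + (a - 1.0) * self.log_y + (b - 1.0) * self.log1m_y)
        return np.where((a > 0) & (b > 0), ll, -np.inf)

    def country_loglik(self, eta, phi=None):
        return np.bincount(self.cidx, weights=self.loglik_rows(eta, phi),
                           minlength=self.J)

    # -- updates ------------------------------------------------------------

    def update_alpha(self):
        prop = self.alpha + self.s_alpha * self.rng.standard_normal(self.J)
        cur_ll = self.country_loglik(self.eta())
        new_ll = self.country_loglik(self.eta(alpha=prop))
        pr_cur = -0.5 * ((self.alpha - self.a) / self.sigma_alpha) ** 2
        pr_new = -0.5 * ((prop - self.a) / self.sigma_alpha) ** 2
        accept = np.log(self.rng.random(self.J)) < (new_ll + pr_new) - (cur_ll + pr_cur)
        self.alpha = np.where(accept, prop, self.alpha)
        self.acc_alpha += accept

    def update_beta(self):
        mean_beta = self.gamma0[None, :] + self.W[:, 1:] @ self.gamma1.T  # (J, K)
        for k in self.rng.permutation(self.K):
            prop = self.beta.copy()
            prop[:, k] = self.beta[:, k] + self.s_beta[:, k] * self.rng.standard_normal(self.J)
            cur_ll = self.country_loglik(self.eta())
            new_ll = self.country_loglik(self.eta(beta=prop))
            tk = max(self.tau[k], 1e-8)
            pr_cur = -0.5 * ((self.beta[:, k] - mean_beta[:, k]) / tk) ** 2
            pr_new = -0.5 * ((prop[:, k] - mean_beta[:, k]) / tk) ** 2
            accept = np.log(self.rng.random(self.J)) < (new_ll + pr_new) - (cur_ll + pr_cur)
            self.beta[:, k] = np.where(accept, prop[:, k], self.beta[:, k])
            self.acc_beta[:, k] += accept

    def update_beta_pairs(self):
        # joint move of a correlated slope pair along its ridge direction,
        # vectorized across countries
        mean_beta = self.gamma0[None, :] + self.W[:, 1:] @ self.gamma1.T
        for p, (k1, k2, v) in enumerate(self.pairs):
            e = self.s_pair[p] * self.rng.standard_normal(self.J)
            prop = self.beta.copy()
            prop[:, k1] += e * v[0]
            prop[:, k2] += e * v[1]
            cur_ll = self.country_loglik(self.eta())
            new_ll = self.country_loglik(self.eta(beta=prop))
            pr = np.zeros(self.J)
            for k, col in ((k1, 0), (k2, 1)):
                tk = max(self.tau[k], 1e-8)
                pr += (-0.5 * ((prop[:, k] - mean_beta[:, k]) / tk) ** 2
                       + 0.5 * ((self.beta[:, k] - mean_beta[:, k]) / tk) ** 2)
            accept = np.log(self.rng.random(self.J)) < (new_ll - cur_ll) + pr
            self.beta[:, k1] = np.where(accept, prop[:, k1], self.beta[:, k1])
            self.beta[:, k2] = np.where(accept, prop[:, k2], self.beta[:, k2])
            self.acc_pair[p] += accept

    def update_hyper_slopes(self):
        # conjugate Normal draw for (gamma0_k, gamma1_k.) given beta[:, k]
        sc = self.spec.prior_scales
        P0 = np.diag([1.0 / sc["gamma0"] ** 2] + [1.0 / sc["gamma1"] ** 2] * self.Mm)
        WtW = self.W.T @ self.W
        for k in range(self.K):
            tk2 = max(self.tau[k], 1e-8) ** 2
            prec = WtW / tk2 + P0
            cov = np.linalg.inv(prec)
            mean = cov @ (self.W.T @ self.beta[:, k]) / tk2
            g = self.rng.multivariate_normal(mean, cov, method="cholesky")
            self.gamma0[k] = g[0]
            self.gamma1[k] = g[1:]

    def update_tau(self):
        sc = self.spec.prior_scales["tau"]
        mean_beta = self.gamma0[None, :] + self.W[:, 1:] @ self.gamma1.T
        for k in range(self.K):
            r2 = float(np.sum((self.beta[:, k] - mean_beta[:, k]) ** 2))

            def logp(t, r2=r2):
                return (-self.J * np.log(t) - 0.5 * r2 / t ** 2
                        - 0.5 * (t / sc) ** 2)

            self.tau[k] = _slice_sample_positive(logp, max(self.tau[k], 1e-6),
                                                 self.rng, w=0.2)

    def update_intercept_hypers(self):
        sc = self.spec.prior_scales
        # conjugate draw for the global intercept a
        prec = self.J / self.sigma_alpha ** 2 + 1.0 / sc["intercept"] ** 2
        mean = (self.alpha.sum() / self.sigma_alpha ** 2) / prec
        self.a = mean + self.rng.standard_normal() / np.sqrt(prec)
        # slice draw for sigma_alpha (half-Normal prior)
        r2 = float(np.sum((self.alpha - self.a) ** 2))

        def logp(s):
            return -self.J * np.log(s) - 0.5 * r2 / s ** 2 - 0.5 * (s / sc["sigma_alpha"]) ** 2

        self.sigma_alpha = _slice_sample_positive(logp, self.sigma_alpha, self.rng, w=0.2)

    # -- interweaving (non-centered) moves -----------------------------------
    # The centered updates above mix poorly when tau or sigma_alpha is small
    # (the hierarchical funnel): slopes are pinned to their hyper-mean and
    # the scale cannot move. Re-expressing the state as standardized
    # residuals u = (beta - mean)/tau and updating the hyperparameters with
    # the residuals held fixed moves the whole block through the likelihood,
    # which mixes well precisely in the small-scale regime. Alternating both
    # parameterizations each sweep (an interweaving strategy) is valid MCMC
    # and covers both regimes.

    def update_hypers_noncentered(self):
        sc = self.spec.prior_scales
        mean_beta = self.gamma0[None, :] + self.W[:, 1:] @ self.gamma1.T

        # gamma0_k: shift all of country slopes' column k through the likelihood
        for k in range(self.K):
            shift = self.s_gamma0[k] * self.rng.standard_normal()
            prop = self.beta.copy()
            prop[:, k] += shift
            g_new = self.gamma0[k] + shift
            cur = (float(self.loglik_rows(self.eta()).sum())
                   - 0.5 * (self.gamma0[k] / sc["gamma0"]) ** 2)
            new = (float(self.loglik_rows(self.eta(beta=prop)).sum())
                   - 0.5 * (g_new / sc["gamma0"]) ** 2)
            if np.log(self.rng.random()) < new - cur:
                self.beta = prop
                self.gamma0[k] = g_new
                self.acc_gamma0[k] += 1

        # joint hyper-mean move along each correlated pair's ridge direction
        for p, (k1, k2, v) in enumerate(self.pairs):
            e = self.s_pair_hyper[p] * self.rng.standard_normal()
            prop = self.beta.copy()
            prop[:, k1] += e * v[0]
            prop[:, k2] += e * v[1]
            g1n, g2n = self.gamma0[k1] + e * v[0], self.gamma0[k2] + e * v[1]
            cur = (float(self.loglik_rows(self.eta()).sum())
                   - 0.5 * (self.gamma0[k1] ** 2 + self.gamma0[k2] ** 2)
                   / sc["gamma0"] ** 2)
            new = (float(self.loglik_rows(self.eta(beta=prop)).sum())
                   - 0.5 * (g1n ** 2 + g2n ** 2) / sc["gamma0"] ** 2)
            if np.log(self.rng.random()) < new - cur:
                self.beta = prop
                self.gamma0[k1], self.gamma0[k2] = g1n, g2n
                self.acc_pair_hyper[p] += 1

        # gamma1_km: tilt column k along the moderator through the likelihood
        for k in range(self.K):
            for m in range(self.Mm):
                shift = self.s_gamma1[k, m] * self.rng.standard_normal()
                prop = self.beta.copy()
                prop[:, k] += shift * self.W[:, 1 + m]
                g_new = self.gamma1[k, m] + shift
                cur = (float(self.loglik_rows(self.eta()).sum())
                       - 0.5 * (self.gamma1[k, m] / sc["gamma1"]) ** 2)
                new = (float(self.loglik_rows(self.eta(beta=prop)).sum())
                       - 0.5 * (g_new / sc["gamma1"]) ** 2)
                if np.log(self.rng.random()) < new - cur:
                    self.beta = prop
                    self.gamma1[k, m] = g_new
                    self.acc_gamma1[k, m] += 1

        # tau_k: rescale the standardized slope residuals through the likelihood
        mean_beta = self.gamma0[None, :] + self.W[:, 1:] @ self.gamma1.T
        for k in range(self.K):
            tk = max(self.tau[k], 1e-10)
            u = (self.beta[:, k] - mean_beta[:, k]) / tk

            def logp(t, k=k, u=u):
                prop = self.beta.copy()
                prop[:, k] = mean_beta[:, k] + t * u
                return (float(self.loglik_rows(self.eta(beta=prop)).sum())
                        - 0.5 * (t / sc["tau"]) ** 2)

            t_new = _slice_sample_positive(logp, tk, self.rng, w=0.1)
            self.beta[:, k] = mean_beta[:, k] + t_new * u
            self.tau[k] = t_new

        # global intercept a: translate all country intercepts
        shift = self.s_a * self.rng.standard_normal()
        prop_alpha = self.alpha + shift
        a_new = self.a + shift
        cur = (float(self.loglik_rows(self.eta()).sum())
               - 0.5 * (self.a / sc["intercept"]) ** 2)
        new = (float(self.loglik_rows(self.eta(alpha=prop_alpha)).sum())
               - 0.5 * (a_new / sc["intercept"]) ** 2)
        if np.log(self.rng.random()) < new - cur:
            self.alpha = prop_alpha
            self.a = a_new
            self.acc_a += 1

        # sigma_alpha: rescale standardized intercept residuals
        sig = max(self.sigma_alpha, 1e-10)
        u = (self.alpha - self.a) / sig

        def logp_sig(s):
            return (float(self.loglik_rows(self.eta(alpha=self.a + s * u)).sum())
                    - 0.5 * (s / sc["sigma_alpha"]) ** 2)

        s_new = _slice_sample_positive(logp_sig, sig, self.rng, w=0.1)
        self.alpha = self.a + s_new * u
        self.sigma_alpha = s_new

    def update_delta_interweave(self):
        # likelihood depends on alpha_j + (Z delta)_j only; holding that sum
        # fixed, delta has an exact Gaussian conditional from the priors.
        sc = self.spec.prior_scales
        psi = self.alpha + self.Z @ self.delta
        prec = (self.Z.T @ self.Z) / self.sigma_alpha ** 2 + np.eye(self.M) / sc["delta"] ** 2
        cov = np.linalg.inv(prec)
        mean = cov @ (self.Z.T @ (psi - self.a)) / self.sigma_alpha ** 2
        self.delta = self.rng.multivariate_normal(mean, cov, method="cholesky")
        self.alpha = psi - self.Z @ self.delta

    def update_delta(self):
        sc = self.spec.prior_scales["delta"]
        prop = self.delta + self.s_delta * self.rng.standard_normal(self.M)
        cur = (float(self.loglik_rows(self.eta()).sum())
               - 0.5 * float(np.sum((self.delta / sc) ** 2)))
        new = (float(self.loglik_rows(self.eta(delta=prop)).sum())
               - 0.5 * float(np.sum((prop / sc) ** 2)))
        if np.log(self.rng.random()) < new - cur:
            self.delta = prop
            self.acc_delta += 1

    def update_phi(self):
        rate = self.spec.prior_scales["phi_rate"]
        prop = self.phi * np.exp(self.s_phi * self.rng.standard_normal())
        # Exponential(rate) prior; log-scale proposal carries a log-Jacobian
        cur = (float(self.loglik_rows(self.eta()).sum())
               - rate * self.phi + np.log(self.phi))
        new = (float(self.loglik_rows(self.eta(), phi=prop).sum())
               - rate * prop + np.log(prop))
        if np.log(self.rng.random()) < new - cur:
            self.phi = prop
            self.acc_phi += 1

    def adapt(self, batch: int, batch_size: int, inner_repeats: int = 3):
        step = min(0.1, 1.0 / np.sqrt(batch + 1))
        for acc, scale, target in (
            (self.acc_alpha, self.s_alpha, 0.44),
            (self.acc_beta, self.s_beta, 0.44),
            (self.acc_pair, self.s_pair, 0.44),
        ):
            rate = acc / (batch_size * inner_repeats)
            scale *= np.exp(np.where(rate > target, step, -step))
            acc[:] = 0.0
        for acc, scale, target in (
            (self.acc_gamma0, self.s_gamma0, 0.44),
            (self.acc_gamma1, self.s_gamma1, 0.44),
            (self.acc_pair_hyper, self.s_pair_hyper, 0.44),
        ):
            rate = acc / batch_size
            scale *= np.exp(np.where(rate > target, step, -step))
            acc[:] = 0.0
        for name, target in (("delta", 0.25), ("phi", 0.44), ("a", 0.44)):
            rate = getattr(self, f"acc_{name}") / batch_size
            setattr(self, f"s_{name}",
                    getattr(self, f"s_{name}") * np.exp(step if rate > target else -step))
            setattr(self, f"acc_{name}", 0.0)

    def sweep(self, inner_repeats: int = 3):
        # the per-coordinate random walks are the slowest-mixing block;
        # repeating them within a sweep is cheaper than whole extra sweeps
        for _ in range(inner_repeats):
            self.update_alpha()
            self.update_beta()
            self.update_beta_pairs()
        self.update_hyper_slopes()
        self.update_tau()
        self.update_intercept_hypers()
        self.update_delta()
        self.update_hypers_noncentered()
        self.update_delta_interweave()
        self.update_phi()


def log_likelihood(y, design: DesignMatrix, alpha, beta, delta, phi,
                   city_covariates=CITY_COVARIATES,
                   country_covariates=COUNTRY_COVARIATES) -> float:
    """Total beta log-likelihood of shares ``y`` under one parameter set."""
    X = design.X[:, [CITY_COVARIATES.index(k) for k in city_covariates]]
    Z = design.Z[:, [COUNTRY_COVARIATES.index(m) for m in country_covariates]]
    c = design.country_index
    eta = alpha[c] + np.einsum("ik,ik->i", X, np.asarray(beta)[c]) + (Z @ delta)[c]
    return float(np.sum(beta_logpdf(y, expit(eta), phi)))


def fit(spec: ModelSpec, design: DesignMatrix, shares: np.ndarray) -> PosteriorDraws:
    """Sample the posterior of the hierarchical beta regression.

    ``shares`` must be row-aligned with ``design`` and already shrunk away
    from the 0/1 boundary. Raises :class:`ConvergenceError` when any
    monitored parameter fails the split R-hat / ESS gate (disable with
    ``spec.check_convergence = False`` for exploratory runs).
    """
    spec.validate()
    y = np.asarray(shares, dtype=float)
    if y.shape[0] != design.n_cities:
        raise ValueError("shares and design are not row-aligned")
    if np.any((y <= 0) | (y >= 1)):
        bad = np.where((y <= 0) | (y >= 1))[0]
        raise ValueError(f"shares at rows {bad.tolist()} lie on the boundary; "
                         "apply shrink_boundary first")

    kcols = [CITY_COVARIATES.index(k) for k in spec.city_covariates]
    mcols = [COUNTRY_COVARIATES.index(m) for m in spec.country_covariates]
    X = design.X[:, kcols]
    Z = design.Z[:, mcols]
    W = np.column_stack(
        [np.ones(design.n_countries)]
        + [design.Z[:, COUNTRY_COVARIATES.index(m)] for m in spec.moderators])

    eta0 = logit(np.clip(y, 1e-6, 1 - 1e-6))
    if not np.all(np.isfinite(eta0)):
        raise ValueError("non-finite empirical logits at initialization")

    chains = []
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    batch_size = 50
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        st = _GibbsState(y, X, Z, design.country_index, W, spec, rng)
        keep = {k: [] for k in ("alpha", "beta", "gamma0", "gamma1", "delta",
                                "tau", "phi", "a", "sigma_alpha")}
        for it in range(spec.warmup + spec.draws):
            st.sweep()
            if it < spec.warmup and (it + 1) % batch_size == 0:
                st.adapt(it // batch_size, batch_size)
            if it >= spec.warmup:
                keep["alpha"].append(st.alpha.copy())
                keep["beta"].append(st.beta.copy())
                keep["gamma0"].append(st.gamma0.copy())
                keep["gamma1"].append(st.gamma1.copy())
                keep["delta"].append(st.delta.copy())
                keep["tau"].append(st.tau.copy())
                keep["phi"].append(st.phi)
                keep["a"].append(st.a)
                keep["sigma_alpha"].append(st.sigma_alpha)
        chains.append({k: np.array(v) for k, v in keep.items()})
        logger.info("chain %d finished (%d kept draws)", c, spec.draws)

    stacked = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}  # (C, D, ...)
    idata = az.from_dict(posterior=stacked)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    max_rhat = float(max(np.nanmax(rhat[v].values) for v in rhat.data_vars))
    min_ess = float(min(np.nanmin(ess[v].values) for v in ess.data_vars))
    diagnostics = {"max_rhat": max_rhat, "min_ess": min_ess,
                   "chains": spec.chains, "draws_per_chain": spec.draws}
    logger.info("fit(%s): max R-hat %.4f, min ESS %.1f", spec.outcome, max_rhat, min_ess)
    if spec.check_convergence and (max_rhat > spec.rhat_threshold
                                   or min_ess < spec.ess_threshold):
        raise ConvergenceError(
            f"sampler failed convergence gate: max R-hat {max_rhat:.4f} "
            f"(limit {spec.rhat_threshold}), min ESS {min_ess:.1f} "
            f"(limit {spec.ess_threshold}); increase warmup/draws")

    flat = {k: np.concatenate([ch[k] for ch in chains], axis=0) for k in chains[0]}
    return PosteriorDraws(
        outcome=spec.outcome,
        alpha=flat["alpha"], beta=flat["beta"], gamma0=flat["gamma0"],
        gamma1=flat["gamma1"], delta=flat["delta"], tau=flat["tau"],
        phi=flat["phi"], a=flat["a"], sigma_alpha=flat["sigma_alpha"],
        city_covariates=tuple(spec.city_covariates),
        country_covariates=tuple(spec.country_covariates),
        moderators=tuple(spec.moderators),
        country_ids=list(design.country_ids),
        registry=dict(design.registry),
        Z=Z,
        diagnostics=diagnostics,
        seed=spec.seed,
    )
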
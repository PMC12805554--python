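"""Bayesian MCMC for the joint outcome / treatment / proxy model.

The sampler is a pure Gibbs scheme: every full conditional is conjugate.

* the binary (or graded-indicator) treatment enters through probit data
  augmentation — each treatment indicator is the sign of a latent Gaussian
  index with unit variance (identification normalization);
* the non-spatial confounder ``U`` (factor scores, prior N(0, I_q), the
  second identification normalization) is sampled row-wise from the normal
  conditional combining the outcome, treatment-index, and proxy likelihoods;
* regression coefficient blocks are joint normal updates;
* the factor loading sign is pinned by flipping any column of ``alpha_wu``
  whose first entry goes negative (together with ``U`` and the matching
  entries of ``alpha_yu`` / ``alpha_au``);
* the per-city spline coefficients ``lambda`` are multivariate normal
  updates shared between the outcome and all treatment equations;
* variances get inverse-gamma updates; the random-effect spread ``tau``
  (half-normal prior) is drawn by gridded inverse-CDF sampling.

Three model variants share this machinery:

``latent_adjustment``
    the full model (U + proxies + spatial term);
``outcome_regression_proxy``
    drops U; proxies enter the outcome regression as fixed covariates;
``no_adjustment``
    drops U and the proxies entirely.  Both baselines retain the spatial
    spline term.

WAIC is computed from the *outcome* model's pointwise log-likelihoods only.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
from scipy.special import logsumexp

from .data_model import RegionTable, TreatmentDesign
from .identification import Assumption5Result, check_assumption5  # re-export
from .updates import (
    sample_normal_regression,
    sample_scale_gridded,
    sample_truncated_normal,
    sample_variance,
)

__all__ = [
    "Priors", "FitConfig", "PosteriorDraws", "fit", "waic", "ate_summary",
    "check_assumption5", "Assumption5Result", "GibbsSampler", "split_rhat",
    "rhat", "plot_trace",
]

VARIANTS = ("latent_adjustment", "outcome_regression_proxy", "no_adjustment")


@dataclasses.dataclass
class Priors:
    """Default weakly informative priors (overridable via config files)."""

    coef_scale: float = 10.0   # N(0, coef_scale^2) on every regression coefficient
    var_shape: float = 0.1     # IG(var_shape, var_rate) on variances
    var_rate: float = 0.1
    tau_scale: float = 5.0     # half-N(0, tau_scale) on the random-effect spread


@dataclasses.dataclass
class FitConfig:
    """MCMC controls for one model fit."""

    variant: str = "latent_adjustment"
    effect: str = "constant"            # or "random" (per-city effects)
    q: int = 1
    r: float = 0.4
    n_burn: int = 50_000
    n_keep: int = 50_000
    thin: int = 10
    priors: Priors = dataclasses.field(default_factory=Priors)
    seed: int | None = None
    fixed: dict = dataclasses.field(default_factory=dict)
    store_latent: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.effect not in ("constant", "random"):
            raise ValueError("effect must be 'constant' or 'random'")
        if min(self.n_burn, self.n_keep) < 1 or self.thin < 1:
            raise ValueError("n_burn, n_keep >= 1 and thin >= 1 required")
        if self.variant == "latent_adjustment" and self.q < 1:
            raise ValueError("latent_adjustment requires q >= 1")

    def replace(self, **kw) -> "FitConfig":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws, pointwise outcome log-likelihoods, WAIC."""

    draws: dict
    loglik: np.ndarray
    waic: float
    config: FitConfig
    effect_names: tuple
    cities: list
    diagnostics: dict = dataclasses.field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.loglik.shape[0]

    def effect_draws(self) -> np.ndarray:
        """(n_draws, K) draws of the estimand (population mean in random mode)."""
        key = "theta_bar" if self.config.effect == "random" else "theta"
        return self.draws[key]


def waic(draws: PosteriorDraws, table: RegionTable | None = None) -> float:
    """WAIC = -2 (lppd - p_waic) from the outcome model's pointwise log-liks."""
    ll = draws.loglik if isinstance(draws, PosteriorDraws) else np.asarray(draws, dtype=float)
    if ll.shape[0] < 2:
        raise ValueError("need at least 2 draws to compute WAIC")
    lppd = float(np.sum(logsumexp(ll, axis=0) - math.log(ll.shape[0])))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic)


def ate_summary(draws: PosteriorDraws, level: float = 0.95) -> dict:
    """Posterior mean and equal-tailed credible interval per effect.

    In random-effect mode the population mean ``theta_bar`` is summarized
    per effect and per-city summaries are attached under ``"cities"``.
    """
    if draws.n_draws < 2:
        raise ValueError("need at least 2 draws")
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2

    def _summ(x):
        return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)),
                "ci_low": float(np.percentile(x, lo)), "ci_high": float(np.percentile(x, hi))}

    th = draws.effect_draws()
    out = {name: _summ(th[:, k]) for k, name in enumerate(draws.effect_names)}
    if draws.config.effect == "random":
        tc = draws.draws["theta_city"]  # (n_draws, M, K)
        out["cities"] = {
            (city.item() if isinstance(city, np.generic) else city):
                {name: _summ(tc[:, i, k]) for k, name in enumerate(draws.effect_names)}
            for i, city in enumerate(draws.cities)
        }
    return out


def rhat(chains) -> float:
    """Potential scale reduction factor across chains of equal length."""
    x = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = x.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 chains of length >= 2")
    W = x.var(axis=1, ddof=1).mean()
    B = n * x.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + B / (W * n)))


def split_rhat(chain: np.ndarray) -> float:
    """Split-R-hat of a single chain (halves treated as two chains)."""
    x = np.asarray(chain, dtype=float).ravel()
    half = x.size // 2
    return rhat(np.stack([x[:half], x[half:2 * half]]))


def plot_trace(draws: PosteriorDraws, path, names=("theta", "sigma2_y")) -> None:
    """Write trace plots of selected scalar chains (convergence monitoring)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    present = [n for n in names if n in draws.draws]
    fig, axes = plt.subplots(len(present), 1, figsize=(8, 2.2 * len(present)),
                             squeeze=False)
    for ax, name in zip(axes[:, 0], present):
        arr = np.asarray(draws.draws[name])
        ax.plot(arr.reshape(arr.shape[0], -1), lw=0.5)
        ax.set_ylabel(name)
    axes[-1, 0].set_xlabel("retained draw")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def fit(table: RegionTable, bases: Mapping | None, design: TreatmentDesign,
        config: FitConfig) -> PosteriorDraws:
    """Run the Gibbs sampler and return thinned posterior draws plus WAIC."""
    return GibbsSampler(table, bases, design, config).run()


class GibbsSampler:
    """One MCMC run; see the module docstring for the block structure."""

    def __init__(self, table, bases, design, config):
        self.config = config
        self.priors = config.priors
        self.rng = np.random.default_rng(config.seed)
        self.y = table.outcome()
        self.A = np.asarray(design.matrix, dtype=float)
        self.n, self.K = self.A.shape
        self.effect_names = tuple(design.columns)
        self.latent = config.variant == "latent_adjustment"
        self.proxy_covariates = config.variant == "outcome_regression_proxy"
        self.W = table.proxies() if config.variant != "no_adjustment" else np.zeros((self.n, 0))
        self.p = self.W.shape[1]
        self.q = config.q if self.latent else 0
        if config.variant != "no_adjustment" and self.p == 0:
            raise ValueError(f"variant {config.variant!r} requires proxy columns")
        for k in range(self.K):
            col = self.A[:, k]
            if col.min() == col.max():
                raise ValueError(f"singular design: treatment column {design.columns[k]!r} "
                                 "is constant (all-treated or all-control)")

        # -- per-city spatial structure ---------------------------------
        self.cities = table.cities
        codes = table.city_index()
        self.M = len(self.cities)
        counts = np.bincount(codes, minlength=self.M)
        self.slices = []
        pos = 0
        for c in counts:
            self.slices.append(slice(pos, pos + int(c)))
            pos += int(c)
        if not np.all(codes == np.repeat(np.arange(self.M), counts)):
            raise ValueError("table rows must be grouped by city")

        self.has_z = config.r > 0
        if self.has_z:
            if bases is None:
                raise ValueError("config.r > 0 but no basis matrices supplied")
            self.B_list, self.L_list = [], []
            for i, city in enumerate(self.cities):
                if city not in bases:
                    raise ValueError(f"no basis matrix for city {city!r}")
                bm = bases[city]
                if bm.B.shape[0] != counts[i]:
                    raise ValueError(f"basis for city {city!r} has {bm.B.shape[0]} rows, "
                                     f"expected {counts[i]}")
                if abs(bm.ratio - config.r) > 1e-9:
                    raise ValueError(f"basis for city {city!r} built at ratio {bm.ratio}, "
                                     f"config.r={config.r}")
                self.B_list.append(bm.B)
                self.L_list.append(bm.L)
            self.total_L = int(sum(self.L_list))
            if self.total_L == 0:
                self.has_z = False
        if self.has_z:
            shapes = {b.shape for b in self.B_list}
            self.uniform = len(shapes) == 1
            if self.uniform:
                self.Bs = np.stack(self.B_list)                      # (M, N, L)
                BtB = np.einsum("mnl,mnk->mlk", self.Bs, self.Bs)
                # eigendecomposition makes the per-iteration lambda update
                # factorization-free: prec = Q (c1*d + 1/s2z) Q^T
                self.btb_evals, self.btb_evecs = np.linalg.eigh(BtB)
            else:
                self.btb_eigs = [np.linalg.eigh(b.T @ b) for b in self.B_list]
        # whether the treatment equations are needed at all
        self.use_treatment_eq = self.latent or self.has_z

        self._init_state()

    # -- state -----------------------------------------------------------
    def _init_state(self):
        cfg, rng = self.config, self.rng
        fx = cfg.fixed
        self.alpha_y = float(fx.get("alpha_y", np.mean(self.y)))
        self.theta = np.zeros(self.K) + np.asarray(fx.get("theta", 0.0), dtype=float)
        self.alpha_yu = np.zeros(self.q) + np.asarray(fx.get("alpha_yu", 0.0), dtype=float)
        self.alpha_yz = float(fx.get("alpha_yz", 0.0))
        self.beta_w = (np.zeros(self.p) + np.asarray(fx.get("beta_w", 0.0), dtype=float)
                       if self.proxy_covariates else np.zeros(0))
        self.alpha_a = np.zeros(self.K) + np.asarray(fx.get("alpha_a", 0.0), dtype=float)
        self.alpha_au = np.zeros((self.K, self.q)) + np.asarray(fx.get("alpha_au", 0.0), dtype=float)
        self.alpha_az = np.zeros(self.K) + np.asarray(fx.get("alpha_az", 0.0), dtype=float)
        if self.latent:
            self.alpha_w = np.zeros(self.p) + np.asarray(fx.get("alpha_w", self.W.mean(axis=0)),
                                                         dtype=float)
            default_wu = 0.5 * np.ones((self.p, self.q))
            self.alpha_wu = np.zeros((self.p, self.q)) + np.asarray(
                fx.get("alpha_wu", default_wu), dtype=float)
        self.sigma2_y = float(fx.get("sigma2_y", max(np.var(self.y), 1e-6)))
        if self.latent:
            self.sigma2_w = np.zeros(self.p) + np.asarray(
                fx.get("sigma2_w", np.maximum(self.W.var(axis=0), 1e-6)), dtype=float)
        self.sigma2_z = float(fx.get("sigma2_z", 1.0))
        self.U = rng.standard_normal((self.n, self.q)) if self.latent else np.zeros((self.n, 0))
        self.Z = np.zeros(self.n)
        if self.has_z:
            if self.uniform:
                self.lam = np.zeros(self.Bs.shape[:1] + self.Bs.shape[2:3])
            else:
                self.lam = [np.zeros(L) for L in self.L_list]
        self.Astar = np.where(self.A > 0, 0.5, -0.5)
        if cfg.effect == "random":
            self.theta_city = np.zeros((self.M, self.K))
            self.theta_bar = np.zeros(self.K)
            self.tau = np.ones(self.K)

    # -- mean pieces -----------------------------------------------------
    def _theta_term(self) -> np.ndarray:
        if self.config.effect == "random":
            out = np.zeros(self.n)
            for i, sl in enumerate(self.slices):
                out[sl] = self.A[sl] @ self.theta_city[i]
            return out
        return self.A @ self.theta

    def _mu_y(self) -> np.ndarray:
        mu = self.alpha_y + self._theta_term()
        if self.latent:
            mu = mu + self.U @ self.alpha_yu
        if self.proxy_covariates:
            mu = mu + self.W @ self.beta_w
        if self.has_z:
            mu = mu + self.alpha_yz * self.Z
        return mu

    def _treat_mean(self, k: int) -> np.ndarray:
        m = self.alpha_a[k] + self.U @ self.alpha_au[k]
        if self.has_z:
            m = m + self.alpha_az[k] * self.Z
        return m

    # -- blocks ----------------------------------------------------------
    def _update_astar(self):
        for k in range(self.K):
            self.Astar[:, k] = sample_truncated_normal(
                self.rng, self._treat_mean(k), 1.0, self.A[:, k] > 0)

    def _update_u(self):
        prec = np.eye(self.q)
        prec += np.outer(self.alpha_yu, self.alpha_yu) / self.sigma2_y
        for k in range(self.K):
            prec += np.outer(self.alpha_au[k], self.alpha_au[k])
        prec += self.alpha_wu.T @ (self.alpha_wu / self.sigma2_w[:, None])

        ry = self.y - self.alpha_y - self._theta_term()
        if self.has_z:
            ry = ry - self.alpha_yz * self.Z
        rhs = ry[:, None] * (self.alpha_yu / self.sigma2_y)
        for k in range(self.K):
            ra = self.Astar[:, k] - self.alpha_a[k]
            if self.has_z:
                ra = ra - self.alpha_az[k] * self.Z
            rhs += ra[:, None] * self.alpha_au[k]
        rw = self.W - self.alpha_w
        rhs += (rw / self.sigma2_w) @ self.alpha_wu

        if self.q == 1:
            prec11 = prec[0, 0]
            self.U = rhs / prec11 + self.rng.standard_normal((self.n, 1)) / np.sqrt(prec11)
        else:
            cov = np.linalg.inv(prec)
            noise = self.rng.standard_normal((self.n, self.q)) @ np.linalg.cholesky(cov).T
            self.U = rhs @ cov + noise

    def _update_outcome_block(self):
        fx = self.config.fixed
        cols, names = [], []
        if "alpha_y" not in fx:
            cols.append(np.ones((self.n, 1))); names.append(("alpha_y", 1))
        if self.config.effect == "constant" and "theta" not in fx:
            cols.append(self.A); names.append(("theta", self.K))
        if self.latent and "alpha_yu" not in fx:
            cols.append(self.U); names.append(("alpha_yu", self.q))
        if self.proxy_covariates and "beta_w" not in fx:
            cols.append(self.W); names.append(("beta_w", self.p))
        if self.has_z and "alpha_yz" not in fx:
            cols.append(self.Z[:, None]); names.append(("alpha_yz", 1))
        if not cols:
            return
        X = np.concatenate(cols, axis=1)
        offset = np.zeros(self.n)
        if "alpha_y" in fx:
            offset += self.alpha_y
        if self.config.effect == "random":
            offset += self._theta_term()
        elif "theta" in fx:
            offset += self.A @ self.theta
        if self.latent and "alpha_yu" in fx:
            offset += self.U @ self.alpha_yu
        if self.proxy_covariates and "beta_w" in fx:
            offset += self.W @ self.beta_w
        if self.has_z and "alpha_yz" in fx:
            offset += self.alpha_yz * self.Z
        beta = sample_normal_regression(self.rng, X, self.y, self.sigma2_y,
                                        self.priors.coef_scale ** 2, offset)
        pos = 0
        for name, width in names:
            val = beta[pos:pos + width]
            pos += width
            if name == "alpha_y":
                self.alpha_y = float(val[0])
            elif name == "theta":
                self.theta = val
            elif name == "alpha_yu":
                self.alpha_yu = val
            elif name == "beta_w":
                self.beta_w = val
            elif name == "alpha_yz":
                self.alpha_yz = float(val[0])

    def _update_treatment_block(self):
        fx = self.config.fixed
        for k in range(self.K):
            cols, names = [], []
            if "alpha_a" not in fx:
                cols.append(np.ones((self.n, 1))); names.append(("alpha_a", 1))
            if self.latent and "alpha_au" not in fx:
                cols.append(self.U); names.append(("alpha_au", self.q))
            if self.has_z and "alpha_az" not in fx:
                cols.append(self.Z[:, None]); names.append(("alpha_az", 1))
            if not cols:
                return
            X = np.concatenate(cols, axis=1)
            offset = np.zeros(self.n)
            if "alpha_a" in fx:
                offset += self.alpha_a[k]
            if self.latent and "alpha_au" in fx:
                offset += self.U @ self.alpha_au[k]
            if self.has_z and "alpha_az" in fx:
                offset += self.alpha_az[k] * self.Z
            beta = sample_normal_regression(self.rng, X, self.Astar[:, k], 1.0,
                                            self.priors.coef_scale ** 2, offset)
            pos = 0
            for name, width in names:
                val = beta[pos:pos + width]
                pos += width
                if name == "alpha_a":
                    self.alpha_a[k] = float(val[0])
                elif name == "alpha_au":
                    self.alpha_au[k] = val
                elif name == "alpha_az":
                    self.alpha_az[k] = float(val[0])

    def _update_proxy_block(self):
        fx = self.config.fixed
        free_w = "alpha_w" not in fx
        free_wu = "alpha_wu" not in fx
        if not (free_w or free_wu):
            return
        for m in range(self.p):
            cols = []
            if free_w:
                cols.append(np.ones((self.n, 1)))
            if free_wu:
                cols.append(self.U)
            X = np.concatenate(cols, axis=1)
            offset = np.zeros(self.n)
            if not free_w:
                offset += self.alpha_w[m]
            if not free_wu:
                offset += self.U @ self.alpha_wu[m]
            beta = sample_normal_regression(self.rng, X, self.W[:, m], self.sigma2_w[m],
                                            self.priors.coef_scale ** 2, offset)
            pos = 0
            if free_w:
                self.alpha_w[m] = float(beta[0]); pos = 1
            if free_wu:
                self.alpha_wu[m] = beta[pos:pos + self.q]
        if free_wu:
            for c in range(self.q):
                if self.alpha_wu[0, c] < 0:
                    self.alpha_wu[:, c] *= -1
                    self.U[:, c] *= -1
                    self.alpha_yu[c] *= -1
                    self.alpha_au[:, c] *= -1

    def _update_lambda(self):
        ry = self.y - (self._mu_y() - self.alpha_yz * self.Z)
        R = (self.alpha_yz / self.sigma2_y) * ry
        if self.use_treatment_eq:
            for k in range(self.K):
                ra = self.Astar[:, k] - (self.alpha_a[k] + self.U @ self.alpha_au[k])
                R = R + self.alpha_az[k] * ra
        c1 = self.alpha_yz ** 2 / self.sigma2_y + float(self.alpha_az @ self.alpha_az)
        if self.uniform:
            M, N, L = self.Bs.shape
            vals = c1 * self.btb_evals + 1.0 / self.sigma2_z       # (M, L)
            b = np.einsum("mnl,mn->ml", self.Bs, R.reshape(M, N))
            tb = np.einsum("mlk,ml->mk", self.btb_evecs, b)        # Q^T b
            z = self.rng.standard_normal((M, L))
            coef = tb / vals + z / np.sqrt(vals)
            self.lam = np.einsum("mlk,mk->ml", self.btb_evecs, coef)
            self.Z = np.einsum("mnl,ml->mn", self.Bs, self.lam).ravel()
        else:
            for i, sl in enumerate(self.slices):
                Li = self.L_list[i]
                if Li == 0:
                    continue
                d, Q = self.btb_eigs[i]
                vals = c1 * d + 1.0 / self.sigma2_z
                tb = Q.T @ (self.B_list[i].T @ R[sl])
                coef = tb / vals + self.rng.standard_normal(Li) / np.sqrt(vals)
                self.lam[i] = Q @ coef
                self.Z[sl] = self.B_list[i] @ self.lam[i]

    def _update_variances(self):
        fx, pr = self.config.fixed, self.priors
        if "sigma2_y" not in fx:
            self.sigma2_y = sample_variance(self.rng, self.y - self._mu_y(),
                                            pr.var_shape, pr.var_rate)
        if self.latent and "sigma2_w" not in fx:
            resid = self.W - self.alpha_w - self.U @ self.alpha_wu.T
            for m in range(self.p):
                self.sigma2_w[m] = sample_variance(self.rng, resid[:, m],
                                                   pr.var_shape, pr.var_rate)
        if self.has_z and "sigma2_z" not in fx:
            lam_all = self.lam.ravel() if self.uniform else np.concatenate(
                [v for v in self.lam if v.size])
            self.sigma2_z = sample_variance(self.rng, lam_all, pr.var_shape, pr.var_rate)

    def _update_random_effects(self):
        pr = self.priors
        r0 = self.y - (self._mu_y() - self._theta_term())
        for i, sl in enumerate(self.slices):
            for k in range(self.K):
                a = self.A[sl, k]
                prec = a @ a / self.sigma2_y + 1.0 / self.tau[k] ** 2
                mean = (a @ r0[sl] / self.sigma2_y
                        + self.theta_bar[k] / self.tau[k] ** 2) / prec
                self.theta_city[i, k] = self.rng.normal(mean, 1.0 / np.sqrt(prec))
        for k in range(self.K):
            prec = self.M / self.tau[k] ** 2 + 1.0 / pr.coef_scale ** 2
            mean = self.theta_city[:, k].sum() / self.tau[k] ** 2 / prec
            self.theta_bar[k] = self.rng.normal(mean, 1.0 / np.sqrt(prec))
            self.tau[k] = sample_scale_gridded(
                self.rng, self.theta_city[:, k] - self.theta_bar[k], pr.tau_scale)

    # -- driver ----------------------------------------------------------
    def _iterate(self):
        if self.use_treatment_eq:
            self._update_astar()
        if self.latent:
            self._update_u()
        self._update_outcome_block()
        if self.use_treatment_eq:
            self._update_treatment_block()
        if self.latent:
            self._update_proxy_block()
        if self.has_z:
            self._update_lambda()
        self._update_variances()
        if self.config.effect == "random":
            self._update_random_effects()

    def run(self) -> PosteriorDraws:
        cfg = self.config
        n_draws = cfg.n_keep // cfg.thin
        if n_draws < 1:
            raise ValueError("n_keep // thin must be >= 1")
        store = {
            "alpha_y": np.empty(n_draws), "sigma2_y": np.empty(n_draws),
            "alpha_a": np.empty((n_draws, self.K)), "alpha_az": np.empty((n_draws, self.K)),
            "alpha_yz": np.empty(n_draws), "sigma2_z": np.empty(n_draws),
        }
        if cfg.effect == "random":
            store["theta_bar"] = np.empty((n_draws, self.K))
            store["theta_city"] = np.empty((n_draws, self.M, self.K))
            store["tau"] = np.empty((n_draws, self.K))
        else:
            store["theta"] = np.empty((n_draws, self.K))
        if self.latent:
            store["alpha_yu"] = np.empty((n_draws, self.q))
            store["alpha_au"] = np.empty((n_draws, self.K, self.q))
            store["alpha_w"] = np.empty((n_draws, self.p))
            store["alpha_wu"] = np.empty((n_draws, self.p, self.q))
            store["sigma2_w"] = np.empty((n_draws, self.p))
            if cfg.store_latent:
                store["U"] = np.empty((n_draws, self.n, self.q))
        if self.proxy_covariates:
            store["beta_w"] = np.empty((n_draws, self.p))
        loglik = np.empty((n_draws, self.n))

        d = 0
        total = cfg.n_burn + cfg.n_keep
        const = -0.5 * math.log(2.0 * math.pi)
        for it in range(total):
            self._iterate()
            if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == cfg.thin - 1:
                mu = self._mu_y()
                ll = const - 0.5 * math.log(self.sigma2_y) \
                    - 0.5 * (self.y - mu) ** 2 / self.sigma2_y
                if not np.all(np.isfinite(ll)):
                    raise RuntimeError(
                        "non-finite outcome log-likelihood (divergence) at iteration "
                        f"{it}; state dump: sigma2_y={self.sigma2_y}, "
                        f"theta={getattr(self, 'theta', None)}, alpha_yz={self.alpha_yz}")
                loglik[d] = ll
                store["alpha_y"][d] = self.alpha_y
                store["sigma2_y"][d] = self.sigma2_y
                store["alpha_a"][d] = self.alpha_a
                store["alpha_az"][d] = self.alpha_az
                store["alpha_yz"][d] = self.alpha_yz
                store["sigma2_z"][d] = self.sigma2_z
                if cfg.effect == "random":
                    store["theta_bar"][d] = self.theta_bar
                    store["theta_city"][d] = self.theta_city
                    store["tau"][d] = self.tau
                else:
                    store["theta"][d] = self.theta
                if self.latent:
                    store["alpha_yu"][d] = self.alpha_yu
                    store["alpha_au"][d] = self.alpha_au
                    store["alpha_w"][d] = self.alpha_w
                    store["alpha_wu"][d] = self.alpha_wu
                    store["sigma2_w"][d] = self.sigma2_w
                    if cfg.store_latent:
                        store["U"][d] = self.U
                if self.proxy_covariates:
                    store["beta_w"][d] = self.beta_w
                d += 1

        draws = PosteriorDraws(draws=store, loglik=loglik, waic=float("nan"),
                               config=cfg, effect_names=self.effect_names,
                               cities=self.cities)
        draws.waic = waic(draws)
        th = draws.effect_draws()
        draws.diagnostics = {
            "split_rhat_theta": [split_rhat(th[:, k]) for k in range(self.K)],
        }
        return draws
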
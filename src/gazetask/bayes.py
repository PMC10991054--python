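"""Posterior inference for the hierarchical models.

Two likelihood backends drive every Bayesian fit in the package:

``GaussianLMM``
    Linear mixed model on the log scale (the lognormal family).  The
    subject-level random effects are integrated out exactly: per subject,
    the marginal distribution of the responses is multivariate normal with
    covariance ``sigma^2 I + Z Sigma Z'``, evaluated via the Woodbury
    identity from per-subject sufficient statistics.  Sampling therefore
    happens in the low-dimensional hyperparameter space only.

``BernoulliGLMM``
    Logistic mixed model.  The random effects have no closed-form
    integral; each subject's contribution is integrated by a Laplace
    approximation around the conditional mode, found with a damped Newton
    iteration batched over subjects and walkers.

Both backends are sampled with the affine-invariant ensemble sampler
(emcee), with the log posterior vectorized across walkers.  Priors are
weakly informative and documented on each parametrization class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import emcee
import numpy as np

__all__ = [
    "PosteriorSummary",
    "FitResult",
    "CholeskyCov",
    "CorrCov2",
    "GaussianLMM",
    "BernoulliGLMM",
    "split_rhat",
]

_BETA_BOUND = 30.0  # hard box on fixed effects; outside -> log prob -inf
_LOG_SD_BOUNDS = (-6.0, 4.0)  # hard box on log-scale SD parameters


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean and central 95% credible interval of one quantity."""

    name: str
    mean: float
    sd: float
    cri_low: float
    cri_high: float
    rhat: float

    def covers(self, value: float) -> bool:
        return self.cri_low <= value <= self.cri_high


@dataclass
class FitResult:
    """Posterior draws plus per-parameter summaries and sampler diagnostics."""

    samples: dict[str, np.ndarray]  # name -> flat posterior draws
    summaries: dict[str, PosteriorSummary]
    acceptance_fraction: float
    n_draws: int

    def __getitem__(self, name: str) -> PosteriorSummary:
        return self.summaries[name]


def split_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin split-Rhat for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half
    before computing the between/within variance ratio.
    """
    c, d = chains.shape
    half = d // 2
    parts = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = parts.shape
    means = parts.mean(axis=1)
    w = parts.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


class CholeskyCov:
    """Unstructured k x k random-effect covariance via its Cholesky factor.

    Parameters are the log diagonal entries followed by the below-diagonal
    entries in row order.  Priors: log-diagonals N(log 0.3, 1.5^2) (SD
    weakly centered below the outcome scale), off-diagonals N(0, 1).
    """

    def __init__(self, k: int, names: Optional[Sequence[str]] = None):
        self.k = k
        self.n_params = k * (k + 1) // 2
        self.names = list(names) if names is not None else [f"re{i}" for i in range(k)]
        self.param_names = [f"log_sd_chol[{n}]" for n in self.names] + [
            f"chol[{self.names[i]},{self.names[j]}]" for i in range(k) for j in range(i)
        ]
        n_off = self.n_params - k
        self.lo = [_LOG_SD_BOUNDS[0]] * k + [-20.0] * n_off
        self.hi = [_LOG_SD_BOUNDS[1]] * k + [20.0] * n_off

    def chol(self, params: np.ndarray) -> np.ndarray:
        w = params.shape[0]
        L = np.zeros((w, self.k, self.k))
        diag = np.exp(params[:, : self.k])
        idx = self.k
        for i in range(self.k):
            L[:, i, i] = diag[:, i]
            for j in range(i):
                L[:, i, j] = params[:, idx]
                idx += 1
        return L

    def log_prior(self, params: np.ndarray) -> np.ndarray:
        logdiag = params[:, : self.k]
        off = params[:, self.k :]
        lp = -0.5 * np.sum((logdiag - np.log(0.3)) ** 2 / 1.5**2, axis=1)
        if off.shape[1]:
            lp = lp - 0.5 * np.sum(off**2, axis=1)
        return lp

    def initial(self, sd: float = 0.3) -> np.ndarray:
        x = np.zeros(self.n_params)
        x[: self.k] = np.log(sd)
        return x


class CorrCov2:
    """2 x 2 random-effect covariance parametrized as (log sd1, log sd2, z).

    The correlation is rho = tanh(z) with a uniform prior on (-1, 1)
    (applied through the tanh Jacobian), so the posterior of rho — the
    quantity of interest in the retest model — is not shrunk by its prior.
    SDs have HalfNormal(1.5) priors.
    """

    k = 2
    n_params = 3

    def __init__(self, names: Sequence[str] = ("day1", "day2")):
        self.names = list(names)
        self.param_names = [f"log_sd[{n}]" for n in self.names] + ["atanh_rho"]
        self.lo = [_LOG_SD_BOUNDS[0]] * 2 + [-6.0]
        self.hi = [_LOG_SD_BOUNDS[1]] * 2 + [6.0]

    def chol(self, params: np.ndarray) -> np.ndarray:
        w = params.shape[0]
        sd = np.exp(params[:, :2])
        rho = np.tanh(params[:, 2])
        L = np.zeros((w, 2, 2))
        L[:, 0, 0] = sd[:, 0]
        L[:, 1, 0] = sd[:, 1] * rho
        L[:, 1, 1] = sd[:, 1] * np.sqrt(np.clip(1.0 - rho**2, 1e-12, None))
        return L

    def log_prior(self, params: np.ndarray) -> np.ndarray:
        log_sd = params[:, :2]
        sd = np.exp(log_sd)
        rho = np.tanh(params[:, 2])
        lp = np.sum(-0.5 * sd**2 / 1.5**2 + log_sd, axis=1)  # HalfNormal + Jacobian
        lp = lp + np.log(np.clip(1.0 - rho**2, 1e-300, None))  # uniform rho, tanh Jacobian
        return lp

    def initial(self, sd: float = 0.3) -> np.ndarray:
        return np.array([np.log(sd), np.log(sd), 0.5])


def _summarize(samples: dict[str, np.ndarray], chains: dict[str, np.ndarray]) -> dict:
    out = {}
    for name, s in samples.items():
        lo, hi = np.percentile(s, [2.5, 97.5])
        out[name] = PosteriorSummary(
            name=name,
            mean=float(s.mean()),
            sd=float(s.std(ddof=1)),
            cri_low=float(lo),
            cri_high=float(hi),
            rhat=split_rhat(chains[name]),
        )
    return out


class _MarginalModel:
    """Shared emcee driver for the marginalized mixed models."""

    beta_prior_sd = 5.0

    # subclasses define: ndim, param_names, log_prob(theta_matrix),
    # initial_point(), derived_samples(chain), _lo/_hi bound vectors

    def _within_bounds(self, theta: np.ndarray) -> np.ndarray:
        return np.all((theta > self._lo[None]) & (theta < self._hi[None]), axis=1)

    def _set_bounds(self, n_extra_sd: int, cov) -> None:
        """Bounds: fixed effects, then n_extra_sd log-SDs, then cov params."""
        lo = [-_BETA_BOUND] * self.p + [_LOG_SD_BOUNDS[0]] * n_extra_sd + list(cov.lo)
        hi = [_BETA_BOUND] * self.p + [_LOG_SD_BOUNDS[1]] * n_extra_sd + list(cov.hi)
        self._lo = np.array(lo)
        self._hi = np.array(hi)

    def sample(
        self,
        seed: int = 0,
        nwalkers: Optional[int] = None,
        nsteps: int = 1500,
        burn: int = 500,
    ) -> FitResult:
        ndim = self.ndim
        nwalkers = nwalkers or max(2 * ndim + 2, 24)
        rng = np.random.RandomState(seed % (2**31 - 1))
        center = self.initial_point()
        p0 = center[None, :] + 0.05 * rng.randn(nwalkers, ndim)
        lp = self.log_prob(p0)
        for _ in range(100):
            bad = ~np.isfinite(lp)
            if not bad.any():
                break
            p0[bad] = center[None, :] + 0.05 * rng.randn(int(bad.sum()), ndim)
            lp = self.log_prob(p0)
        # differential-evolution moves mix much better than the default
        # stretch move at this dimensionality
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, self.log_prob, vectorize=True, moves=moves
        )
        sampler._random = rng
        sampler.run_mcmc(p0, nsteps, progress=False)
        chain = sampler.get_chain(discard=burn)  # (draws, walkers, ndim)
        samples, chains = self.derived_samples(chain)
        return FitResult(
            samples=samples,
            summaries=_summarize(samples, chains),
            acceptance_fraction=float(sampler.acceptance_fraction.mean()),
            n_draws=int(chain.shape[0] * chain.shape[1]),
        )

    def _base_derived(self, chain: np.ndarray) -> tuple[dict, dict]:
        """Raw per-parameter draws (draws x walkers x ndim -> flat)."""
        samples, chains = {}, {}
        for i, name in enumerate(self.param_names):
            chains[name] = chain[:, :, i].T  # (walkers, draws)
            samples[name] = chain[:, :, i].reshape(-1)
        return samples, chains


class GaussianLMM(_MarginalModel):
    """Gaussian linear mixed model with exactly marginalized random effects.

    Fit on ``log(y)`` for the lognormal family.  ``X`` (n x p) are fixed
    effect columns, ``Z`` (n x k) random-effect columns, ``groups`` integer
    subject codes.  Parameter vector: fixed effects, log residual SD, then
    the covariance parametrization.
    """

    def __init__(
        self,
        X: np.ndarray,
        Z: np.ndarray,
        y: np.ndarray,
        groups: np.ndarray,
        fixed_names: Sequence[str],
        cov,
    ):
        X = np.asarray(X, float)
        Z = np.asarray(Z, float)
        y = np.asarray(y, float)
        groups = np.asarray(groups)
        self.p = X.shape[1]
        self.k = Z.shape[1]
        assert cov.k == self.k
        self.cov = cov
        self.fixed_names = list(fixed_names)
        self.param_names = self.fixed_names + ["log_sigma"] + cov.param_names
        self.ndim = self.p + 1 + cov.n_params
        self._set_bounds(1, cov)  # one extra log-SD: the residual sigma

        codes = np.unique(groups)
        S = len(codes)
        self.n_i = np.zeros(S)
        self.yty = np.zeros(S)
        self.Xty = np.zeros((S, self.p))
        self.Zty = np.zeros((S, self.k))
        self.XtX = np.zeros((S, self.p, self.p))
        self.ZtX = np.zeros((S, self.k, self.p))
        self.ZtZ = np.zeros((S, self.k, self.k))
        for s, code in enumerate(codes):
            m = groups == code
            Xs, Zs, ys = X[m], Z[m], y[m]
            self.n_i[s] = m.sum()
            self.yty[s] = ys @ ys
            self.Xty[s] = Xs.T @ ys
            self.Zty[s] = Zs.T @ ys
            self.XtX[s] = Xs.T @ Xs
            self.ZtX[s] = Zs.T @ Xs
            self.ZtZ[s] = Zs.T @ Zs
        self.n_total = float(self.n_i.sum())
        # pooled OLS for initialization
        XtX_all = self.XtX.sum(axis=0)
        Xty_all = self.Xty.sum(axis=0)
        self._beta0 = np.linalg.solve(XtX_all + 1e-8 * np.eye(self.p), Xty_all)
        resid_var = max(
            (self.yty.sum() - self._beta0 @ Xty_all) / max(self.n_total - self.p, 1.0), 1e-4
        )
        self._sigma0 = np.sqrt(resid_var)

    def initial_point(self) -> np.ndarray:
        # start residual SD below the OLS value: it absorbs the RE variance otherwise
        return np.concatenate(
            [self._beta0, [np.log(self._sigma0 * 0.7)], self.cov.initial(self._sigma0 * 0.5)]
        )

    def _loglik_rows(self, t: np.ndarray) -> np.ndarray:
        beta = t[:, : self.p]
        log_sigma = t[:, self.p]
        sigma2 = np.exp(2.0 * log_sigma)
        L = self.cov.chol(t[:, self.p + 1 :])
        Sigma = L @ np.swapaxes(L, 1, 2)
        logdet_Sigma = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
        Sigma_inv = np.linalg.inv(Sigma)

        A = sigma2[:, None, None, None] * Sigma_inv[:, None] + self.ZtZ[None]
        try:
            cholA = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return np.full(t.shape[0], -np.inf)
        logdetA = 2.0 * np.sum(np.log(np.diagonal(cholA, axis1=2, axis2=3)), axis=2)
        q = self.Zty[None] - np.einsum("skp,wp->wsk", self.ZtX, beta)
        u = np.linalg.solve(A, q[..., None])[..., 0]
        quad_re = np.einsum("wsk,wsk->ws", q, u)
        rr = (
            self.yty[None]
            - 2.0 * np.einsum("sp,wp->ws", self.Xty, beta)
            + np.einsum("wp,spq,wq->ws", beta, self.XtX, beta, optimize=True)
        )
        per_subj = (
            self.n_i[None] * np.log(2.0 * np.pi)
            + (self.n_i[None] - self.k) * 2.0 * log_sigma[:, None]
            + logdet_Sigma[:, None]
            + logdetA
            + (rr - quad_re) / sigma2[:, None]
        )
        return -0.5 * per_subj.sum(axis=1)

    def _logprior_rows(self, t: np.ndarray) -> np.ndarray:
        beta = t[:, : self.p]
        log_sigma = t[:, self.p]
        return (
            -0.5 * np.sum(beta**2, axis=1) / self.beta_prior_sd**2
            - 0.5 * np.exp(2 * log_sigma) / 2.0**2
            + log_sigma  # HalfNormal(2) prior on sigma with log Jacobian
            + self.cov.log_prior(t[:, self.p + 1 :])
        )

    def log_likelihood(self, theta: np.ndarray) -> np.ndarray:
        """Exact marginal log likelihood (random effects integrated out)."""
        theta = np.atleast_2d(theta)
        out = np.full(theta.shape[0], -np.inf)
        ok = self._within_bounds(theta)
        if ok.any():
            out[ok] = self._loglik_rows(theta[ok])
        return out

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        out = np.full(theta.shape[0], -np.inf)
        ok = self._within_bounds(theta)
        if not ok.any():
            return out
        t = theta[ok]
        lp = self._loglik_rows(t) + self._logprior_rows(t)
        out[ok] = np.where(np.isfinite(lp), lp, -np.inf)
        return out

    def derived_samples(self, chain: np.ndarray) -> tuple[dict, dict]:
        samples, chains = self._base_derived(chain)
        self._add_sigma_rho(samples, chains, chain, offset=self.p + 1)
        return samples, chains

    def _add_sigma_rho(self, samples, chains, chain, offset):
        d, w, _ = chain.shape
        flatc = chain.reshape(d * w, -1)
        L = self.cov.chol(flatc[:, offset:])
        Sigma = L @ np.swapaxes(L, 1, 2)
        sds = np.sqrt(np.diagonal(Sigma, axis1=1, axis2=2))
        for i, name in enumerate(self.cov.names):
            s = sds[:, i]
            samples[f"re_sd[{name}]"] = s
            chains[f"re_sd[{name}]"] = s.reshape(d, w).T
        if self.k == 2:
            rho = Sigma[:, 1, 0] / np.clip(sds[:, 0] * sds[:, 1], 1e-12, None)
            samples["rho"] = rho
            chains["rho"] = rho.reshape(d, w).T
        if "log_sigma" in self.param_names:
            i = self.param_names.index("log_sigma")
            sig = np.exp(chain[:, :, i]).reshape(-1)
            samples["sigma"] = sig
            chains["sigma"] = np.exp(chain[:, :, i]).T


class BernoulliGLMM(_MarginalModel):
    """Logistic mixed model with Laplace-marginalized random effects.

    Subjects are padded to a common trial count and masked; the conditional
    mode of each subject's random effects is found by damped Newton
    iterations batched over (walker, subject).
    """

    def __init__(
        self,
        X: np.ndarray,
        Z: np.ndarray,
        y: np.ndarray,
        groups: np.ndarray,
        fixed_names: Sequence[str],
        cov,
        newton_iters: int = 30,
    ):
        X = np.asarray(X, float)
        Z = np.asarray(Z, float)
        y = np.asarray(y, float)
        groups = np.asarray(groups)
        self.p = X.shape[1]
        self.k = Z.shape[1]
        assert cov.k == self.k
        self.cov = cov
        self.newton_iters = newton_iters
        self.fixed_names = list(fixed_names)
        self.param_names = self.fixed_names + cov.param_names
        self.ndim = self.p + cov.n_params
        self._set_bounds(0, cov)

        codes = np.unique(groups)
        S = len(codes)
        N = int(max((groups == c).sum() for c in codes))
        self.Xp = np.zeros((S, N, self.p))
        self.Zp = np.zeros((S, N, self.k))
        self.yp = np.zeros((S, N))
        self.mask = np.zeros((S, N))
        for s, code in enumerate(codes):
            m = groups == code
            n = int(m.sum())
            self.Xp[s, :n] = X[m]
            self.Zp[s, :n] = Z[m]
            self.yp[s, :n] = y[m]
            self.mask[s, :n] = 1.0
        # regularized pooled logistic regression for initialization
        self._beta0 = self._pooled_logit(X, y)

    def _pooled_logit(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        beta = np.zeros(self.p)
        for _ in range(50):
            eta = np.clip(X @ beta, -35, 35)
            mu = 1.0 / (1.0 + np.exp(-eta))
            g = X.T @ (y - mu) - beta / 25.0
            H = (X * (mu * (1 - mu))[:, None]).T @ X + np.eye(self.p) / 25.0
            step = np.linalg.solve(H, g)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-8:
                break
        return beta

    def initial_point(self) -> np.ndarray:
        return np.concatenate([self._beta0, self.cov.initial(0.5)])

    def _loglik_rows(self, t: np.ndarray, ok: np.ndarray, W: int) -> np.ndarray:
        w = t.shape[0]
        beta = t[:, : self.p]
        L = self.cov.chol(t[:, self.p :])
        Sigma = L @ np.swapaxes(L, 1, 2)
        logdet_Sigma = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
        Sigma_inv = np.linalg.inv(Sigma)

        eta0 = np.einsum("snp,wp->wsn", self.Xp, beta)
        S = self.Xp.shape[0]
        # warm-start the mode search from the previous evaluation: the modes
        # vary continuously with theta, so this only changes iteration count
        cache = getattr(self, "_b_cache", None)
        b = cache[ok].copy() if cache is not None and cache.shape[0] == W else np.zeros((w, S, self.k))
        for _ in range(self.newton_iters):
            eta = np.clip(eta0 + np.einsum("snk,wsk->wsn", self.Zp, b), -35, 35)
            mu = 1.0 / (1.0 + np.exp(-eta))
            g = np.einsum("snk,wsn->wsk", self.Zp, (self.yp[None] - mu) * self.mask[None])
            g = g - np.einsum("wij,wsj->wsi", Sigma_inv, b)
            wdiag = mu * (1.0 - mu) * self.mask[None]
            H = np.einsum("sni,wsn,snj->wsij", self.Zp, wdiag, self.Zp, optimize=True) + Sigma_inv[:, None]
            step = np.linalg.solve(H, g[..., None])[..., 0]
            norm = np.linalg.norm(step, axis=-1, keepdims=True)
            step = step * np.minimum(1.0, 4.0 / np.clip(norm, 1e-12, None))  # damping
            b = b + step
            if float(np.abs(step).max()) < 1e-8:
                break
        if cache is not None and cache.shape[0] == W:
            cache[ok] = b
        else:
            full = np.zeros((W, S, self.k))
            full[ok] = b
            self._b_cache = full
        eta = np.clip(eta0 + np.einsum("snk,wsk->wsn", self.Zp, b), -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll_cond = np.sum(
            (self.yp[None] * eta - np.logaddexp(0.0, eta)) * self.mask[None], axis=2
        )
        quad = np.einsum("wsi,wij,wsj->ws", b, Sigma_inv, b, optimize=True)
        wdiag = mu * (1.0 - mu) * self.mask[None]
        H = np.einsum("sni,wsn,snj->wsij", self.Zp, wdiag, self.Zp, optimize=True) + Sigma_inv[:, None]
        sign, logdetH = np.linalg.slogdet(H)
        loglik = np.sum(
            ll_cond - 0.5 * quad - 0.5 * (logdet_Sigma[:, None] + logdetH), axis=1
        )
        return np.where(np.all(sign > 0, axis=1), loglik, -np.inf)

    def log_likelihood(self, theta: np.ndarray) -> np.ndarray:
        """Laplace-approximate marginal log likelihood."""
        theta = np.atleast_2d(theta)
        W = theta.shape[0]
        out = np.full(W, -np.inf)
        ok = self._within_bounds(theta)
        if ok.any():
            out[ok] = self._loglik_rows(theta[ok], ok, W)
        return out

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        W = theta.shape[0]
        out = np.full(W, -np.inf)
        ok = self._within_bounds(theta)
        if not ok.any():
            return out
        t = theta[ok]
        lp = (
            self._loglik_rows(t, ok, W)
            - 0.5 * np.sum(t[:, : self.p] ** 2, axis=1) / self.beta_prior_sd**2
            + self.cov.log_prior(t[:, self.p :])
        )
        out[ok] = np.where(np.isfinite(lp), lp, -np.inf)
        return out

    def derived_samples(self, chain: np.ndarray) -> tuple[dict, dict]:
        samples, chains = self._base_derived(chain)
        d, w, _ = chain.shape
        flatc = chain.reshape(d * w, -1)
        L = self.cov.chol(flatc[:, self.p :])
        Sigma = L @ np.swapaxes(L, 1, 2)
        sds = np.sqrt(np.diagonal(Sigma, axis1=1, axis2=2))
        for i, name in enumerate(self.cov.names):
            samples[f"re_sd[{name}]"] = sds[:, i]
            chains[f"re_sd[{name}]"] = sds[:, i].reshape(d, w).T
        if self.k == 2:
            rho = Sigma[:, 1, 0] / np.clip(sds[:, 0] * sds[:, 1], 1e-12, None)
            samples["rho"] = rho
            chains["rho"] = rho.reshape(d, w).T
        return samples, chains
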
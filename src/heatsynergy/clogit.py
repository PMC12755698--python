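"""Conditional (matched-set) logistic regression: exact likelihood, Newton MLE
and Bayesian posterior sampling.

For a stratum ``s`` with rows ``x_1 … x_m`` and case row ``c``, the
conditional likelihood contribution is

    log L_s(beta) = eta_c - logsumexp_j(eta_j),      eta_j = x_j . beta,

the probability that, given one event in the stratum, it fell on the case
day. Stratum-constant covariates cancel exactly — the case-crossover's
confounding-control property. The log-likelihood is concave in ``beta``.

Two estimators share this likelihood:

* :class:`ConditionalLogisticRegression` — a damped Newton maximizer with
  analytic gradient/Hessian, observed-information covariance and explicit
  separation / non-identifiability reporting. It doubles as the
  deterministic oracle for the sampler.
* :class:`BayesianConditionalLogistic` — affine-invariant ensemble MCMC
  (emcee) over ``prior x conditional likelihood`` with independent
  ``normal(0, prior_scale^2)`` priors (``prior_scale=None`` gives a flat
  prior). Walkers are initialized in a small ball around the MLE; diagnostics
  (split-R-hat over walker groups, bulk ESS) are computed with arviz and a
  fit is rejected when they miss the configured thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

__all__ = [
    "StratumData",
    "SeparationError",
    "ConvergenceError",
    "NonIdentifiableWarning",
    "stratum_loglik",
    "conditional_loglik",
    "fit_mle",
    "sample_posterior",
    "ConditionalLogisticRegression",
    "BayesianConditionalLogistic",
]


class SeparationError(RuntimeError):
    """The conditional likelihood is unbounded (perfect separation)."""


class ConvergenceError(RuntimeError):
    """Optimization or MCMC diagnostics failed the acceptance gates."""


class NonIdentifiableWarning(UserWarning):
    """The within-stratum design is rank deficient; coefficients not unique."""


@dataclass
class StratumData:
    """Design rows of one matched set plus the index of its case row."""

    set_id: object
    rows: np.ndarray
    case_index: int

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[0] < 2:
            raise ValueError("a stratum needs at least 2 design rows")
        if not 0 <= self.case_index < self.rows.shape[0]:
            raise ValueError("case_index out of range")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("non-finite design entries in stratum")


def stratum_loglik(beta, s: StratumData) -> float:
    """Exact conditional log-likelihood of one stratum; value in (-inf, 0)."""
    beta = np.asarray(beta, dtype=float)
    eta = s.rows @ beta
    return float(eta[s.case_index] - logsumexp(eta))


class _PackedStrata:
    """Group-sorted design with reduceat bounds for vectorized likelihood."""

    def __init__(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        groups = np.asarray(groups)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite design entries")
        if len(y) != len(X) or len(groups) != len(X):
            raise ValueError("X, y and groups must have equal length")
        order = np.argsort(groups, kind="stable")
        self.X = X[order]
        self.y = y[order].astype(int)
        self.groups = groups[order]
        # stratum boundaries
        change = np.flatnonzero(self.groups[1:] != self.groups[:-1]) + 1
        self.starts = np.concatenate([[0], change])
        self.sizes = np.diff(np.concatenate([self.starts, [len(self.X)]]))
        if np.any(self.sizes < 2):
            raise ValueError("every stratum needs at least 2 rows")
        cases_per = np.add.reduceat(self.y, self.starts)
        if np.any(cases_per != 1):
            raise ValueError("every stratum must contain exactly one case row")
        self.case_mask = self.y.astype(bool)
        self.n_strata = len(self.starts)
        self.n_params = X.shape[1]

    def _lse(self, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-stratum logsumexp and softmax weights, broadcast over columns."""
        m = np.maximum.reduceat(eta, self.starts, axis=0)
        m_full = np.repeat(m, self.sizes, axis=0)
        e = np.exp(eta - m_full)
        denom = np.add.reduceat(e, self.starts, axis=0)
        lse = m + np.log(denom)
        w = e / np.repeat(denom, self.sizes, axis=0)
        return lse, w

    def loglik(self, beta: np.ndarray) -> np.ndarray:
        """Total conditional log-likelihood; beta may be (p,) or (p, k)."""
        beta2 = np.atleast_2d(np.asarray(beta, dtype=float).T).T  # (p, k)
        eta = self.X @ beta2
        lse, _ = self._lse(eta)
        ll = eta[self.case_mask].sum(axis=0) - lse.sum(axis=0)
        return ll[0] if np.ndim(beta) == 1 else ll

    def loglik_grad(self, beta: np.ndarray) -> tuple[float, np.ndarray]:
        eta = self.X @ beta
        lse, w = self._lse(eta[:, None])
        w = w[:, 0]
        ll = float(eta[self.case_mask].sum() - lse.sum())
        grad = self.X[self.case_mask].sum(axis=0) - self.X.T @ w
        return ll, grad

    def hessian(self, beta: np.ndarray) -> np.ndarray:
        eta = self.X @ beta
        _, w = self._lse(eta[:, None])
        w = w[:, 0]
        Xw = self.X * w[:, None]
        M = np.add.reduceat(Xw, self.starts, axis=0)  # per-stratum weighted mean rows
        return -(self.X.T @ Xw - M.T @ M)


def conditional_loglik(beta, X, y, groups) -> float:
    """Sum of stratum log-likelihoods over a long-format matched design."""
    return float(_PackedStrata(X, y, groups).loglik(np.asarray(beta, dtype=float)))


class ConditionalLogisticRegression(BaseEstimator):
    """Maximum-likelihood conditional logistic regression (Newton ascent).

    Parameters
    ----------
    tol : float
        Convergence threshold on the gradient max-norm.
    max_iter : int
        Newton iteration budget.

    Attributes
    ----------
    coef_ : (p,) MLE of the design coefficients.
    cov_ : (p, p) inverse observed information at the MLE.
    bse_ : (p,) standard errors.
    loglik_ : maximized log-likelihood.
    n_iter_ : Newton iterations used.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, groups):
        packed = _PackedStrata(X, y, groups)
        p = packed.n_params

        # identifiability: within-stratum centered design must have full rank
        centered = packed.X - np.repeat(
            np.add.reduceat(packed.X, packed.starts, axis=0) / packed.sizes[:, None],
            packed.sizes,
            axis=0,
        )
        rank = np.linalg.matrix_rank(centered)
        self.identifiable_ = bool(rank == p)
        if not self.identifiable_:
            warnings.warn(
                "within-stratum design is rank deficient; the conditional "
                "likelihood is flat along some directions and coefficients are "
                "not identifiable",
                NonIdentifiableWarning,
                stacklevel=2,
            )

        beta = np.zeros(p)
        ll, grad = packed.loglik_grad(beta)
        for it in range(1, self.max_iter + 1):
            if np.max(np.abs(grad)) <= self.tol:
                break
            H = packed.hessian(beta)
            try:
                step = np.linalg.solve(H - 1e-12 * np.eye(p), grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            step = -step  # ascent direction (H is negative definite)
            # damped Newton: never decrease the log-likelihood (concavity check)
            t = 1.0
            for _ in range(60):
                cand = beta + t * step
                ll_new, grad_new = packed.loglik_grad(cand)
                if ll_new >= ll - 1e-12:
                    break
                t *= 0.5
            else:  # pragma: no cover - line search failing on a concave function
                raise ConvergenceError("line search failed on the concave log-likelihood")
            beta, ll, grad = cand, ll_new, grad_new
        self.n_iter_ = it if p else 0
        converged = bool(np.max(np.abs(grad)) <= max(self.tol, 1e-6)) if p else True
        if p and np.max(np.abs(beta)) > 50.0:
            # under separation the gradient also vanishes as beta diverges,
            # so a huge "converged" coefficient is separation, not a solution
            raise SeparationError(
                "conditional likelihood appears unbounded (diverging coefficients); "
                "the cases are separated from referents in the design"
            )
        if not converged and self.identifiable_:
            raise ConvergenceError(
                f"Newton did not reach gradient norm <= 1e-6 in {self.max_iter} iterations"
            )
        self.coef_ = beta
        self.loglik_ = ll
        H = packed.hessian(beta)
        if self.identifiable_:
            self.cov_ = np.linalg.inv(-H)
            self.bse_ = np.sqrt(np.diag(self.cov_))
        else:
            self.cov_ = np.full((p, p), np.nan)
            self.bse_ = np.full(p, np.nan)
        return self

    def score(self, X, y, groups) -> float:
        """Conditional log-likelihood of held-out matched sets at the MLE."""
        return conditional_loglik(self.coef_, X, y, groups)


class BayesianConditionalLogistic(BaseEstimator):
    """Bayesian conditional logistic regression via ensemble MCMC.

    Parameters
    ----------
    prior_scale : float or None
        SD of the independent normal(0, sigma^2) coefficient priors;
        ``None`` means a flat (improper) prior.
    n_draws : int
        Minimum number of retained post-warmup draws (pooled over walkers).
    warmup_steps : int
        Ensemble steps discarded as warmup.
    sample_steps : int or None
        Post-warmup ensemble steps; default ``max(ceil(n_draws / n_walkers),
        1000)`` — the floor keeps per-walker chains long enough for stable
        split-R-hat. Moves are a differential-evolution mixture (80% DEMove,
        20% DESnookerMove), which mixes much faster here than the stretch
        move.
    n_walkers : int or None
        Ensemble size; default ``max(4 * n_params + 4, 16)`` (rounded even).
    n_chains : int
        Walker groups used as pseudo-chains for split-R-hat.
    rhat_max, ess_min : float
        Acceptance gates on the diagnostics (fit rejected otherwise when
        ``check_diagnostics``).
    random_state : int or None
        Seed for walker initialization and moves.

    Attributes
    ----------
    draws_ : (n_draws, p) posterior draws.
    rhat_, ess_bulk_, mcse_mean_ : per-coefficient diagnostics.
    mle_ : the :class:`ConditionalLogisticRegression` used for initialization.
    """

    def __init__(
        self,
        prior_scale: float | None = 5.0,
        n_draws: int = 4000,
        warmup_steps: int = 1000,
        sample_steps: int | None = None,
        n_walkers: int | None = None,
        n_chains: int = 4,
        rhat_max: float = 1.01,
        ess_min: float = 400.0,
        check_diagnostics: bool = True,
        random_state: int | None = None,
    ):
        self.prior_scale = prior_scale
        self.n_draws = n_draws
        self.warmup_steps = warmup_steps
        self.sample_steps = sample_steps
        self.n_walkers = n_walkers
        self.n_chains = n_chains
        self.rhat_max = rhat_max
        self.ess_min = ess_min
        self.check_diagnostics = check_diagnostics
        self.random_state = random_state

    def fit(self, X, y, groups):
        import emcee

        packed = _PackedStrata(X, y, groups)
        p = packed.n_params
        nw = self.n_walkers or max(4 * p + 4, 16)
        nw += nw % 2
        rng = np.random.default_rng(self.random_state)

        mle = ConditionalLogisticRegression().fit(X, y, groups)
        self.mle_ = mle
        center = mle.coef_

        # Precondition with the Laplace approximation: sample z with
        # beta = mle + L z, L = chol(inverse observed information), so the
        # target is near-spherical and the stretch move mixes quickly.
        if mle.identifiable_ and np.all(np.isfinite(mle.cov_)):
            L = np.linalg.cholesky(mle.cov_)
        else:
            L = np.eye(p)

        sigma2 = None if self.prior_scale is None else float(self.prior_scale) ** 2

        def log_prob(z: np.ndarray) -> np.ndarray:
            beta = center + z @ L.T  # (nw, p)
            ll = packed.loglik(beta.T)
            if sigma2 is not None:
                ll = ll - 0.5 * np.sum(beta**2, axis=1) / sigma2
            return ll

        init = 0.1 * rng.standard_normal((nw, p))
        sample_steps = self.sample_steps or max(int(np.ceil(self.n_draws / nw)), 1000)
        steps = self.warmup_steps + sample_steps
        moves = [
            (emcee.moves.DEMove(), 0.8),
            (emcee.moves.DESnookerMove(), 0.2),
        ]
        sampler = emcee.EnsembleSampler(nw, p, log_prob, vectorize=True, moves=moves)
        sampler.random_state = np.random.RandomState(
            rng.integers(0, 2**31)
        ).get_state()
        sampler.run_mcmc(init, steps, progress=False)
        chain = sampler.get_chain(discard=self.warmup_steps)  # (steps, nw, p)
        chain = center + chain @ L.T  # back to the coefficient scale

        self.rhat_, self.ess_bulk_, self.mcse_mean_ = _diagnostics(
            chain, self.n_chains
        )
        self.acceptance_fraction_ = float(np.mean(sampler.acceptance_fraction))
        self.draws_ = chain.reshape(-1, p)
        self.n_draws_ = self.draws_.shape[0]
        if self.check_diagnostics:
            report = self.diagnostics_
            if np.any(self.rhat_ >= self.rhat_max) or np.any(
                self.ess_bulk_ <= self.ess_min
            ):
                raise ConvergenceError(f"MCMC diagnostics failed acceptance gates: {report}")
        return self

    @property
    def diagnostics_(self) -> dict:
        return {
            "rhat": [float(r) for r in self.rhat_],
            "ess_bulk": [float(e) for e in self.ess_bulk_],
            "mcse_mean": [float(m) for m in self.mcse_mean_],
            "acceptance_fraction": self.acceptance_fraction_,
            "n_draws": int(self.n_draws_),
        }

    def posterior_mean_(self) -> np.ndarray:
        return self.draws_.mean(axis=0)


def _diagnostics(chain: np.ndarray, n_chains: int) -> tuple[np.ndarray, ...]:
    """Split-R-hat, bulk ESS and MCSE from an (steps, walkers, p) chain.

    Walkers are concatenated into ``n_chains`` groups; arviz then applies its
    rank-normalized split-R-hat and ESS to the grouped chains.
    """
    import arviz as az

    steps, nw, p = chain.shape
    per = nw // n_chains
    grouped = (
        chain[:, : per * n_chains, :]
        .reshape(steps, n_chains, per, p)
        .transpose(1, 2, 0, 3)
        .reshape(n_chains, per * steps, p)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(grouped)
        rhat = az.rhat(ds)["x"].to_numpy()
        ess = az.ess(ds)["x"].to_numpy()
        mcse = az.mcse(ds)["x"].to_numpy()
    return np.atleast_1d(rhat), np.atleast_1d(ess), np.atleast_1d(mcse)


def fit_mle(X, y, groups) -> ConditionalLogisticRegression:
    """Maximum-likelihood fit; see :class:`ConditionalLogisticRegression`."""
    return ConditionalLogisticRegression().fit(X, y, groups)


def sample_posterior(
    X,
    y,
    groups,
    prior_scale: float | None = 5.0,
    seed: int | None = None,
    **mcmc_kwargs,
) -> BayesianConditionalLogistic:
    """Posterior sampling; see :class:`BayesianConditionalLogistic`."""
    return BayesianConditionalLogistic(
        prior_scale=prior_scale, random_state=seed, **mcmc_kwargs
    ).fit(X, y, groups)
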
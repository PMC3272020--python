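"""Maximum-posterior EM fitting of the Dirichlet multinomial mixture.

The E-step computes responsibilities by Bayes' theorem from the closed-form
per-component evidences; the M-step updates the mixture weights in closed
form and maximises each component's share of the expected log posterior over
lam = log(alpha) with BFGS, using an analytic digamma gradient.  The Gamma
hyperprior on every alpha_kj keeps parameters for unobserved taxa finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp

from .core import (
    CountMatrix,
    DirichletComponent,
    Hyperprior,
    MixtureModel,
    _log_weights,
    log_component_evidence_matrix,
    log_dataset_evidence,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "responsibilities",
    "log_hyperprior",
    "expected_log_posterior",
    "update_weights",
    "optimize_component",
    "fit_dmm",
]

_LAM_FLOOR = np.log(1e-6)


@dataclass(frozen=True)
class FitConfig:
    """Settings for one EM fit.

    max_em_iters caps the number of full EM cycles; em_rel_tol is the
    relative change of the expected-log-posterior bound below which the fit
    is declared converged.  optimizer_grad_tol is the BFGS gradient sup-norm
    target in the per-component M-step.  n_restarts runs independent
    initialisations (seeds derived from ``seed``) and keeps the best final
    objective.
    """

    hyperprior: Hyperprior = field(default_factory=Hyperprior)
    max_em_iters: int = 250
    em_rel_tol: float = 1e-6
    optimizer_grad_tol: float = 1e-5
    n_restarts: int = 1
    seed: int = 0
    init_method: str = "kmeans"  # or "random_soft"

    def __post_init__(self) -> None:
        if self.max_em_iters < 1:
            raise ValueError("max_em_iters must be >= 1")
        if self.em_rel_tol <= 0 or self.optimizer_grad_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.init_method not in ("kmeans", "random_soft"):
            raise ValueError("init_method must be 'kmeans' or 'random_soft'")


@dataclass(frozen=True)
class Responsibilities:
    """N x K posterior membership probabilities E[z_ik]; rows sum to 1."""

    z: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2:
            raise ValueError("z must be 2-D")
        if np.any(z < -1e-12) or np.any(z > 1 + 1e-12):
            raise ValueError("responsibilities must lie in [0, 1]")
        if not np.allclose(z.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("responsibility rows must sum to 1")
        object.__setattr__(self, "z", z)


@dataclass
class FitResult:
    """Converged maximum-posterior estimate (MPE) of one DMM fit."""

    model: MixtureModel
    responsibilities: Responsibilities
    lower_bound_trace: list[float]
    neg_log_posterior: float
    converged: bool
    config: FitConfig
    optimizer_warnings: int = 0
    empty_components: list[int] = field(default_factory=list)


def responsibilities(X: CountMatrix, model: MixtureModel) -> Responsibilities:
    """E-step: z_ik = pi_k p(x_i|alpha_k) / sum_l pi_l p(x_i|alpha_l)."""
    log_ev = log_component_evidence_matrix(X, model, include_coefficient=False)
    log_num = log_ev + _log_weights(model.weights)[None, :]
    z = np.exp(log_num - logsumexp(log_num, axis=1, keepdims=True))
    return Responsibilities(z=z)


def log_hyperprior(model: MixtureModel, hp: Hyperprior) -> float:
    """Log density of the Gamma hyperprior evaluated in lam = log(alpha) space.

    After the change of variables the per-parameter density is
    eta*log(nu) - lnGamma(eta) + eta*lam - nu*exp(lam); the total sums over
    all K*S parameters.
    """
    const = hp.eta * np.log(hp.nu) - gammaln(hp.eta)
    total = 0.0
    for comp in model.components:
        total += float(np.sum(const + hp.eta * comp.lam - hp.nu * np.exp(comp.lam)))
    return total


def expected_log_posterior(
    X: CountMatrix, z: Responsibilities, model: MixtureModel, hp: Hyperprior
) -> float:
    """EM objective: sum_ik z_ik [log pi_k + log p(x_i|alpha_k)] + log hyperprior.

    This is the Jensen lower bound on the (complete-data) log posterior of
    the hyperparameters; EM never decreases it.  The multinomial coefficient
    is included so that at K=1 the bound equals the dataset log evidence plus
    the hyperprior term.
    """
    zm = z.z
    log_ev = log_component_evidence_matrix(X, model, include_coefficient=True)
    terms = log_ev + _log_weights(model.weights)[None, :]
    # z_ik = 0 kills the term even when log pi_k = -inf
    vals = np.where(zm > 0, zm * terms, 0.0)
    return float(vals.sum()) + log_hyperprior(model, hp)


def update_weights(z: Responsibilities) -> np.ndarray:
    """Closed-form weight M-step: pi_k = (1/N) sum_i z_ik."""
    return z.z.mean(axis=0)


def _component_objective(
    lam: np.ndarray,
    counts: np.ndarray,
    totals: np.ndarray,
    z_col: np.ndarray,
    hp: Hyperprior,
):
    """Negative responsibility-weighted log evidence + hyperprior, with gradient.

    Only the lam-dependent terms are kept (the multinomial coefficient and
    the hyperprior normalising constant are dropped).
    """
    alpha = np.exp(lam)
    if not np.all(np.isfinite(alpha)):
        return np.inf, np.zeros_like(lam)
    theta = alpha.sum()
    f = (
        z_col @ (gammaln(counts + alpha).sum(axis=1) - gammaln(totals + theta))
        + z_col.sum() * (gammaln(theta) - gammaln(alpha).sum())
        + np.sum(hp.eta * lam - hp.nu * alpha)
    )
    if not np.isfinite(f):
        return np.inf, np.zeros_like(lam)
    dig_tot = z_col.sum() * digamma(theta) - z_col @ digamma(totals + theta)
    dig_a = z_col @ digamma(counts + alpha) - z_col.sum() * digamma(alpha)
    grad = alpha * (dig_a + dig_tot) + hp.eta - hp.nu * alpha
    return -f, -grad


def optimize_component(
    X: CountMatrix,
    z_col: np.ndarray,
    lam0: np.ndarray,
    hp: Hyperprior,
    cfg: FitConfig,
) -> tuple[np.ndarray, bool]:
    """M-step for one component: BFGS maximisation of its share of the bound.

    Returns the optimised lam vector and a flag that is False when the
    optimiser hit its iteration cap before reaching the gradient tolerance
    (the best iterate is still returned).
    """
    z_col = np.asarray(z_col, dtype=float)
    if np.any(z_col < -1e-12) or np.any(z_col > 1 + 1e-12):
        raise ValueError("z_col entries must lie in [0, 1]")
    counts = X.counts.astype(float)
    totals = X.row_totals.astype(float)
    res = minimize(
        _component_objective,
        np.asarray(lam0, dtype=float),
        args=(counts, totals, z_col, hp),
        method="BFGS",
        jac=True,
        options={"gtol": cfg.optimizer_grad_tol, "maxiter": 500},
    )
    ok = bool(np.max(np.abs(res.jac)) <= cfg.optimizer_grad_tol * 10)
    if not ok:
        warnings.warn(
            f"component optimizer stopped with gradient sup-norm {np.max(np.abs(res.jac)):.2e}",
            UserWarning,
            stacklevel=2,
        )
    return res.x, ok


def _init_responsibilities(
    X: CountMatrix, K: int, cfg: FitConfig, rng: np.random.Generator, seed: int
) -> np.ndarray:
    if K == 1:
        return np.ones((X.n_samples, 1))
    if cfg.init_method == "kmeans" and K <= X.n_samples:
        from sklearn.cluster import KMeans

        p = X.relative_abundances()
        km = KMeans(n_clusters=K, n_init=1, random_state=seed % (2**31))
        labels = km.fit_predict(p)
        z = np.zeros((X.n_samples, K))
        z[np.arange(X.n_samples), labels] = 1.0
        # guard against empty clusters from degenerate data
        for k in range(K):
            if z[:, k].sum() == 0:
                z[rng.integers(X.n_samples), :] = 0.0
                z[rng.integers(X.n_samples), k] = 1.0
        return z
    return rng.dirichlet(np.ones(K), size=X.n_samples)


def _init_lambda(X: CountMatrix, z: np.ndarray) -> np.ndarray:
    """Scale-aware start: weighted mean relative abundance times theta0 = S/2."""
    p = X.relative_abundances()
    S = X.n_taxa
    K = z.shape[1]
    lam0 = np.empty((K, S))
    theta0 = S / 2.0
    for k in range(K):
        w = z[:, k]
        tot = w.sum()
        mean_p = (w @ p) / tot if tot > 0 else np.full(S, 1.0 / S)
        lam0[k] = np.log(np.maximum(mean_p * theta0, 1e-6))
    return lam0


def _single_fit(X: CountMatrix, K: int, cfg: FitConfig, seed: int) -> FitResult:
    rng = np.random.default_rng(seed)
    hp = cfg.hyperprior
    z = _init_responsibilities(X, K, cfg, rng, seed)
    lam = _init_lambda(X, z)
    weights = z.mean(axis=0)
    n_warn = 0
    # initial M-step from the hard/soft init
    for k in range(K):
        lam[k], ok = optimize_component(X, z[:, k], lam[k], hp, cfg)
        n_warn += not ok
    model = MixtureModel(
        components=[DirichletComponent(lam=lam[k]) for k in range(K)], weights=weights
    )
    trace: list[float] = []
    converged = False
    empty: list[int] = []
    resp = responsibilities(X, model)
    for _ in range(cfg.max_em_iters):
        z = resp.z
        weights = update_weights(resp)
        empty = [k for k in range(K) if z[:, k].sum() < 1e-8]
        for k in range(K):
            lam[k], ok = optimize_component(X, z[:, k], lam[k], hp, cfg)
            n_warn += not ok
        model = MixtureModel(
            components=[DirichletComponent(lam=lam[k]) for k in range(K)],
            weights=weights,
        )
        # trace the exact log posterior (evidence x hyperprior), which EM
        # never decreases; the entropy-free expected complete-data objective
        # can dip by optimizer noise near convergence
        bound = log_dataset_evidence(X, model) + log_hyperprior(model, hp)
        trace.append(bound)
        if len(trace) >= 2:
            prev = trace[-2]
            rel = abs(bound - prev) / max(abs(prev), 1.0)
            if rel < cfg.em_rel_tol:
                converged = True
                break
        resp = responsibilities(X, model)
    if empty:
        warnings.warn(
            f"component(s) {empty} received negligible responsibility; their "
            "parameters are hyperprior-dominated",
            UserWarning,
            stacklevel=2,
        )
    resp = responsibilities(X, model)
    return FitResult(
        model=model,
        responsibilities=resp,
        lower_bound_trace=trace,
        neg_log_posterior=-trace[-1],
        converged=converged,
        config=cfg,
        optimizer_warnings=n_warn,
        empty_components=empty,
    )


def fit_dmm(X: CountMatrix, K: int, cfg: FitConfig | None = None) -> FitResult:
    """Fit a K-component DMM by maximum-posterior EM.

    Alternates the responsibility E-step, the closed-form weight update and
    per-component BFGS maximisation until the relative change of the expected
    log posterior falls below ``em_rel_tol``.  With ``n_restarts > 1`` the
    best final objective across independently initialised runs is kept.
    Deterministic for a given config and seed.
    """
    if cfg is None:
        cfg = FitConfig()
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > X.n_samples:
        warnings.warn(
            f"K={K} exceeds the number of samples N={X.n_samples}",
            UserWarning,
            stacklevel=2,
        )
    best: FitResult | None = None
    for r in range(cfg.n_restarts):
        seed = (cfg.seed + 1000003 * r) % (2**31)
        fit = _single_fit(X, K, cfg, seed)
        if best is None or -fit.neg_log_posterior > -best.neg_log_posterior:
            best = fit
    assert best is not None
    return best
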
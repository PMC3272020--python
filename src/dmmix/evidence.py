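"""Laplace-approximated model evidence for choosing the number of components.

The log model evidence is approximated at the maximum posterior estimate as

    log p(X | K) ~= log posterior(Theta*) + (P/2) log 2pi - (1/2) log det H,

where H is the Hessian of the negative expected log posterior at Theta* with
responsibilities frozen at their converged values, and P the number of free
parameters.  The negative of this quantity is reported so that a better fit
corresponds to a smaller value.  The inverse Hessian's diagonal supplies
approximate credible intervals for the component compositions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .core import CountMatrix, Hyperprior, log_dataset_evidence
from .em import FitConfig, FitResult, fit_dmm, log_hyperprior

__all__ = [
    "LaplaceResult",
    "ModelSelectionResult",
    "CredibleIntervalTable",
    "neg_log_posterior_hessian",
    "laplace_evidence",
    "select_k",
    "credible_intervals",
]

_EIG_FLOOR = 1e-10


def _trigamma(x):
    return polygamma(1, x)


@dataclass(frozen=True)
class LaplaceResult:
    """Negative Laplace log evidence and the pieces that produced it."""

    neg_laplace_log_evidence: float
    P: int
    log_det_hessian: float
    hessian_condition_ok: bool
    include_weight_block: bool = True


@dataclass
class ModelSelectionResult:
    """Evidence sweep over candidate component numbers K."""

    k_values: list[int]
    neg_evidences: list[float]
    best_k: int
    fits: list[FitResult]
    laplace_results: list[LaplaceResult] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.k_values, "neg_log_evidence": self.neg_evidences})


@dataclass
class CredibleIntervalTable:
    """Per component and taxon: (lower, mpe, upper) relative abundance in %."""

    lower: np.ndarray  # K x S
    mpe: np.ndarray
    upper: np.ndarray
    taxon_names: list[str]

    def as_frame(self) -> pd.DataFrame:
        K, S = self.mpe.shape
        rows = []
        for k in range(K):
            for j in range(S):
                rows.append(
                    {
                        "component": k + 1,
                        "taxon": self.taxon_names[j],
                        "lower_pct": self.lower[k, j],
                        "mpe_pct": self.mpe[k, j],
                        "upper_pct": self.upper[k, j],
                    }
                )
        return pd.DataFrame(rows)


def neg_log_posterior_hessian(
    X: CountMatrix, fit: FitResult, include_weight_block: bool = True
) -> np.ndarray:
    """Analytic Hessian of the negative expected log posterior at the MPE.

    Responsibilities are held at their converged values, so the matrix is
    block diagonal: one dense S x S block per component in lam = log(alpha)
    (digamma/trigamma curvature of the marginal evidence plus the
    nu*exp(lam) hyperprior diagonal) and, optionally, a (K-1) x (K-1) block
    for softmax-reparameterised mixture weights.
    """
    if not fit.converged:
        warnings.warn("Hessian requested for a non-converged fit", UserWarning, stacklevel=2)
    model = fit.model
    K, S = model.n_components, model.n_taxa
    z = fit.responsibilities.z
    counts = X.counts.astype(float)
    totals = X.row_totals.astype(float)
    nu = fit.config.hyperprior.nu
    P = K * S + (K - 1 if include_weight_block else 0)
    H = np.zeros((P, P))
    for k, comp in enumerate(model.components):
        a = comp.alpha
        th = a.sum()
        w = z[:, k]
        wsum = w.sum()
        # curvature pieces of the responsibility-weighted log evidence
        A = w @ digamma(counts + a) - wsum * digamma(a)
        B = wsum * digamma(th) - float(w @ digamma(totals + th))
        C = w @ _trigamma(counts + a) - wsum * _trigamma(a)
        D = wsum * _trigamma(th) - float(w @ _trigamma(totals + th))
        block = np.outer(a, a) * D
        block[np.diag_indices(S)] += a * (A + B) + a**2 * C - nu * a
        # H is the Hessian of the NEGATIVE objective
        H[k * S : (k + 1) * S, k * S : (k + 1) * S] = -block
        bad = np.argwhere(~np.isfinite(block))
        if bad.size:
            raise FloatingPointError(
                f"non-finite Hessian entry at component {k}, taxon index {bad[0]}"
            )
    if include_weight_block and K > 1:
        # softmax pi_k = exp(g_k)/sum_l exp(g_l), g_K fixed; objective part
        # sum_k N_k log pi_k with N_k = sum_i z_ik gives N (diag(pi) - pi pi^T)
        # on the K-1 free coordinates.
        pi = model.weights
        N = X.n_samples
        Wb = N * (np.diag(pi[:-1]) - np.outer(pi[:-1], pi[:-1]))
        H[K * S :, K * S :] = Wb
    return H


def laplace_evidence(
    X: CountMatrix, fit: FitResult, include_weight_block: bool = True
) -> LaplaceResult:
    """Negative Laplace log evidence of a converged fit.

    Uses the true log posterior (dataset log evidence plus log hyperprior) at
    the MPE and the frozen-responsibility Hessian.  Near-singular or
    indefinite Hessians are handled by flooring eigenvalues at 1e-10 and
    flagging the result rather than raising, so a model-selection sweep
    always completes.
    """
    H = neg_log_posterior_hessian(X, fit, include_weight_block)
    P = H.shape[0]
    eigvals = np.linalg.eigvalsh(H)
    ok = bool(np.all(eigvals > _EIG_FLOOR))
    log_det = float(np.sum(np.log(np.maximum(eigvals, _EIG_FLOOR))))
    log_post = log_dataset_evidence(X, fit.model) + log_hyperprior(
        fit.model, fit.config.hyperprior
    )
    log_ev = log_post + 0.5 * P * np.log(2 * np.pi) - 0.5 * log_det
    return LaplaceResult(
        neg_laplace_log_evidence=float(-log_ev),
        P=P,
        log_det_hessian=log_det,
        hessian_condition_ok=ok,
        include_weight_block=include_weight_block,
    )


def select_k(
    X: CountMatrix,
    k_min: int,
    k_max: int,
    cfg: FitConfig | None = None,
    include_weight_block: bool = True,
) -> ModelSelectionResult:
    """Fit every K in [k_min, k_max] and pick the smallest negative evidence."""
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    if cfg is None:
        cfg = FitConfig()
    k_values: list[int] = []
    neg_evs: list[float] = []
    fits: list[FitResult] = []
    laps: list[LaplaceResult] = []
    for K in range(k_min, k_max + 1):
        try:
            fit = fit_dmm(X, K, cfg)
            lap = laplace_evidence(X, fit, include_weight_block)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"fit for K={K} failed ({exc}); skipping", UserWarning, stacklevel=2)
            continue
        k_values.append(K)
        neg_evs.append(lap.neg_laplace_log_evidence)
        fits.append(fit)
        laps.append(lap)
    if not k_values:
        raise RuntimeError("every candidate K failed to fit")
    best_k = k_values[int(np.argmin(neg_evs))]
    return ModelSelectionResult(
        k_values=k_values,
        neg_evidences=neg_evs,
        best_k=best_k,
        fits=fits,
        laplace_results=laps,
    )


def credible_intervals(
    fit: FitResult,
    laplace: LaplaceResult | None = None,
    X: CountMatrix | None = None,
    taxon_names: list[str] | None = None,
) -> CredibleIntervalTable:
    """Approximate 95% credible intervals on component compositions.

    The lam-scale standard deviation sigma_kj is the square root of the
    corresponding diagonal element of the inverse Hessian; the interval
    endpoints exp(lam +/- 2 sigma) are mapped to relative abundance by
    renormalising against the other parameters of the component, and
    reported in percent.  Parameters whose Hessian block is singular get
    NaN endpoints.
    """
    if X is None:
        raise ValueError("X (the fitted count matrix) is required to form the Hessian")
    include_wb = laplace.include_weight_block if laplace is not None else True
    H = neg_log_posterior_hessian(X, fit, include_weight_block=include_wb)
    model = fit.model
    K, S = model.n_components, model.n_taxa
    sigma = np.full((K, S), np.nan)
    try:
        Hinv = np.linalg.inv(H)
        diag = np.diag(Hinv)[: K * S]
        with np.errstate(invalid="ignore"):
            sigma = np.sqrt(np.where(diag > 0, diag, np.nan)).reshape(K, S)
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian; intervals reported as missing", UserWarning, stacklevel=2)
    lower = np.full((K, S), np.nan)
    mpe = np.full((K, S), np.nan)
    upper = np.full((K, S), np.nan)
    for k, comp in enumerate(model.components):
        a = comp.alpha
        th = a.sum()
        mpe[k] = 100.0 * a / th
        rest = th - a
        for bound_arr, sign in ((lower, -1.0), (upper, +1.0)):
            end = np.exp(comp.lam + sign * 2.0 * sigma[k])
            bound_arr[k] = 100.0 * end / (end + rest)
    lo = np.minimum(lower, upper)
    hi = np.maximum(lower, upper)
    names = taxon_names or (X.taxon_names if X is not None else [f"taxon_{j}" for j in range(S)])
    return CredibleIntervalTable(lower=lo, mpe=mpe, upper=hi, taxon_names=list(names))
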
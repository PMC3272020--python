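"""Exact probability computations for the Dirichlet multinomial mixture.

All evidence arithmetic is carried out in log space through ``gammaln``;
Gamma-function values are never exponentiated directly, so library sizes in
the tens of thousands are handled without overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "CountMatrix",
    "DirichletComponent",
    "MixtureModel",
    "Hyperprior",
    "PosteriorMixture",
    "log_multinomial_beta",
    "log_component_evidence",
    "log_mixture_evidence",
    "posterior_mixture",
    "component_mean",
]


class InvalidParameterError(ValueError):
    """A Dirichlet parameter vector is non-positive or non-finite."""


@dataclass(frozen=True)
class CountMatrix:
    """Samples-by-taxa matrix of non-negative integer read counts.

    Rows are community samples, columns are taxa/OTUs/genera.  ``row_totals``
    gives the library size J_i of each sample.
    """

    counts: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    taxon_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("counts must be a 2-D matrix with N >= 1, S >= 1")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValueError("counts must be integral")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(f"negative count at sample row {i}, taxon column {j}")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        n, s = counts.shape
        sample_ids = self.sample_ids
        if sample_ids is None:
            sample_ids = [f"sample_{i}" for i in range(n)]
        taxon_names = self.taxon_names
        if taxon_names is None:
            taxon_names = [f"taxon_{j}" for j in range(s)]
        sample_ids = [str(x) for x in sample_ids]
        taxon_names = [str(x) for x in taxon_names]
        if len(sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(taxon_names) != s:
            raise ValueError("taxon_names length does not match number of columns")
        if len(set(sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(taxon_names)) != s:
            raise ValueError("taxon_names must be unique")
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "taxon_names", taxon_names)
        empty = np.flatnonzero(self.row_totals == 0)
        if empty.size:
            warnings.warn(
                f"{empty.size} sample(s) have zero total counts "
                f"(first: {sample_ids[empty[0]]}); their evidence is 1",
                UserWarning,
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        """Library sizes J_i = sum_j x_ij."""
        return self.counts.sum(axis=1)

    def relative_abundances(self) -> np.ndarray:
        """Row-normalised counts; all-zero rows map to uniform."""
        totals = self.row_totals.astype(float)
        safe = np.where(totals > 0, totals, 1.0)
        p = self.counts / safe[:, None]
        p[totals == 0] = 1.0 / self.n_taxa
        return p


def _validate_alpha(alpha: np.ndarray) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 1 or alpha.size < 1:
        raise InvalidParameterError("alpha must be a non-empty 1-D vector")
    if not np.all(np.isfinite(alpha)) or np.any(alpha <= 0):
        raise InvalidParameterError("alpha entries must be finite and strictly positive")
    return alpha


@dataclass(frozen=True)
class DirichletComponent:
    """One Dirichlet metacommunity, parameterised by lam = log(alpha).

    ``alpha`` is the Dirichlet parameter vector, ``theta = sum(alpha)`` its
    precision (large theta concentrates communities near the mean), and
    ``mean = alpha / theta`` the expected community composition.
    """

    lam: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam, dtype=float)
        if lam.ndim != 1 or lam.size < 1:
            raise InvalidParameterError("lam must be a non-empty 1-D vector")
        if not np.all(np.isfinite(lam)):
            raise InvalidParameterError("lam entries must be finite")
        object.__setattr__(self, "lam", lam)

    @classmethod
    def from_alpha(cls, alpha) -> "DirichletComponent":
        return cls(lam=np.log(_validate_alpha(np.asarray(alpha, dtype=float))))

    @property
    def alpha(self) -> np.ndarray:
        return np.exp(self.lam)

    @property
    def theta(self) -> float:
        """Precision theta = sum_j alpha_j."""
        return float(self.alpha.sum())

    @property
    def mean(self) -> np.ndarray:
        """Mean composition m = alpha / theta (on the simplex)."""
        a = self.alpha
        return a / a.sum()

    @property
    def n_taxa(self) -> int:
        return self.lam.size


@dataclass(frozen=True)
class MixtureModel:
    """K Dirichlet components with mixture weights pi on the simplex."""

    components: list[DirichletComponent]
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("need at least one component")
        s = self.components[0].n_taxa
        if any(c.n_taxa != s for c in self.components):
            raise ValueError("all components must share the taxon dimension")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.components),):
            raise ValueError("weights length must equal number of components")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-8):
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w / w.sum())

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_taxa(self) -> int:
        return self.components[0].n_taxa

    def mean_matrix(self) -> np.ndarray:
        """K x S matrix of component mean compositions."""
        return np.stack([c.mean for c in self.components])

    def alpha_matrix(self) -> np.ndarray:
        return np.stack([c.alpha for c in self.components])


@dataclass(frozen=True)
class Hyperprior:
    """I.i.d. Gamma(eta, nu) hyperprior on every Dirichlet parameter alpha_kj.

    ``eta`` is the shape and ``nu`` the rate; the default (0.1, 0.1) has mean
    1 and is vague, regularising taxa with no reads away from alpha -> 0.
    """

    eta: float = 0.1
    nu: float = 0.1

    def __post_init__(self) -> None:
        if not (self.eta > 0 and self.nu > 0):
            raise ValueError("eta and nu must be positive")


@dataclass(frozen=True)
class PosteriorMixture:
    """Posterior over a sample's community vector: again a Dirichlet mixture.

    Component k has parameters alpha_k + x (conjugate update) and weight equal
    to the posterior probability that the sample derives from metacommunity k.
    """

    components: list[DirichletComponent]
    weights: np.ndarray


def log_multinomial_beta(alpha) -> float:
    """Log multinomial Beta function log B(alpha) = sum_j lnGamma(alpha_j) - lnGamma(sum_j alpha_j).

    B(alpha) is the normalising constant of the Dirichlet distribution.
    """
    alpha = _validate_alpha(alpha)
    return float(gammaln(alpha).sum() - gammaln(alpha.sum()))


def _log_multinomial_coeff(x: np.ndarray) -> np.ndarray:
    """Row-wise log multinomial coefficient log(J! / prod_j x_j!)."""
    x = np.asarray(x, dtype=float)
    return gammaln(x.sum(axis=-1) + 1) - gammaln(x + 1).sum(axis=-1)


def _check_counts_vector(x) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError("x must be a 1-D count vector")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("x must contain non-negative integers")
    return x.astype(np.int64)


def log_component_evidence(x, comp: DirichletComponent, include_coefficient: bool = True) -> float:
    """Log marginal likelihood log p(x | alpha) of a count vector under one Dirichlet.

    The latent community composition integrates out analytically:
    log p(x|alpha) = [log multinomial coefficient] + log B(alpha + x) - log B(alpha).
    With the coefficient included the values are true probabilities that sum
    to one over all count vectors of a given total; the coefficient is
    constant in the parameters and so never affects fitting or model
    comparison at fixed data.
    """
    x = _check_counts_vector(x)
    alpha = comp.alpha
    if x.size != alpha.size:
        raise ValueError(f"dimension mismatch: x has {x.size} taxa, alpha has {alpha.size}")
    out = log_multinomial_beta(alpha + x) - log_multinomial_beta(alpha)
    if include_coefficient:
        out += float(_log_multinomial_coeff(x))
    return float(out)


def log_component_evidence_matrix(
    X: CountMatrix, model: MixtureModel, include_coefficient: bool = True
) -> np.ndarray:
    """N x K matrix of log p(x_i | alpha_k), vectorised over samples and components."""
    counts = X.counts
    if counts.shape[1] != model.n_taxa:
        raise ValueError(
            f"dimension mismatch: matrix has {counts.shape[1]} taxa, model has {model.n_taxa}"
        )
    totals = X.row_totals
    out = np.empty((X.n_samples, model.n_components))
    for k, comp in enumerate(model.components):
        a = comp.alpha
        th = a.sum()
        out[:, k] = (
            gammaln(counts + a).sum(axis=1)
            - gammaln(a).sum()
            - gammaln(totals + th)
            + gammaln(th)
        )
    if include_coefficient:
        out += _log_multinomial_coeff(counts)[:, None]
    return out


def _log_weights(weights: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(weights)


def log_mixture_evidence(x, model: MixtureModel, include_coefficient: bool = True) -> float:
    """Log evidence log p(x | Theta) = log sum_k pi_k p(x | alpha_k).

    Computed with log-sum-exp stabilisation.  The dataset-level evidence is
    the sum of this quantity over samples.
    """
    lse = np.array(
        [log_component_evidence(x, c, include_coefficient) for c in model.components]
    )
    return float(logsumexp(lse + _log_weights(model.weights)))


def log_dataset_evidence(
    X: CountMatrix, model: MixtureModel, include_coefficient: bool = True
) -> float:
    """Sum over samples of the log mixture evidence."""
    le = log_component_evidence_matrix(X, model, include_coefficient)
    return float(logsumexp(le + _log_weights(model.weights)[None, :], axis=1).sum())


def posterior_mixture(x, model: MixtureModel) -> PosteriorMixture:
    """Posterior distribution of a sample's community vector.

    By conjugacy this is again a Dirichlet mixture: component k gains the
    observed counts (alpha_k + x) and is reweighted by Bayes' theorem with
    the per-component evidences.
    """
    x = _check_counts_vector(x)
    log_ev = np.array([log_component_evidence(x, c, include_coefficient=False) for c in model.components])
    log_w = log_ev + _log_weights(model.weights)
    w = np.exp(log_w - logsumexp(log_w))
    comps = [DirichletComponent.from_alpha(c.alpha + x) for c in model.components]
    return PosteriorMixture(components=comps, weights=w)


def component_mean(comp: DirichletComponent) -> np.ndarray:
    """Mean composition m_j = alpha_j / sum_j' alpha_j' of a metacommunity."""
    return comp.mean
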
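"""Metacommunity-level summaries: clustering, difference tables, matching.

Samples are hard-assigned to the component with the highest posterior
membership probability (the enterotype/envirotype call).  Metacommunities
are compared through the sum of absolute differences of their mean
compositions to a reference — a statistic that runs from 0% for identical
means to 200% for disjoint support — and matched across fits by
Bray–Curtis distance between mean vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DirichletComponent
from .em import FitResult

__all__ = [
    "ClusterAssignment",
    "hard_assign",
    "difference_to_reference",
    "bray_curtis",
    "match_components",
    "cross_tabulate",
    "heatmap_matrix",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """Hard cluster labels (1-based) and the posterior probability of each."""

    labels: np.ndarray
    max_posterior: np.ndarray


def hard_assign(fit: FitResult) -> ClusterAssignment:
    """Assign each sample to its maximum-responsibility component.

    Ties break toward the lowest component index; labels are 1-based to
    match the usual enterotype numbering.
    """
    z = fit.responsibilities.z
    labels = np.argmax(z, axis=1) + 1
    return ClusterAssignment(labels=labels, max_posterior=z[np.arange(z.shape[0]), labels - 1])


def _means(components: list[DirichletComponent] | np.ndarray) -> np.ndarray:
    if isinstance(components, np.ndarray):
        return np.atleast_2d(np.asarray(components, dtype=float))
    return np.stack([c.mean for c in components])


def difference_to_reference(
    components: list[DirichletComponent] | np.ndarray,
    reference: DirichletComponent | np.ndarray,
    taxon_names: list[str] | None = None,
) -> pd.DataFrame:
    """Decompose how each component's mean differs from a reference mean.

    Per component k the total difference d_k = 100 * sum_j |m_kj - m_ref,j|
    runs from 0% (identical) to 200% (disjoint support).  Per taxon the
    contribution c_j = 100 * sum_k |m_kj - m_ref,j| is ranked descending and
    a cumulative share of the grand total reported, reproducing the layout
    of the ranked genus tables used for enterotype composition.

    Returns a DataFrame with columns ``taxon``, ``reference_pct``,
    ``component_<k>_pct``, ``diff_pct``, ``cumulative_pct`` and attrs
    ``component_totals_pct`` / ``grand_total_pct``.
    """
    M = _means(components)
    ref = reference.mean if isinstance(reference, DirichletComponent) else np.asarray(reference, float)
    if M.shape[1] != ref.size:
        raise ValueError("components and reference must share the taxon dimension")
    K, S = M.shape
    absdiff = np.abs(M - ref[None, :])
    d_k = 100.0 * absdiff.sum(axis=1)
    c_j = 100.0 * absdiff.sum(axis=0)
    grand = float(d_k.sum())
    order = np.argsort(-c_j, kind="stable")
    names = taxon_names or [f"taxon_{j}" for j in range(S)]
    cum = np.cumsum(c_j[order])
    cum_pct = 100.0 * cum / grand if grand > 0 else np.zeros(S)
    data = {
        "taxon": [names[j] for j in order],
        "reference_pct": 100.0 * ref[order],
    }
    for k in range(K):
        data[f"component_{k + 1}_pct"] = 100.0 * M[k, order]
    data["diff_pct"] = c_j[order]
    data["cumulative_pct"] = cum_pct
    table = pd.DataFrame(data)
    table.attrs["component_totals_pct"] = d_k.tolist()
    table.attrs["grand_total_pct"] = grand
    return table


def bray_curtis(u, v) -> float:
    """Bray–Curtis dissimilarity 1 - sum_j min(u_j, v_j) of two relative-abundance profiles.

    For inputs on the simplex this equals the general form
    1 - 2*sum(min)/(sum u + sum v); it is 0 for identical and 1 for
    disjoint-support profiles.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("profiles must share the taxon dimension")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("profiles must be non-negative")
    return float(1.0 - 2.0 * np.minimum(u, v).sum() / (u.sum() + v.sum()))


def match_components(means_a, means_b) -> tuple[dict[int, int], np.ndarray]:
    """Match each mean vector of A to its Bray–Curtis-nearest partner in B.

    Greedy one-to-one matching (smallest distance claimed first) when
    |A| <= |B|; otherwise each A component independently takes its nearest
    B partner.  The full |A| x |B| distance matrix is returned for audit.
    """
    A = _means(means_a)
    B = _means(means_b)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("component lists must be non-empty")
    D = np.array([[bray_curtis(a, b) for b in B] for a in A])
    mapping: dict[int, int] = {}
    if A.shape[0] <= B.shape[0]:
        work = D.copy()
        for _ in range(A.shape[0]):
            i, j = np.unravel_index(np.argmin(work), work.shape)
            mapping[int(i)] = int(j)
            work[i, :] = np.inf
            work[:, j] = np.inf
    else:
        for i in range(A.shape[0]):
            mapping[int(i)] = int(np.argmin(D[i]))
    return mapping, D


def cross_tabulate(assignment: ClusterAssignment, labels) -> pd.DataFrame:
    """Row-normalised percentage of each category's samples in each cluster.

    ``labels`` is a per-sample sequence of categories (e.g. BMI classes);
    rows sum to 100% within rounding.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != assignment.labels.shape[0]:
        raise ValueError("labels must align with the assigned samples")
    tab = pd.crosstab(pd.Series(labels, name="class"), pd.Series(assignment.labels, name="cluster"))
    return 100.0 * tab.div(tab.sum(axis=1), axis=0)


def heatmap_matrix(rel_abundance: np.ndarray) -> np.ndarray:
    """Square-root transform for heat-map export (square values to recover relative abundance)."""
    return np.sqrt(np.asarray(rel_abundance, dtype=float))
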
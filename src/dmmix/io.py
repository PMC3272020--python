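"""Readers and writers for count tables and fitted-model files.

TSV is the canonical dialect (header row of taxon names, first column the
sample IDs); commas are accepted on read by sniffing.  Taxa-as-rows exports
common in amplicon pipelines are handled with a transpose flag.  BIOM 1.0
(JSON) tables are read directly.  Fitted models round-trip through a
schema-versioned JSON document that records every setting needed to
regenerate the fit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CountMatrix, DirichletComponent, Hyperprior, MixtureModel
from .em import FitConfig, FitResult, Responsibilities

__all__ = [
    "read_counts",
    "write_counts",
    "write_model",
    "read_model",
    "MODEL_SCHEMA_VERSION",
]

MODEL_SCHEMA_VERSION = 1


def _read_biom_json(path: Path) -> pd.DataFrame:
    doc = json.loads(path.read_text())
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat = np.asarray(doc["data"], dtype=float)
    # BIOM stores observations (taxa) as rows; transpose to samples-as-rows
    return pd.DataFrame(mat.T, index=samples, columns=taxa)


def read_counts(path, taxa_as_rows: bool = False) -> CountMatrix:
    """Load a count table from TSV/CSV (or BIOM-JSON) into a CountMatrix.

    Delimited text must carry a header row of taxon names and sample IDs in
    the first column; set ``taxa_as_rows=True`` for the transposed layout.
    Negative, fractional or duplicate entries are rejected with the
    offending coordinate named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".biom":
        df = _read_biom_json(path)
    else:
        sep = None
        head = path.read_text().splitlines()[0] if path.stat().st_size else ""
        sep = "\t" if "\t" in head else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if taxa_as_rows:
            df = df.T
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate taxon name {dup!r}")
    vals = df.to_numpy()
    bad = np.argwhere(~np.isfinite(vals.astype(float)) | (vals.astype(float) < 0)
                      | (vals.astype(float) != np.floor(vals.astype(float))))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"invalid count {vals[i, j]!r} at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
        )
    return CountMatrix(
        counts=vals.astype(np.int64),
        sample_ids=[str(s) for s in df.index],
        taxon_names=[str(t) for t in df.columns],
    )


def write_counts(X: CountMatrix, path) -> None:
    """Write a CountMatrix as TSV in the samples-as-rows dialect read_counts consumes."""
    df = pd.DataFrame(X.counts, index=X.sample_ids, columns=X.taxon_names)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    """Read a two-column (sample ID, label) TSV/CSV into a Series."""
    path = Path(path)
    head = path.read_text().splitlines()[0]
    sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: sample ID and label")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def write_model(fit: FitResult, path, extra: dict | None = None) -> None:
    """Serialise a FitResult (model, hyperprior, config, trace) to JSON."""
    model = fit.model
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "K": model.n_components,
        "n_taxa": model.n_taxa,
        "weights": model.weights.tolist(),
        "components": [
            {
                "lam": c.lam.tolist(),
                "alpha": c.alpha.tolist(),
                "theta": c.theta,
                "mean": c.mean.tolist(),
            }
            for c in model.components
        ],
        "hyperprior": {"eta": fit.config.hyperprior.eta, "nu": fit.config.hyperprior.nu},
        "fit": {
            "seed": fit.config.seed,
            "max_em_iters": fit.config.max_em_iters,
            "em_rel_tol": fit.config.em_rel_tol,
            "optimizer_grad_tol": fit.config.optimizer_grad_tol,
            "n_restarts": fit.config.n_restarts,
            "init_method": fit.config.init_method,
            "converged": fit.converged,
            "neg_log_posterior": fit.neg_log_posterior,
            "lower_bound_trace": list(fit.lower_bound_trace),
            "multinomial_coefficient_included": True,
            "hessian_weight_block_default": True,
        },
        "responsibilities": fit.responsibilities.z.tolist(),
    }
    if extra:
        doc["extra"] = extra
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model(path) -> FitResult:
    """Load a model JSON written by write_model back into a FitResult."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {doc.get('schema_version')!r}")
    comps = [DirichletComponent(lam=np.array(c["lam"])) for c in doc["components"]]
    model = MixtureModel(components=comps, weights=np.array(doc["weights"]))
    hp = Hyperprior(eta=doc["hyperprior"]["eta"], nu=doc["hyperprior"]["nu"])
    f = doc["fit"]
    cfg = FitConfig(
        hyperprior=hp,
        max_em_iters=f["max_em_iters"],
        em_rel_tol=f["em_rel_tol"],
        optimizer_grad_tol=f["optimizer_grad_tol"],
        n_restarts=f["n_restarts"],
        seed=f["seed"],
        init_method=f["init_method"],
    )
    return FitResult(
        model=model,
        responsibilities=Responsibilities(z=np.array(doc["responsibilities"])),
        lower_bound_trace=list(f["lower_bound_trace"]),
        neg_log_posterior=f["neg_log_posterior"],
        converged=f["converged"],
        config=cfg,
    )
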
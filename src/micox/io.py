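"""Readers and writers for the package's tab-separated text formats.

Formats:

* expression matrix -- TSV, first column sample IDs, header row gene IDs,
  samples as rows; missing values are rejected, not imputed.
* clinical table -- TSV with columns sample_id, survival_time_months,
  event_status (1 = death observed, 0 = censored).
* network edge list -- TSV gene_a / gene_b / weight (gene_a < gene_b
  lexicographically) with a JSON sidecar carrying theta/sigma metadata.
* fitted model -- coefficients TSV plus JSON sidecar (lambda, alpha,
  convergence report, Breslow baseline table).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SurvivalData, validate_expression
from .network import MINetwork

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_network",
    "write_network",
    "write_model",
    "read_model",
    "align_samples",
]


def read_expression(path) -> pd.DataFrame:
    """Load a samples x genes TSV matrix and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = path.open().readline().rstrip("\n").split("\t")[1:]
    dup = {g for g in header if header.count(g) > 1}
    if dup:
        raise ValueError(f"duplicate gene IDs: {sorted(dup)}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no gene columns found (is it tab-separated?)")
    df.index.name = None
    df.columns.name = None
    return validate_expression(df)


def write_expression(expr: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    expr.to_csv(path, sep="\t", index_label="sample_id")


def read_clinical(path) -> SurvivalData:
    """Load the clinical TSV (sample_id, survival_time_months, event_status)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "survival_time_months", "event_status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return SurvivalData.from_dataframe(df)


def write_clinical(surv: SurvivalData, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    surv.to_frame().to_csv(path, sep="\t", index=False)


def align_samples(expr: pd.DataFrame, surv: SurvivalData):
    """Join expression and clinical data on sample ID (expression order).

    Raises with the list of offending IDs when either side has samples
    the other lacks.
    """
    expr_ids = list(expr.index)
    clin_ids = set(surv.sample_ids)
    missing_clin = [s for s in expr_ids if s not in clin_ids]
    extra_clin = [s for s in surv.sample_ids if s not in set(expr_ids)]
    if missing_clin or extra_clin:
        raise ValueError(
            f"sample IDs do not match: {len(missing_clin)} expression-only "
            f"(e.g. {missing_clin[:3]}), {len(extra_clin)} clinical-only (e.g. {extra_clin[:3]})"
        )
    return expr, surv.subset(np.asarray(expr_ids))


def _sidecar(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def write_network(net: MINetwork, path) -> None:
    """Edge list TSV + JSON sidecar with genes and threshold metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    net.to_frame().to_csv(path, sep="\t", index=False)
    meta = {
        "genes": list(net.genes),
        "theta": net.theta,
        "sigma": net.sigma,
        "complete": net.complete,
        "kind": net.kind,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_network(path, genes=None) -> MINetwork:
    """Load an edge-list TSV (header optional) into an MINetwork.

    Metadata is restored from the JSON sidecar when present; otherwise
    ``genes`` must supply the node universe (defaults to the genes seen
    on edges).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    first = path.open().readline().split("\t")
    has_header = len(first) >= 3 and not _is_number(first[2])
    df = pd.read_csv(
        path, sep="\t", header=0 if has_header else None,
        names=["gene_a", "gene_b", "weight"],
    )
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    if genes is None:
        genes = meta.get("genes")
    if genes is None:
        genes = sorted(set(df["gene_a"]) | set(df["gene_b"]))
    genes = tuple(genes)
    order = {g: i for i, g in enumerate(genes)}
    unknown = sorted(
        (set(df["gene_a"]) | set(df["gene_b"])) - set(genes)
    )
    if unknown:
        raise ValueError(f"edge list references genes outside the gene universe: {unknown[:5]}")
    edges = {}
    for a, b, w in df.itertuples(index=False):
        pair = (a, b) if order[a] < order[b] else (b, a)
        edges[pair] = float(w)
    return MINetwork(
        genes=genes,
        edges=edges,
        theta=float(meta.get("theta", 0.0)),
        sigma=float(meta.get("sigma", 0.0)),
        complete=bool(meta.get("complete", False)),
        kind=meta.get("kind", "mi"),
    )


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_model(model, path) -> None:
    """Serialize a fitted NetCoxSurvival: coefficients TSV + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    genes = model.genes_ if model.genes_ is not None else [
        f"g{i}" for i in range(model.coef_.size)
    ]
    pd.DataFrame({"gene_id": list(genes), "beta": model.coef_}).to_csv(
        path, sep="\t", index=False
    )
    meta = {
        "lambda": model.lam,
        "alpha": model.alpha,
        "converged": bool(model.converged_),
        "n_iter": int(model.n_iter_),
        "objective": model.objective_value_,
        "baseline": model.baseline_hazard_.to_dict(orient="list"),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_model(path) -> dict:
    """Load a serialized model into a plain dict (beta Series + metadata)."""
    path = Path(path)
    coef = pd.read_csv(path, sep="\t").set_index("gene_id")["beta"]
    meta = json.loads(_sidecar(path).read_text())
    meta["beta"] = coef
    meta["baseline"] = pd.DataFrame(meta["baseline"])
    return meta
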
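"""Unified estimator dispatch and the tabular report writer.

``estimate_lfdr`` runs any of the six estimators on an
:class:`~enrichlfdr.contingency.EnrichmentDataset`; ``build_report`` and
``write_report`` assemble the per-category TSV that the command-line
interface emits (one row per category, '#'-prefixed metadata header,
missing cells as NA).
"""

from __future__ import annotations

import sys
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .bbe import bbe_lfdr
from .contingency import EnrichmentDataset, fisher_pvalues
from .histogram import hbe_lfdr, z_transform
from .nml import nml_ratio, nmle_lfdr
from .pmm import eb_bayes_factor, fit_pmm, mle_lfdr

__all__ = ["estimate_lfdr", "build_report", "write_report", "METHODS"]

METHODS = ("bbe", "mle2", "mle3", "hbe", "hbe_en", "nmle")

#: Bayes-factor thresholds conventionally read as strong / overwhelming
#: evidence of enrichment.
BF_STRONG = 10.0
BF_OVERWHELMING = 100.0


def estimate_lfdr(dataset: EnrichmentDataset, method: str,
                  pi0: float | None = None, seed: int = 0,
                  restarts: int = 10, **histogram_kw: Any) -> np.ndarray:
    """Per-category local-FDR estimates by the named method.

    ``pi0`` is required for (and only used by) the NML-based estimator;
    the p-value-based methods derive their p-values from the two-sided
    Fisher exact test on the dataset's tables.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if method != "nmle" and dataset.m < 2:
        raise ValueError(
            f"method {method!r} needs data for at least 2 categories; only "
            "the NML-based estimator (with a supplied pi0) handles a single "
            "category"
        )
    if method == "bbe":
        return bbe_lfdr(fisher_pvalues(dataset))
    if method in ("hbe", "hbe_en"):
        z = z_transform(fisher_pvalues(dataset))
        kind = "theoretical" if method == "hbe" else "empirical"
        return hbe_lfdr(z, null_kind=kind, **histogram_kw)
    if method in ("mle2", "mle3"):
        k = 2 if method == "mle2" else 3
        fit = fit_pmm(dataset, k=k, restarts=restarts, seed=seed)
        return mle_lfdr(fit, dataset)
    # nmle
    if pi0 is None:
        raise ValueError("the NML-based estimator requires a pi0 value")
    bfs = np.array([nml_ratio(int(t), int(s), dataset.n, dataset.N)
                    for t, s in zip(dataset.t, dataset.s)])
    return np.array([nmle_lfdr(float(bf), pi0) for bf in bfs])


def _evidence_flag(bf: float) -> str:
    if not np.isfinite(bf):
        return "overwhelming" if bf > 0 else "none"
    if bf >= BF_OVERWHELMING:
        return "overwhelming"
    if bf >= BF_STRONG:
        return "strong"
    return "none"


def build_report(dataset: EnrichmentDataset, methods: list[str],
                 pi0: float | None = None, seed: int = 0,
                 restarts: int = 10) -> pd.DataFrame:
    """One row per category with p-values and the requested LFDR columns.

    Mixture methods add empirical-Bayes Bayes-factor columns; the NML
    method adds the NML ratio, its log, and evidence flags at the 10/100
    thresholds.  Failed methods leave their columns as NA.
    """
    if not methods:
        raise ValueError("need at least one estimation method")
    for method in methods:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
    pvals = fisher_pvalues(dataset)
    out = pd.DataFrame({
        "category_id": dataset.category_ids,
        "t": dataset.t,
        "s": dataset.s,
        "p_value": pvals,
    })
    flags = [[] for _ in range(dataset.m)]
    for method in methods:
        if method in ("mle2", "mle3"):
            k = 2 if method == "mle2" else 3
            fit = fit_pmm(dataset, k=k, restarts=restarts, seed=seed)
            est = mle_lfdr(fit, dataset)
            out[f"lfdr_{method}"] = est
            if 0.0 < fit.pi0_hat < 1.0:
                out[f"bf_eb_{method}"] = [
                    eb_bayes_factor(float(v), fit.pi0_hat) if v > 0 else np.inf
                    for v in est
                ]
            if fit.boundary:
                for fl in flags:
                    fl.append(f"{method}_boundary_fit")
        elif method == "nmle":
            bfs = np.array([
                nml_ratio(int(t), int(s), dataset.n, dataset.N)
                for t, s in zip(dataset.t, dataset.s)
            ])
            out["bf_nml"] = bfs
            out["log_bf_nml"] = np.log(np.maximum(bfs, 1e-300))
            out["lfdr_nmle"] = [nmle_lfdr(float(bf), pi0) for bf in bfs]
            for fl, bf in zip(flags, bfs):
                ev = _evidence_flag(float(bf))
                if ev != "none":
                    fl.append(f"nml_{ev}_evidence")
        else:
            out[f"lfdr_{method}"] = estimate_lfdr(dataset, method, seed=seed)
    out["flags"] = [";".join(fl) if fl else "NA" for fl in flags]
    return out


def write_report(df: pd.DataFrame, path: str | Path, dataset: EnrichmentDataset,
                 options: dict[str, Any] | None = None,
                 precision: int | None = 6) -> None:
    """Write the report TSV with a '#'-prefixed metadata header.

    Numeric columns are rendered at ``precision`` significant digits
    (``None`` keeps full precision); reports are byte-identical across runs
    with identical inputs and options.
    """
    path = Path(path)
    fmt = df.copy()
    if precision is not None:
        for col in fmt.columns:
            if pd.api.types.is_float_dtype(fmt[col]):
                fmt[col] = fmt[col].map(
                    lambda v: f"{v:.{precision}g}" if np.isfinite(v)
                    else ("inf" if v > 0 else "NA"))
    with open(path, "w") as fh:
        fh.write(f"# enrichlfdr v{__version__}\n")
        fh.write(f"# n={dataset.n}\n")
        fh.write(f"# N={dataset.N}\n")
        for key, val in sorted((options or {}).items()):
            fh.write(f"# {key}={val}\n")
        fmt.to_csv(fh, sep="\t", index=False, na_rep="NA")


def log(msg: str, level: str = "INFO") -> None:
    print(f"[enrichlfdr {level}] {msg}", file=sys.stderr)
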
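"""Differential expression between two tag libraries via the exact test of
Audic & Claverie, with Benjamini-Hochberg FDR and TPM-ratio thresholds.

Given a gene observed x times among N1 clean tags in library 1, the count y
among N2 clean tags in library 2 follows, under equal expression,

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

a negative binomial NB(x+1, N1/(N1+N2)) in y. The two-sided p-value doubles
the smaller of the two inclusive tails, capped at 1. Tails are evaluated
through the regularized incomplete beta function (exact and stable up to
counts of 10^6); tests cross-check against direct log-gamma summation.

Screening uses the conventional thresholds FDR <= 0.001 and
|log2(TPM2/TPM1)| >= 1, with a small TPM floor standing in for zero counts
so that genes absent from one library keep a finite ratio.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

DEFAULT_TPM_FLOOR = 0.001
DEFAULT_FDR = 0.001
DEFAULT_LFC = 1.0


def ac_pvalue(x, y, n1: int, n2: int):
    """Two-sided exact-test p-value for counts x (library 1) vs y (library 2).

    Accepts scalars or arrays for x and y; library sizes n1, n2 are scalars.
    p = min(1, 2*min(P(Y<=y|x), P(Y>=y|x))) with Y ~ NB(x+1, n1/(n1+n2)).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if min(n1, n2) < 1:
        raise ValueError("library sizes must be >= 1")
    xf = x.astype(np.float64)
    yf = y.astype(np.float64)
    q = n1 / (n1 + n2)
    lower = special.betainc(xf + 1.0, yf + 1.0, q)  # P(Y <= y)
    upper = np.where(  # P(Y >= y) = I_{1-q}(y, x+1) for y >= 1
        yf > 0, special.betainc(np.maximum(yf, 1.0), xf + 1.0, 1.0 - q), 1.0
    )
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return float(p) if p.ndim == 0 else p


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p_values, dtype=np.float64)
    if arr.size == 0:
        return arr
    if np.any(np.isnan(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def log2_ratio(tpm1, tpm2, floor: float = DEFAULT_TPM_FLOOR):
    """log2(max(tpm2, floor) / max(tpm1, floor)); the floor keeps zeros finite."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    t1 = np.maximum(np.asarray(tpm1, dtype=np.float64), floor)
    t2 = np.maximum(np.asarray(tpm2, dtype=np.float64), floor)
    r = np.log2(t2 / t1)
    return float(r) if r.ndim == 0 else r


class DESummary(NamedTuple):
    n_up: int
    n_down: int
    n_ns: int


def differential_expression(
    counts1: pd.Series,
    counts2: pd.Series,
    n1: int | None = None,
    n2: int | None = None,
    floor: float = DEFAULT_TPM_FLOOR,
) -> pd.DataFrame:
    """Build the per-gene DE table from two unambiguous count vectors.

    n1/n2 default to the clean-library totals implied by the counts. The test
    uses raw counts with the library sizes; the ratio column uses TPMs.
    """
    idx = counts1.index.union(counts2.index)
    x = counts1.reindex(idx).fillna(0).astype(np.int64)
    y = counts2.reindex(idx).fillna(0).astype(np.int64)
    n1 = int(x.sum()) if n1 is None else int(n1)
    n2 = int(y.sum()) if n2 is None else int(n2)
    tpm1 = x / n1 * 1e6
    tpm2 = y / n2 * 1e6
    p = ac_pvalue(x.to_numpy(), y.to_numpy(), n1, n2)
    table = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "tpm1": tpm1,
            "tpm2": tpm2,
            "log2_ratio": log2_ratio(tpm1.to_numpy(), tpm2.to_numpy(), floor),
            "p_value": p,
            "fdr": bh_fdr(p),
        },
        index=idx,
    )
    table.index.name = "gene"
    table.attrs["n1"] = n1
    table.attrs["n2"] = n2
    return table


def screen_degs(
    table: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
) -> tuple[pd.DataFrame, DESummary]:
    """Assign up/down/ns calls at the given FDR and |log2 ratio| thresholds."""
    out = table.copy()
    sig = out["fdr"] <= fdr_threshold
    call = np.where(
        sig & (out["log2_ratio"] >= lfc_threshold),
        "up",
        np.where(sig & (out["log2_ratio"] <= -lfc_threshold), "down", "ns"),
    )
    out["call"] = call
    return out, DESummary(
        n_up=int((call == "up").sum()),
        n_down=int((call == "down").sum()),
        n_ns=int((call == "ns").sum()),
    )
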
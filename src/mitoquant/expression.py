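"""Two-group TPM comparison: expression filter, signed fold change, BH FDR.

The table carries one row per gene with TPM for group A and group B plus a
per-gene p-value from an upstream differential-expression engine (the
p-values are inputs here, not recomputed). Processing:

1. drop genes silent in both groups (TPM > 0 in at least one group);
2. signed fold change — +tpm_b/tpm_a when B >= A, −tpm_a/tpm_b otherwise,
   so the sign says which group is higher and the magnitude is always >= 1;
3. Benjamini–Hochberg step-up FDR adjustment of the p-values;
4. differential-expression call at FDR strictly < alpha (default 0.05).

Genes expressed in exactly one group get a signed infinite fold with an
``infinite_fold`` flag; an optional pseudocount replaces that convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["filter_expressed", "fold_change", "bh_fdr", "de_call", "run_de"]


def filter_expressed(table: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with TPM > 0 in at least one group."""
    keep = (table["tpm_a"] > 0) | (table["tpm_b"] > 0)
    return table.loc[keep].reset_index(drop=True)


def fold_change(
    tpm_a: np.ndarray | float, tpm_b: np.ndarray | float, pseudocount: float = 0.0
) -> np.ndarray | float:
    """Signed TPM ratio: +B/A when B >= A, −A/B otherwise.

    A zero denominator yields ±inf (flagged downstream) unless a
    ``pseudocount`` is supplied, in which case it is added to both sides
    before the ratio. Both-zero inputs are undefined (filter upstream).
    """
    a = np.asarray(tpm_a, dtype=float)
    b = np.asarray(tpm_b, dtype=float)
    if np.any((a == 0) & (b == 0) & (pseudocount == 0)):
        raise ValueError("fold change undefined when both TPMs are 0; filter first")
    a = a + pseudocount
    b = b + pseudocount
    with np.errstate(divide="ignore"):
        up = np.divide(b, a, out=np.full_like(b, np.inf), where=a > 0)
        down = np.divide(a, b, out=np.full_like(a, np.inf), where=b > 0)
    out = np.where(b >= a, up, -down)
    return float(out) if out.ndim == 0 else out


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone in rank)."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def de_call(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag differential expression at FDR strictly below ``alpha``."""
    if "fdr" not in table:
        raise ValueError("compute FDR before calling differential expression")
    out = table.copy()
    out["de_call"] = out["fdr"] < alpha
    return out


def run_de(
    table: pd.DataFrame, alpha: float = 0.05, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Full pipeline: filter → fold change → BH FDR → DE call.

    Input columns: ``gene``, ``tpm_a``, ``tpm_b``, ``pval``. Output adds
    ``fold_change``, ``infinite_fold``, ``fdr``, ``de_call``.
    """
    out = filter_expressed(table)
    fc = fold_change(out["tpm_a"].to_numpy(), out["tpm_b"].to_numpy(), pseudocount)
    out["fold_change"] = fc
    out["infinite_fold"] = ~np.isfinite(fc)
    out["fdr"] = bh_fdr(out["pval"].to_numpy())
    return de_call(out, alpha=alpha)
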
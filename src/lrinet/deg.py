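"""Conventional differential-expression arm of the pipeline.

Per gene: a two-sided Welch two-sample t-test on log2 expression (case vs
control), log2 fold change as the difference of group means, Benjamini–
Hochberg adjustment across all tested genes, and the dual DEG filter
(adjusted p ≤ alpha AND |LFC| ≥ lfc_min). This stage exists as the
comparison arm against which LRI-salient genes are judged; a plain Welch
test is used for the group contrast (see docs/methods.md for how this
differs from moderated-variance approaches).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .build import MicroarrayExperimentSituation
from .errors import InsufficientDataError, ValidationError


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    p_(k) ↦ min over r ≥ k of p_(r)·m/r, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_deg(
    mes: MicroarrayExperimentSituation,
    alpha: float = 0.05,
    lfc_min: float = 2.0,
) -> pd.DataFrame:
    """Welch-test DEG table with BH adjustment and the dual threshold.

    Returns a DataFrame indexed like the expression matrices with columns
    ``lfc``, ``t``, ``pvalue``, ``adj_pvalue``, ``is_deg``.
    """
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must lie in (0, 1]")
    if lfc_min < 0:
        raise ValidationError("lfc_min must be non-negative")
    case = mes.diseased.to_numpy(dtype=float)
    ctrl = mes.reference.to_numpy(dtype=float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise InsufficientDataError("need at least 2 samples per group")

    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)  # both group variances zero
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero variance in both groups; "
            "p set to 1 where the fold change is also zero",
            stacklevel=2,
        )
        # identical constants: no evidence, p = 1; separated constants:
        # the groups differ exactly, p -> 0
        p = np.where(degenerate & (lfc == 0), 1.0, p)
        p = np.where(degenerate & (lfc != 0), 0.0, p)
        t = np.where(degenerate, 0.0, t)

    adj = bh_adjust(p)
    is_deg = (adj <= alpha) & (np.abs(lfc) >= lfc_min)
    return pd.DataFrame(
        {
            "lfc": lfc,
            "t": t,
            "pvalue": p,
            "adj_pvalue": adj,
            "is_deg": is_deg,
        },
        index=mes.diseased.index.rename("gene"),
    )
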
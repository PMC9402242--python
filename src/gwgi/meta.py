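"""Inverse-variance fixed-effect meta-analysis with heterogeneity statistics.

Per-study estimates ``(beta_i, se_i)`` combine with weights ``w_i = 1/se_i^2``:
``beta = sum(w b)/sum(w)``, ``se = 1/sqrt(sum w)``; heterogeneity is
summarised by Cochran's ``Q = sum w (b_i - beta)^2`` (chi-square on k-1 df
under homogeneity) and ``I^2 = max(0, (Q - (k-1))/Q) * 100`` percent.

:func:`se_from_or_p` back-reconstructs a Wald standard error from a printed
(OR, P) pair, which is what lets published per-study summary rows be combined
without access to the underlying data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["MetaResult", "se_from_or_p", "fixed_effect_meta", "weighted_info"]


@dataclass
class MetaResult:
    beta: float
    se: float
    z: float
    p: float
    or_: float
    q: float
    q_p: float
    i2: float  # percent, 0-100
    k: int
    inputs: list = field(default_factory=list)


def se_from_or_p(or_: float, p: float) -> float:
    """Wald SE implied by an (odds ratio, two-sided P) pair.

    ``se = |ln OR| / z`` with ``z`` the two-sided normal quantile of P.
    Round-trip consistent with the Wald P computation used throughout.
    """
    if or_ <= 0.0:
        raise ValueError("odds ratio must be positive")
    if or_ == 1.0:
        raise ValueError("OR = 1 leaves the z-score undefined")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")
    z = stats.norm.isf(p / 2.0)
    return float(abs(np.log(or_)) / z)


def fixed_effect_meta(inputs) -> MetaResult:
    """Combine per-study (beta, se[, label]) tuples by inverse variance.

    With a single study the input is returned unchanged (q = 0, i2 = 0,
    q_p defined as 1).
    """
    recs = []
    for item in inputs:
        if len(item) == 2:
            b, s = item
            lab = f"study{len(recs)}"
        else:
            b, s, lab = item
        b, s = float(b), float(s)
        if s <= 0.0:
            raise ValueError(f"nonpositive se for {lab}")
        recs.append((b, s, lab))
    if not recs:
        raise ValueError("no studies to combine")
    betas = np.array([r[0] for r in recs])
    ses = np.array([r[1] for r in recs])
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    q = float((w * (betas - beta) ** 2).sum())
    k = len(recs)
    q_p = 1.0 if k == 1 else float(stats.chi2.sf(q, df=k - 1))
    i2 = 0.0 if q <= k - 1 else float((q - (k - 1)) / q * 100.0)
    return MetaResult(
        beta=beta,
        se=se,
        z=z,
        p=float(2.0 * stats.norm.sf(abs(z))),
        or_=float(np.exp(beta)),
        q=q,
        q_p=q_p,
        i2=i2,
        k=k,
        inputs=recs,
    )


def weighted_info(info_scores, sample_sizes) -> float:
    """Sample-size weighted mean imputation info score."""
    info = np.asarray(info_scores, dtype=float)
    n = np.asarray(sample_sizes, dtype=float)
    if info.size == 0:
        raise ValueError("no info scores")
    if info.shape != n.shape:
        raise ValueError("info_scores and sample_sizes lengths differ")
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    return float((n * info).sum() / n.sum())
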
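"""Association tests for gene-sex interaction analysis.

The two workhorse tests of the two-step design live here:

* :func:`case_only_test` - logistic regression of sex on SNP dosage among
  cases only. Under gene-sex independence in the source population and a
  rare disease, the dosage coefficient estimates the SNP x sex interaction
  log-odds-ratio for disease, with considerably better efficiency than the
  full case-control interaction model.
* :func:`case_control_interaction_test` - the standard model
  ``logit P(D) = b0 + b1 SNP + b2 sex + b3 SNP*sex (+ covariates)``,
  returning the b3 term. Robust to gene-sex dependence, hence used to
  validate case-only candidates.

Plus per-stratum risk models, minor-allele-frequency utilities and the
genomic-control inflation factor.

Sex is handled as an indicator internally (0 = male, 1 = female); any
two-level coding (``{1, 2}``, string labels) is accepted, and the
interaction estimate is invariant to the affine recoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .logistic import fit_logistic, firth_logistic

__all__ = [
    "AssocResult",
    "NotEstimable",
    "LambdaResult",
    "case_only_test",
    "case_control_interaction_test",
    "stratified_risk",
    "maf",
    "maf_by_group",
    "sex_maf_difference_test",
    "genomic_lambda",
]


@dataclass
class AssocResult:
    """One fitted term for one SNP."""

    snp_id: str
    term: str
    beta: float
    se: float
    z: float
    p: float
    or_: float
    n: int
    n_cases: int
    method: str
    converged: bool

    def __post_init__(self):
        # stored summaries must stay mutually consistent
        assert np.isclose(self.or_, np.exp(self.beta), rtol=1e-12)

    @classmethod
    def from_fit(cls, fit, index, *, snp_id, term, n, n_cases):
        beta = float(fit.params[index])
        se = float(fit.se[index])
        z = beta / se
        return cls(
            snp_id=snp_id,
            term=term,
            beta=beta,
            se=se,
            z=z,
            p=float(2.0 * stats.norm.sf(abs(z))),
            or_=float(np.exp(beta)),
            n=n,
            n_cases=n_cases,
            method=fit.method,
            converged=fit.converged,
        )


@dataclass
class NotEstimable:
    """Marker for a stratum/test that cannot be estimated (e.g. one class)."""

    snp_id: str
    term: str
    reason: str


@dataclass
class LambdaResult:
    """Genomic-control inflation factor over a set of association tests."""

    lambda_: float
    n_tests: int


_FITTERS = {"mle": fit_logistic, "firth": firth_logistic}


def encode_binary(values, name: str) -> np.ndarray:
    """Map a two-level variable onto {0, 1}.

    Accepts 0/1, the GWAS-traditional 1/2 sex coding, and the string labels
    used in phenotype files. Interaction and slope estimates are invariant to
    which affine two-level coding comes in.
    """
    v = np.asarray(values)
    if v.dtype.kind in "OUS":
        low = np.char.lower(v.astype(str))
        mapping = {
            "male": 0, "m": 0, "female": 1, "f": 1,
            "never": 0, "ever": 1,
            "control": 0, "case": 1,
        }
        try:
            return np.array([mapping[x] for x in low], dtype=float)
        except KeyError as exc:
            raise ValueError(f"unrecognised {name} label: {exc.args[0]!r}") from exc
    v = v.astype(float)
    uniq = np.unique(v[~np.isnan(v)])
    if uniq.size > 2:
        raise ValueError(f"{name} has more than two levels: {uniq}")
    if np.isin(uniq, (0.0, 1.0)).all():
        return v
    if np.isin(uniq, (1.0, 2.0)).all():
        return v - 1.0
    if uniq.size == 2:  # any other two-level numeric coding
        return (v == uniq.max()).astype(float)
    raise ValueError(f"{name} is constant; need two levels")


def _as_matrix(covariates) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((0, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"cov{j}" for j in range(arr.shape[1])]


def case_only_test(
    dosage,
    sex,
    covariates=None,
    method: str = "mle",
    *,
    disease=None,
    snp_id: str = "snp",
) -> AssocResult:
    """Case-only interaction test: regress sex on dosage among cases.

    Parameters
    ----------
    dosage : array_like
        Imputed allele dosage in [0, 2] (additive coding), cases only.
    sex : array_like
        Two-level sex variable; internally female = 1.
    covariates : array_like or DataFrame, optional
        Adjustment covariates (smoking, principal components, study
        indicators). No intercept column; it is added here.
    method : {"mle", "firth"}
    disease : array_like, optional
        If given, must be all-cases; guards against accidentally passing a
        mixed sample, which would invalidate the case-only reading.

    Returns
    -------
    AssocResult for the dosage term. Its ``beta`` estimates the SNP x sex
    interaction log-OR under gene-sex independence and a rare disease.
    """
    dosage = np.asarray(dosage, dtype=float)
    if disease is not None:
        d = encode_binary(disease, "disease")
        if not np.all(d == 1.0):
            raise ValueError("case_only_test requires an all-case sample")
    if np.ptp(dosage[~np.isnan(dosage)]) == 0.0:
        raise ValueError("dosage is constant; case-only test undefined")
    y = encode_binary(sex, "sex")
    C, _ = _as_matrix(covariates)
    cols = [np.ones_like(dosage), dosage]
    if C.size:
        cols.extend(C.T)
    X = np.column_stack(cols)
    keep = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y = X[keep], y[keep]
    fit = _FITTERS[method](X, y)
    n = int(keep.sum())
    return AssocResult.from_fit(
        fit, 1, snp_id=snp_id, term="snp", n=n, n_cases=n
    )


def case_control_interaction_test(
    dosage,
    sex,
    smoking,
    pcs,
    disease,
    method: str = "mle",
    *,
    extra_covariates=None,
    snp_id: str = "snp",
) -> AssocResult:
    """Case-control SNP x sex interaction test; returns the b3 term.

    Adjusts for smoking and the principal components (and any extra
    covariates such as study indicators), per the standard interaction
    model ``logit P(D) ~ SNP + sex + SNP*sex + smoking + PCs``.
    """
    dosage = np.asarray(dosage, dtype=float)
    s = encode_binary(sex, "sex")
    y = encode_binary(disease, "disease")
    if np.ptp(s[~np.isnan(s)]) == 0.0:
        raise ValueError("sex is constant")
    if np.ptp(y[~np.isnan(y)]) == 0.0:
        raise ValueError("disease is constant")
    smoke = encode_binary(smoking, "smoking") if smoking is not None else None
    P, _ = _as_matrix(pcs)
    E, _ = _as_matrix(extra_covariates)
    cols = [np.ones_like(dosage), dosage, s, dosage * s]
    if smoke is not None:
        cols.append(smoke)
    if P.size:
        cols.extend(P.T)
    if E.size:
        cols.extend(E.T)
    X = np.column_stack(cols)
    keep = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y = X[keep], y[keep]
    fit = _FITTERS[method](X, y)
    return AssocResult.from_fit(
        fit, 3, snp_id=snp_id, term="snp:sex",
        n=int(keep.sum()), n_cases=int(y.sum()),
    )


def stratified_risk(
    dosage,
    disease,
    covariates,
    stratum_labels,
    method: str = "mle",
    *,
    snp_id: str = "snp",
) -> dict:
    """Per-stratum logistic fit of disease on dosage (+ covariates).

    Stratifying covariates (e.g. sex when strata are male/female) must be
    excluded from ``covariates`` by the caller - inside a stratum they are
    constant and would make the design singular.

    Returns a dict mapping stratum label to :class:`AssocResult`, or to
    :class:`NotEstimable` when a stratum holds a single outcome class.
    """
    dosage = np.asarray(dosage, dtype=float)
    y = encode_binary(disease, "disease")
    C, _ = _as_matrix(covariates)
    labels = np.asarray(stratum_labels)
    out: dict = {}
    for lab in pd.unique(labels):
        m = labels == lab
        ys = y[m]
        if np.unique(ys[~np.isnan(ys)]).size < 2:
            out[lab] = NotEstimable(snp_id, "snp", "single outcome class")
            continue
        cols = [np.ones(int(m.sum())), dosage[m]]
        if C.size:
            cols.extend(C[m].T)
        X = np.column_stack(cols)
        keep = np.isfinite(X).all(axis=1) & np.isfinite(ys)
        try:
            fit = _FITTERS[method](X[keep], ys[keep])
        except (ValueError, RuntimeError) as exc:
            out[lab] = NotEstimable(snp_id, "snp", str(exc))
            continue
        out[lab] = AssocResult.from_fit(
            fit, 1, snp_id=snp_id, term="snp",
            n=int(keep.sum()), n_cases=int(ys[keep].sum()),
        )
    return out


def maf(dosages) -> float:
    """Minor-allele frequency from dosages: mean/2, oriented to the minor allele."""
    d = np.asarray(dosages, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no dosages")
    f = float(d.mean() / 2.0)
    return min(f, 1.0 - f)


def maf_by_group(dosages, labels) -> dict:
    """Allele frequency of the pooled minor allele, per group."""
    d = np.asarray(dosages, dtype=float)
    labels = np.asarray(labels)
    pooled = float(np.nanmean(d) / 2.0)
    flip = pooled > 0.5
    out = {}
    for lab in pd.unique(labels):
        g = d[labels == lab]
        g = g[np.isfinite(g)]
        if g.size == 0:
            raise ValueError(f"empty group {lab!r}")
        f = float(g.mean() / 2.0)
        out[lab] = 1.0 - f if flip else f
    return out


def sex_maf_difference_test(dosages, sex) -> float:
    """Two-proportion chi-square comparing allele frequencies between sexes.

    Estimated allele counts (sum of dosages, out of 2n alleles per group)
    enter a 1-df 2x2 chi-square directly; fractional counts are allowed
    because dosages are expectations, not hard calls.
    """
    d = np.asarray(dosages, dtype=float)
    s = encode_binary(sex, "sex")
    counts = []
    for val in (0.0, 1.0):
        g = d[(s == val) & np.isfinite(d)]
        if g.size < 2:
            raise ValueError("need >= 2 samples per sex group")
        counts.append((float(g.sum()), 2.0 * g.size - float(g.sum())))
    obs = np.array(counts)  # rows: sex, cols: (minor, major) allele counts
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    if np.allclose(obs, exp):
        return 1.0
    stat = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(stat, df=1))


#: median of the 1-df chi-square distribution
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


def genomic_lambda(p_values) -> LambdaResult:
    """Genomic-control inflation factor.

    ``lambda = median(chi2_1 quantile of the p-values) / 0.4549...``; 1 under
    a calibrated null, >1 signals inflation of the test statistics.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 100:
        raise ValueError("genomic lambda needs >= 100 p-values")
    if np.any((p <= 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return LambdaResult(float(np.median(chi) / CHI2_NULL_MEDIAN), int(p.size))
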
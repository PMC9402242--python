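"""Sex-aware expression quantitative trait (eQTL) analysis.

Dosages from imputation are converted to best-guess genotype codes before
expression modelling: an additive 0/1/2 coding for common variants
(MAF >= 0.1) and a dominant carrier coding for low-frequency variants
(MAF < 0.1), where too few rare homozygotes exist to support a third group.
Dosages falling in the unlisted gaps between the coding windows carry too
much imputation uncertainty for a best guess and come back missing.

Expression processing follows the fixed order: average duplicated samples on
the rpkm scale, drop samples with rpkm < 0.25, then log2-transform. Group
comparisons use the equal-variance Student's t (Welch behind a flag); the
genotype x sex interaction on log2 expression is an ordinary least-squares
fit of ``log2(rpkm) ~ code + sex + code:sex``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .assoc import AssocResult, NotEstimable, encode_binary
from .simulate import ExpressionSet

__all__ = [
    "RegionZTable",
    "dosage_to_genotype",
    "code_dosages",
    "prepare_expression",
    "group_expression_test",
    "expression_interaction",
    "ld_r2",
    "region_z_comparison",
]


def dosage_to_genotype(dosage: float, maf: float) -> float:
    """Best-guess genotype code for one dosage value.

    Additive rule (MAF >= 0.1): <=0.2 -> 0; [0.4, 0.6] -> 1; >=0.8 -> 2.
    Dominant rule (MAF < 0.1): <=0.4 -> 0; >=0.6 -> 1 (carrier).
    Values in the uncovered gaps return NaN (missing).
    """
    if np.isnan(dosage):
        return np.nan
    if not 0.0 <= dosage <= 2.0:
        raise ValueError(f"dosage {dosage} outside [0, 2]")
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"MAF {maf} outside (0, 0.5]")
    if maf >= 0.1:
        if dosage <= 0.2:
            return 0.0
        if 0.4 <= dosage <= 0.6:
            return 1.0
        if dosage >= 0.8:
            return 2.0
        return np.nan
    if dosage <= 0.4:
        return 0.0
    if dosage >= 0.6:
        return 1.0
    return np.nan


def code_dosages(dosages, maf: float) -> np.ndarray:
    """Vectorised :func:`dosage_to_genotype`."""
    d = np.asarray(dosages, dtype=float)
    if np.any((d < 0.0) | (d > 2.0)):
        raise ValueError("dosage outside [0, 2]")
    return np.array([dosage_to_genotype(x, maf) for x in d])


def prepare_expression(
    rpkm_table: pd.DataFrame,
    gene: str,
    *,
    sex=None,
    genotype_code=None,
) -> ExpressionSet:
    """Build an :class:`ExpressionSet` for one gene.

    Parameters
    ----------
    rpkm_table : DataFrame with columns sample_id, gene, rpkm and optionally
        sex. Duplicate (sample, gene) rows are averaged on the rpkm scale
        *before* the rpkm < 0.25 filter, then values are log2-transformed.
    sex, genotype_code : optional per-sample mappings (dict or Series keyed
        by sample_id) merged onto the retained samples.
    """
    sub = rpkm_table[rpkm_table["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent from expression table")
    if (sub["rpkm"] < 0.0).any():
        raise ValueError("negative rpkm values")
    n_dup = int(sub.duplicated("sample_id").sum())
    avg = sub.groupby("sample_id", sort=False).agg(
        rpkm=("rpkm", "mean"),
        **({"sex": ("sex", "first")} if "sex" in sub.columns else {}),
    )
    keep = avg["rpkm"] >= 0.25
    n_drop = int((~keep).sum())
    avg = avg[keep]
    if avg.empty:
        raise ValueError("all samples filtered out at rpkm < 0.25")
    frame = pd.DataFrame(
        {
            "sample_id": avg.index,
            "log2_expr": np.log2(avg["rpkm"].to_numpy()),
        }
    )
    if "sex" in avg.columns:
        frame["sex"] = avg["sex"].to_numpy()
    if sex is not None:
        frame["sex"] = pd.Series(sex).reindex(frame["sample_id"]).to_numpy()
    if "sex" not in frame.columns:
        frame["sex"] = np.nan
    if genotype_code is not None:
        frame["genotype_code"] = (
            pd.Series(genotype_code).reindex(frame["sample_id"]).to_numpy()
        )
    else:
        frame["genotype_code"] = np.nan
    frame = frame[["sample_id", "sex", "genotype_code", "log2_expr"]]
    return ExpressionSet(
        samples=frame.reset_index(drop=True),
        gene=gene,
        n_dropped_low_expr=n_drop,
        n_duplicates_averaged=n_dup,
    )


def group_expression_test(
    exprset: ExpressionSet,
    strata=("combined", "male", "female"),
    *,
    welch: bool = False,
) -> dict:
    """Student's t comparison of mean log2 expression, carrier vs non-carrier.

    Genotype groups are non-carriers (code 0) versus carriers (code >= 1);
    with dominant coding this is exactly {0} vs {1}. A stratum whose smaller
    group has <= 1 sample is reported :class:`NotEstimable` rather than
    raising - one carrier cannot support a variance estimate.

    Returns a dict per stratum with group sizes, group means and the
    two-sided p (or a NotEstimable marker).
    """
    s = exprset.samples
    out = {}
    for stratum in strata:
        if stratum == "combined":
            sub = s
        else:
            sub = s[s["sex"] == stratum]
        sub = sub[np.isfinite(sub["genotype_code"])]
        g0 = sub.loc[sub["genotype_code"] == 0, "log2_expr"].to_numpy()
        g1 = sub.loc[sub["genotype_code"] >= 1, "log2_expr"].to_numpy()
        if min(g0.size, g1.size) <= 1:
            out[stratum] = NotEstimable(
                exprset.gene, "genotype", "a genotype group has <= 1 sample"
            )
            continue
        t, p = stats.ttest_ind(g1, g0, equal_var=not welch)
        out[stratum] = {
            "n": (int(g0.size), int(g1.size)),
            "means": (float(g0.mean()), float(g1.mean())),
            "t": float(t),
            "p": float(p),
        }
    return out


def expression_interaction(exprset: ExpressionSet) -> AssocResult:
    """Genotype x sex interaction on log2 expression by OLS.

    Fits ``log2_expr ~ code + female + code:female`` and returns the
    interaction term with its t-based two-sided p-value.
    """
    s = exprset.samples
    code = s["genotype_code"].to_numpy(dtype=float)
    female = encode_binary(s["sex"].to_numpy(), "sex")
    y = s["log2_expr"].to_numpy(dtype=float)
    keep = np.isfinite(code) & np.isfinite(female) & np.isfinite(y)
    code, female, y = code[keep], female[keep], y[keep]
    if np.unique(female).size < 2:
        raise ValueError("both sexes required for the interaction model")
    if np.unique(code).size < 2:
        raise ValueError("need >= 2 genotype codes")
    X = np.column_stack([np.ones_like(code), code, female, code * female])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design in expression interaction model")
    res = sm.OLS(y, X).fit()
    beta = float(res.params[3])
    return AssocResult(
        snp_id=exprset.gene,
        term="genotype:sex",
        beta=beta,
        se=float(res.bse[3]),
        z=float(res.tvalues[3]),
        p=float(res.pvalues[3]),
        or_=float(np.exp(beta)),
        n=int(keep.sum()),
        n_cases=0,
        method="ols",
        converged=True,
    )


def ld_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of two dosage vectors."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("constant dosage vector; r2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class RegionZTable:
    """Matched risk-interaction vs expression-interaction z-scores, with LD."""

    table: pd.DataFrame  # snp_id, pos, z_risk, z_expr, ld_r2_with_reference
    reference_snp: str


def region_z_comparison(
    scan_records,
    expression_results,
    reference_snp: str,
    dosages,
) -> RegionZTable:
    """Pair each SNP's risk-interaction z with its expression-interaction z.

    Parameters
    ----------
    scan_records : iterable of ScanRecord (the risk z is the joint case-only
        meta z).
    expression_results : mapping snp_id -> AssocResult from
        :func:`expression_interaction`.
    reference_snp : LD reference (its own r2 is 1 by construction).
    dosages : DataFrame (samples x snp_id columns) used for pairwise r2.
    """
    if reference_snp not in dosages.columns:
        raise ValueError(f"reference SNP {reference_snp!r} missing from dosages")
    ref = dosages[reference_snp].to_numpy(dtype=float)
    rows = []
    for rec in scan_records:
        if rec.meta is None or rec.snp_id not in expression_results:
            continue
        if rec.snp_id not in dosages.columns:
            continue
        rows.append(
            {
                "snp_id": rec.snp_id,
                "pos": rec.pos,
                "z_risk": rec.meta.z,
                "z_expr": expression_results[rec.snp_id].z,
                "ld_r2_with_reference": ld_r2(
                    dosages[rec.snp_id].to_numpy(dtype=float), ref
                ),
            }
        )
    if not rows:
        raise ValueError("no overlapping SNPs between scan and expression results")
    table = pd.DataFrame(rows).sort_values("pos", ignore_index=True)
    return RegionZTable(table=table, reference_snp=reference_snp)
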
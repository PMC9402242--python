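"""The two-step genome-wide interaction cascade.

Stage order, per SNP:

1. imputation-quality filter: info >= ``info_min_discovery`` in the
   discovery study, info > ``info_min_each_replication`` in every
   replication study (strict), and sample-size weighted replication info
   >= ``info_min_weighted_replication``;
2. case-only tests in the discovery arm and the pooled replication arm
   (study indicators as covariates), combined by inverse-variance
   fixed-effect meta-analysis;
3. step-1 call: joint P below ``joint_p_threshold`` *and* strictly more
   significant than both arms;
4. case-control SNP x sex interaction on all cases + controls pooled;
5. Firth confirmation when the pooled MAF is below ``firth_maf_threshold``;
6. final call: every stage passed.

Every SNP yields a complete :class:`ScanRecord`; a stage failure is recorded
on the record and the scan continues. The whole cascade is exposed both as
the :class:`TwoStepScan` model object (``.fit()`` -> results with a records
table and a stage-count summary) and as the :func:`two_step_scan` function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .assoc import (
    AssocResult,
    case_control_interaction_test,
    case_only_test,
    encode_binary,
)
from .meta import MetaResult, fixed_effect_meta, weighted_info

__all__ = [
    "ScanConfig",
    "ScanRecord",
    "TwoStepScan",
    "TwoStepScanResults",
    "filter_by_info",
    "two_step_scan",
    "concordance_report",
]


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds and covariates of the cascade.

    Defaults are the genome-scale study values; a desk-scale run on a
    handful of synthetic SNPs should relax ``joint_p_threshold`` to a
    Bonferroni level matched to the number of SNPs actually scanned.
    """

    info_min_discovery: float = 0.7
    info_min_each_replication: float = 0.2
    info_min_weighted_replication: float = 0.7
    joint_p_threshold: float = 5e-8
    cc_p_threshold: float = 0.05
    firth_maf_threshold: float = 0.05
    covariates: tuple = ("smoking", "pc1", "pc2", "pc3", "pc4", "pc5")
    subtype: Optional[str] = None
    replication_mode: str = "pooled"  # or "per_study_meta"
    # step 1 also demands the joint P beat both arms' P; turning this off
    # saturates the cascade for threshold-free plumbing checks
    require_joint_more_significant: bool = True

    def __post_init__(self):
        for name in (
            "joint_p_threshold",
            "cc_p_threshold",
            "firth_maf_threshold",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.replication_mode not in ("pooled", "per_study_meta"):
            raise ValueError("replication_mode must be 'pooled' or 'per_study_meta'")


@dataclass
class ScanRecord:
    """Per-SNP ledger of every cascade stage."""

    snp_id: str
    chrom: str
    pos: int
    maf: float
    passed_info: bool
    info_reasons: list = field(default_factory=list)
    case_only_discovery: Optional[AssocResult] = None
    case_only_replication: Optional[AssocResult] = None
    meta: Optional[MetaResult] = None
    passed_step1: bool = False
    case_control: Optional[AssocResult] = None
    firth: Optional[AssocResult] = None
    final_significant: bool = False
    error: Optional[str] = None


def filter_by_info(collection, config: ScanConfig):
    """Apply the imputation-quality filter across a study collection.

    Returns ``(kept_snp_ids, reasons)`` where ``reasons`` maps every excluded
    SNP to the list of criteria it failed (``discovery_info``,
    ``replication_info_each``, ``replication_info_weighted``).
    """
    disc = collection[0]
    reps = collection[1:]
    snp_ids = list(disc.variants["snp_id"])
    for st in collection:
        missing = st.variants["info_score"].isna()
        if missing.any():
            bad = st.variants.loc[missing, "snp_id"].iloc[0]
            raise ValueError(f"missing info score for {bad} in {st.study_id}")
        if list(st.variants["snp_id"]) != snp_ids:
            raise ValueError("studies do not share a common variant panel")
    rep_sizes = [len(st.samples) for st in reps]
    kept, reasons = [], {}
    disc_info = disc.variants["info_score"].to_numpy()
    rep_info = np.array([st.variants["info_score"].to_numpy() for st in reps])
    for j, snp in enumerate(snp_ids):
        why = []
        if disc_info[j] < config.info_min_discovery:
            why.append("discovery_info")
        if rep_info.size:
            if np.any(rep_info[:, j] <= config.info_min_each_replication):
                why.append("replication_info_each")
            if (
                weighted_info(rep_info[:, j], rep_sizes)
                < config.info_min_weighted_replication
            ):
                why.append("replication_info_weighted")
        if why:
            reasons[snp] = why
        else:
            kept.append(snp)
    return kept, reasons


def _covariate_matrix(samples: pd.DataFrame, names, *, study_dummies: bool):
    cols = {}
    for name in names:
        if name == "smoking":
            cols["smoking"] = encode_binary(samples["smoking"].to_numpy(), "smoking")
        elif name in samples.columns:
            cols[name] = samples[name].to_numpy(dtype=float)
        else:
            raise ValueError(f"covariate {name!r} missing from phenotypes")
    frame = pd.DataFrame(cols, index=samples.index)
    if study_dummies and samples["study"].nunique() > 1:
        dummies = pd.get_dummies(samples["study"], prefix="study", drop_first=True)
        frame = pd.concat([frame, dummies.astype(float)], axis=1)
    return frame


def _pooled(collection, subtype=None):
    frames, dosages = [], []
    for st in collection:
        frames.append(st.samples)
        dosages.append(st.dosages)
    samples = pd.concat(frames, ignore_index=True)
    dose = np.vstack(dosages)
    if subtype is not None:
        if "subtype" not in samples.columns:
            raise ValueError("subtype filter requested but no subtype column")
        keep = (samples["disease"] == "control") | (
            samples["subtype"] == subtype
        )
        samples = samples[keep.to_numpy()].reset_index(drop=True)
        dose = dose[keep.to_numpy()]
    return samples, dose


class TwoStepScan:
    """Two-step interaction scan over a study collection.

    Parameters
    ----------
    collection : list of StudyCohort
        Study 0 is the discovery cohort; the rest form the replication arm.
    config : ScanConfig, optional
    """

    def __init__(self, collection, config: Optional[ScanConfig] = None):
        if len(collection) < 2:
            raise ValueError("need a discovery and at least one replication study")
        self.collection = list(collection)
        self.config = config or ScanConfig()

    def fit(self) -> "TwoStepScanResults":
        cfg = self.config
        collection = self.collection
        kept, reasons = filter_by_info(collection, cfg)
        kept_set = set(kept)

        disc = collection[0]
        reps = collection[1:]
        pooled_samples, pooled_dose = _pooled(collection, cfg.subtype)
        rep_samples, rep_dose = _pooled(reps, cfg.subtype)
        if cfg.subtype is not None:
            disc_keep = (disc.samples["disease"] == "control") | (
                disc.samples["subtype"] == cfg.subtype
            )
            disc_samples = disc.samples[disc_keep.to_numpy()].reset_index(drop=True)
            disc_dose = disc.dosages[disc_keep.to_numpy()]
        else:
            disc_samples, disc_dose = disc.samples, disc.dosages

        disc_cases = (disc_samples["disease"] == "case").to_numpy()
        rep_cases = (rep_samples["disease"] == "case").to_numpy()

        cov_disc = _covariate_matrix(
            disc_samples[disc_cases], cfg.covariates, study_dummies=False
        )
        cov_rep = _covariate_matrix(
            rep_samples[rep_cases], cfg.covariates, study_dummies=True
        )
        cov_cc = _covariate_matrix(pooled_samples, cfg.covariates, study_dummies=True)
        # pre-split per-study case covariates if replication is meta-combined
        if cfg.replication_mode == "per_study_meta":
            rep_case_parts = []
            for st in reps:
                cases = (st.samples["disease"] == "case").to_numpy()
                rep_case_parts.append(
                    (
                        st.samples[cases],
                        _covariate_matrix(
                            st.samples[cases], cfg.covariates, study_dummies=False
                        ),
                        cases,
                    )
                )

        sex_disc = disc_samples.loc[disc_cases, "sex"].to_numpy()
        sex_rep = rep_samples.loc[rep_cases, "sex"].to_numpy()

        variants = disc.variants
        order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
        records = []
        for j in order:
            snp = variants["snp_id"].iloc[j]
            chrom = str(variants["chrom"].iloc[j])
            pos = int(variants["pos"].iloc[j])
            col = pooled_dose[:, j]
            freq = float(np.nanmean(col) / 2.0)
            flip = freq > 0.5
            snp_maf = 1.0 - freq if flip else freq
            rec = ScanRecord(
                snp_id=snp,
                chrom=chrom,
                pos=pos,
                maf=snp_maf,
                passed_info=snp in kept_set,
                info_reasons=reasons.get(snp, []),
            )
            if not rec.passed_info:
                records.append(rec)
                continue

            def dose_of(matrix, mask=None):
                d = matrix[:, j] if mask is None else matrix[mask, j]
                return 2.0 - d if flip else d

            try:
                rec.case_only_discovery = case_only_test(
                    dose_of(disc_dose, disc_cases),
                    sex_disc,
                    cov_disc,
                    snp_id=snp,
                )
                if cfg.replication_mode == "pooled":
                    rec.case_only_replication = case_only_test(
                        dose_of(rep_dose, rep_cases),
                        sex_rep,
                        cov_rep,
                        snp_id=snp,
                    )
                    meta_inputs = [
                        (
                            rec.case_only_discovery.beta,
                            rec.case_only_discovery.se,
                            "discovery",
                        ),
                        (
                            rec.case_only_replication.beta,
                            rec.case_only_replication.se,
                            "replication",
                        ),
                    ]
                    rep_p = rec.case_only_replication.p
                else:
                    per_study = []
                    for st, (samp, cov, cases) in zip(reps, rep_case_parts):
                        d = st.dosages[cases, j]
                        r = case_only_test(
                            2.0 - d if flip else d,
                            samp["sex"].to_numpy(),
                            cov,
                            snp_id=snp,
                        )
                        per_study.append((r.beta, r.se, st.study_id))
                    rep_meta = fixed_effect_meta(per_study)
                    rec.case_only_replication = AssocResult(
                        snp_id=snp,
                        term="snp",
                        beta=rep_meta.beta,
                        se=rep_meta.se,
                        z=rep_meta.z,
                        p=rep_meta.p,
                        or_=rep_meta.or_,
                        n=int(rep_cases.sum()),
                        n_cases=int(rep_cases.sum()),
                        method="meta",
                        converged=True,
                    )
                    meta_inputs = [
                        (
                            rec.case_only_discovery.beta,
                            rec.case_only_discovery.se,
                            "discovery",
                        )
                    ] + per_study
                    rep_p = rep_meta.p
                rec.meta = fixed_effect_meta(meta_inputs)
                rec.passed_step1 = rec.meta.p < cfg.joint_p_threshold and (
                    not cfg.require_joint_more_significant
                    or (
                        rec.meta.p < rec.case_only_discovery.p
                        and rec.meta.p < rep_p
                    )
                )
                if rec.passed_step1:
                    # smoking already sits inside cov_cc; do not duplicate it
                    cc_kwargs = dict(
                        dosage=dose_of(pooled_dose),
                        sex=pooled_samples["sex"].to_numpy(),
                        smoking=None,
                        pcs=cov_cc,
                        disease=pooled_samples["disease"].to_numpy(),
                        snp_id=snp,
                    )
                    rec.case_control = case_control_interaction_test(**cc_kwargs)
                    passed_step2 = rec.case_control.p < cfg.cc_p_threshold
                    if passed_step2 and snp_maf < cfg.firth_maf_threshold:
                        rec.firth = case_control_interaction_test(
                            method="firth", **cc_kwargs
                        )
                        rec.final_significant = rec.firth.p < cfg.cc_p_threshold
                    else:
                        rec.final_significant = passed_step2
            except (ValueError, RuntimeError) as exc:
                rec.error = f"{type(exc).__name__}: {exc}"
            records.append(rec)
        return TwoStepScanResults(records, cfg)


def two_step_scan(collection, config: Optional[ScanConfig] = None):
    """Functional entry point; see :class:`TwoStepScan`."""
    return TwoStepScan(collection, config).fit().records


_STAGE_COLUMNS = [
    ("case_only_discovery", "disc"),
    ("case_only_replication", "rep"),
    ("case_control", "cc"),
    ("firth", "firth"),
]


@dataclass
class TwoStepScanResults:
    records: list
    config: ScanConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "maf": r.maf,
                "passed_info": r.passed_info,
                "info_reasons": ";".join(r.info_reasons),
                "passed_step1": r.passed_step1,
                "final_significant": r.final_significant,
                "error": r.error or "",
            }
            for attr, tag in _STAGE_COLUMNS:
                res = getattr(r, attr)
                for f in ("beta", "se", "z", "p", "or_"):
                    row[f"{tag}_{f.rstrip('_')}"] = (
                        getattr(res, f) if res is not None else np.nan
                    )
            m = r.meta
            for f in ("beta", "se", "z", "p", "or_", "q", "q_p", "i2"):
                row[f"meta_{f.rstrip('_') if f == 'or_' else f}"] = (
                    getattr(m, f) if m is not None else np.nan
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def manhattan_frame(self) -> pd.DataFrame:
        """Plot-ready (chrom, pos, p) table of joint case-only p-values."""
        return pd.DataFrame(
            [
                {"chrom": r.chrom, "pos": r.pos, "p": r.meta.p}
                for r in self.records
                if r.meta is not None
            ]
        )

    @property
    def stage_counts(self) -> dict:
        recs = self.records
        return {
            "snps": len(recs),
            "passed_info": sum(r.passed_info for r in recs),
            "tested": sum(r.meta is not None for r in recs),
            "passed_step1": sum(r.passed_step1 for r in recs),
            "case_control_tested": sum(r.case_control is not None for r in recs),
            "firth_tested": sum(r.firth is not None for r in recs),
            "final_significant": sum(r.final_significant for r in recs),
            "errors": sum(r.error is not None for r in recs),
        }

    def summary(self) -> str:
        c = self.stage_counts
        lines = [
            "Two-step gene-sex interaction scan",
            f"SNPs scanned: {c['snps']}; info-filter pass: {c['passed_info']}",
            f"step-1 pass (joint P < {self.config.joint_p_threshold:g}): "
            f"{c['passed_step1']}",
            f"case-control tested: {c['case_control_tested']}; "
            f"Firth-confirmed subset: {c['firth_tested']}",
            f"final significant: {c['final_significant']}; errors: {c['errors']}",
        ]
        for r in self.records:
            if r.final_significant:
                firth_note = (
                    f", Firth OR {r.firth.or_:.2f} P {r.firth.p:.2e}"
                    if r.firth
                    else ""
                )
                lines.append(
                    f"  {r.snp_id}: MAF {r.maf:.3f}, joint OR {r.meta.or_:.2f} "
                    f"P {r.meta.p:.2e}, cc P {r.case_control.p:.2e}{firth_note}"
                )
        return "\n".join(lines)


def concordance_report(dosages, phenotypes: pd.DataFrame, snp_ids=None):
    """Ordinary-vs-Firth concordance of case-only fits over a SNP panel.

    Parameters
    ----------
    dosages : DataFrame (samples x SNPs) or ndarray
    phenotypes : DataFrame with disease, sex, smoking, pc1.. columns aligned
        to the dosage rows.
    snp_ids : subset of columns to fit (>= 10 required).

    Returns
    -------
    (table, summary) where table has one row per SNP
    (beta_mle, p_mle, beta_firth, p_firth, error) and summary reports the
    Pearson correlation of betas and of -log10 P over SNPs where both fits
    succeeded.
    """
    if isinstance(dosages, np.ndarray):
        dosages = pd.DataFrame(
            dosages, columns=[f"snp{j}" for j in range(dosages.shape[1])]
        )
    if snp_ids is None:
        snp_ids = list(dosages.columns)
    if len(snp_ids) < 10:
        raise ValueError("concordance report needs >= 10 SNPs")
    cases = encode_binary(phenotypes["disease"].to_numpy(), "disease") == 1.0
    pheno = phenotypes[cases]
    cov_names = [
        c for c in phenotypes.columns if c == "smoking" or c.startswith("pc")
    ]
    cov = _covariate_matrix(
        pheno.assign(study="one"), cov_names, study_dummies=False
    )
    sex = pheno["sex"].to_numpy()
    rows = []
    for snp in snp_ids:
        d = dosages.loc[:, snp].to_numpy()[cases]
        row = {"snp_id": snp, "error": ""}
        for method in ("mle", "firth"):
            try:
                r = case_only_test(d, sex, cov, method=method, snp_id=snp)
                row[f"beta_{method}"] = r.beta
                row[f"p_{method}"] = r.p
            except (ValueError, RuntimeError) as exc:
                row[f"beta_{method}"] = np.nan
                row[f"p_{method}"] = np.nan
                row["error"] += f"{method}:{type(exc).__name__};"
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[["beta_mle", "beta_firth"]].notna().all(axis=1)
    sub = table[ok]
    summary = {
        "n_snps": int(len(table)),
        "n_compared": int(ok.sum()),
        "beta_correlation": float(
            np.corrcoef(sub["beta_mle"], sub["beta_firth"])[0, 1]
        ),
        "logp_correlation": float(
            np.corrcoef(-np.log10(sub["p_mle"]), -np.log10(sub["p_firth"]))[0, 1]
        ),
    }
    return table, summary
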
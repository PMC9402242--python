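"""Synthetic multi-study case-control cohorts and expression datasets.

The generator reproduces the statistical structure the two-step gene-sex
interaction analysis assumes, so every downstream stage is testable without
consortium data:

* Hardy-Weinberg genotypes at configurable minor-allele frequencies, with an
  optional sex-differential allele frequency (``maf_sex_delta``, female minus
  male) emulating sexually antagonistic selection - exactly the mechanism
  that breaks the case-only test's independence assumption.
* Imputation-style dosages: a noisy signal ``g + N(0, info_noise_sd)`` is
  converted to the posterior mean of the genotype under the HWE prior, which
  is what imputation software outputs. The per-SNP info score is the
  variance-ratio ``Var(dosage)/Var(genotype)`` capped at 1: exactly 1 for
  noiseless dosages, and monotonically decreasing in the noise level.
* Sex-dependent smoking prevalence, Gaussian principal components, and a
  logistic disease model ``logit P(D) = b0 + b1 g + b2 female + b3 g*female
  + b_smoke smoke + b_pc sum(PC)``.
* Case-control ascertainment by rejection sampling from a large base
  population - the conditional structure the case-only test relies on.
* Multi-study collections (study 0 is the discovery cohort) sharing one
  variant panel, with per-study info scores.

All randomness descends from a single scenario seed through
``numpy.random.SeedSequence`` spawn keys, so a (scenario, seed) pair fully
determines the output, study by study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "SimScenario",
    "StudyCohort",
    "ExpressionSet",
    "SimulationError",
    "simulate_study",
    "simulate_collection",
    "simulate_expression",
]


class SimulationError(RuntimeError):
    """Raised when a scenario cannot deliver its target sample counts."""


@dataclass(frozen=True)
class SimScenario:
    """Data-generating parameters for a multi-study case-control collection.

    Defaults mirror the margins of a large lung-cancer consortium: ~40%
    female, smoking prevalence 0.87 in men and 0.73 in women, a mild male
    excess among cases, and a baseline disease prevalence of 5%. SNP effects
    default to the global null; tests and studies plant effects explicitly.
    """

    n_cases_per_study: tuple
    n_controls_per_study: tuple
    n_snps: int = 10
    maf_range: tuple = (0.05, 0.5)
    maf_sex_delta: float = 0.0  # female minus male allele frequency
    sex_fraction_female: float = 0.40
    smoking_prev_by_sex: tuple = (0.87, 0.73)  # (male, female)
    beta_snp: float = 0.0
    beta_sex: float = -0.075  # female vs male log-odds of disease
    beta_smoke: float = 1.5
    beta_interaction: float = 0.0
    baseline_prevalence: float = 0.05
    n_pcs: int = 5
    pc_effect: float = 0.0
    info_noise_sd: float = 0.1
    causal_snp: int = 0
    causal_maf: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        cases = tuple(int(x) for x in self.n_cases_per_study)
        controls = tuple(int(x) for x in self.n_controls_per_study)
        object.__setattr__(self, "n_cases_per_study", cases)
        object.__setattr__(self, "n_controls_per_study", controls)
        if len(cases) != len(controls):
            raise ValueError("case and control count lists differ in length")
        if any(x <= 0 for x in cases + controls):
            raise ValueError("per-study sample counts must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5] with lo <= hi")
        if not 0.0 < self.sex_fraction_female < 1.0:
            raise ValueError("sex_fraction_female must lie in (0, 1)")
        if not all(0.0 < x < 1.0 for x in self.smoking_prev_by_sex):
            raise ValueError("smoking prevalences must lie in (0, 1)")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        if self.info_noise_sd < 0.0:
            raise ValueError("info_noise_sd must be nonnegative")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if not 0 <= self.causal_snp < self.n_snps:
            raise ValueError("causal_snp out of range")
        if self.causal_maf is not None and not 0.0 < self.causal_maf <= 0.5:
            raise ValueError("causal_maf must lie in (0, 0.5]")

    @property
    def n_studies(self) -> int:
        return len(self.n_cases_per_study)


@dataclass
class StudyCohort:
    """One study's samples, dosage matrix and variant panel."""

    study_id: str
    samples: pd.DataFrame  # sample_id, sex, smoking, disease, pc1..pcK
    dosages: np.ndarray  # samples x snps, values in [0, 2]
    variants: pd.DataFrame  # snp_id, chrom, pos, ref, alt, info_score

    def __post_init__(self):
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage matrix does not align with samples/variants")
        if self.dosages.size and (
            self.dosages.min() < 0.0 or self.dosages.max() > 2.0
        ):
            raise ValueError("dosages must lie in [0, 2]")


@dataclass
class ExpressionSet:
    """Per-sample expression values with sex and coded genotype, post-filter."""

    samples: pd.DataFrame  # sample_id, sex, genotype_code, log2_expr
    gene: str
    n_dropped_low_expr: int
    n_duplicates_averaged: int


_BASES = np.array(list("ACGT"))


def _variant_frame(scenario: SimScenario) -> tuple[pd.DataFrame, np.ndarray]:
    """Shared variant panel + per-SNP (sex-averaged) MAFs for a scenario."""
    rng = np.random.default_rng(
        np.random.SeedSequence(scenario.seed, spawn_key=(0xC0FFEE,))
    )
    m = scenario.n_snps
    lo, hi = scenario.maf_range
    mafs = rng.uniform(lo, hi, size=m)
    if scenario.causal_maf is not None:
        mafs[scenario.causal_snp] = scenario.causal_maf
    pos = 10_000 + 997 * np.arange(m)  # 1-based, deterministic spacing
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    ref, alt = _BASES[ref_i], _BASES[alt_i]
    frame = pd.DataFrame(
        {
            "snp_id": [f"1:{p}:{r}:{a}" for p, r, a in zip(pos, ref, alt)],
            "chrom": "1",
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "info_score": np.nan,
        }
    )
    return frame, mafs


def _sex_mafs(scenario: SimScenario, mafs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    half = scenario.maf_sex_delta / 2.0
    pf = np.clip(mafs + half, 1e-6, 1.0 - 1e-6)
    pm = np.clip(mafs - half, 1e-6, 1.0 - 1e-6)
    return pm, pf


def _posterior_dosage(g: np.ndarray, p, sd: float, rng) -> np.ndarray:
    """Imputation-style dosage: E[g | g + noise] under the HWE(p) prior."""
    if sd == 0.0:
        return g.astype(float)
    signal = g + rng.normal(0.0, sd, size=g.shape)
    p = np.broadcast_to(np.asarray(p, dtype=float), g.shape)
    states = np.arange(3.0).reshape((3,) + (1,) * g.ndim)
    prior = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    # posterior over genotype states given the noisy signal
    w = prior * np.exp(-((signal[None, ...] - states) ** 2) / (2.0 * sd**2))
    return (w * states).sum(axis=0) / w.sum(axis=0)


def _info_scores(dosages: np.ndarray, genotypes: np.ndarray) -> np.ndarray:
    vd = dosages.var(axis=0)
    vg = genotypes.var(axis=0)
    out = np.ones(dosages.shape[1])
    ok = vg > 0
    out[ok] = np.minimum(1.0, vd[ok] / vg[ok])
    return out


def simulate_study(scenario: SimScenario, study_index: int) -> StudyCohort:
    """Generate one study cohort by rejection sampling.

    Base-population individuals are drawn in chunks (sex, smoking, PCs, the
    causal genotype, then disease from the logistic model) until the target
    case and control counts are met; non-causal SNP genotypes, being
    independent of disease, are filled in for retained samples only.

    Raises
    ------
    SimulationError
        If the target case count cannot be reached from a base population
        capped at ~50x the expected requirement (the scenario's realized
        prevalence is far below its nominal one).
    """
    if not 0 <= study_index < scenario.n_studies:
        raise ValueError(
            f"study_index {study_index} out of range for "
            f"{scenario.n_studies} studies"
        )
    n_cases = scenario.n_cases_per_study[study_index]
    n_controls = scenario.n_controls_per_study[study_index]
    rng = np.random.default_rng(
        np.random.SeedSequence(scenario.seed, spawn_key=(1, study_index))
    )
    variants, mafs = _variant_frame(scenario)
    pm, pf = _sex_mafs(scenario, mafs)
    j = scenario.causal_snp

    b0 = special.logit(scenario.baseline_prevalence)
    need_base = int(n_cases / scenario.baseline_prevalence + n_controls)
    cap = max(50 * need_base, 20 * (n_cases + n_controls))

    kept: list[dict] = []
    got_cases = got_controls = drawn = 0
    chunk = max(2 * (n_cases + n_controls), 2_000)
    while (got_cases < n_cases or got_controls < n_controls) and drawn < cap:
        if drawn:
            # re-size from the realized prevalence so low-prevalence
            # scenarios neither overdraw nor loop excessively
            p_hat = max(got_cases / drawn, 0.5 / drawn)
            q_hat = max(got_controls / drawn, 0.5 / drawn)
            need = max(
                (n_cases - got_cases) / p_hat, (n_controls - got_controls) / q_hat
            )
            chunk = int(np.clip(1.25 * need, 2_000, 500_000))
        m = min(chunk, cap - drawn)
        drawn += m
        female = rng.random(m) < scenario.sex_fraction_female
        smoke_p = np.where(
            female, scenario.smoking_prev_by_sex[1], scenario.smoking_prev_by_sex[0]
        )
        smoking = rng.random(m) < smoke_p
        pcs = rng.standard_normal((m, scenario.n_pcs))
        p_causal = np.where(female, pf[j], pm[j])
        g = rng.binomial(2, p_causal).astype(float)
        eta = (
            b0
            + scenario.beta_snp * g
            + scenario.beta_sex * female
            + scenario.beta_smoke * smoking
            + scenario.beta_interaction * g * female
            + scenario.pc_effect * pcs.sum(axis=1)
        )
        disease = rng.random(m) < special.expit(eta)
        # retain in draw order up to the remaining quota
        case_idx = np.flatnonzero(disease)[: n_cases - got_cases]
        ctrl_idx = np.flatnonzero(~disease)[: n_controls - got_controls]
        idx = np.sort(np.concatenate([case_idx, ctrl_idx]))
        got_cases += case_idx.size
        got_controls += ctrl_idx.size
        kept.append(
            dict(
                female=female[idx],
                smoking=smoking[idx],
                pcs=pcs[idx],
                g=g[idx],
                disease=disease[idx],
            )
        )
    if got_cases < n_cases or got_controls < n_controls:
        raise SimulationError(
            f"study {study_index}: needed {n_cases} cases/{n_controls} controls "
            f"but found {got_cases}/{got_controls} in {drawn} base draws; "
            "raise baseline_prevalence or lower the targets"
        )

    female = np.concatenate([k["female"] for k in kept])
    smoking = np.concatenate([k["smoking"] for k in kept])
    pcs = np.concatenate([k["pcs"] for k in kept])
    g_causal = np.concatenate([k["g"] for k in kept])
    disease = np.concatenate([k["disease"] for k in kept])
    n = female.size

    # non-causal genotypes for retained samples only
    P = np.where(female[:, None], pf[None, :], pm[None, :])
    genotypes = rng.binomial(2, P).astype(float)
    genotypes[:, j] = g_causal
    dosages = _posterior_dosage(genotypes, P, scenario.info_noise_sd, rng)
    variants = variants.copy()
    variants["info_score"] = _info_scores(dosages, genotypes)

    sid = f"study{study_index}"
    samples = pd.DataFrame(
        {
            "sample_id": [f"{sid}_s{i}" for i in range(n)],
            "study": sid,
            "sex": np.where(female, "female", "male"),
            "smoking": np.where(smoking, "ever", "never"),
            "disease": np.where(disease, "case", "control"),
        }
    )
    for k in range(scenario.n_pcs):
        samples[f"pc{k + 1}"] = pcs[:, k]
    return StudyCohort(sid, samples, dosages, variants)


def simulate_collection(scenario: SimScenario) -> list[StudyCohort]:
    """All studies of a scenario; study 0 is the discovery cohort."""
    if scenario.n_studies < 2:
        raise ValueError(
            "two-step design needs >= 2 studies (discovery + replication)"
        )
    return [simulate_study(scenario, i) for i in range(scenario.n_studies)]


def simulate_expression(
    genotype_codes,
    sex,
    effect_male: float,
    effect_female: float,
    base_log2: float,
    noise_sd: float,
    seed: int,
    *,
    gene: str = "GENE",
) -> ExpressionSet:
    """Log-normal expression with per-sex genotype effects.

    ``log2(rpkm) = base + effect_sex * code + N(0, noise_sd)``; samples whose
    resulting rpkm falls below the 0.25 floor are dropped and counted, so the
    emitted set satisfies the expression-set contract.
    """
    codes = np.asarray(genotype_codes, dtype=float)
    sexv = np.asarray(sex)
    if codes.shape != sexv.shape:
        raise ValueError("genotype and sex lengths differ")
    present = np.isfinite(codes)
    if not present.any():
        raise ValueError("all genotype codes missing")
    from .assoc import encode_binary

    female = encode_binary(sexv, "sex")
    rng = np.random.default_rng(seed)
    effect = np.where(female == 1.0, effect_female, effect_male)
    log2 = base_log2 + effect * codes + rng.normal(0.0, noise_sd, codes.shape)
    rpkm = np.power(2.0, log2)
    keep = present & (rpkm >= 0.25)
    dropped = int((present & (rpkm < 0.25)).sum())
    frame = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(codes.size)],
            "sex": np.where(female == 1.0, "female", "male"),
            "genotype_code": codes,
            "log2_expr": log2,
        }
    )[keep]
    return ExpressionSet(
        samples=frame.reset_index(drop=True),
        gene=gene,
        n_dropped_low_expr=dropped,
        n_duplicates_averaged=0,
    )
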
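"""Readers and writers for the tabular formats the pipeline touches.

TSV is the native dialect (UTF-8, '.' decimal, scientific notation allowed).
Every writer stamps a schema header comment (``# gwgi-schema: <name>.v1``)
on its first line; readers reject files carrying a schema they do not
support. Dosage matrices can also arrive as VCF 4.x with a per-sample DS
FORMAT field (read-only, via cyvcf2). Variant identifiers are normalized to
``chr:pos:ref:alt`` with 1-based positions throughout.

All writes are atomic: content lands in a temporary file in the target
directory and is renamed into place.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scan import ScanConfig
from .simulate import SimScenario, StudyCohort

__all__ = [
    "SchemaError",
    "read_dosage",
    "read_phenotypes",
    "write_phenotypes",
    "write_dosage",
    "write_variants",
    "write_cohort",
    "read_cohort",
    "write_collection",
    "read_collection",
    "write_table",
    "read_scenario_config",
    "read_scan_config",
]

SCHEMAS = {
    "phenotypes": "gwgi-schema: phenotypes.v1",
    "dosage": "gwgi-schema: dosage.v1",
    "variants": "gwgi-schema: variants.v1",
    "results": "gwgi-schema: results.v1",
}

PHENO_COLUMNS = ["sample_id", "study", "sex", "smoking", "disease"]
_ALLOWED = {
    "sex": {"male", "female"},
    "smoking": {"ever", "never"},
    "disease": {"case", "control"},
}


class SchemaError(ValueError):
    """A file carries a schema header this reader does not support."""


def _atomic_write(path, text: str):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(frame: pd.DataFrame, path, schema: str):
    """Write a TSV with its schema header, atomically.

    P-values and other floats are serialized with repr precision; columns
    documented by the header row.
    """
    header = SCHEMAS.get(schema, f"gwgi-schema: {schema}.v1")
    body = frame.to_csv(sep="\t", index=False, float_format="%.10g")
    _atomic_write(path, f"# {header}\n{body}")


def _read_tsv(path, schema: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    expected = SCHEMAS.get(schema, f"gwgi-schema: {schema}.v1")
    skip = 0
    if first.startswith("# gwgi-schema:"):
        if first.lstrip("# ") != expected:
            raise SchemaError(
                f"{path.name}: unsupported schema {first!r}, expected {expected!r}"
            )
        skip = 1
    return pd.read_csv(path, sep="\t", skiprows=skip)


def normalize_variant_id(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate a phenotype table.

    Required columns: sample_id, study, sex, smoking, disease, pc1..pc5.
    Categorical labels are checked against the allowed sets and sample_id
    uniqueness is enforced.
    """
    frame = _read_tsv(path, "phenotypes")
    required = PHENO_COLUMNS + [f"pc{k}" for k in range(1, 6)]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    for col, allowed in _ALLOWED.items():
        bad = set(frame[col].unique()) - allowed
        if bad:
            raise ValueError(f"unknown {col} label(s): {sorted(bad)}")
    return frame


def write_phenotypes(frame: pd.DataFrame, path):
    write_table(frame, path, "phenotypes")


def write_dosage(dosages: np.ndarray, snp_ids, sample_ids, path):
    """Dosage TSV: one row per SNP, one column per sample."""
    frame = pd.DataFrame(
        np.asarray(dosages).T, index=pd.Index(snp_ids, name="snp_id"),
        columns=sample_ids,
    )
    write_table(frame.reset_index(), path, "dosage")


def write_variants(variants: pd.DataFrame, path):
    write_table(variants, path, "variants")


def _validate_dosages(mat: np.ndarray, snp_ids, sample_ids):
    bad = np.argwhere((mat < 0.0) | (mat > 2.0) | ~np.isfinite(mat))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"dosage {mat[i, j]!r} out of [0, 2] at SNP {snp_ids[j]!r}, "
            f"sample {sample_ids[i]!r}"
        )


def read_dosage(path, format: str = "tsv"):
    """Read a dosage matrix.

    Parameters
    ----------
    path : TSV as written by :func:`write_dosage`, or a VCF with a DS
        FORMAT field when ``format="vcf_ds"``.

    Returns
    -------
    (dosages, variants) : dosages is a DataFrame (samples x snp_id columns);
        variants a frame with snp_id, chrom, pos (1-based), ref, alt and,
        for VCF input, any INFO-score key found (``INFO`` or ``R2``).
    """
    if format == "tsv":
        frame = _read_tsv(path, "dosage")
        snp_ids = frame["snp_id"].astype(str).tolist()
        samples = [c for c in frame.columns if c != "snp_id"]
        mat = frame[samples].to_numpy(dtype=float).T  # samples x snps
        _validate_dosages(mat, snp_ids, samples)
        parts = [s.split(":") for s in snp_ids]
        variants = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": [p[0] for p in parts],
                "pos": [int(p[1]) if len(p) > 1 else -1 for p in parts],
                "ref": [p[2] if len(p) > 2 else "N" for p in parts],
                "alt": [p[3] if len(p) > 3 else "N" for p in parts],
            }
        )
        return pd.DataFrame(mat, columns=snp_ids, index=samples), variants
    if format == "vcf_ds":
        return _read_vcf_ds(path)
    raise ValueError(f"unknown dosage format {format!r}")


def _read_vcf_ds(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, rows, meta = [], [], []
    for var in vcf:
        vid = normalize_variant_id(var.CHROM, var.POS, var.REF, var.ALT[0])
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is None:
            raise ValueError(f"record {vid} carries no DS FORMAT field")
        col = np.asarray(ds, dtype=float).ravel()
        info_score = var.INFO.get("INFO", var.INFO.get("R2", np.nan))
        snp_ids.append(vid)
        rows.append(col)
        meta.append(
            {
                "snp_id": vid,
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "info_score": info_score,
            }
        )
    mat = np.array(rows).T if rows else np.empty((len(samples), 0))
    _validate_dosages(mat, snp_ids, samples)
    return (
        pd.DataFrame(mat, columns=snp_ids, index=samples),
        pd.DataFrame(meta),
    )


def write_vcf_ds(cohort: StudyCohort, path):
    """Minimal VCF 4.2 writer with per-sample DS and per-site INFO score."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Allele dosage">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cohort.samples["sample_id"]),
    ]
    for j, v in cohort.variants.iterrows():
        ds = "\t".join(f"{d:.4g}" for d in cohort.dosages[:, j])
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.snp_id}\t{v.ref}\t{v.alt}\t.\t.\t"
            f"INFO={v.info_score:.4g}\tDS\t{ds}"
        )
    _atomic_write(path, "\n".join(lines) + "\n")


def write_cohort(cohort: StudyCohort, directory):
    """Write one study as phenotype/dosage/variant TSVs under ``directory``."""
    d = Path(directory)
    write_phenotypes(cohort.samples, d / "phenotypes.tsv")
    write_dosage(
        cohort.dosages,
        cohort.variants["snp_id"],
        cohort.samples["sample_id"],
        d / "dosages.tsv",
    )
    write_variants(cohort.variants, d / "variants.tsv")


def read_cohort(directory) -> StudyCohort:
    d = Path(directory)
    samples = read_phenotypes(d / "phenotypes.tsv")
    dose, _ = read_dosage(d / "dosages.tsv")
    variants = _read_tsv(d / "variants.tsv", "variants")
    missing = set(samples["sample_id"]) - set(dose.index)
    if missing:
        raise ValueError(
            f"samples absent from dosage matrix: {sorted(missing)[:3]}..."
            if len(missing) > 3
            else f"samples absent from dosage matrix: {sorted(missing)}"
        )
    dose = dose.loc[samples["sample_id"]]
    variants["chrom"] = variants["chrom"].astype(str)
    return StudyCohort(
        study_id=str(samples["study"].iloc[0]),
        samples=samples,
        dosages=dose.to_numpy(dtype=float),
        variants=variants,
    )


def write_collection(collection, directory):
    for i, cohort in enumerate(collection):
        write_cohort(cohort, Path(directory) / f"study_{i:03d}")


def read_collection(directory) -> list:
    d = Path(directory)
    dirs = sorted(p for p in d.iterdir() if p.is_dir() and p.name.startswith("study_"))
    if not dirs:
        raise ValueError(f"no study_* directories under {d}")
    return [read_cohort(p) for p in dirs]


def _load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key: value mapping")
    return data


def read_scenario_config(path) -> SimScenario:
    """Build a SimScenario from a flat YAML mapping of its field names."""
    data = _load_yaml(path)
    for key in ("n_cases_per_study", "n_controls_per_study", "maf_range",
                "smoking_prev_by_sex"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return SimScenario(**data)


def read_scan_config(path) -> ScanConfig:
    data = _load_yaml(path)
    if "covariates" in data and isinstance(data["covariates"], list):
        data["covariates"] = tuple(data["covariates"])
    return ScanConfig(**data)
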
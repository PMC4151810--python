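"""Cohort data model and TSV/CSV/VCF ingestion.

A cohort is one row per patient: six 0/1/2 genotype codes (variant-allele
counts against :data:`iripred.panel.DEFAULT_PANEL`), gender, age in years,
the binary severe-toxicity outcome (grade >=3 hematologic toxicity at any
point during therapy), and a training/validation split label.

Missing values are accepted as empty cells, ``NA`` or ``.`` and always
written back as ``NA``.  Lines starting with ``#`` are provenance headers
and are skipped on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import DEFAULT_PANEL, MISSING, LocusDef, validate_panel

log = logging.getLogger(__name__)

GENOTYPE_COLUMNS = tuple(l.locus_id for l in DEFAULT_PANEL)
REQUIRED_COLUMNS = ("patient_id", *GENOTYPE_COLUMNS, "gender", "age", "toxicity", "split")

_MISSING_TOKENS = {"", "NA", "."}
_SPLITS = {"training", "validation", "unassigned"}


class CohortParseError(ValueError):
    """Raised when a cohort file cell cannot be interpreted."""


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    genotypes: tuple[int, ...]  # variant-allele counts, MISSING allowed
    gender: str | None  # "M", "F" or None
    age_years: int
    toxicity: int | None  # 1 = severe toxicity, 0 = none, None = unknown
    split: str = "unassigned"

    def with_split(self, split: str) -> "PatientRecord":
        return replace(self, split=split)


@dataclass
class Cohort:
    panel: tuple[LocusDef, ...] = DEFAULT_PANEL
    records: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_panel(self.panel)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, split: str) -> "Cohort":
        return Cohort(self.panel, [r for r in self.records if r.split == split])

    def locus_index(self, locus_id: str) -> int:
        for i, l in enumerate(self.panel):
            if l.locus_id == locus_id:
                return i
        raise KeyError(f"unknown locus {locus_id!r}")

    # --- array views used by the numeric stages -------------------------
    def genotype_matrix(self) -> np.ndarray:
        """(n, n_loci) int matrix of variant-allele counts, MISSING = -1."""
        if not self.records:
            return np.empty((0, len(self.panel)), dtype=np.int64)
        return np.array([r.genotypes for r in self.records], dtype=np.int64)

    def toxicity_array(self) -> np.ndarray:
        return np.array(
            [MISSING if r.toxicity is None else r.toxicity for r in self.records],
            dtype=np.int64,
        )

    def gender_array(self) -> np.ndarray:
        """0 = male, 1 = female, -1 = unknown."""
        code = {"M": 0, "F": 1, None: MISSING}
        return np.array([code[r.gender] for r in self.records], dtype=np.int64)

    def age_array(self) -> np.ndarray:
        return np.array([r.age_years for r in self.records], dtype=np.int64)


def _parse_genotype(token: str, row: int, column: str) -> int:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return MISSING
    if token in ("0", "1", "2"):
        return int(token)
    raise CohortParseError(
        f"row {row}, column {column}: genotype code {token!r} is not one of 0/1/2/NA"
    )


def _cell(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return str(value).strip()


def read_cohort(path, dialect: str = "tsv") -> Cohort:
    """Read a patient table; see module docstring for the column contract."""
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#", keep_default_na=False)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortParseError(f"missing required columns: {missing_cols}")

    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        genotypes = tuple(
            _parse_genotype(_cell(row[c]), i, c) for c in GENOTYPE_COLUMNS
        )
        gender_tok = _cell(row["gender"])
        if gender_tok in _MISSING_TOKENS:
            gender = None
        elif gender_tok in ("M", "F"):
            gender = gender_tok
        else:
            raise CohortParseError(f"row {i}, column gender: {gender_tok!r} not M/F/NA")
        age_tok = _cell(row["age"])
        try:
            age = int(age_tok)
        except ValueError:
            raise CohortParseError(f"row {i}, column age: {age_tok!r} is not an integer")
        tox_tok = _cell(row["toxicity"])
        if tox_tok in _MISSING_TOKENS:
            toxicity = None
        elif tox_tok in ("0", "1"):
            toxicity = int(tox_tok)
        else:
            raise CohortParseError(f"row {i}, column toxicity: {tox_tok!r} not 0/1/NA")
        split_tok = _cell(row["split"]) or "unassigned"
        if split_tok not in _SPLITS:
            raise CohortParseError(
                f"row {i}, column split: {split_tok!r} not in {sorted(_SPLITS)}"
            )
        records.append(
            PatientRecord(_cell(row["patient_id"]), genotypes, gender, age, toxicity, split_tok)
        )
    cohort = Cohort(DEFAULT_PANEL, records)
    issues = validate_cohort(cohort)
    if issues:
        raise CohortParseError("; ".join(issues))
    return cohort


def write_cohort(cohort: Cohort, path, dialect: str = "tsv", header_lines: list[str] | None = None) -> None:
    """Write a cohort; ``read_cohort(write_cohort(c))`` reproduces ``c``."""
    sep = {"tsv": "\t", "csv": ","}[dialect]

    def g(v: int) -> str:
        return "NA" if v == MISSING else str(v)

    rows = []
    for r in cohort.records:
        rows.append(
            {
                "patient_id": r.patient_id,
                **{c: g(v) for c, v in zip(GENOTYPE_COLUMNS, r.genotypes)},
                "gender": r.gender if r.gender is not None else "NA",
                "age": str(r.age_years),
                "toxicity": "NA" if r.toxicity is None else str(r.toxicity),
                "split": r.split,
            }
        )
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)


def validate_cohort(cohort: Cohort) -> list[str]:
    """Return human-readable descriptions of every invariant violation."""
    issues: list[str] = []
    seen: set[str] = set()
    for r in cohort.records:
        if r.patient_id in seen:
            issues.append(f"duplicate patient_id {r.patient_id!r}")
        seen.add(r.patient_id)
        if len(r.genotypes) != len(cohort.panel):
            issues.append(
                f"{r.patient_id}: genotype vector length {len(r.genotypes)} != panel size"
            )
        for c, v in zip(GENOTYPE_COLUMNS, r.genotypes):
            if v not in (0, 1, 2, MISSING):
                issues.append(f"{r.patient_id}: {c} genotype {v} out of range")
        if not (0 <= r.age_years <= 130):
            issues.append(f"{r.patient_id}: age {r.age_years} outside [0, 130]")
        if r.gender not in ("M", "F", None):
            issues.append(f"{r.patient_id}: gender {r.gender!r} invalid")
        if r.toxicity not in (0, 1, None):
            issues.append(f"{r.patient_id}: toxicity {r.toxicity!r} invalid")
        if r.split not in _SPLITS:
            issues.append(f"{r.patient_id}: split {r.split!r} invalid")
    return issues


def read_vcf_genotypes(path, panel: tuple[LocusDef, ...] = DEFAULT_PANEL,
                       site_map: dict[str, str] | None = None) -> dict[str, dict[str, int]]:
    """Extract variant-allele counts for the panel sites from a VCF.

    Sites are matched by rs ID (the VCF ``ID`` column); ``site_map`` may
    override the rs ID used for a locus (``locus_id -> site id``).  The
    repeat polymorphisms (TA6/TA7, T9/T10) are expected as REF/ALT sequence
    alleles at their usual positions; whichever of REF/ALT is longer is
    taken as the longer-repeat allele.  Half-calls and no-calls map to
    MISSING.  A panel site absent from the file is logged and left MISSING
    for every sample.

    Returns ``{sample_id: {locus_id: count}}`` with MISSING = -1.
    """
    import pysam

    site_map = site_map or {}
    wanted = {site_map.get(l.locus_id, l.rs_id): l for l in panel}
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    table: dict[str, dict[str, int]] = {
        s: {l.locus_id: MISSING for l in panel} for s in samples
    }
    seen: set[str] = set()
    for rec in vcf:
        if rec.id not in wanted:
            continue
        locus = wanted[rec.id]
        seen.add(rec.id)
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt) or len(gt) != 2:
                continue  # half-call / no-call stays MISSING
            # count of ALT alleles = count of the panel's variant allele;
            # for the repeat loci the ALT is the non-reference repeat length.
            table[s][locus.locus_id] = sum(1 for a in gt if a != 0)
    for site_id, locus in wanted.items():
        if site_id not in seen:
            log.warning(
                "site %s (%s) absent from VCF; locus left MISSING for all samples",
                site_id, locus.locus_id,
            )
            warnings.warn(f"site {site_id} absent from VCF", stacklevel=2)
    return table
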
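"""Readers and writers for the pipeline's tabular formats.

Formats (all plain text):

* sample sheet — CSV, header
  ``sample_id,group,age,sex,mmse,fab,apoe_a1,apoe_a2,duration_months,onset_age``
* beta matrix — TSV, first column ``locus_id``, one column per sample
* locus annotation manifest — CSV with Illumina-450K-style semicolon-separated
  per-transcript fields, header
  ``target_id,is_cpg,gene,accession,refgene_group,island_relation,chr,pos``
* pyrosequencing table — CSV, header ``sample_id,cpg_index,percent_methylation``

Missing values are empty cells on disk and ``None``/NaN in memory.  Readers
validate against the domain invariants and raise :class:`FormatError` naming
the offending row/field rather than silently coercing.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("NC", "aMCI", "AD")
SEXES = ("F", "M")
APOE_ALLELES = ("e2", "e3", "e4")
REFGENE_GROUPS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR")
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: RefGene groups counted as promoter-proximal in the candidate funnel.
PROMOTER_GROUPS = frozenset({"TSS1500", "TSS200", "5'UTR", "1stExon"})


class FormatError(ValueError):
    """An on-disk table violates the format contract or a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SampleRecord:
    """One subject of the cohort: diagnostic group plus clinical covariates.

    MMSE (0-30) and FAB (0-18) are administered to aMCI/AD patients only, so
    NC records normally carry ``None`` for the scores, disease duration and
    onset age.
    """

    sample_id: str
    group: str
    age: float
    sex: str
    mmse: int | None = None
    fab: int | None = None
    apoe_alleles: tuple[str, str] = ("e3", "e3")
    duration_months: float | None = None
    onset_age: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(f"sample {self.sample_id!r}: unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise FormatError(f"sample {self.sample_id!r}: unknown sex {self.sex!r}")
        if len(self.apoe_alleles) != 2 or any(
            a not in APOE_ALLELES for a in self.apoe_alleles
        ):
            raise FormatError(
                f"sample {self.sample_id!r}: invalid APOE alleles {self.apoe_alleles!r}"
            )
        # store the unordered pair canonically
        self.apoe_alleles = tuple(sorted(self.apoe_alleles))  # type: ignore[assignment]
        if self.mmse is not None and not 0 <= self.mmse <= 30:
            raise FormatError(
                f"sample {self.sample_id!r}: mmse={self.mmse} outside [0, 30]"
            )
        if self.fab is not None and not 0 <= self.fab <= 18:
            raise FormatError(
                f"sample {self.sample_id!r}: fab={self.fab} outside [0, 18]"
            )


@dataclass
class BetaMatrix:
    """Methylation fractions, loci x samples, in [0, 1] with NaN for missing."""

    locus_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_loci, n_samples), float, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise FormatError("duplicate locus ids in beta matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in beta matrix")
        if self.values.shape != (len(self.locus_ids), len(self.sample_ids)):
            raise FormatError(
                f"beta matrix shape {self.values.shape} does not match "
                f"{len(self.locus_ids)} loci x {len(self.sample_ids)} samples"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise FormatError("beta values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def locus_index(self, locus_id: str) -> int:
        try:
            return self.locus_ids.index(locus_id)
        except ValueError:
            raise KeyError(f"locus {locus_id!r} not in beta matrix") from None

    def row(self, locus_id: str) -> np.ndarray:
        return self.values[self.locus_index(locus_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return BetaMatrix(list(self.locus_ids), list(sample_ids), self.values[:, idx])

    def subset_loci(self, locus_ids: Sequence[str]) -> "BetaMatrix":
        idx = [self.locus_index(l) for l in locus_ids]
        return BetaMatrix(list(locus_ids), list(self.sample_ids), self.values[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.locus_ids, columns=self.sample_ids)


@dataclass
class LocusAnnotation:
    """450K-style annotation for one locus.

    Multi-transcript fields (``gene_names``, ``accessions``, ``refgene_groups``)
    are kept as aligned lists — one entry per overlapping transcript — because
    the promoter filter uses any-transcript membership.
    """

    target_id: str
    is_cpg: bool
    gene_names: list[str] = field(default_factory=list)
    accessions: list[str] = field(default_factory=list)
    refgene_groups: list[str] = field(default_factory=list)
    island_relation: str = "OpenSea"
    chromosome: str = "chr1"
    position: int = 1

    def __post_init__(self) -> None:
        n = len(self.gene_names)
        if not (len(self.accessions) == len(self.refgene_groups) == n):
            raise FormatError(
                f"locus {self.target_id!r}: gene/accession/group lists have "
                f"unequal lengths ({n}, {len(self.accessions)}, "
                f"{len(self.refgene_groups)})"
            )
        bad = [g for g in self.refgene_groups if g not in REFGENE_GROUPS]
        if bad:
            raise FormatError(f"locus {self.target_id!r}: unknown RefGene group {bad[0]!r}")
        if self.island_relation not in ISLAND_RELATIONS:
            raise FormatError(
                f"locus {self.target_id!r}: unknown island relation "
                f"{self.island_relation!r}"
            )

    @property
    def has_accession(self) -> bool:
        return any(a for a in self.accessions)

    @property
    def in_promoter(self) -> bool:
        return any(g in PROMOTER_GROUPS for g in self.refgene_groups)

    @property
    def in_island(self) -> bool:
        return self.island_relation == "Island"


@dataclass
class PyroTable:
    """Long-format pyrosequencing output: per-sample, per-CpG percent methylation."""

    data: pd.DataFrame  # columns: sample_id, cpg_index, percent_methylation

    def __post_init__(self) -> None:
        required = ["sample_id", "cpg_index", "percent_methylation"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"pyro table missing columns: {missing}")
        pm = self.data["percent_methylation"]
        if ((pm < 0) | (pm > 100)).any():
            raise FormatError("percent_methylation outside [0, 100]")
        if (self.data["cpg_index"] < 1).any():
            raise FormatError("cpg_index must be >= 1")

    @property
    def cpg_indices(self) -> list[int]:
        return sorted(self.data["cpg_index"].unique())

    def for_cpg(self, cpg_index: int) -> pd.Series:
        sub = self.data[self.data["cpg_index"] == cpg_index]
        return sub.set_index("sample_id")["percent_methylation"]


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_HEADER = [
    "sample_id", "group", "age", "sex", "mmse", "fab",
    "apoe_a1", "apoe_a2", "duration_months", "onset_age",
]


def _parse_opt_float(cell: str) -> float | None:
    return None if cell == "" else float(cell)


def _parse_opt_int(cell: str) -> int | None:
    return None if cell == "" else int(round(float(cell)))


def read_sample_sheet(path) -> list[SampleRecord]:
    """Read the clinical sample sheet, validating every row."""
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        got = reader.fieldnames or []
        if got != SAMPLE_SHEET_HEADER:
            raise FormatError(
                f"sample sheet header {got} != expected {SAMPLE_SHEET_HEADER}"
            )
        for i, row in enumerate(reader, start=2):  # header is line 1
            if None in row.values() or None in row:
                raise FormatError(f"sample sheet row {i}: wrong number of fields")
            try:
                rec = SampleRecord(
                    sample_id=row["sample_id"],
                    group=row["group"],
                    age=float(row["age"]),
                    sex=row["sex"],
                    mmse=_parse_opt_int(row["mmse"]),
                    fab=_parse_opt_int(row["fab"]),
                    apoe_alleles=(row["apoe_a1"], row["apoe_a2"]),
                    duration_months=_parse_opt_float(row["duration_months"]),
                    onset_age=_parse_opt_float(row["onset_age"]),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"sample sheet row {i}: {exc}") from exc
            if rec.sample_id in seen:
                raise FormatError(
                    f"sample sheet row {i}: duplicate sample_id {rec.sample_id!r}"
                )
            seen.add(rec.sample_id)
            records.append(rec)
    return records


def _fmt_opt(value, ndigits: int | None = None) -> str:
    if value is None:
        return ""
    if ndigits is not None and isinstance(value, float):
        return format(value, f".{ndigits}f")
    return str(value)


def write_sample_sheet(records: Iterable[SampleRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SAMPLE_SHEET_HEADER)
        for r in records:
            writer.writerow([
                r.sample_id, r.group, format(r.age, ".2f"), r.sex,
                _fmt_opt(r.mmse), _fmt_opt(r.fab),
                r.apoe_alleles[0], r.apoe_alleles[1],
                _fmt_opt(r.duration_months, 2), _fmt_opt(r.onset_age, 2),
            ])


def cohort_by_group(records: Sequence[SampleRecord]) -> dict[str, list[SampleRecord]]:
    out: dict[str, list[SampleRecord]] = {g: [] for g in GROUPS}
    for r in records:
        out[r.group].append(r)
    return out


# ---------------------------------------------------------------------------
# Beta matrix
# ---------------------------------------------------------------------------


def read_beta_matrix(path) -> BetaMatrix:
    """Read a loci x samples TSV of methylation fractions."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "locus_id":
            raise FormatError("beta matrix header must start with 'locus_id'")
        sample_ids = header[1:]
        locus_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"beta matrix line {lineno}: {len(parts)} fields, "
                    f"expected {len(header)}"
                )
            locus = parts[0]
            vals = []
            for sample, cell in zip(sample_ids, parts[1:]):
                if cell == "":
                    vals.append(math.nan)
                    continue
                v = float(cell)
                if not 0.0 <= v <= 1.0:
                    raise FormatError(
                        f"beta value {v} outside [0, 1] at locus {locus!r}, "
                        f"sample {sample!r}"
                    )
                vals.append(v)
            locus_ids.append(locus)
            rows.append(vals)
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return BetaMatrix(locus_ids, sample_ids, values)


def write_beta_matrix(beta: BetaMatrix, path, ndigits: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\t" + "\t".join(beta.sample_ids) + "\n")
        for locus, row in zip(beta.locus_ids, beta.values):
            cells = ["" if not np.isfinite(v) else format(v, f".{ndigits}f") for v in row]
            fh.write(locus + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Annotation manifest
# ---------------------------------------------------------------------------

MANIFEST_HEADER = [
    "target_id", "is_cpg", "gene", "accession", "refgene_group",
    "island_relation", "chr", "pos",
]

def _split_semicolon(cell: str) -> list[str]:
    return [] if cell == "" else cell.split(";")


def read_manifest(path) -> list[LocusAnnotation]:
    """Read a 450K-style annotation manifest with semicolon-aligned fields."""
    out: list[LocusAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if (reader.fieldnames or []) != MANIFEST_HEADER:
            raise FormatError(
                f"manifest header {reader.fieldnames} != expected {MANIFEST_HEADER}"
            )
        for i, row in enumerate(reader, start=2):
            island = row["island_relation"]
            if island == "":
                island = "OpenSea"
            try:
                ann = LocusAnnotation(
                    target_id=row["target_id"],
                    is_cpg=row["is_cpg"].strip().lower() in ("true", "1", "yes"),
                    gene_names=_split_semicolon(row["gene"]),
                    accessions=_split_semicolon(row["accession"]),
                    refgene_groups=_split_semicolon(row["refgene_group"]),
                    island_relation=island,
                    chromosome=row["chr"],
                    position=int(row["pos"]),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"manifest row {i}: {exc}") from exc
            out.append(ann)
    return out


def write_manifest(annotations: Iterable[LocusAnnotation], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_HEADER)
        for a in annotations:
            writer.writerow([
                a.target_id, a.is_cpg,
                ";".join(a.gene_names), ";".join(a.accessions),
                ";".join(a.refgene_groups), a.island_relation,
                a.chromosome, a.position,
            ])


def manifest_index(annotations: Iterable[LocusAnnotation]) -> dict[str, LocusAnnotation]:
    return {a.target_id: a for a in annotations}


# ---------------------------------------------------------------------------
# Pyrosequencing tables
# ---------------------------------------------------------------------------


def read_pyro_table(path) -> PyroTable:
    df = pd.read_csv(path, dtype={"sample_id": str})
    try:
        df["cpg_index"] = df["cpg_index"].astype(int)
        df["percent_methylation"] = df["percent_methylation"].astype(float)
    except (KeyError, ValueError) as exc:
        raise FormatError(f"pyro table: {exc}") from exc
    return PyroTable(df)


def write_pyro_table(table: PyroTable, path) -> None:
    df = table.data[["sample_id", "cpg_index", "percent_methylation"]].copy()
    df["percent_methylation"] = df["percent_methylation"].map(lambda v: format(v, ".3f"))
    df.to_csv(path, index=False)
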
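"""Readers and writers for every external format the pipeline touches.

Variant calls travel as MAF-compatible tab-delimited tables.  Two dialects
are supported:

* ``maf`` — the standard MAF columns only (``Hugo_Symbol``, ``Chromosome``,
  ``Start_Position``, ``Reference_Allele``, ``Tumor_Seq_Allele2``,
  ``Variant_Classification``, ``Variant_Type``, ``Tumor_Sample_Barcode``,
  ``t_depth``, ``t_alt_count``, ``n_depth``).  Evidence fields that a plain
  MAF lacks (phred quality, strand-bias p, normal VAF, dbSNP membership,
  population allele frequencies) load as *missing*, never as fabricated
  defaults.
* ``extended`` — additionally consumes the evidence columns
  ``phred_quality``, ``strand_bias_p``, ``n_vaf``, ``dbsnp_member``,
  ``pop_af_1kg_eur``, ``pop_af_exac_nfe`` whenever they are present.

Coordinates are 1-based inclusive (MAF convention); all variants are
reported on the plus strand.  Missing numeric cells are encoded as the
empty string on disk — never 0, because 0 is a meaningful allele frequency.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "VariantRecord",
    "ClinicalRecord",
    "GeneSetCollection",
    "EdgeList",
    "FormatError",
    "read_variant_table",
    "write_variant_table",
    "read_clinical_table",
    "write_clinical_table",
    "read_gene_sets",
    "read_ppi_edges",
    "variant_key",
]

PRE = "PRE"
POST = "POST"

VARIANT_CLASSIFICATIONS = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Splice_Site",
        "Nonstop_Mutation",
        "Translation_Start_Site",
        "Silent",
    }
)

VARIANT_TYPES = frozenset({"SNV", "MNV", "INS", "DEL"})


class FormatError(ValueError):
    """A file does not conform to the documented on-disk format."""


@dataclass
class VariantRecord:
    """One annotated somatic variant call in one tumor sample.

    ``tumor_vaf`` is derivable (alt reads / depth) and recomputed when the
    input table lacks it.  Optional evidence fields are ``None`` when the
    source table did not carry them.
    """

    patient_id: str
    sample_id: str
    timepoint: str  # PRE | POST
    gene: str
    chromosome: str
    position: int  # 1-based inclusive
    ref_allele: str
    alt_allele: str
    variant_type: str
    variant_classification: str
    tumor_depth: int
    tumor_alt_reads: int
    tumor_vaf: float | None = None
    phred_quality: float | None = None
    strand_bias_p: float | None = None
    normal_depth: int | None = None
    normal_vaf: float | None = None
    dbsnp_member: bool | None = None
    pop_af_1kg_eur: float | None = None
    pop_af_exac_nfe: float | None = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"ref and alt alleles are identical ({self.ref_allele}) at "
                f"{self.chromosome}:{self.position}"
            )
        if self.tumor_alt_reads > self.tumor_depth:
            raise ValueError(
                f"tumor_alt_reads ({self.tumor_alt_reads}) exceeds tumor_depth "
                f"({self.tumor_depth}) at {self.chromosome}:{self.position}"
            )
        if self.tumor_vaf is None and self.tumor_depth > 0:
            self.tumor_vaf = self.tumor_alt_reads / self.tumor_depth
        if (
            self.tumor_vaf is not None
            and self.tumor_depth > 0
            and abs(self.tumor_vaf - self.tumor_alt_reads / self.tumor_depth) > 0.005
        ):
            raise ValueError(
                f"tumor_vaf {self.tumor_vaf:.4f} inconsistent with "
                f"{self.tumor_alt_reads}/{self.tumor_depth} at "
                f"{self.chromosome}:{self.position}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Genomic identity key: (chromosome, position, ref, alt)."""
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


def variant_key(record: VariantRecord) -> tuple[str, int, str, str]:
    return record.key


@dataclass
class ClinicalRecord:
    """Per-patient clinical annotations used by the association stages."""

    patient_id: str
    age_years: int | None = None
    response: str | None = None  # pCR | RD
    relapse: bool | None = None
    stage: str | None = None
    grade: str | None = None
    stils_pre: float | None = None
    stils_post: float | None = None

    def __post_init__(self) -> None:
        if self.response is not None and self.response not in ("pCR", "RD"):
            raise FormatError(
                f"unknown response label {self.response!r} for patient "
                f"{self.patient_id}; allowed: pCR, RD"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets (upper-case HUGO symbols) with a source tag per set."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)  # set_name -> tag

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


@dataclass(frozen=True)
class EdgeList:
    """Undirected, deduplicated protein-protein interaction edges."""

    edges: frozenset[tuple[str, str]]  # each stored as sorted pair

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> frozenset[str]:
        return frozenset(g for pair in self.edges for g in pair)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return tuple(sorted((a, b))) in self.edges


# ---------------------------------------------------------------------------
# variant tables

_MAF_REQUIRED = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
    "t_depth",
    "t_alt_count",
    "n_depth",
]

_EXTENSION_COLUMNS = [
    "phred_quality",
    "strand_bias_p",
    "n_vaf",
    "dbsnp_member",
    "pop_af_1kg_eur",
    "pop_af_exac_nfe",
]

#: Fixed on-disk column order for :func:`write_variant_table`.
VARIANT_TABLE_COLUMNS = (
    _MAF_REQUIRED[:8]
    + ["Patient_ID", "Timepoint", "t_depth", "t_alt_count", "t_vaf", "n_depth"]
    + _EXTENSION_COLUMNS
)


def _parse_float(cell: str, column: str, line: int) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise FormatError(f"line {line}: non-numeric value {cell!r} in column {column}")


def _parse_int(cell: str, column: str, line: int) -> int:
    try:
        return int(cell)
    except ValueError:
        raise FormatError(f"line {line}: non-numeric value {cell!r} in column {column}")


def _parse_bool(cell: str, column: str, line: int) -> bool | None:
    if cell == "":
        return None
    low = cell.strip().lower()
    if low in ("true", "1", "yes", "y"):
        return True
    if low in ("false", "0", "no", "n"):
        return False
    raise FormatError(f"line {line}: non-boolean value {cell!r} in column {column}")


def _split_barcode(barcode: str, line: int) -> tuple[str, str]:
    """Derive (patient_id, timepoint) from a '<patient>_<PRE|POST>' barcode."""
    if "_" in barcode:
        patient, _, suffix = barcode.rpartition("_")
        if suffix.upper() in (PRE, POST):
            return patient, suffix.upper()
    raise FormatError(
        f"line {line}: cannot derive patient/timepoint from sample barcode "
        f"{barcode!r}; supply Patient_ID and Timepoint columns or use "
        f"'<patient>_PRE' / '<patient>_POST' barcodes"
    )


def read_variant_table(path: str | Path, dialect: str = "extended") -> list[VariantRecord]:
    """Load a MAF-compatible variant table; order follows input rows.

    ``dialect='maf'`` consumes only standard MAF columns; ``'extended'``
    additionally reads the evidence columns when present.  Missing optional
    columns yield missing field values.
    """
    if dialect not in ("maf", "extended"):
        raise ValueError(f"unknown dialect {dialect!r}; use 'maf' or 'extended'")
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        idx = {name: i for i, name in enumerate(header)}
        for col in _MAF_REQUIRED:
            if col not in idx:
                raise FormatError(f"{path}: missing required column {col}")
        use_ext = dialect == "extended"

        def cell(row: list[str], col: str) -> str:
            i = idx.get(col)
            if i is None or i >= len(row):
                return ""
            return row[i]

        records: list[VariantRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and row[0] == ""):
                continue
            barcode = cell(row, "Tumor_Sample_Barcode")
            patient = cell(row, "Patient_ID")
            timepoint = cell(row, "Timepoint").upper()
            if not patient or timepoint not in (PRE, POST):
                patient, timepoint = _split_barcode(barcode, lineno)
            depth = _parse_int(cell(row, "t_depth"), "t_depth", lineno)
            alt = _parse_int(cell(row, "t_alt_count"), "t_alt_count", lineno)
            vaf = _parse_float(cell(row, "t_vaf"), "t_vaf", lineno)
            n_depth_cell = cell(row, "n_depth")
            record = VariantRecord(
                patient_id=patient,
                sample_id=barcode,
                timepoint=timepoint,
                gene=cell(row, "Hugo_Symbol"),
                chromosome=cell(row, "Chromosome"),
                position=_parse_int(cell(row, "Start_Position"), "Start_Position", lineno),
                ref_allele=cell(row, "Reference_Allele"),
                alt_allele=cell(row, "Tumor_Seq_Allele2"),
                variant_type=cell(row, "Variant_Type"),
                variant_classification=cell(row, "Variant_Classification"),
                tumor_depth=depth,
                tumor_alt_reads=alt,
                tumor_vaf=vaf,
                normal_depth=(
                    _parse_int(n_depth_cell, "n_depth", lineno) if n_depth_cell else None
                ),
            )
            if use_ext:
                record.phred_quality = _parse_float(
                    cell(row, "phred_quality"), "phred_quality", lineno
                )
                record.strand_bias_p = _parse_float(
                    cell(row, "strand_bias_p"), "strand_bias_p", lineno
                )
                record.normal_vaf = _parse_float(cell(row, "n_vaf"), "n_vaf", lineno)
                record.dbsnp_member = _parse_bool(
                    cell(row, "dbsnp_member"), "dbsnp_member", lineno
                )
                record.pop_af_1kg_eur = _parse_float(
                    cell(row, "pop_af_1kg_eur"), "pop_af_1kg_eur", lineno
                )
                record.pop_af_exac_nfe = _parse_float(
                    cell(row, "pop_af_exac_nfe"), "pop_af_exac_nfe", lineno
                )
            records.append(record)
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, float):
        return repr(value)  # shortest round-trip representation
    return str(value)


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records in the fixed :data:`VARIANT_TABLE_COLUMNS` order.

    ``read_variant_table(write_variant_table(x), 'extended')`` is the
    identity on every field, including missing-value status.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_TABLE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.gene,
                    r.chromosome,
                    _fmt(r.position),
                    r.ref_allele,
                    r.alt_allele,
                    r.variant_classification,
                    r.variant_type,
                    r.sample_id,
                    r.patient_id,
                    r.timepoint,
                    _fmt(r.tumor_depth),
                    _fmt(r.tumor_alt_reads),
                    _fmt(r.tumor_vaf),
                    _fmt(r.normal_depth),
                    _fmt(r.phred_quality),
                    _fmt(r.strand_bias_p),
                    _fmt(r.normal_vaf),
                    _fmt(r.dbsnp_member),
                    _fmt(r.pop_af_1kg_eur),
                    _fmt(r.pop_af_exac_nfe),
                ]
            )


# ---------------------------------------------------------------------------
# clinical sheets

CLINICAL_COLUMNS = [
    "patient_id",
    "age_years",
    "response",
    "relapse",
    "stage",
    "grade",
    "stils_pre",
    "stils_post",
]


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "patient_id" not in reader.fieldnames:
            raise FormatError(f"{path}: missing required column patient_id")
        out: list[ClinicalRecord] = []
        for lineno, row in enumerate(reader, start=2):
            response = (row.get("response") or "").strip()
            if response and response not in ("pCR", "RD"):
                raise FormatError(
                    f"line {lineno}: unknown response label {response!r}; "
                    "allowed values: pCR, RD"
                )
            relapse = _parse_bool(row.get("relapse") or "", "relapse", lineno)
            if not response and relapse is None:
                raise FormatError(
                    f"line {lineno}: response and relapse are both missing for "
                    f"patient {row.get('patient_id')!r}"
                )
            out.append(
                ClinicalRecord(
                    patient_id=row["patient_id"],
                    age_years=(
                        _parse_int(row["age_years"], "age_years", lineno)
                        if (row.get("age_years") or "").strip()
                        else None
                    ),
                    response=response or None,
                    relapse=relapse,
                    stage=(row.get("stage") or "").strip() or None,
                    grade=(row.get("grade") or "").strip() or None,
                    stils_pre=_parse_float(row.get("stils_pre") or "", "stils_pre", lineno),
                    stils_post=_parse_float(
                        row.get("stils_post") or "", "stils_post", lineno
                    ),
                )
            )
    return out


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CLINICAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    _fmt(r.age_years),
                    r.response or "",
                    _fmt(r.relapse),
                    r.stage or "",
                    r.grade or "",
                    _fmt(r.stils_pre),
                    _fmt(r.stils_post),
                ]
            )


# ---------------------------------------------------------------------------
# gene sets (GMT) and PPI edge lists

_SOURCE_PREFIXES = (("KEGG_", "KEGG"), ("GO_", "GO"), ("GOBP_", "GO"))


def read_gene_sets(path: str | Path, source: str = "custom") -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Gene symbols are upper-cased and deduplicated within a set.  The source
    tag is inferred from ``KEGG_``/``GO_`` name prefixes, falling back to
    *source*.
    """
    path = Path(path)
    collection = GeneSetCollection()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields; GMT "
                    "requires name, description and at least one gene"
                )
            name = fields[0]
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} is empty")
            tag = source
            for prefix, inferred in _SOURCE_PREFIXES:
                if name.upper().startswith(prefix):
                    tag = inferred
                    break
            collection.sets[name] = genes
            collection.sources[name] = tag
    return collection


def read_ppi_edges(path: str | Path) -> EdgeList:
    """Load a two-column TSV edge list (header ``gene_a``/``gene_b``).

    Edges are symmetrized: reversed duplicates collapse and self-loops are
    dropped, so the result is invariant under row permutation and pair
    reversal of the input file.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty edge list")
        if len(header) < 2:
            raise FormatError(f"{path}: edge list needs two tab-separated columns")
        rows = reader
        if header[0].upper() not in ("GENE_A", "GENEA", "SOURCE"):
            # headerless file: treat the first line as an edge
            rows = [header] + list(reader)  # type: ignore[assignment]
        for lineno, row in enumerate(rows, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: line {lineno}: expected two columns")
            a, b = row[0].strip().upper(), row[1].strip().upper()
            if not a or not b or a == b:
                continue
            edges.add(tuple(sorted((a, b))))  # type: ignore[arg-type]
    return EdgeList(edges=frozenset(edges))
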
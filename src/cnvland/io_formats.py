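"""Domain records and readers/writers for every external table the pipeline touches.

File formats (all plain text, tab-delimited, header rows required):

* CNV/LOH call table: ``sample_id  chrom  start  end  type  [copy_number]``
  with 1-based coordinates matching the interval convention of
  :mod:`cnvland.intervals` and ``type`` in {DEL, DUP, LOH}.  Array platforms
  export tabular calls, so the project format is a TSV rather than VCF; a BED
  export (0-based half-open) is provided for interoperability.
* Gene models: BED12, exon blocks reconstructed from block sizes/starts.
  Gene flags (CEG / imprinted / dosage-sensitive) come from flat one-symbol-
  per-line lists joined on the BED name column.
* Syndrome regions: BED3 plus two extra columns (comma-separated applicable
  variant types and a disorder label).
* Patient metadata TSV: ``patient_id  sex  consanguineous  diagnosis_group``
  plus optional ADOS-2 columns (``ados_sa  ados_rrb  ados_total
  ados_severity``) and ``age_years``.

Every reader rejects malformed rows with errors naming the file and row.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .intervals import ChromosomeTable, GenomicInterval, IntervalError

__all__ = [
    "FormatError",
    "VariantType",
    "CnvCall",
    "AdosScores",
    "Patient",
    "GeneModel",
    "SyndromeRegion",
    "ControlCohort",
    "TYPE_ALIASES",
    "read_cnv_table",
    "write_cnv_table",
    "write_cnv_bed",
    "read_gene_models",
    "write_gene_models_bed",
    "read_gene_flags",
    "read_patients",
    "write_patients",
    "read_syndrome_regions",
    "write_syndrome_regions",
]

log = logging.getLogger("cnvland")


class FormatError(ValueError):
    """Malformed input file; message carries file path and row number."""


class VariantType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    LOH = "LOH"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: opt-in aliases for platforms that export GAIN/LOSS tokens
TYPE_ALIASES: Mapping[str, str] = {"GAIN": "DUP", "LOSS": "DEL"}


@dataclass(frozen=True)
class CnvCall:
    """One per-sample variant call (deletion, duplication or LOH run)."""

    sample_id: str
    interval: GenomicInterval
    vtype: VariantType
    copy_number: Optional[int] = None
    source_tag: Optional[str] = None

    @property
    def length(self) -> int:
        return self.interval.length

    def key(self) -> tuple:
        """Identity key used to join calls with planted-truth records."""
        return (
            self.sample_id,
            self.interval.chrom,
            self.interval.start,
            self.interval.end,
            self.vtype,
        )


@dataclass(frozen=True)
class AdosScores:
    """ADOS-2 scores: social affect, restricted/repetitive behaviour, total, severity."""

    social_affect: float
    rrb: float
    total: float
    severity: float

    def __post_init__(self) -> None:
        for name in ("social_affect", "rrb", "total", "severity"):
            if getattr(self, name) < 0:
                raise FormatError(f"ADOS {name} must be non-negative")


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: str  # "male" | "female"
    consanguineous: Optional[bool] = None
    diagnosis_group: tuple[str, ...] = ()
    ados: Optional[AdosScores] = None
    age_years: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise FormatError(f"sex must be male/female, got {self.sex!r}")


@dataclass(frozen=True)
class GeneModel:
    """Exon-resolved gene record with optional constraint/imprinting flags."""

    gene_id: str
    symbol: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.exons:
            raise FormatError(f"{self.symbol}: gene model needs at least one exon")
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.span.chrom:
                raise FormatError(f"{self.symbol}: exon off-chromosome")
            if exon.start < self.span.start or exon.end > self.span.end:
                raise FormatError(f"{self.symbol}: exon {exon} outside span {self.span}")
            if prev_end is not None and exon.start < prev_end:
                raise FormatError(f"{self.symbol}: exons overlap or are unsorted")
            prev_end = exon.end

    @property
    def is_ceg(self) -> bool:
        return "CEG" in self.flags

    @property
    def is_imprinted(self) -> bool:
        return "imprinted" in self.flags

    @property
    def is_dosage_sensitive(self) -> bool:
        return "dosage_sensitive" in self.flags


@dataclass(frozen=True)
class SyndromeRegion:
    """Curated genomic region whose disruption defines a known syndrome."""

    name: str
    interval: GenomicInterval
    applicable_types: frozenset[VariantType]
    disorder_label: str = ""

    def __post_init__(self) -> None:
        if not self.applicable_types:
            raise FormatError(f"{self.name}: applicable_types must be non-empty")
        if VariantType.LOH in self.applicable_types:
            raise FormatError(f"{self.name}: syndrome regions apply to DEL/DUP only")


class ControlCohort:
    """A population control call set, indexed by (chromosome, variant type).

    ``n_samples`` is the number of genotyped control individuals, which is the
    denominator of every control frequency; it is typically much larger than
    the number of distinct samples contributing calls.
    """

    def __init__(self, n_samples: int, calls: Sequence[CnvCall]):
        if n_samples <= 0:
            raise ValueError(f"control cohort needs n_samples > 0, got {n_samples}")
        self.n_samples = int(n_samples)
        self.calls = tuple(calls)

    @cached_property
    def index(self) -> dict[tuple[str, VariantType], IntervalTree]:
        trees: dict[tuple[str, VariantType], IntervalTree] = {}
        for call in self.calls:
            key = (call.interval.chrom, call.vtype)
            trees.setdefault(key, IntervalTree()).addi(
                call.interval.start, call.interval.end, call
            )
        return trees


# ---------------------------------------------------------------------------
# CNV call tables


_CALL_COLUMNS = ("sample_id", "chrom", "start", "end", "type", "copy_number")


def read_cnv_table(
    path,
    namespace: str = "",
    aliases: Optional[Mapping[str, str]] = None,
    chroms: Optional[ChromosomeTable] = None,
) -> list[CnvCall]:
    """Parse the project call TSV, returning calls in file order.

    ``namespace`` is prefixed to sample ids (used to keep control sample ids
    distinct from patient ids).  ``aliases`` optionally maps foreign type
    tokens (e.g. GAIN/LOSS) onto DEL/DUP; parsing is strict by default.
    """
    path = Path(path)
    calls: list[CnvCall] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        missing = [c for c in _CALL_COLUMNS[:5] if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        for rowno, row in enumerate(reader, start=2):
            try:
                token = row["type"].strip()
                if aliases and token in aliases:
                    token = aliases[token]
                try:
                    vtype = VariantType(token)
                except ValueError:
                    raise FormatError(f"unknown variant type token {token!r}")
                interval = GenomicInterval(
                    row["chrom"].strip(),
                    int(row["start"].replace(",", "")),
                    int(row["end"].replace(",", "")),
                )
                if chroms is not None:
                    interval.validate_against(chroms)
                cn_text = (row.get("copy_number") or "").strip()
                copy_number = int(cn_text) if cn_text else None
                sample = row["sample_id"].strip()
                if not sample:
                    raise FormatError("empty sample_id")
                calls.append(
                    CnvCall(
                        sample_id=namespace + sample,
                        interval=interval,
                        vtype=vtype,
                        copy_number=copy_number,
                    )
                )
            except (FormatError, IntervalError, ValueError) as exc:
                raise FormatError(f"{path}: row {rowno}: {exc}") from exc
    log.info("read %d calls from %s", len(calls), path)
    return calls


def write_cnv_table(calls: Iterable[CnvCall], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for call in calls:
            cn = "" if call.copy_number is None else str(call.copy_number)
            fh.write(
                f"{call.sample_id}\t{call.interval.chrom}\t{call.interval.start}"
                f"\t{call.interval.end}\t{call.vtype.value}\t{cn}\n"
            )


def write_cnv_bed(calls: Iterable[CnvCall], path) -> None:
    """BED export: 0-based half-open, name = sample_id|type."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for call in calls:
            fh.write(
                f"{call.interval.chrom}\t{call.interval.start - 1}"
                f"\t{call.interval.end - 1}\t{call.sample_id}|{call.vtype.value}\n"
            )


# ---------------------------------------------------------------------------
# Gene models (BED12 + flag lists)


def read_gene_flags(path) -> frozenset[str]:
    """One gene symbol per line; '#' starts a comment."""
    symbols = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.add(line)
    return frozenset(symbols)


def read_gene_models(
    bed12_path,
    flag_files: Optional[Mapping[str, object]] = None,
) -> list[GeneModel]:
    """Read BED12 gene models; attach flags by joining flat symbol lists.

    ``flag_files`` maps a flag name (``CEG``, ``imprinted``,
    ``dosage_sensitive``) to a path of a one-symbol-per-line file.
    """
    flags_by_symbol: dict[str, set[str]] = {}
    for flag, fpath in (flag_files or {}).items():
        for symbol in read_gene_flags(fpath):
            flags_by_symbol.setdefault(symbol, set()).add(flag)

    genes: list[GeneModel] = []
    bed12_path = Path(bed12_path)
    with bed12_path.open(encoding="utf-8") as fh:
        for rowno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\r\n").split("\t")
            if len(parts) < 12:
                raise FormatError(f"{bed12_path}: row {rowno}: BED12 needs 12 columns")
            try:
                chrom = parts[0]
                chrom_start = int(parts[1])
                chrom_end = int(parts[2])
                name = parts[3]
                block_count = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
                if len(sizes) != block_count or len(starts) != block_count:
                    raise FormatError("block count disagrees with block lists")
                span = GenomicInterval(chrom, chrom_start + 1, chrom_end + 1)
                exons = []
                for bstart, bsize in zip(starts, sizes):
                    estart = chrom_start + bstart + 1
                    exons.append(GenomicInterval(chrom, estart, estart + bsize))
                if starts[0] != 0 or starts[-1] + sizes[-1] != chrom_end - chrom_start:
                    raise FormatError("exon blocks do not tile to the gene span")
                genes.append(
                    GeneModel(
                        gene_id=name,
                        symbol=name,
                        span=span,
                        exons=tuple(exons),
                        flags=frozenset(flags_by_symbol.get(name, ())),
                    )
                )
            except (FormatError, IntervalError, ValueError) as exc:
                raise FormatError(f"{bed12_path}: row {rowno}: {exc}") from exc
    log.info("read %d gene models from %s", len(genes), bed12_path)
    return genes


def write_gene_models_bed(genes: Iterable[GeneModel], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for g in genes:
            cs = g.span.start - 1
            ce = g.span.end - 1
            sizes = ",".join(str(e.length) for e in g.exons)
            starts = ",".join(str(e.start - 1 - cs) for e in g.exons)
            fh.write(
                f"{g.span.chrom}\t{cs}\t{ce}\t{g.symbol}\t0\t+\t{cs}\t{ce}\t0\t"
                f"{len(g.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# Patients


_BOOL_TOKENS = {"yes": True, "no": False, "na": None, "": None}


def read_patients(path) -> list[Patient]:
    path = Path(path)
    patients: list[Patient] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "patient_id" not in reader.fieldnames:
            raise FormatError(f"{path}: missing patient_id column")
        for rowno, row in enumerate(reader, start=2):
            try:
                pid = row["patient_id"].strip()
                if pid in seen:
                    raise FormatError(f"duplicate patient_id {pid!r}")
                seen.add(pid)
                cons_text = (row.get("consanguineous") or "").strip().lower()
                if cons_text not in _BOOL_TOKENS:
                    raise FormatError(f"bad consanguineous token {cons_text!r}")
                diag = tuple(
                    t.strip()
                    for t in (row.get("diagnosis_group") or "").split(",")
                    if t.strip()
                )
                ados_fields = [
                    (row.get(c) or "").strip()
                    for c in ("ados_sa", "ados_rrb", "ados_total", "ados_severity")
                ]
                ados = None
                if all(ados_fields):
                    ados = AdosScores(*(float(x) for x in ados_fields))
                elif any(ados_fields):
                    raise FormatError("partial ADOS record; need all four scores")
                age_text = (row.get("age_years") or "").strip()
                patients.append(
                    Patient(
                        patient_id=pid,
                        sex=row["sex"].strip().lower(),
                        consanguineous=_BOOL_TOKENS[cons_text],
                        diagnosis_group=diag,
                        ados=ados,
                        age_years=float(age_text) if age_text else None,
                    )
                )
            except (FormatError, ValueError) as exc:
                raise FormatError(f"{path}: row {rowno}: {exc}") from exc
    return patients


def write_patients(patients: Iterable[Patient], path) -> None:
    cols = (
        "patient_id\tsex\tconsanguineous\tdiagnosis_group"
        "\tados_sa\tados_rrb\tados_total\tados_severity\tage_years"
    )
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(cols + "\n")
        for p in patients:
            cons = {True: "yes", False: "no", None: "NA"}[p.consanguineous]
            diag = ",".join(p.diagnosis_group)
            if p.ados is not None:
                ados = (
                    f"{p.ados.social_affect:g}\t{p.ados.rrb:g}"
                    f"\t{p.ados.total:g}\t{p.ados.severity:g}"
                )
            else:
                ados = "\t\t\t"
            age = f"{p.age_years:g}" if p.age_years is not None else ""
            fh.write(f"{p.patient_id}\t{p.sex}\t{cons}\t{diag}\t{ados}\t{age}\n")


# ---------------------------------------------------------------------------
# Syndrome regions (BED + applicable types + disorder label)


def read_syndrome_regions(path) -> list[SyndromeRegion]:
    path = Path(path)
    regions: list[SyndromeRegion] = []
    with path.open(encoding="utf-8") as fh:
        for rowno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\r\n").split("\t")
            if len(parts) < 6:
                raise FormatError(
                    f"{path}: row {rowno}: need chrom,start,end,name,types,label"
                )
            try:
                interval = GenomicInterval(parts[0], int(parts[1]) + 1, int(parts[2]) + 1)
                types = frozenset(
                    VariantType(t.strip()) for t in parts[4].split(",") if t.strip()
                )
                regions.append(
                    SyndromeRegion(
                        name=parts[3],
                        interval=interval,
                        applicable_types=types,
                        disorder_label=parts[5],
                    )
                )
            except (FormatError, IntervalError, ValueError) as exc:
                raise FormatError(f"{path}: row {rowno}: {exc}") from exc
    return regions


def write_syndrome_regions(regions: Iterable[SyndromeRegion], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for r in regions:
            types = ",".join(sorted(t.value for t in r.applicable_types))
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start - 1}\t{r.interval.end - 1}"
                f"\t{r.name}\t{types}\t{r.disorder_label}\n"
            )
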
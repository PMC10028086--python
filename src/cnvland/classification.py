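"""Deterministic evidence-rule classification of frequency-annotated calls.

Clinical CNV interpretation weighs variant type, size, location, gene content
and population frequency.  The full ACMG/ClinGen point system depends on
curated databases and expert judgement; this module implements a transparent,
auditable surrogate: a fixed rule cascade over locally supplied annotation
tables, with every decision recorded as an evidence code.  First match wins:

1. not rare                                      -> benign   [COMMON_VARIANT]
2. rare, reciprocal overlap > threshold with a syndrome region applicable to
   the call's type                               -> pathogenic [SYNDROME_REGION_MATCH]
3. rare deletion fully containing >=1 dosage-sensitive gene
                                                 -> pathogenic [DOSAGE_GENE_HIT]
4. rare LOH                                      -> VOUS     [LOH_EVENT]
   (+ IMPRINTED_GENE_HIT appended when imprinted genes are exonically hit)
5. rare call hitting >=1 gene exon               -> VOUS     [GENE_CONTENT]
6. rare call hitting no exon                     -> benign   [NO_GENE_CONTENT]
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .filtering import FrequencyAnnotatedCall
from .gene_analysis import GeneIndex
from .intervals import (
    ChromosomeTable,
    GenomicInterval,
    is_subtelomeric,
    reciprocal_overlap,
    round_half_up,
)
from .io_formats import GeneModel, Patient, SyndromeRegion, VariantType

__all__ = [
    "PATHOGENIC",
    "VOUS",
    "BENIGN",
    "Evidence",
    "ClassifyConfig",
    "AnnotationBundle",
    "ClassifiedCall",
    "classify_call",
    "classify_all",
    "CohortSummary",
    "summarize_cohort",
    "size_histogram",
]

log = logging.getLogger("cnvland")

PATHOGENIC = "pathogenic"
VOUS = "VOUS"
BENIGN = "benign"


class Evidence:
    COMMON_VARIANT = "COMMON_VARIANT"
    SYNDROME_REGION_MATCH = "SYNDROME_REGION_MATCH"
    DOSAGE_GENE_HIT = "DOSAGE_GENE_HIT"
    LOH_EVENT = "LOH_EVENT"
    IMPRINTED_GENE_HIT = "IMPRINTED_GENE_HIT"
    GENE_CONTENT = "GENE_CONTENT"
    NO_GENE_CONTENT = "NO_GENE_CONTENT"


@dataclass(frozen=True)
class ClassifyConfig:
    ro_threshold: float = 0.5
    subtelomere_window: int = 5_000_000

    def __post_init__(self) -> None:
        if not 0 < self.ro_threshold < 1:
            raise ValueError("ro_threshold must be in (0, 1)")
        if self.subtelomere_window < 0:
            raise ValueError("subtelomere_window must be >= 0")


@dataclass(frozen=True)
class AnnotationBundle:
    """Locally supplied annotation: syndrome regions + exon-resolved genes."""

    syndrome_regions: tuple[SyndromeRegion, ...]
    gene_index: GeneIndex
    chrom_table: ChromosomeTable

    @classmethod
    def build(
        cls,
        syndrome_regions: Iterable[SyndromeRegion],
        genes: Iterable[GeneModel],
        chrom_table: ChromosomeTable,
    ) -> "AnnotationBundle":
        return cls(
            syndrome_regions=tuple(syndrome_regions),
            gene_index=GeneIndex(genes),
            chrom_table=chrom_table,
        )


@dataclass(frozen=True)
class ClassifiedCall:
    annotated: FrequencyAnnotatedCall
    label: str
    evidence: tuple[str, ...]
    subtelomeric: bool
    genes_hit: tuple[str, ...]
    ceg_count: int
    matched_region: Optional[str] = None

    @property
    def sample_id(self) -> str:
        return self.annotated.sample_id

    @property
    def interval(self) -> GenomicInterval:
        return self.annotated.interval

    @property
    def vtype(self) -> VariantType:
        return self.annotated.vtype

    @property
    def is_rare(self) -> bool:
        return self.annotated.is_rare


def classify_call(
    annotated: FrequencyAnnotatedCall,
    bundle: AnnotationBundle,
    cfg: ClassifyConfig = ClassifyConfig(),
) -> ClassifiedCall:
    """Apply the rule cascade to one frequency-annotated call."""
    if bundle is None:
        raise ValueError("annotation bundle is required")
    iv = annotated.interval
    exon_genes = bundle.gene_index.exon_hits(iv)
    genes_hit = tuple(sorted(g.symbol for g in exon_genes))
    ceg_count = sum(1 for g in exon_genes if g.is_ceg)
    subtel = is_subtelomeric(iv, bundle.chrom_table, cfg.subtelomere_window)

    def result(label: str, *evidence: str, region: Optional[str] = None) -> ClassifiedCall:
        return ClassifiedCall(
            annotated=annotated,
            label=label,
            evidence=tuple(evidence),
            subtelomeric=subtel,
            genes_hit=genes_hit,
            ceg_count=ceg_count,
            matched_region=region,
        )

    # 1. common variants are benign irrespective of content
    if not annotated.is_rare:
        return result(BENIGN, Evidence.COMMON_VARIANT)

    # 2. reciprocal-overlap match to a type-applicable syndrome region
    for region in bundle.syndrome_regions:
        if annotated.vtype not in region.applicable_types:
            continue
        if reciprocal_overlap(iv, region.interval) > cfg.ro_threshold:
            return result(
                PATHOGENIC, Evidence.SYNDROME_REGION_MATCH, region=region.name
            )

    # 3. deletion removing a whole dosage-sensitive gene
    if annotated.vtype is VariantType.DEL:
        contained = [
            g for g in bundle.gene_index.span_hits(iv)
            if g.is_dosage_sensitive and iv.contains(g.span)
        ]
        if contained:
            return result(PATHOGENIC, Evidence.DOSAGE_GENE_HIT)

    # 4. rare LOH: uncertain significance; flag imprinted-gene overlap
    if annotated.vtype is VariantType.LOH:
        imprinted = any(g.is_imprinted for g in exon_genes)
        if imprinted:
            return result(VOUS, Evidence.LOH_EVENT, Evidence.IMPRINTED_GENE_HIT)
        return result(VOUS, Evidence.LOH_EVENT)

    # 5./6. gene content decides between VOUS and benign
    if genes_hit:
        return result(VOUS, Evidence.GENE_CONTENT)
    return result(BENIGN, Evidence.NO_GENE_CONTENT)


def classify_all(
    annotated_calls: Sequence[FrequencyAnnotatedCall],
    bundle: AnnotationBundle,
    cfg: ClassifyConfig = ClassifyConfig(),
) -> list[ClassifiedCall]:
    out = [classify_call(a, bundle, cfg) for a in annotated_calls]
    counts = {label: sum(c.label == label for c in out)
              for label in (PATHOGENIC, VOUS, BENIGN)}
    log.info("classified %d calls: %s", len(out), counts)
    return out


# ---------------------------------------------------------------------------
# Cohort summary


LABELS = (PATHOGENIC, VOUS, BENIGN)


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    n_calls: int
    class_counts: dict[str, int]
    class_percent: dict[str, float]
    carriers: dict[str, tuple[str, ...]]
    yield_percent: dict[str, float]
    subtelomeric_carriers: dict[str, tuple[str, ...]]
    subtelomeric_yield_percent: dict[str, float]
    size_stats: pd.DataFrame  # label, type, n, mean_bp, median_bp

    def class_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(LABELS),
                "n_calls": [self.class_counts[l] for l in LABELS],
                "percent": [self.class_percent[l] for l in LABELS],
                "n_carriers": [len(self.carriers[l]) for l in LABELS],
                "yield_percent": [self.yield_percent[l] for l in LABELS],
            }
        )


def summarize_cohort(
    classified: Sequence[ClassifiedCall],
    patients: Sequence[Patient],
    chroms: ChromosomeTable,
    cfg: ClassifyConfig = ClassifyConfig(),
) -> CohortSummary:
    """Cohort accounting: per-class call counts/percentages, per-patient yield
    (a patient counts once per class when carrying >=1 call of that class),
    subtelomeric yield and per-class/per-type size statistics.

    Percentages are reported to two decimals, ties rounded half up.
    """
    patient_ids = {p.patient_id for p in patients}
    for call in classified:
        if call.sample_id not in patient_ids:
            raise ValueError(f"call sample {call.sample_id!r} is not a cohort patient")

    n_calls = len(classified)
    class_counts = {l: 0 for l in LABELS}
    carriers: dict[str, set[str]] = {l: set() for l in LABELS}
    subtel_carriers: dict[str, set[str]] = {l: set() for l in LABELS}
    size_rows: dict[tuple[str, VariantType], list[int]] = defaultdict(list)

    for call in classified:
        class_counts[call.label] += 1
        carriers[call.label].add(call.sample_id)
        if call.subtelomeric:
            subtel_carriers[call.label].add(call.sample_id)
        size_rows[(call.label, call.vtype)].append(call.interval.length)

    def pct(num: int, den: int) -> float:
        return round_half_up(100.0 * num / den, 2) if den else 0.0

    n_patients = len(patients)
    size_stats = pd.DataFrame(
        [
            {
                "label": label,
                "type": vtype.value,
                "n": len(sizes),
                "mean_bp": float(np.mean(sizes)),
                "median_bp": float(np.median(sizes)),
            }
            for (label, vtype), sizes in sorted(
                size_rows.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
            )
        ],
        columns=["label", "type", "n", "mean_bp", "median_bp"],
    )
    return CohortSummary(
        n_patients=n_patients,
        n_calls=n_calls,
        class_counts=class_counts,
        class_percent={l: pct(class_counts[l], n_calls) for l in LABELS},
        carriers={l: tuple(sorted(carriers[l])) for l in LABELS},
        yield_percent={l: pct(len(carriers[l]), n_patients) for l in LABELS},
        subtelomeric_carriers={l: tuple(sorted(subtel_carriers[l])) for l in LABELS},
        subtelomeric_yield_percent={
            l: pct(len(subtel_carriers[l]), n_patients) for l in LABELS
        },
        size_stats=size_stats,
    )


def size_histogram(
    classified: Sequence[ClassifiedCall],
    bins: Sequence[tuple[float, float]],
) -> pd.DataFrame:
    """Counts per (label, type, bin); bins are half-open [lo, hi) in bp.

    ``hi`` may be ``float('inf')`` for an open last bin.  Bins must be
    ascending and non-overlapping; gaps are allowed but calls falling into a
    gap are not counted (the returned frame carries an ``unbinned`` column
    total so conservation can be checked).
    """
    if not bins:
        raise ValueError("need at least one bin")
    prev_hi = -float("inf")
    for lo, hi in bins:
        if hi <= lo:
            raise ValueError(f"bin ({lo}, {hi}) is empty or reversed")
        if lo < prev_hi:
            raise ValueError("bins overlap")
        prev_hi = hi

    def bin_of(size: int) -> Optional[int]:
        for i, (lo, hi) in enumerate(bins):
            if lo <= size < hi:
                return i
        return None

    counts: dict[tuple[str, str], list[int]] = defaultdict(lambda: [0] * len(bins))
    unbinned: dict[tuple[str, str], int] = defaultdict(int)
    for call in classified:
        key = (call.label, call.vtype.value)
        i = bin_of(call.interval.length)
        if i is None:
            unbinned[key] += 1
        else:
            counts[key][i] += 1

    rows = []
    for key in sorted(set(counts) | set(unbinned)):
        row = {"label": key[0], "type": key[1]}
        for i, (lo, hi) in enumerate(bins):
            hi_text = "inf" if hi == float("inf") else f"{int(hi)}"
            row[f"bin_{int(lo)}_{hi_text}"] = counts[key][i]
        row["unbinned"] = unbinned[key]
        rows.append(row)
    return pd.DataFrame(rows)
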
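"""Exon-aware gene disruption, CEG burden, focal candidates, shared minimal
critical regions and LOH-specific analyses.

A gene is *disrupted* by a variant when the variant overlaps at least one base
of at least one exon.  Intron-only overlap does not count: constraint metrics
such as the critical-exon-gene (CEG) score are exon-level, and variants that
spare every exon of a gene leave its transcripts intact, so candidate-gene
counting excludes them.  Span-level overlap remains available
(``exon_aware=False``) for descriptive gene counts.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, minimal_critical_region, overlap_length
from .io_formats import CnvCall, GeneModel, Patient, VariantType
from .statistics import WelchResult, welch_t

__all__ = [
    "GeneIndex",
    "GeneHit",
    "genes_disrupted",
    "CegBurden",
    "ceg_burden",
    "focal_candidates",
    "SharedRegion",
    "shared_critical_regions",
    "LohBurden",
    "LohComparison",
    "loh_consanguinity_burden",
    "ImprintedLohRow",
    "imprinted_loh",
]

log = logging.getLogger("cnvland")


class GeneIndex:
    """Chromosome-indexed gene spans and exons for fast overlap queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = tuple(genes)
        self._span: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._exon: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for gene in self.genes:
            self._span[gene.span.chrom].addi(gene.span.start, gene.span.end, gene)
            for exon in gene.exons:
                self._exon[exon.chrom].addi(exon.start, exon.end, gene)

    def span_hits(self, iv: GenomicInterval) -> set[GeneModel]:
        tree = self._span.get(iv.chrom)
        if tree is None:
            return set()
        return {h.data for h in tree.overlap(iv.start, iv.end)}

    def exon_hits(self, iv: GenomicInterval) -> set[GeneModel]:
        tree = self._exon.get(iv.chrom)
        if tree is None:
            return set()
        return {h.data for h in tree.overlap(iv.start, iv.end)}


@dataclass(frozen=True)
class GeneHit:
    """One (gene, variant) disruption record."""

    gene: GeneModel
    call: object  # CnvCall or ClassifiedCall
    exonic: bool
    fully_contained: bool


def _call_interval(call) -> GenomicInterval:
    return call.interval


def genes_disrupted(call, index: GeneIndex, exon_aware: bool = True) -> list[GeneHit]:
    """Genes hit by ``call``; exon-aware mode requires >=1 bp of exon overlap."""
    iv = _call_interval(call)
    exonic = index.exon_hits(iv)
    candidates = exonic if exon_aware else index.span_hits(iv)
    hits = [
        GeneHit(
            gene=g,
            call=call,
            exonic=g in exonic,
            fully_contained=iv.contains(g.span),
        )
        for g in candidates
    ]
    hits.sort(key=lambda h: (h.gene.span.start, h.gene.symbol))
    return hits


# ---------------------------------------------------------------------------
# CEG burden


@dataclass(frozen=True)
class CegClassRow:
    label: str
    n_calls: int
    total_ceg_hits: int
    unique_cegs: int
    mean_per_call: float


@dataclass(frozen=True)
class CegBurden:
    per_call: tuple[tuple[object, int], ...]
    per_class: dict[str, CegClassRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": r.label,
                    "n_calls": r.n_calls,
                    "total_ceg_hits": r.total_ceg_hits,
                    "unique_cegs": r.unique_cegs,
                    "mean_per_call": r.mean_per_call,
                }
                for r in self.per_class.values()
            ]
        )


def ceg_burden(classified_calls: Sequence, index: GeneIndex) -> CegBurden:
    """Per-call distinct exonically-hit CEG counts and per-class summaries.

    Only DEL/DUP calls enter the burden (CEG burden is a copy-number dosage
    metric; LOH runs do not change dosage).
    """
    per_call: list[tuple[object, int]] = []
    by_class: dict[str, list[tuple[object, set[str]]]] = defaultdict(list)
    for call in classified_calls:
        if call.vtype is VariantType.LOH:
            continue
        cegs = {g.symbol for g in index.exon_hits(call.interval) if g.is_ceg}
        per_call.append((call, len(cegs)))
        by_class[call.label].append((call, cegs))
    per_class: dict[str, CegClassRow] = {}
    for label, rows in by_class.items():
        total = sum(len(c) for _, c in rows)
        unique = set().union(*(c for _, c in rows)) if rows else set()
        per_class[label] = CegClassRow(
            label=label,
            n_calls=len(rows),
            total_ceg_hits=total,
            unique_cegs=len(unique),
            mean_per_call=total / len(rows) if rows else float("nan"),
        )
    return CegBurden(per_call=tuple(per_call), per_class=per_class)


def focal_candidates(
    classified_calls: Sequence,
    index: GeneIndex,
    max_size: int = 1_000_000,
) -> pd.DataFrame:
    """Pathogenic/VOUS DEL/DUP calls < ``max_size`` bp with >=1 exonic CEG.

    Short focal variants hitting a constrained gene are the strongest
    single-gene candidates; the table is sorted by size ascending.
    """
    rows = []
    for call in classified_calls:
        if call.vtype is VariantType.LOH or call.label not in ("pathogenic", "VOUS"):
            continue
        if call.interval.length >= max_size:
            continue
        cegs = sorted(
            g.symbol for g in index.exon_hits(call.interval) if g.is_ceg
        )
        if not cegs:
            continue
        rows.append(
            {
                "sample_id": call.sample_id,
                "chrom": call.interval.chrom,
                "start": call.interval.start,
                "end": call.interval.end,
                "type": call.vtype.value,
                "label": call.label,
                "size_bp": call.interval.length,
                "ceg_symbols": ",".join(cegs),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "chrom", "start", "end", "type",
            "label", "size_bp", "ceg_symbols",
        ],
    )
    return frame.sort_values(
        ["size_bp", "sample_id", "chrom", "start"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Shared minimal critical regions


@dataclass(frozen=True)
class SharedRegion:
    region: GenomicInterval
    vtype: VariantType
    patients: tuple[str, ...]
    calls: tuple
    genes: tuple[str, ...]


def _maximal_cover_sets(items: Sequence) -> list[tuple]:
    """Maximal sets of mutually-intersecting intervals on one chromosome.

    For 1-D intervals pairwise intersection implies a common point (Helly),
    so the maximal mutually-overlapping groups are the cover sets of the
    elementary segments between breakpoints, pruned to maximal ones.
    """
    points = sorted({p for it in items for p in (it.interval.start, it.interval.end)})
    cover_sets: list[frozenset[int]] = []
    for lo, hi in zip(points, points[1:]):
        active = frozenset(
            i for i, it in enumerate(items)
            if it.interval.start <= lo and it.interval.end >= hi
        )
        if active:
            cover_sets.append(active)
    uniq = sorted(set(cover_sets), key=lambda s: (-len(s), sorted(s)))
    maximal: list[frozenset[int]] = []
    for s in uniq:
        if not any(s < m for m in maximal):
            maximal.append(s)
    return [tuple(items[i] for i in sorted(s)) for s in maximal]


def shared_critical_regions(
    classified_calls: Sequence,
    min_patients: int = 2,
    gene_index: Optional[GeneIndex] = None,
) -> list[SharedRegion]:
    """Minimal critical regions shared by >= ``min_patients`` distinct patients.

    Calls are grouped by chromosome and variant type; a group is a maximal set
    of mutually-intersecting calls, and only groups contributed by enough
    distinct patients are reported (several overlapping calls from a single
    patient do not form a group).  The region is the intersection of all
    member calls; reported genes are those with exonic overlap inside it.
    """
    by_key: dict[tuple[str, VariantType], list] = defaultdict(list)
    for call in classified_calls:
        by_key[(call.interval.chrom, call.vtype)].append(call)

    regions: list[SharedRegion] = []
    for (chrom, vtype), group_calls in sorted(
        by_key.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        for members in _maximal_cover_sets(group_calls):
            patients = sorted({c.sample_id for c in members})
            if len(patients) < min_patients:
                continue
            region = minimal_critical_region([c.interval for c in members])
            if region is None:  # pragma: no cover - mutual overlap guarantees it
                continue
            genes: tuple[str, ...] = ()
            if gene_index is not None:
                genes = tuple(sorted(g.symbol for g in gene_index.exon_hits(region)))
            regions.append(
                SharedRegion(
                    region=region,
                    vtype=vtype,
                    patients=tuple(patients),
                    calls=tuple(members),
                    genes=genes,
                )
            )
    regions.sort(key=lambda r: (r.region.chrom, r.region.start, r.vtype.value))
    return regions


# ---------------------------------------------------------------------------
# LOH analyses


@dataclass(frozen=True)
class LohBurden:
    group: str
    n_patients: int
    mean_count: float
    mean_length_bp: float
    per_patient_counts: dict[str, int]


@dataclass(frozen=True)
class LohComparison:
    consanguineous: LohBurden
    non_consanguineous: LohBurden
    welch: Optional[WelchResult]
    underpowered: bool
    excluded_unknown: int


def _burden(group: str, patients: Sequence[Patient], calls_by_patient) -> LohBurden:
    counts = {p.patient_id: len(calls_by_patient.get(p.patient_id, ())) for p in patients}
    lengths = [
        c.interval.length
        for p in patients
        for c in calls_by_patient.get(p.patient_id, ())
    ]
    return LohBurden(
        group=group,
        n_patients=len(patients),
        mean_count=float(np.mean(list(counts.values()))) if counts else float("nan"),
        mean_length_bp=float(np.mean(lengths)) if lengths else float("nan"),
        per_patient_counts=counts,
    )


def loh_consanguinity_burden(
    loh_calls: Sequence, patients: Sequence[Patient]
) -> LohComparison:
    """LOH burden (count/patient, mean length) by parental consanguinity.

    Offspring of consanguineous unions carry long runs of homozygosity across
    the genome, so their LOH count per patient and mean run length are
    elevated.  Patients with unknown consanguinity are excluded and counted.
    The per-patient LOH counts of the two groups are compared with Welch's
    t-test when both groups support it; otherwise the comparison is flagged
    underpowered.
    """
    known = [p for p in patients if p.consanguineous is not None]
    unknown = len(patients) - len(known)
    if not known:
        raise ValueError("consanguinity status unknown for every patient")
    if unknown:
        log.info("LOH burden: excluded %d patients with unknown consanguinity", unknown)
    cons = [p for p in known if p.consanguineous]
    outbred = [p for p in known if not p.consanguineous]

    calls_by_patient: dict[str, list] = defaultdict(list)
    known_ids = {p.patient_id for p in known}
    for call in loh_calls:
        if call.vtype is VariantType.LOH and call.sample_id in known_ids:
            calls_by_patient[call.sample_id].append(call)

    b_cons = _burden("consanguineous", cons, calls_by_patient)
    b_out = _burden("non_consanguineous", outbred, calls_by_patient)

    welch = None
    underpowered = True
    x = list(b_cons.per_patient_counts.values())
    y = list(b_out.per_patient_counts.values())
    if len(x) >= 2 and len(y) >= 2 and np.var(x) > 0 and np.var(y) > 0:
        welch = welch_t(x, y)
        underpowered = False
    return LohComparison(
        consanguineous=b_cons,
        non_consanguineous=b_out,
        welch=welch,
        underpowered=underpowered,
        excluded_unknown=unknown,
    )


@dataclass(frozen=True)
class ImprintedLohRow:
    call: object
    genes: tuple[str, ...]


def imprinted_loh(loh_calls: Sequence, index: GeneIndex) -> tuple[list[ImprintedLohRow], frozenset[str]]:
    """LOH calls exonically hitting >=1 imprinted gene, plus the gene union.

    An extended homozygous run over an imprinted locus is compatible with
    uniparental disomy, which can silence the sole expressed allele; such
    calls are flagged for follow-up (the classifier gives them VOUS status
    with imprinted-gene evidence).
    """
    rows: list[ImprintedLohRow] = []
    union: set[str] = set()
    for call in loh_calls:
        if call.vtype is not VariantType.LOH:
            continue
        genes = sorted(
            g.symbol for g in index.exon_hits(call.interval) if g.is_imprinted
        )
        if genes:
            rows.append(ImprintedLohRow(call=call, genes=tuple(genes)))
            union.update(genes)
    return rows, frozenset(union)
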
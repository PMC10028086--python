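"""Seeded synthetic-cohort generator.

Emulates the structure of a clinical chromosomal-microarray cohort so that
every pipeline stage is testable without any data download: a 212-patient
neurodevelopmental-disorder cohort (male:female about 2.2:1, consanguinity
status known for roughly half the families), a scaled-down population control
cohort, a toy genome with exon-resolved gene models carrying CEG / imprinted /
dosage-sensitivity flags, a syndrome-region catalogue, and per-patient
CNV/LOH call sets with planted ground truth:

* pathogenic calls are planted as >50%-reciprocal-overlap matches to syndrome
  regions, or as deletions fully containing a dosage-sensitive gene;
* common calls are drawn from catalogue loci replicated into >1% of control
  samples (and of patients), so frequency annotation marks them common;
* VOUS calls are rare exon-hitting variants planted in a configured number of
  carrier patients;
* LOH counts per patient follow a Poisson law whose mean is elevated for
  children of consanguineous parents; most LOH is drawn from a common
  run-of-homozygosity pool, and rare LOH (a slice of the VOUS carriers')
  optionally covers imprinted genes;
* duplication carriers' ADOS-2 social-affect and severity scores are shifted
  by a configured effect.

Every placement of a rare planted call is rejection-sampled so that it does
not reciprocally match a syndrome region (unless it is the planted pathogenic
mechanism), a common-catalogue locus, or more than one other rare planted
call — this keeps planted rare calls rare and planted labels recoverable.

A single integer seed drives one named substream per component, so adding a
component never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .intervals import ChromosomeTable, GenomicInterval, reciprocal_overlap
from .io_formats import (
    AdosScores,
    CnvCall,
    ControlCohort,
    GeneModel,
    Patient,
    SyndromeRegion,
    VariantType,
)

__all__ = [
    "SizeModel",
    "GenomeConfig",
    "SyntheticConfig",
    "TruthRecord",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate",
    "generate_gene_models",
]

_STREAMS = {
    "genome": 0,
    "catalogue": 1,
    "patients": 2,
    "pathogenic": 3,
    "vous": 4,
    "loh": 5,
    "background": 6,
    "controls": 7,
    "ados": 8,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream])))


@dataclass(frozen=True)
class SizeModel:
    """Truncated log-normal size distribution (bp)."""

    median_bp: float
    sigma: float
    min_bp: float
    max_bp: float

    def __post_init__(self) -> None:
        if not 0 < self.min_bp <= self.median_bp <= self.max_bp:
            raise ValueError(f"inconsistent size model {self}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def draw(self, rng: np.random.Generator) -> int:
        for _ in range(1000):
            size = math.exp(rng.normal(math.log(self.median_bp), self.sigma))
            if self.min_bp <= size <= self.max_bp:
                return int(size)
        return int(min(max(self.median_bp, self.min_bp), self.max_bp))


@dataclass(frozen=True)
class GenomeConfig:
    """Toy genome: a few chromosomes, dense enough to place everything."""

    assembly: str = "toy"
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chr1", 30_000_000),
        ("chr2", 20_000_000),
        ("chr3", 10_000_000),
    )
    n_genes: int = 300
    gene_span: SizeModel = SizeModel(25_000, 0.6, 2_000, 200_000)
    max_exons: int = 8
    ceg_rate: float = 0.15
    imprinted_rate: float = 0.06
    dosage_rate: float = 0.06

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chrom_lengths)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults are the emulated study conditions."""

    seed: int = 0
    n_patients: int = 212
    male_fraction: float = 145 / 212
    known_consanguinity_fraction: float = 109 / 212
    consanguineous_fraction: float = 26 / 109
    n_controls: int = 500
    pathogenic_carrier_count: int = 26
    pathogenic_call_count: int = 27
    vous_carrier_count: int = 121
    loh_rate_consanguineous: float = 12.95
    loh_rate_outbred: float = 1.0
    rare_loh_fraction: float = 0.3
    imprinted_loh_fraction: float = 0.5
    ados_assessed_fraction: float = 95 / 212
    ados_severity_effect: float = 1.5
    ados_social_affect_effect: float = 2.5
    common_calls_rate: float = 3.0
    rare_benign_rate: float = 0.7
    control_background_rate: float = 2.0
    vous_extra_calls_rate: float = 0.4
    genome: GenomeConfig = GenomeConfig()
    n_syndrome_regions: int = 8
    syndrome_size: SizeModel = SizeModel(1_500_000, 0.4, 800_000, 4_000_000)
    n_common_loci: int = 30
    common_size: SizeModel = SizeModel(120_000, 0.6, 60_000, 800_000)
    n_common_roh: int = 25
    roh_size: SizeModel = SizeModel(4_000_000, 0.4, 2_050_000, 9_800_000)
    pathogenic_dosage_size: SizeModel = SizeModel(400_000, 0.5, 60_000, 2_000_000)
    vous_del_size: SizeModel = SizeModel(110_000, 0.7, 32_000, 2_000_000)
    vous_dup_size: SizeModel = SizeModel(300_000, 0.8, 60_000, 3_000_000)
    rare_benign_size: SizeModel = SizeModel(60_000, 0.5, 32_000, 300_000)
    rare_loh_size_consanguineous: SizeModel = SizeModel(6_500_000, 0.25, 2_050_000, 9_800_000)
    rare_loh_size_outbred: SizeModel = SizeModel(3_200_000, 0.35, 2_050_000, 9_800_000)

    def __post_init__(self) -> None:
        for name in (
            "male_fraction", "known_consanguinity_fraction",
            "consanguineous_fraction", "ados_assessed_fraction",
            "rare_loh_fraction", "imprinted_loh_fraction",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.pathogenic_carrier_count > self.n_patients:
            raise ValueError("pathogenic carriers exceed cohort size")
        if self.vous_carrier_count > self.n_patients:
            raise ValueError("VOUS carriers exceed cohort size")
        if self.pathogenic_call_count < self.pathogenic_carrier_count:
            raise ValueError("need at least one pathogenic call per carrier")
        for name in (
            "loh_rate_consanguineous", "loh_rate_outbred", "common_calls_rate",
            "rare_benign_rate", "control_background_rate", "vous_extra_calls_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    chrom: str
    start: int
    end: int
    vtype: VariantType
    label: str
    mechanism: str

    def key(self) -> tuple:
        return (self.sample_id, self.chrom, self.start, self.end, self.vtype)


@dataclass(frozen=True)
class SyntheticTruth:
    calls: tuple[TruthRecord, ...]
    pathogenic_carriers: frozenset[str]
    vous_carriers: frozenset[str]
    dup_carriers: frozenset[str]

    def by_key(self) -> dict[tuple, TruthRecord]:
        return {r.key(): r for r in self.calls}


@dataclass(frozen=True)
class SyntheticDataset:
    config: SyntheticConfig
    chrom_table: ChromosomeTable
    gene_models: tuple[GeneModel, ...]
    syndrome_regions: tuple[SyndromeRegion, ...]
    patients: tuple[Patient, ...]
    case_calls: tuple[CnvCall, ...]
    control_cohort: ControlCohort
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# genome


def generate_gene_models(
    genome: GenomeConfig, rng: np.random.Generator
) -> tuple[GeneModel, ...]:
    """Non-overlapping exon-resolved gene models with configured flag rates.

    Genes are laid left to right per chromosome with exponential gaps; exon
    blocks tile each span end to end (alternating exon/intron segments), so
    the first exon starts at the span start and the last ends at the span end.
    """
    total_span = genome.n_genes * (genome.gene_span.median_bp + 2_000)
    if total_span > 0.8 * genome.total_length:
        raise ValueError(
            f"cannot place {genome.n_genes} genes on a "
            f"{genome.total_length / 1e6:.0f} Mb genome"
        )
    lengths = dict(genome.chrom_lengths)
    per_chrom = {
        chrom: int(round(genome.n_genes * l / genome.total_length))
        for chrom, l in genome.chrom_lengths
    }
    genes: list[GeneModel] = []
    idx = 0
    for chrom, n in per_chrom.items():
        chrom_len = lengths[chrom]
        spans = [genome.gene_span.draw(rng) for _ in range(n)]
        slack = chrom_len - sum(spans) - 1
        if slack <= n:
            raise ValueError(f"gene density infeasible for {chrom}")
        gaps = rng.dirichlet(np.ones(n + 1)) * slack
        pos = 1
        for span_len, gap in zip(spans, gaps[:-1]):
            pos += int(gap)
            start = max(1, pos)
            end = start + span_len
            idx += 1
            genes.append(
                _make_gene(f"G{idx:04d}", chrom, start, end, genome, rng)
            )
            pos = end
    return tuple(genes)


def _make_gene(
    symbol: str, chrom: str, start: int, end: int,
    genome: GenomeConfig, rng: np.random.Generator,
) -> GeneModel:
    span = GenomicInterval(chrom, start, end)
    max_k = max(1, min(genome.max_exons, span.length // 400))
    k = int(rng.integers(1, max_k + 1))
    if k == 1:
        exons = (span,)
    else:
        cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * k - 2, replace=False))
        bounds = [start, *cuts.tolist(), end]
        exons = tuple(
            GenomicInterval(chrom, bounds[2 * i], bounds[2 * i + 1])
            for i in range(k)
        )
    flags = set()
    if rng.random() < genome.ceg_rate:
        flags.add("CEG")
    if rng.random() < genome.imprinted_rate:
        flags.add("imprinted")
    if rng.random() < genome.dosage_rate:
        flags.add("dosage_sensitive")
    return GeneModel(
        gene_id=symbol, symbol=symbol, span=span, exons=exons, flags=frozenset(flags)
    )


def _place_interval(
    rng: np.random.Generator,
    chrom_lengths: Sequence[tuple[str, int]],
    size: int,
) -> Optional[GenomicInterval]:
    weights = np.array([l for _, l in chrom_lengths], dtype=float)
    weights /= weights.sum()
    i = int(rng.choice(len(chrom_lengths), p=weights))
    chrom, chrom_len = chrom_lengths[i]
    if size >= chrom_len:
        return None
    start = int(rng.integers(1, chrom_len - size + 1))
    return GenomicInterval(chrom, start, start + size)


def _matches_any(iv: GenomicInterval, others, threshold: float) -> int:
    return sum(1 for o in others if reciprocal_overlap(iv, o) > threshold)


class _Placer:
    """Rejection sampler keeping planted rare calls rare and truth recoverable."""

    def __init__(self, cfg: SyntheticConfig):
        self.cfg = cfg
        self.chrom_lengths = cfg.genome.chrom_lengths
        self.syndrome_ivs: list[GenomicInterval] = []
        self.common_ivs: list[GenomicInterval] = []
        self.rare_ivs: dict[VariantType, list[GenomicInterval]] = {
            t: [] for t in VariantType
        }

    def ok_rare(self, iv: GenomicInterval, vtype: VariantType,
                allow_syndrome: bool = False) -> bool:
        if not allow_syndrome and _matches_any(iv, self.syndrome_ivs, 0.45):
            return False
        if _matches_any(iv, self.common_ivs, 0.45):
            return False
        # at most one other rare planted call may reciprocally match (2/N stays rare)
        if _matches_any(iv, self.rare_ivs[vtype], 0.5) > 1:
            return False
        return True

    def register_rare(self, iv: GenomicInterval, vtype: VariantType) -> None:
        self.rare_ivs[vtype].append(iv)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dataset; deterministic given ``config.seed``."""
    cfg = config
    genome = cfg.genome
    chrom_table = ChromosomeTable(
        assembly=genome.assembly, lengths=dict(genome.chrom_lengths)
    )
    genes = generate_gene_models(genome, _rng(cfg.seed, "genome"))
    placer = _Placer(cfg)

    # --- annotation catalogues -------------------------------------------
    rng = _rng(cfg.seed, "catalogue")
    syndrome_regions: list[SyndromeRegion] = []
    tries = 0
    while len(syndrome_regions) < cfg.n_syndrome_regions:
        tries += 1
        if tries > 10_000:
            raise ValueError("cannot place syndrome regions; genome too small")
        iv = _place_interval(rng, genome.chrom_lengths, cfg.syndrome_size.draw(rng))
        if iv is None or _matches_any(iv, placer.syndrome_ivs, 0.3):
            continue
        kinds = [
            frozenset({VariantType.DEL}),
            frozenset({VariantType.DUP}),
            frozenset({VariantType.DEL, VariantType.DUP}),
        ]
        types = kinds[int(rng.choice(3, p=[0.4, 0.3, 0.3]))]
        i = len(syndrome_regions) + 1
        syndrome_regions.append(
            SyndromeRegion(
                name=f"SR{i:02d}", interval=iv,
                applicable_types=types, disorder_label=f"syndrome_{i}",
            )
        )
        placer.syndrome_ivs.append(iv)

    common_loci: list[tuple[GenomicInterval, VariantType]] = []
    tries = 0
    while len(common_loci) < cfg.n_common_loci:
        tries += 1
        if tries > 50_000:
            raise ValueError("cannot place common loci")
        iv = _place_interval(rng, genome.chrom_lengths, cfg.common_size.draw(rng))
        if iv is None or _matches_any(iv, placer.syndrome_ivs, 0.4):
            continue
        vtype = VariantType.DEL if rng.random() < 0.55 else VariantType.DUP
        common_loci.append((iv, vtype))
        placer.common_ivs.append(iv)

    roh_pool: list[GenomicInterval] = []
    tries = 0
    while len(roh_pool) < cfg.n_common_roh:
        tries += 1
        if tries > 50_000:
            raise ValueError("cannot place common ROH loci")
        iv = _place_interval(rng, genome.chrom_lengths, cfg.roh_size.draw(rng))
        if iv is not None:
            roh_pool.append(iv)
    roh_lengths = np.array([iv.length for iv in roh_pool], dtype=float)

    # --- patients ---------------------------------------------------------
    rng = _rng(cfg.seed, "patients")
    n = cfg.n_patients
    n_male = int(round(cfg.male_fraction * n))
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sexes)
    n_known = int(round(cfg.known_consanguinity_fraction * n))
    n_cons = int(round(cfg.consanguineous_fraction * n_known))
    cons_status: list[Optional[bool]] = (
        [True] * n_cons + [False] * (n_known - n_cons) + [None] * (n - n_known)
    )
    rng.shuffle(cons_status)
    diag_labels = np.array(["ASD", "DD", "speech_delay", "ID", "epilepsy", "ADHD"])
    diag_probs = np.array([0.30, 0.18, 0.28, 0.08, 0.09, 0.07])
    patient_ids = [f"P{i + 1:03d}" for i in range(n)]
    diagnoses = []
    for _ in range(n):
        k = int(rng.integers(1, 4))
        diagnoses.append(tuple(sorted(
            rng.choice(diag_labels, size=k, replace=False, p=diag_probs)
        )))
    n_ados = int(round(cfg.ados_assessed_fraction * n))
    ados_mask = np.zeros(n, dtype=bool)
    ados_mask[rng.choice(n, size=n_ados, replace=False)] = True

    # --- carrier assignment ----------------------------------------------
    rng = _rng(cfg.seed, "pathogenic")
    carrier_idx = rng.choice(n, size=cfg.pathogenic_carrier_count, replace=False)
    pathogenic_carriers = [patient_ids[i] for i in sorted(carrier_idx)]
    # one (or more) carriers receive a second call until the call count is met
    call_owners = list(pathogenic_carriers)
    extra = cfg.pathogenic_call_count - cfg.pathogenic_carrier_count
    if extra > 0:
        call_owners += list(rng.choice(pathogenic_carriers, size=extra, replace=False))

    dosage_genes = [g for g in genes if g.is_dosage_sensitive]
    region_slots = [r for r in syndrome_regions for _ in range(2)]
    rng.shuffle(region_slots)
    n_syn_calls = min(
        len(region_slots),
        max((len(call_owners) + 1) // 2, len(call_owners) - len(dosage_genes)),
    )
    if len(call_owners) - n_syn_calls > len(dosage_genes):
        raise ValueError(
            "not enough syndrome-region slots and dosage-sensitive genes "
            "for the requested pathogenic call count"
        )

    case_calls: list[CnvCall] = []
    truth: list[TruthRecord] = []

    def add_call(pid: str, iv: GenomicInterval, vtype: VariantType,
                 label: str, mechanism: str) -> None:
        case_calls.append(CnvCall(pid, iv, vtype, source_tag=mechanism))
        truth.append(TruthRecord(pid, iv.chrom, iv.start, iv.end, vtype, label, mechanism))

    chrom_len_map = dict(genome.chrom_lengths)
    used_dosage: list[GeneModel] = []
    for j, pid in enumerate(call_owners):
        if j < n_syn_calls:
            region = region_slots[j]
            riv = region.interval
            chrom_len = chrom_len_map[riv.chrom]
            for _ in range(200):
                size = int(riv.length * rng.uniform(0.95, 1.25))
                start = riv.start - int(rng.uniform(0, 0.1) * riv.length)
                start = max(1, min(start, chrom_len - size))
                iv = GenomicInterval(riv.chrom, start, min(start + size, chrom_len + 1))
                if reciprocal_overlap(iv, riv) > 0.55:
                    break
            vtype = sorted(region.applicable_types, key=lambda t: t.value)[
                int(rng.integers(0, len(region.applicable_types)))
            ]
            add_call(pid, iv, vtype, "pathogenic", "syndrome_match")
            placer.register_rare(iv, vtype)
        else:
            for _ in range(500):
                gene = dosage_genes[int(rng.integers(0, len(dosage_genes)))]
                if gene in used_dosage:
                    continue
                size = max(cfg.pathogenic_dosage_size.draw(rng), gene.span.length + 2_000)
                chrom_len = chrom_len_map[gene.span.chrom]
                lo = max(1, gene.span.end - size)
                hi = min(gene.span.start, chrom_len - size)
                if hi < lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
                iv = GenomicInterval(gene.span.chrom, start, start + size)
                if placer.ok_rare(iv, VariantType.DEL):
                    used_dosage.append(gene)
                    add_call(pid, iv, VariantType.DEL, "pathogenic", "dosage_del")
                    placer.register_rare(iv, VariantType.DEL)
                    break
            else:
                raise ValueError("could not place a dosage-sensitive pathogenic deletion")

    # --- VOUS plants ------------------------------------------------------
    rng = _rng(cfg.seed, "vous")
    vous_idx = rng.choice(n, size=cfg.vous_carrier_count, replace=False)
    vous_carriers = [patient_ids[i] for i in sorted(vous_idx)]
    exonic_genes = [g for g in genes if not g.is_dosage_sensitive]
    for pid in vous_carriers:
        n_calls = 1 + int(rng.poisson(cfg.vous_extra_calls_rate))
        for _ in range(n_calls):
            for _ in range(500):
                vtype = VariantType.DEL if rng.random() < 0.55 else VariantType.DUP
                model = cfg.vous_del_size if vtype is VariantType.DEL else cfg.vous_dup_size
                size = model.draw(rng)
                gene = exonic_genes[int(rng.integers(0, len(exonic_genes)))]
                exon = gene.exons[int(rng.integers(0, len(gene.exons)))]
                ovl = min(500, exon.length)
                chrom_len = chrom_len_map[gene.span.chrom]
                lo = max(1, exon.start - size + ovl)
                hi = min(exon.end - ovl, chrom_len - size)
                if hi < lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
                iv = GenomicInterval(gene.span.chrom, start, start + size)
                if vtype is VariantType.DEL and any(
                    iv.contains(g.span) for g in dosage_genes
                ):
                    continue
                if placer.ok_rare(iv, vtype):
                    add_call(pid, iv, vtype, "VOUS", "vous_exonic")
                    placer.register_rare(iv, vtype)
                    break
            else:
                raise ValueError("could not place a VOUS call")

    # --- LOH --------------------------------------------------------------
    rng = _rng(cfg.seed, "loh")
    imprinted_genes = [g for g in genes if g.is_imprinted]
    vous_set = set(vous_carriers)
    w_cons = roh_lengths**2 / (roh_lengths**2).sum()
    w_out = (1.0 / roh_lengths) / (1.0 / roh_lengths).sum()
    for pid, cons in zip(patient_ids, cons_status):
        rate = cfg.loh_rate_consanguineous if cons else cfg.loh_rate_outbred
        m = int(rng.poisson(rate))
        m_common = min(m, len(roh_pool))
        n_rare = 0
        if pid in vous_set and m_common > 0:
            n_rare = int(rng.binomial(m_common, cfg.rare_loh_fraction))
        weights = w_cons if cons else w_out
        loci = rng.choice(len(roh_pool), size=m_common, replace=False, p=weights)
        for locus in loci[: m_common - n_rare]:
            iv = roh_pool[int(locus)]
            add_call(pid, iv, VariantType.LOH, "benign", "common_roh")
        size_model = (
            cfg.rare_loh_size_consanguineous if cons else cfg.rare_loh_size_outbred
        )
        for j_rare in range(n_rare):
            for _ in range(300):
                size = size_model.draw(rng)
                if imprinted_genes and rng.random() < cfg.imprinted_loh_fraction:
                    gene = imprinted_genes[int(rng.integers(0, len(imprinted_genes)))]
                    exon = gene.exons[0]
                    chrom_len = chrom_len_map[gene.span.chrom]
                    lo = max(1, exon.end - size)
                    hi = min(exon.start, chrom_len - size)
                    if hi < lo:
                        continue
                    start = int(rng.integers(lo, hi + 1))
                    iv = GenomicInterval(gene.span.chrom, start, start + size)
                else:
                    iv = _place_interval(rng, genome.chrom_lengths, size)
                    if iv is None:
                        continue
                if _matches_any(iv, roh_pool, 0.5):
                    continue
                if _matches_any(iv, placer.rare_ivs[VariantType.LOH], 0.5) > 1:
                    continue
                add_call(pid, iv, VariantType.LOH, "VOUS", "vous_loh")
                placer.register_rare(iv, VariantType.LOH)
                break
            else:
                # dense toy genomes can leave no rare-compatible position;
                # keep the per-patient count by drawing a common locus instead
                iv = roh_pool[int(loci[m_common - n_rare + j_rare])]
                add_call(pid, iv, VariantType.LOH, "benign", "common_roh")

    # --- benign background ------------------------------------------------
    rng = _rng(cfg.seed, "background")
    all_exons_by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        all_exons_by_chrom.setdefault(g.span.chrom, []).extend(g.exons)
    for pid in patient_ids:
        c = int(rng.poisson(cfg.common_calls_rate))
        for locus in rng.choice(len(common_loci), size=min(c, len(common_loci)), replace=False):
            iv, vtype = common_loci[int(locus)]
            add_call(pid, iv, vtype, "benign", "common_locus")
        r = int(rng.poisson(cfg.rare_benign_rate))
        for _ in range(r):
            for _ in range(500):
                vtype = VariantType.DEL if rng.random() < 0.5 else VariantType.DUP
                size = cfg.rare_benign_size.draw(rng)
                if vtype is VariantType.DUP:
                    size = max(size, 50_000)
                iv = _place_interval(rng, genome.chrom_lengths, size)
                if iv is None:
                    continue
                exons = all_exons_by_chrom.get(iv.chrom, ())
                if any(
                    min(iv.end, e.end) > max(iv.start, e.start) for e in exons
                ):
                    continue
                if not placer.ok_rare(iv, vtype):
                    continue
                add_call(pid, iv, vtype, "benign", "rare_benign")
                placer.register_rare(iv, vtype)
                break
            # silently skip if unplaceable: benign background is best-effort

    # --- controls ---------------------------------------------------------
    rng = _rng(cfg.seed, "controls")
    control_calls: list[CnvCall] = []
    n_ctrl = cfg.n_controls
    min_common = max(1, math.ceil(0.012 * n_ctrl))
    for i, (iv, vtype) in enumerate(common_loci):
        freq = rng.uniform(0.015, 0.06)
        k = max(min_common, int(round(freq * n_ctrl)))
        for s in rng.choice(n_ctrl, size=min(k, n_ctrl), replace=False):
            control_calls.append(CnvCall(f"C{s + 1:04d}", iv, vtype))
    for i, iv in enumerate(roh_pool):
        freq = rng.uniform(0.015, 0.05)
        k = max(min_common, int(round(freq * n_ctrl)))
        for s in rng.choice(n_ctrl, size=min(k, n_ctrl), replace=False):
            control_calls.append(CnvCall(f"C{s + 1:04d}", iv, VariantType.LOH))
    bg_sizes = SizeModel(90_000, 0.8, 30_000, 1_500_000)
    for s in range(n_ctrl):
        b = int(rng.poisson(cfg.control_background_rate))
        for _ in range(b):
            vtype = [VariantType.DEL, VariantType.DUP, VariantType.LOH][
                int(rng.choice(3, p=[0.4, 0.3, 0.3]))
            ]
            size = (
                int(rng.uniform(2_000_000, 10_000_000))
                if vtype is VariantType.LOH
                else bg_sizes.draw(rng)
            )
            iv = _place_interval(rng, genome.chrom_lengths, size)
            if iv is None:
                continue
            if _matches_any(iv, placer.rare_ivs[vtype], 0.45):
                continue
            control_calls.append(CnvCall(f"C{s + 1:04d}", iv, vtype))

    # --- ADOS -------------------------------------------------------------
    rng = _rng(cfg.seed, "ados")
    dup_carriers = frozenset(
        r.sample_id for r in truth
        if r.vtype is VariantType.DUP and r.label in ("pathogenic", "VOUS")
    )
    patients: list[Patient] = []
    for i, pid in enumerate(patient_ids):
        ados = None
        if ados_mask[i]:
            sa = rng.normal(10.0, 3.0)
            rrb = rng.normal(3.0, 1.5)
            sev = rng.normal(5.5, 1.8)
            if pid in dup_carriers:
                sa += cfg.ados_social_affect_effect
                sev += cfg.ados_severity_effect
            sa = float(np.clip(sa, 0.0, 20.0))
            rrb = float(np.clip(rrb, 0.0, 8.0))
            sev = float(np.clip(sev, 1.0, 10.0))
            ados = AdosScores(
                social_affect=round(sa, 1), rrb=round(rrb, 1),
                total=round(sa + rrb, 1), severity=round(sev, 1),
            )
        patients.append(
            Patient(
                patient_id=pid,
                sex=str(sexes[i]),
                consanguineous=cons_status[i],
                diagnosis_group=diagnoses[i],
                ados=ados,
                age_years=float(round(rng.uniform(1.5, 19.0), 1)),
            )
        )

    case_calls.sort(key=lambda c: c.key())
    control_calls.sort(key=lambda c: c.key())
    truth.sort(key=lambda r: r.key())
    return SyntheticDataset(
        config=cfg,
        chrom_table=chrom_table,
        gene_models=genes,
        syndrome_regions=tuple(syndrome_regions),
        patients=tuple(patients),
        case_calls=tuple(case_calls),
        control_cohort=ControlCohort(n_samples=n_ctrl, calls=control_calls),
        truth=SyntheticTruth(
            calls=tuple(truth),
            pathogenic_carriers=frozenset(pathogenic_carriers),
            vous_carriers=frozenset(vous_carriers),
            dup_carriers=dup_carriers,
        ),
    )


# ---------------------------------------------------------------------------
# on-disk export (the formats the readers consume), plus truth tables


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write every generated table in the formats the io module reads."""
    from pathlib import Path

    from .io_formats import (
        write_cnv_table,
        write_gene_models_bed,
        write_patients,
        write_syndrome_regions,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cnv_table(dataset.case_calls, outdir / "case_calls.tsv")
    write_cnv_table(dataset.control_cohort.calls, outdir / "control_calls.tsv")
    (outdir / "control_n_samples.txt").write_text(
        f"{dataset.control_cohort.n_samples}\n", encoding="utf-8"
    )
    write_patients(dataset.patients, outdir / "patients.tsv")
    write_gene_models_bed(dataset.gene_models, outdir / "genes.bed")
    for flag, fname in (
        ("CEG", "ceg.txt"),
        ("imprinted", "imprinted.txt"),
        ("dosage_sensitive", "dosage_sensitive.txt"),
    ):
        symbols = sorted(g.symbol for g in dataset.gene_models if flag in g.flags)
        (outdir / fname).write_text("".join(s + "\n" for s in symbols), encoding="utf-8")
    write_syndrome_regions(dataset.syndrome_regions, outdir / "syndrome_regions.bed")
    with open(outdir / "chroms.tsv", "w", encoding="utf-8") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in dataset.config.genome.chrom_lengths:
            fh.write(f"{chrom}\t{length}\n")
    with open(outdir / "truth_calls.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tchrom\tstart\tend\ttype\tlabel\tmechanism\n")
        for r in dataset.truth.calls:
            fh.write(
                f"{r.sample_id}\t{r.chrom}\t{r.start}\t{r.end}"
                f"\t{r.vtype.value}\t{r.label}\t{r.mechanism}\n"
            )
    with open(outdir / "truth_carriers.tsv", "w", encoding="utf-8") as fh:
        fh.write("patient_id\tgroup\n")
        for group, members in (
            ("pathogenic", dataset.truth.pathogenic_carriers),
            ("VOUS", dataset.truth.vous_carriers),
            ("duplication", dataset.truth.dup_carriers),
        ):
            for pid in sorted(members):
                fh.write(f"{pid}\t{group}\n")
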
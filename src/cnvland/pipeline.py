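"""End-to-end orchestration: filtering -> frequency -> classification ->
gene-level analyses -> statistics, plus the report bundle and run manifest.

Each stage consumes the previous stage's output and the manifest records
stage-by-stage call counts, so conservation (input = kept + removed,
rare + common = annotated, class counts sum to classified) is checkable for
every run.  Reports are written deterministically: identical inputs yield a
byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .classification import (
    AnnotationBundle,
    ClassifiedCall,
    CohortSummary,
    classify_all,
    size_histogram,
    summarize_cohort,
)
from .config import PipelineConfig
from .filtering import (
    FrequencyAnnotatedCall,
    annotate_frequencies,
    apply_size_type_filters,
    split_rare_common,
)
from .gene_analysis import (
    CegBurden,
    GeneIndex,
    LohComparison,
    ceg_burden,
    focal_candidates,
    imprinted_loh,
    loh_consanguinity_burden,
    shared_critical_regions,
)
from .intervals import ChromosomeTable
from .io_formats import (
    CnvCall,
    ControlCohort,
    GeneModel,
    Patient,
    SyndromeRegion,
    VariantType,
)
from .statistics import AdosComparison, TwoByTwoResult, ados_group_compare, fisher_2x2

__all__ = ["PipelineResult", "run_pipeline", "write_report", "DEFAULT_SIZE_BINS"]

log = logging.getLogger("cnvland")

#: kb-scale bins used for the size-distribution report
DEFAULT_SIZE_BINS = (
    (30_000.0, 2_000_000.0),
    (2_000_000.0, 20_000_000.0),
    (20_000_000.0, float("inf")),
)


@dataclass
class PipelineResult:
    config: PipelineConfig
    kept: list[CnvCall]
    removed: list
    annotated: list[FrequencyAnnotatedCall]
    rare: list[FrequencyAnnotatedCall]
    common: list[FrequencyAnnotatedCall]
    classified: list[ClassifiedCall]
    summary: CohortSummary
    histogram: pd.DataFrame
    ceg: CegBurden
    focal: pd.DataFrame
    shared_regions: list
    loh_comparison: Optional[LohComparison]
    imprinted_rows: list
    imprinted_union: frozenset
    sex_burden: Optional[TwoByTwoResult]
    ados: AdosComparison
    manifest: dict


def run_pipeline(
    calls: Sequence[CnvCall],
    patients: Sequence[Patient],
    controls: ControlCohort,
    genes: Sequence[GeneModel],
    syndrome_regions: Sequence[SyndromeRegion],
    chrom_table: ChromosomeTable,
    config: PipelineConfig = PipelineConfig(),
    extra_controls: Optional[ControlCohort] = None,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run every analysis stage on an in-memory cohort."""
    cfg = config
    kept, removed = apply_size_type_filters(calls, cfg.filters)
    annotated = annotate_frequencies(
        kept, controls, len(patients), cfg.filters, extra_controls=extra_controls
    )
    rare, common = split_rare_common(annotated, cfg.filters)

    bundle = AnnotationBundle.build(syndrome_regions, genes, chrom_table)
    classified = classify_all(annotated, bundle, cfg.classification)
    summary = summarize_cohort(classified, patients, chrom_table, cfg.classification)
    histogram = size_histogram(classified, DEFAULT_SIZE_BINS)

    index = bundle.gene_index
    clinical = [c for c in classified if c.label in ("pathogenic", "VOUS")]
    ceg = ceg_burden(clinical, index)
    focal = focal_candidates(clinical, index, cfg.focal_max_size)
    shared = shared_critical_regions(
        [c for c in clinical if c.vtype is not VariantType.LOH],
        min_patients=cfg.min_shared_patients,
        gene_index=index,
    )

    loh_calls = [c for c in classified if c.vtype is VariantType.LOH]
    loh_cmp = None
    if any(p.consanguineous is not None for p in patients):
        loh_cmp = loh_consanguinity_burden(loh_calls, patients)
    imprinted_rows, imprinted_union = imprinted_loh(
        [c for c in loh_calls if c.is_rare], index
    )

    sex_burden = None
    path_carriers = set(summary.carriers["pathogenic"])
    by_sex = {"female": 0, "male": 0}
    for p in patients:
        if p.patient_id in path_carriers:
            by_sex[p.sex] += 1
    n_f = sum(1 for p in patients if p.sex == "female")
    n_m = len(patients) - n_f
    if path_carriers:
        sex_burden = fisher_2x2(
            by_sex["female"], n_f - by_sex["female"],
            by_sex["male"], n_m - by_sex["male"],
        )

    ados = ados_group_compare(patients, classified)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg.to_dict(),
        "counts": {
            "input_calls": len(calls),
            "kept": len(kept),
            "removed": len(removed),
            "annotated": len(annotated),
            "rare": len(rare),
            "common": len(common),
            "classified": len(classified),
            "class_counts": summary.class_counts,
        },
        "conservation": {
            "filter": len(calls) == len(kept) + len(removed),
            "rarity_split": len(annotated) == len(rare) + len(common),
            "classes": sum(summary.class_counts.values()) == len(classified),
        },
    }
    if not all(manifest["conservation"].values()):  # pragma: no cover
        raise AssertionError(f"conservation violated: {manifest['conservation']}")
    return PipelineResult(
        config=cfg, kept=kept, removed=removed, annotated=annotated,
        rare=rare, common=common, classified=classified, summary=summary,
        histogram=histogram, ceg=ceg, focal=focal, shared_regions=shared,
        loh_comparison=loh_cmp, imprinted_rows=imprinted_rows,
        imprinted_union=imprinted_union, sex_burden=sex_burden,
        ados=ados, manifest=manifest,
    )


# ---------------------------------------------------------------------------
# report bundle


def _classified_frame(classified: Sequence[ClassifiedCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "type": c.vtype.value,
                "size_bp": c.interval.length,
                "control_frequency": round(c.annotated.control_frequency, 6),
                "cohort_frequency": round(c.annotated.cohort_frequency, 6),
                "is_rare": c.is_rare,
                "label": c.label,
                "evidence": ";".join(c.evidence),
                "subtelomeric": c.subtelomeric,
                "ceg_count": c.ceg_count,
                "genes_hit": ",".join(c.genes_hit),
            }
            for c in classified
        ]
    )


def write_report(result: PipelineResult, outdir) -> list[Path]:
    """Write the report bundle (TSVs + manifest.json) deterministically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def tsv(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)

    tsv("classified_calls.tsv", _classified_frame(result.classified))
    tsv("class_summary.tsv", result.summary.class_table())
    tsv("size_stats.tsv", result.summary.size_stats)
    tsv("size_histogram.tsv", result.histogram)
    tsv("ceg_burden.tsv", result.ceg.to_frame())
    tsv("focal_candidates.tsv", result.focal)
    tsv(
        "shared_regions.tsv",
        pd.DataFrame(
            [
                {
                    "chrom": r.region.chrom,
                    "start": r.region.start,
                    "end": r.region.end,
                    "size_bp": r.region.length,
                    "type": r.vtype.value,
                    "n_patients": len(r.patients),
                    "patients": ",".join(r.patients),
                    "genes": ",".join(r.genes),
                }
                for r in result.shared_regions
            ],
            columns=["chrom", "start", "end", "size_bp", "type",
                     "n_patients", "patients", "genes"],
        ),
    )
    tsv(
        "imprinted_loh.tsv",
        pd.DataFrame(
            [
                {
                    "sample_id": r.call.sample_id,
                    "chrom": r.call.interval.chrom,
                    "start": r.call.interval.start,
                    "end": r.call.interval.end,
                    "imprinted_genes": ",".join(r.genes),
                }
                for r in result.imprinted_rows
            ],
            columns=["sample_id", "chrom", "start", "end", "imprinted_genes"],
        ),
    )

    stats_rows = []
    if result.sex_burden is not None:
        sb = result.sex_burden
        stats_rows.append(
            {
                "test": "sex_pathogenic_burden_fisher",
                "statistic": round(sb.odds_ratio, 4),
                "p": sb.p_two_sided,
                "detail": f"table={sb.table}",
            }
        )
    if result.loh_comparison is not None and result.loh_comparison.welch is not None:
        w = result.loh_comparison.welch
        stats_rows.append(
            {
                "test": "loh_count_consanguinity_welch",
                "statistic": round(w.t, 4),
                "p": w.p_two_sided,
                "detail": f"means={w.mean_x:.3f}/{w.mean_y:.3f}",
            }
        )
    for component, w in sorted(result.ados.results.items()):
        stats_rows.append(
            {
                "test": f"ados_{component}_dup_vs_negative_welch",
                "statistic": round(w.t, 4),
                "p": w.p_two_sided,
                "detail": f"means={w.mean_x:.3f}/{w.mean_y:.3f} n={w.n_x}/{w.n_y}",
            }
        )
    tsv("statistics.tsv", pd.DataFrame(
        stats_rows, columns=["test", "statistic", "p", "detail"]
    ))

    if result.loh_comparison is not None:
        lc = result.loh_comparison
        tsv("loh_burden.tsv", pd.DataFrame(
            [
                {
                    "group": b.group,
                    "n_patients": b.n_patients,
                    "mean_loh_per_patient": round(b.mean_count, 4),
                    "mean_loh_length_bp": round(b.mean_length_bp, 1)
                    if b.mean_length_bp == b.mean_length_bp else "",
                }
                for b in (lc.consanguineous, lc.non_consanguineous)
            ]
        ))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    written.append(manifest_path)
    return written


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
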
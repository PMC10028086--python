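"""Size/type pre-filters and population-frequency annotation.

The raw call set is first reduced by per-type size filters (the resolution
floor of the array: deletions < 30 kb and duplications < 50 kb are unreliable;
LOH runs are kept only in the 2-10 Mb window because shorter runs are noise
and longer ones usually reflect genotyping artefacts or whole-arm events).

Each surviving call is then annotated with two frequencies:

* control frequency -- the fraction of control-cohort *samples* carrying at
  least one same-type call whose reciprocal overlap with the query strictly
  exceeds the configured threshold (default 50%);
* cohort frequency -- the same statistic computed within the patient cohort
  itself (the query's own sample matches itself, so this is always >= 1/N).

A call is *rare* when every frequency is strictly below the rare-frequency
cut-off (default 1%); common calls in either source are excluded from
clinical interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .intervals import GenomicInterval, reciprocal_overlap
from .io_formats import CnvCall, ControlCohort, VariantType

__all__ = [
    "FilterConfig",
    "RemovedCall",
    "FrequencyAnnotatedCall",
    "apply_size_type_filters",
    "control_frequency",
    "build_call_index",
    "sample_frequency",
    "annotate_frequencies",
    "split_rare_common",
]

log = logging.getLogger("cnvland")


@dataclass(frozen=True)
class FilterConfig:
    """Size, reciprocal-overlap and rarity thresholds (all configurable)."""

    min_del_size: int = 30_000
    min_dup_size: int = 50_000
    loh_min: int = 2_000_000
    loh_max: int = 10_000_000
    ro_threshold: float = 0.5
    rare_frequency: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_del_size", "min_dup_size", "loh_min", "loh_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.loh_min >= self.loh_max:
            raise ValueError("loh_min must be below loh_max")
        if not 0 < self.ro_threshold < 1:
            raise ValueError("ro_threshold must be in (0, 1)")
        if not 0 < self.rare_frequency < 1:
            raise ValueError("rare_frequency must be in (0, 1)")


@dataclass(frozen=True)
class RemovedCall:
    call: CnvCall
    reason: str


@dataclass(frozen=True)
class FrequencyAnnotatedCall:
    """A call plus its control/cohort frequencies and the rare/common verdict."""

    call: CnvCall
    control_frequency: float
    cohort_frequency: float
    is_rare: bool

    @property
    def vtype(self) -> VariantType:
        return self.call.vtype

    @property
    def interval(self) -> GenomicInterval:
        return self.call.interval

    @property
    def sample_id(self) -> str:
        return self.call.sample_id


def apply_size_type_filters(
    calls: Sequence[CnvCall], cfg: FilterConfig
) -> tuple[list[CnvCall], list[RemovedCall]]:
    """Partition calls into kept and removed-with-reason.

    Boundaries are inclusive on the keep side: a deletion of exactly
    ``min_del_size`` survives ("excluding < 30 kb"), and the LOH window is the
    closed interval [loh_min, loh_max].
    """
    kept: list[CnvCall] = []
    removed: list[RemovedCall] = []
    for call in calls:
        size = call.length
        reason = None
        if call.vtype is VariantType.DEL and size < cfg.min_del_size:
            reason = "del_too_small"
        elif call.vtype is VariantType.DUP and size < cfg.min_dup_size:
            reason = "dup_too_small"
        elif call.vtype is VariantType.LOH:
            if size < cfg.loh_min:
                reason = "loh_too_small"
            elif size > cfg.loh_max:
                reason = "loh_too_large"
        if reason is None:
            kept.append(call)
        else:
            removed.append(RemovedCall(call, reason))
    log.info(
        "size/type filter: %d in -> %d kept, %d removed",
        len(calls), len(kept), len(removed),
    )
    return kept, removed


CallIndex = Mapping[tuple[str, VariantType], IntervalTree]


def build_call_index(calls: Iterable[CnvCall]) -> dict[tuple[str, VariantType], IntervalTree]:
    """Index calls by (chromosome, type) for overlap queries."""
    trees: dict[tuple[str, VariantType], IntervalTree] = {}
    for call in calls:
        key = (call.interval.chrom, call.vtype)
        trees.setdefault(key, IntervalTree()).addi(
            call.interval.start, call.interval.end, call
        )
    return trees


def sample_frequency(
    call: CnvCall,
    index: CallIndex,
    n_samples: int,
    ro_threshold: float,
    exclude_sample: Optional[str] = None,
) -> float:
    """Fraction of samples with >=1 same-type call reciprocally matching ``call``.

    The denominator is samples, not calls, and a sample with several matching
    calls counts once.  ``exclude_sample`` drops one sample from the numerator
    (used for the leave-one-out rarity rule within the patient cohort).
    """
    if n_samples <= 0:
        raise ValueError("frequency denominator must be positive")
    tree = index.get((call.interval.chrom, call.vtype))
    if tree is None:
        return 0.0
    matching: set[str] = set()
    for hit in tree.overlap(call.interval.start, call.interval.end):
        other: CnvCall = hit.data
        if other.sample_id in matching or other.sample_id == exclude_sample:
            continue
        if reciprocal_overlap(call.interval, other.interval) > ro_threshold:
            matching.add(other.sample_id)
    return len(matching) / n_samples


def control_frequency(
    call: CnvCall, controls: ControlCohort, cfg: FilterConfig
) -> float:
    """Control-cohort frequency of ``call`` under the reciprocal-overlap rule."""
    if controls is None:
        raise ValueError("control cohort is required")
    return sample_frequency(call, controls.index, controls.n_samples, cfg.ro_threshold)


def annotate_frequencies(
    calls: Sequence[CnvCall],
    controls: ControlCohort,
    n_cohort_samples: int,
    cfg: FilterConfig,
    extra_controls: Optional[ControlCohort] = None,
) -> list[FrequencyAnnotatedCall]:
    """Annotate every call with control and cohort frequencies.

    ``extra_controls`` is an optional second control table (e.g. a public
    variant catalogue pre-converted to the project format); its frequency is
    folded into the reported control frequency by taking the maximum, and a
    call is rare only if all sources are below the rarity cut-off.

    The reported cohort frequency is the observed fraction (a singleton call
    prints 1/N because it matches itself), but the rarity rule is
    leave-one-out: a variant cannot count as evidence of its own commonness,
    so ``is_rare`` compares the fraction of *other* patients carrying a
    matching call against the cut-off.
    """
    cohort_index = build_call_index(calls)
    out: list[FrequencyAnnotatedCall] = []
    for call in calls:
        ctrl = control_frequency(call, controls, cfg)
        if extra_controls is not None:
            ctrl = max(ctrl, control_frequency(call, extra_controls, cfg))
        cohort = sample_frequency(call, cohort_index, n_cohort_samples, cfg.ro_threshold)
        cohort_loo = sample_frequency(
            call, cohort_index, n_cohort_samples, cfg.ro_threshold,
            exclude_sample=call.sample_id,
        )
        is_rare = ctrl < cfg.rare_frequency and cohort_loo < cfg.rare_frequency
        out.append(
            FrequencyAnnotatedCall(
                call=call,
                control_frequency=ctrl,
                cohort_frequency=cohort,
                is_rare=is_rare,
            )
        )
    n_rare = sum(a.is_rare for a in out)
    log.info("frequency annotation: %d calls, %d rare / %d common",
             len(out), n_rare, len(out) - n_rare)
    return out


def split_rare_common(
    annotated: Sequence[FrequencyAnnotatedCall], cfg: FilterConfig
) -> tuple[list[FrequencyAnnotatedCall], list[FrequencyAnnotatedCall]]:
    """Partition annotated calls into (rare, common); sizes conserve."""
    rare = [a for a in annotated if a.is_rare]
    common = [a for a in annotated if not a.is_rare]
    return rare, common
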
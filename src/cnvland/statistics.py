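"""Statistical machinery: Fisher 2x2 with odds ratio, Welch's t, hypergeometric
gene-set over-representation with BH FDR, and ddPCR Poisson quantification.

Conventions
-----------
* Fisher's exact two-sided p is the sum of probabilities of all tables with
  the observed margins whose probability does not exceed the observed table's
  (the "sum of small probabilities" convention of mainstream packages).  The
  odds ratio is the sample cross-product (a*d)/(b*c); when any cell is zero
  the Haldane-Anscombe +0.5 continuity correction is applied to the odds
  ratio (and flagged) while the p-value uses the uncorrected table.
* Welch's t uses the unequal-variance statistic with Welch-Satterthwaite
  degrees of freedom.
* Over-representation p is the upper-tail hypergeometric probability;
  Benjamini-Hochberg adjustment runs across the sets surviving the set-size
  window, and the minimum-overlap rule acts as a report filter only.
* ddPCR concentration follows the Poisson relation lambda = -ln(1 - k/n) for
  k positive droplets of n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_formats import Patient, VariantType

__all__ = [
    "TwoByTwoResult",
    "fisher_2x2",
    "WelchResult",
    "welch_t",
    "EnrichmentThresholds",
    "EnrichmentRow",
    "enrich",
    "DdpcrResult",
    "ddpcr_quantify",
    "AdosComparison",
    "ados_group_compare",
]


# ---------------------------------------------------------------------------
# Fisher's exact test


@dataclass(frozen=True)
class TwoByTwoResult:
    table: tuple[int, int, int, int]  # (a, b, c, d): exposure rows, outcome cols
    odds_ratio: float
    p_two_sided: float
    correction_applied: bool


def fisher_2x2(a: int, b: int, c: int, d: int) -> TwoByTwoResult:
    """Two-sided Fisher's exact test and sample odds ratio for a 2x2 table."""
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    correction = min(a, b, c, d) == 0
    if correction:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    odds_ratio = (aa * dd) / (bb * cc)
    return TwoByTwoResult(
        table=(a, b, c, d),
        odds_ratio=odds_ratio,
        p_two_sided=float(min(1.0, p)),
        correction_applied=correction,
    )


# ---------------------------------------------------------------------------
# Welch's t-test


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_two_sided: float
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t-test (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    for name, v in (("x", x), ("y", y)):
        if v.size < 2:
            raise ValueError(f"group {name} needs >= 2 observations")
        if np.var(v, ddof=1) == 0:
            raise ValueError(f"group {name} has zero variance")
    vx = np.var(x, ddof=1) / x.size
    vy = np.var(y, ddof=1) / y.size
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(
        t=float(t), df=float(df), p_two_sided=float(p),
        mean_x=float(x.mean()), mean_y=float(y.mean()),
        n_x=int(x.size), n_y=int(y.size),
    )


# ---------------------------------------------------------------------------
# Gene-set over-representation


@dataclass(frozen=True)
class EnrichmentThresholds:
    """Selection and significance rules for over-representation reporting."""

    min_overlap: int = 5          # >= 5 query genes in the set
    min_set_size: int = 50        # strict >: sets of exactly 50 are excluded
    max_set_size: int = 1000      # strict <
    p_cutoff: float = 1e-3
    fdr_cutoff: float = 1e-2


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    q: float
    passes: bool


def enrich(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``query_genes`` in each gene set.

    The BH family is the collection of sets surviving the size window; the
    minimum-overlap rule and the p/FDR cut-offs then decide ``passes``.
    Rows are sorted by p ascending.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query_genes) & universe
    if frozenset(query_genes) - universe:
        raise ValueError("query genes outside the universe")
    N, n = len(universe), len(query)

    tested: list[tuple[str, int, int, float]] = []
    for set_id, members in sorted(gene_sets.items()):
        K = len(frozenset(members) & universe)
        if not (thresholds.min_set_size < K < thresholds.max_set_size):
            continue
        k = len(frozenset(members) & query)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        tested.append((set_id, k, K, p))

    rows: list[EnrichmentRow] = []
    if tested:
        pvals = [t[3] for t in tested]
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for (set_id, k, K, p), q in zip(tested, qvals):
            passes = (
                k >= thresholds.min_overlap
                and p < thresholds.p_cutoff
                and q < thresholds.fdr_cutoff
            )
            rows.append(
                EnrichmentRow(
                    set_id=set_id, overlap=k, set_size=K,
                    query_size=n, universe_size=N,
                    p=p, q=float(q), passes=passes,
                )
            )
    rows.sort(key=lambda r: (r.p, r.set_id))
    return rows


# ---------------------------------------------------------------------------
# ddPCR Poisson quantification


@dataclass(frozen=True)
class DdpcrResult:
    lam: float                     # mean target copies per droplet
    copies_per_uL: float
    copy_number: Optional[float]   # target vs reference, x2 for diploid


def ddpcr_quantify(
    k_positive: int,
    n_total: int,
    droplet_volume_uL: float = 0.00085,
    k_ref: Optional[int] = None,
    n_ref: Optional[int] = None,
) -> DdpcrResult:
    """Absolute quantification from the positive-droplet fraction.

    ``lambda = -ln(1 - k/n)`` converts the positive fraction into mean copies
    per droplet; dividing by the droplet volume gives copies/uL.  With a
    reference assay the diploid copy number is ``2 * lambda_t / lambda_r``.
    Saturated wells (k == n) carry no information and are rejected.
    """
    if n_total <= 0 or not 0 <= k_positive <= n_total:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k_positive}, n={n_total}")
    if droplet_volume_uL <= 0:
        raise ValueError("droplet volume must be positive")
    if k_positive == n_total:
        raise ValueError("saturated well: every droplet positive")
    lam = -math.log1p(-k_positive / n_total)
    copies = lam / droplet_volume_uL
    copy_number = None
    if k_ref is not None:
        if n_ref is None:
            raise ValueError("reference well size n_ref required with k_ref")
        ref = ddpcr_quantify(k_ref, n_ref, droplet_volume_uL)
        if ref.lam == 0:
            raise ValueError("reference assay has zero concentration")
        copy_number = 2.0 * lam / ref.lam
    return DdpcrResult(lam=lam, copies_per_uL=copies, copy_number=copy_number)


# ---------------------------------------------------------------------------
# ADOS group comparison


_ADOS_COMPONENTS = ("social_affect", "rrb", "total", "severity")


@dataclass(frozen=True)
class AdosComparison:
    """Welch comparisons of ADOS-2 components: rare-duplication carriers vs
    patients carrying no clinically rare variant."""

    results: dict[str, WelchResult]
    skipped: dict[str, str]
    n_dup_carriers: int
    n_cnv_negative: int


def ados_group_compare(
    patients: Sequence[Patient], classified_calls: Sequence
) -> AdosComparison:
    """Compare ADOS-2 scores between duplication carriers and CNV-negative patients.

    Duplication carriers have >=1 rare duplication; the comparison group has
    no rare variant of any type.  Patients without ADOS records are ignored.
    Components with a group below two scored patients are skipped with a
    reason rather than raising.
    """
    dup_carriers: set[str] = set()
    rare_any: set[str] = set()
    for call in classified_calls:
        if getattr(call, "is_rare", None) is None:
            is_rare = call.annotated.is_rare  # ClassifiedCall
        else:
            is_rare = call.is_rare
        if is_rare:
            rare_any.add(call.sample_id)
            if call.vtype is VariantType.DUP:
                dup_carriers.add(call.sample_id)

    dup_group = [p for p in patients if p.patient_id in dup_carriers and p.ados]
    neg_group = [
        p for p in patients if p.patient_id not in rare_any and p.ados
    ]

    results: dict[str, WelchResult] = {}
    skipped: dict[str, str] = {}
    if not dup_group and not neg_group:
        return AdosComparison({}, {}, 0, 0)
    for component in _ADOS_COMPONENTS:
        x = [getattr(p.ados, component) for p in dup_group]
        y = [getattr(p.ados, component) for p in neg_group]
        if len(x) < 2 or len(y) < 2:
            skipped[component] = "group_too_small"
            continue
        try:
            results[component] = welch_t(x, y)
        except ValueError as exc:
            skipped[component] = str(exc)
    return AdosComparison(
        results=results,
        skipped=skipped,
        n_dup_carriers=len(dup_group),
        n_cnv_negative=len(neg_group),
    )
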
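"""Evidence-rule cascade, cohort accounting and size histograms."""

import pytest

from cnvland.classification import (
    BENIGN,
    PATHOGENIC,
    VOUS,
    AnnotationBundle,
    ClassifiedCall,
    ClassifyConfig,
    Evidence,
    classify_all,
    classify_call,
    size_histogram,
    summarize_cohort,
)
from cnvland.datasets import load_pathogenic_calls
from cnvland.filtering import FilterConfig, FrequencyAnnotatedCall, annotate_frequencies
from cnvland.intervals import ChromosomeTable, GenomicInterval
from cnvland.io_formats import (
    CnvCall,
    ControlCohort,
    GeneModel,
    Patient,
    SyndromeRegion,
    VariantType,
)

CHROMS = ChromosomeTable.hg38()


def _gene(symbol, chrom, start, end, flags=(), exons=None):
    span = GenomicInterval(chrom, start, end)
    return GeneModel(
        gene_id=symbol, symbol=symbol, span=span,
        exons=tuple(exons) if exons else (span,),
        flags=frozenset(flags),
    )


@pytest.fixture(scope="module")
def bundle():
    regions = [
        SyndromeRegion(
            "PWSAS_like",
            GenomicInterval("chr15", 22_750_000, 28_300_000),
            frozenset({VariantType.DEL, VariantType.DUP}),
            "imprinting_region",
        ),
        SyndromeRegion(
            "DEL_only",
            GenomicInterval("chr7", 73_000_000, 74_500_000),
            frozenset({VariantType.DEL}),
            "del_syndrome",
        ),
    ]
    genes = [
        _gene("DOSE1", "chr2", 50_000_000, 50_100_000, {"dosage_sensitive"}),
        _gene("IMP1", "chr3", 10_000_000, 10_050_000, {"imprinted"}),
        _gene("CEG1", "chr4", 20_000_000, 20_040_000, {"CEG"}),
        _gene(
            "INTRONIC", "chr5", 1_000_000, 2_000_000,
            exons=[
                GenomicInterval("chr5", 1_000_000, 1_001_000),
                GenomicInterval("chr5", 1_999_000, 2_000_000),
            ],
        ),
    ]
    return AnnotationBundle.build(regions, genes, CHROMS)


def annotated(chrom, start, end, vtype, rare=True, ctrl=0.0):
    call = CnvCall("P1", GenomicInterval(chrom, start, end), vtype)
    return FrequencyAnnotatedCall(
        call=call, control_frequency=ctrl, cohort_frequency=1 / 212, is_rare=rare
    )


class TestRuleCascade:
    def test_common_variant_is_benign_regardless_of_content(self, bundle):
        # even a syndrome-region match stays benign when common
        c = classify_call(
            annotated("chr15", 22_838_642, 28_314_382, VariantType.DEL,
                      rare=False, ctrl=0.05),
            bundle,
        )
        assert c.label == BENIGN
        assert c.evidence == (Evidence.COMMON_VARIANT,)

    def test_syndrome_region_match(self, bundle):
        c = classify_call(
            annotated("chr15", 22_838_642, 28_314_382, VariantType.DEL), bundle
        )
        assert c.label == PATHOGENIC
        assert c.evidence == (Evidence.SYNDROME_REGION_MATCH,)
        assert c.matched_region == "PWSAS_like"

    def test_syndrome_region_type_specificity(self, bundle):
        dup = classify_call(
            annotated("chr7", 73_050_000, 74_450_000, VariantType.DUP), bundle
        )
        assert dup.label != PATHOGENIC or Evidence.SYNDROME_REGION_MATCH not in dup.evidence

    def test_dosage_gene_deletion(self, bundle):
        c = classify_call(
            annotated("chr2", 49_900_000, 50_200_000, VariantType.DEL), bundle
        )
        assert c.label == PATHOGENIC
        assert c.evidence == (Evidence.DOSAGE_GENE_HIT,)
        # a partial hit of the dosage gene is not a whole-gene loss
        partial = classify_call(
            annotated("chr2", 50_050_000, 50_200_000, VariantType.DEL), bundle
        )
        assert partial.label == VOUS

    def test_rare_loh_is_vous_with_imprinted_flag(self, bundle):
        plain = classify_call(
            annotated("chr1", 10_000_000, 15_000_000, VariantType.LOH), bundle
        )
        assert plain.label == VOUS and plain.evidence == (Evidence.LOH_EVENT,)
        imprinted = classify_call(
            annotated("chr3", 8_000_000, 12_000_000, VariantType.LOH), bundle
        )
        assert imprinted.label == VOUS
        assert Evidence.IMPRINTED_GENE_HIT in imprinted.evidence

    def test_gene_content_and_empty_calls(self, bundle):
        exonic = classify_call(
            annotated("chr4", 20_010_000, 20_020_000, VariantType.DEL), bundle
        )
        assert exonic.label == VOUS and exonic.ceg_count == 1
        intron_only = classify_call(
            annotated("chr5", 1_200_000, 1_800_000, VariantType.DEL), bundle
        )
        assert intron_only.label == BENIGN
        assert intron_only.evidence == (Evidence.NO_GENE_CONTENT,)
        desert = classify_call(
            annotated("chr6", 50_000_000, 50_500_000, VariantType.DUP), bundle
        )
        assert desert.label == BENIGN

    def test_determinism(self, bundle):
        a = annotated("chr15", 22_838_642, 28_314_382, VariantType.DEL)
        assert classify_call(a, bundle) == classify_call(a, bundle)

    def test_missing_bundle_errors(self):
        with pytest.raises(ValueError):
            classify_call(
                annotated("chr1", 1, 100, VariantType.DEL), None
            )

    def test_rarity_threshold_monotonicity(self, bundle):
        """Lowering the rare-frequency cut-off only moves calls toward benign."""
        iv = GenomicInterval("chr4", 20_010_000, 20_020_000)
        controls = ControlCohort(
            1_000, [CnvCall(f"c{i}", iv, VariantType.DEL) for i in range(7)]
        )
        call = CnvCall("P1", iv, VariantType.DEL)
        labels = {}
        for cut in (0.005, 0.02):
            cfg = FilterConfig(rare_frequency=cut)
            ann = annotate_frequencies([call], controls, 212, cfg)[0]
            labels[cut] = classify_call(ann, bundle).label
        assert labels[0.005] == BENIGN  # 0.007 is common at the stricter cut
        assert labels[0.02] == VOUS     # and clinically rare at the looser one


class TestCohortSummary:
    def _mk_classified(self, bundle, spec):
        """spec: list of (patient, chrom, start, end, vtype, rare)."""
        ann = [
            annotated(chrom, start, end, vtype, rare=rare)
            for _, chrom, start, end, vtype, rare in spec
        ]
        ann = [
            FrequencyAnnotatedCall(
                call=CnvCall(pid, a.call.interval, a.call.vtype),
                control_frequency=a.control_frequency,
                cohort_frequency=a.cohort_frequency,
                is_rare=a.is_rare,
            )
            for (pid, *_), a in zip(spec, ann)
        ]
        return classify_all(ann, bundle)

    def test_yields_match_hand_computed_fractions(self, bundle):
        patients = [Patient(f"P{i}", "male") for i in range(8)]
        spec = [
            ("P0", "chr15", 22_838_642, 28_314_382, VariantType.DEL, True),  # pathogenic
            ("P1", "chr2", 49_900_000, 50_200_000, VariantType.DEL, True),   # pathogenic
            ("P1", "chr4", 20_010_000, 20_020_000, VariantType.DEL, True),   # VOUS too
            ("P2", "chr4", 20_010_000, 20_020_000, VariantType.DUP, True),   # VOUS
            ("P3", "chr6", 1_000_000, 1_200_000, VariantType.DEL, False),    # benign
        ]
        summary = summarize_cohort(self._mk_classified(bundle, spec), patients, CHROMS)
        assert summary.class_counts == {PATHOGENIC: 2, VOUS: 2, BENIGN: 1}
        assert summary.yield_percent[PATHOGENIC] == 25.0   # 2/8
        assert summary.yield_percent[VOUS] == 25.0         # P1, P2
        assert summary.carriers[PATHOGENIC] == ("P0", "P1")
        # patients in several classes count once per class
        assert "P1" in summary.carriers[VOUS]
        assert sum(summary.class_counts.values()) == summary.n_calls

    def test_zero_pathogenic_cohort(self, bundle):
        patients = [Patient("P0", "female")]
        spec = [("P0", "chr6", 1_000_000, 1_200_000, VariantType.DEL, False)]
        summary = summarize_cohort(self._mk_classified(bundle, spec), patients, CHROMS)
        assert summary.yield_percent[PATHOGENIC] == 0.0
        assert not summary.size_stats.query("label == 'pathogenic'").shape[0]

    def test_orphan_sample_rejected(self, bundle):
        spec = [("GHOST", "chr6", 1_000_000, 1_200_000, VariantType.DEL, False)]
        with pytest.raises(ValueError, match="GHOST"):
            summarize_cohort(
                self._mk_classified(bundle, spec), [Patient("P0", "male")], CHROMS
            )

    def test_class_percentages_sum_to_100(self, small_result):
        assert sum(small_result.summary.class_percent.values()) == pytest.approx(
            100.0, abs=0.02
        )


def _published_as_classified():
    records = load_pathogenic_calls()
    out = []
    for r in records:
        ann = FrequencyAnnotatedCall(
            call=r.call, control_frequency=0.0,
            cohort_frequency=1 / 212, is_rare=True,
        )
        out.append(
            ClassifiedCall(
                annotated=ann, label=PATHOGENIC,
                evidence=(Evidence.SYNDROME_REGION_MATCH,),
                subtelomeric=False, genes_hit=(), ceg_count=0,
            )
        )
    return out


class TestPublishedTableAccounting:
    def test_mean_deletion_size_matches_printed_size_column(self):
        """Coordinate-derived mean of the 16 deletions equals the mean of the
        printed per-call sizes (5.6855 Mb)."""
        printed_mb = [
            4.843, 5.476, 0.476, 5.959, 3.529, 22.553, 1.689, 2.231,
            21.929, 0.102, 1.421, 8.560, 4.519, 6.160, 0.087, 1.434,
        ]
        expected = sum(printed_mb) / len(printed_mb)
        calls = [c for c in _published_as_classified() if c.vtype is VariantType.DEL]
        assert len(calls) == 16
        mean_mb = sum(c.interval.length for c in calls) / len(calls) / 1e6
        assert mean_mb == pytest.approx(expected, abs=1e-3)

    def test_size_histogram_of_published_deletions(self):
        calls = [c for c in _published_as_classified() if c.vtype is VariantType.DEL]
        bins = [(30_000.0, 2_000_000.0), (2_000_000.0, 20_000_000.0),
                (20_000_000.0, float("inf"))]
        frame = size_histogram(calls, bins)
        row = frame.loc[(frame.label == PATHOGENIC) & (frame.type == "DEL")].iloc[0]
        assert [row.iloc[2], row.iloc[3], row.iloc[4]] == [6, 8, 2]
        assert row.unbinned == 0


class TestSizeHistogram:
    def test_single_call_lands_in_first_bin(self):
        calls = _published_as_classified()[:0]
        ann = annotated("chr1", 1_000_000, 1_040_000, VariantType.DEL)
        call = ClassifiedCall(
            annotated=ann, label=VOUS, evidence=(Evidence.GENE_CONTENT,),
            subtelomeric=False, genes_hit=("G",), ceg_count=0,
        )
        frame = size_histogram([call], [(30_000, 100_000), (100_000, float("inf"))])
        assert frame.iloc[0, 2] == 1 and frame.iloc[0, 3] == 0

    def test_empty_input_and_bad_bins(self):
        assert size_histogram([], [(1, 2)]).empty
        with pytest.raises(ValueError, match="overlap"):
            size_histogram([], [(1, 10), (5, 20)])
        with pytest.raises(ValueError):
            size_histogram([], [(10, 10)])
        with pytest.raises(ValueError):
            size_histogram([], [])
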
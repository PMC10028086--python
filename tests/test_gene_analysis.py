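"""Gene disruption, CEG burden, focal candidates, shared regions and LOH."""

import itertools
import random

import numpy as np
import pytest

from cnvland.classification import PATHOGENIC, VOUS, ClassifiedCall, Evidence
from cnvland.filtering import FrequencyAnnotatedCall
from cnvland.gene_analysis import (
    GeneIndex,
    ceg_burden,
    focal_candidates,
    genes_disrupted,
    imprinted_loh,
    loh_consanguinity_burden,
    shared_critical_regions,
)
from cnvland.intervals import GenomicInterval, minimal_critical_region
from cnvland.io_formats import CnvCall, GeneModel, Patient, VariantType


def _gene(symbol, chrom, start, end, flags=(), exons=None):
    span = GenomicInterval(chrom, start, end)
    return GeneModel(
        gene_id=symbol, symbol=symbol, span=span,
        exons=tuple(exons) if exons else (span,),
        flags=frozenset(flags),
    )


def _classified(pid, chrom, start, end, vtype, label=VOUS):
    call = CnvCall(pid, GenomicInterval(chrom, start, end), vtype)
    ann = FrequencyAnnotatedCall(call, 0.0, 1 / 212, True)
    return ClassifiedCall(
        annotated=ann, label=label, evidence=(Evidence.GENE_CONTENT,),
        subtelomeric=False, genes_hit=(), ceg_count=0,
    )


THREE_EXON = _gene(
    "G3X", "chr1", 1_000_000, 1_100_000,
    exons=[
        GenomicInterval("chr1", 1_000_000, 1_002_000),
        GenomicInterval("chr1", 1_050_000, 1_052_000),
        GenomicInterval("chr1", 1_098_000, 1_100_000),
    ],
)


class TestGenesDisrupted:
    def test_intron_only_overlap_is_not_a_hit(self):
        index = GeneIndex([THREE_EXON])
        call = _classified("P1", "chr1", 1_010_000, 1_040_000, VariantType.DEL)
        assert genes_disrupted(call, index, exon_aware=True) == []
        span_hits = genes_disrupted(call, index, exon_aware=False)
        assert [h.gene.symbol for h in span_hits] == ["G3X"]
        assert not span_hits[0].exonic

    def test_full_containment_flag(self):
        index = GeneIndex([THREE_EXON])
        call = _classified("P1", "chr1", 900_000, 1_200_000, VariantType.DEL)
        (hit,) = genes_disrupted(call, index)
        assert hit.exonic and hit.fully_contained

    def test_exon_hits_subset_of_span_hits_on_random_calls(self, small_dataset):
        index = GeneIndex(small_dataset.gene_models)
        rng = random.Random(9)
        for _ in range(100):
            chrom, length = small_dataset.config.genome.chrom_lengths[
                rng.randrange(3)
            ]
            start = rng.randint(1, length - 200_000)
            call = _classified("P", chrom, start, start + rng.randint(10_000, 150_000),
                               VariantType.DEL)
            exon = {h.gene for h in genes_disrupted(call, index, exon_aware=True)}
            span = {h.gene for h in genes_disrupted(call, index, exon_aware=False)}
            assert exon <= span


class TestCegBurden:
    def _fixture(self):
        """26 pathogenic calls carrying 195 CEG hits in total -> mean 7.50."""
        genes = []
        calls = []
        pos = 1_000_000
        gene_i = 0
        # distribute 195 hits over 26 calls: 13 calls x 8 CEGs + 13 x 7 CEGs
        for call_i, n_ceg in enumerate([8] * 13 + [7] * 13):
            span = 10_000 * n_ceg + 20_000
            for j in range(n_ceg):
                gene_i += 1
                g0 = pos + 10_000 * j
                genes.append(_gene(f"CEG{gene_i}", "chr1", g0, g0 + 8_000, {"CEG"}))
            calls.append(
                _classified(f"P{call_i}", "chr1", pos - 1_000, pos + span,
                            VariantType.DEL, PATHOGENIC)
            )
            pos += span + 50_000
        return genes, calls

    def test_mean_cegs_per_pathogenic_call(self):
        genes, calls = self._fixture()
        burden = ceg_burden(calls, GeneIndex(genes))
        row = burden.per_class[PATHOGENIC]
        assert row.n_calls == 26
        assert row.total_ceg_hits == 195
        assert row.unique_cegs == 195
        assert row.mean_per_call == pytest.approx(7.50)
        assert row.unique_cegs <= row.total_ceg_hits

    def test_gene_hit_through_two_exons_counts_once(self):
        two_exon = _gene(
            "CEG_2X", "chr1", 1_000, 50_000, {"CEG"},
            exons=[GenomicInterval("chr1", 1_000, 5_000),
                   GenomicInterval("chr1", 45_000, 50_000)],
        )
        call = _classified("P1", "chr1", 500, 60_000, VariantType.DEL, PATHOGENIC)
        burden = ceg_burden([call], GeneIndex([two_exon]))
        assert burden.per_call[0][1] == 1

    def test_no_ceg_annotation_gives_zero(self):
        genes = [_gene("G1", "chr1", 1_000, 50_000)]
        call = _classified("P1", "chr1", 500, 60_000, VariantType.DEL, PATHOGENIC)
        burden = ceg_burden([call], GeneIndex(genes))
        assert burden.per_class[PATHOGENIC].total_ceg_hits == 0

    def test_loh_excluded_from_burden(self):
        genes = [_gene("C", "chr1", 1_000, 50_000, {"CEG"})]
        loh = _classified("P1", "chr1", 500, 60_000, VariantType.LOH)
        assert ceg_burden([loh], GeneIndex(genes)).per_call == ()


class TestFocalCandidates:
    GENES = [
        _gene("PLCB1_like", "chr20", 8_100_000, 8_500_000, {"CEG"}),
        _gene(
            "INTRON_CEG", "chr9", 1_000_000, 2_000_000, {"CEG"},
            exons=[GenomicInterval("chr9", 1_000_000, 1_001_000),
                   GenomicInterval("chr9", 1_999_000, 2_000_000)],
        ),
    ]

    def test_focal_pathogenic_deletion_listed(self):
        index = GeneIndex(self.GENES)
        focal = _classified("P20", "chr20", 8_117_650, 8_593_664,
                            VariantType.DEL, PATHOGENIC)     # 476 kb
        big = _classified("P21", "chr20", 8_000_000, 9_200_000,
                          VariantType.DEL, PATHOGENIC)       # 1.2 Mb
        intronic = _classified("P22", "chr9", 1_200_000, 1_700_000,
                               VariantType.DEL, VOUS)        # 500 kb, intron only
        frame = focal_candidates([focal, big, intronic], index)
        assert list(frame.sample_id) == ["P20"]
        assert frame.iloc[0].ceg_symbols == "PLCB1_like"
        assert frame.iloc[0].size_bp == 476_014

    def test_sorted_by_size(self):
        index = GeneIndex(self.GENES)
        calls = [
            _classified("A", "chr20", 8_117_650, 8_593_664, VariantType.DEL, VOUS),
            _classified("B", "chr20", 8_117_650, 8_217_650, VariantType.DUP, VOUS),
        ]
        frame = focal_candidates(calls, index)
        assert list(frame.sample_id) == ["B", "A"]


def _brute_force_shared(calls, min_patients):
    """Oracle: maximal subsets with non-empty common intersection, enumerated."""
    results = set()
    for r in range(len(calls), 1, -1):
        for combo in itertools.combinations(range(len(calls)), r):
            members = [calls[i] for i in combo]
            if len({c.interval.chrom for c in members}) > 1:
                continue
            if len({c.vtype for c in members}) > 1:
                continue
            region = minimal_critical_region([c.interval for c in members])
            if region is None:
                continue
            if any(set(combo) < set(prev) for prev in results):
                continue
            results.add(combo)
    return {
        combo
        for combo in results
        if len({calls[i].sample_id for i in combo}) >= min_patients
    }


class TestSharedCriticalRegions:
    def test_two_patient_deletion_intersection(self):
        gene = _gene("PSMC3_like", "chr11", 47_410_000, 47_430_000, {"CEG"})
        calls = [
            _classified("P119", "chr11", 47_400_000, 47_426_473, VariantType.DEL),
            _classified("P121", "chr11", 47_418_769, 47_500_000, VariantType.DEL),
        ]
        (region,) = shared_critical_regions(calls, 2, GeneIndex([gene]))
        assert region.region.length == 7_704
        assert region.patients == ("P119", "P121")
        assert region.genes == ("PSMC3_like",)
        assert all(c.interval.contains(region.region) for c in region.calls)

    def test_single_patient_and_same_patient_overlap_excluded(self):
        solo = [_classified("P1", "chr1", 1_000, 50_000, VariantType.DEL)]
        assert shared_critical_regions(solo, 2) == []
        same_patient = [
            _classified("P1", "chr1", 1_000, 50_000, VariantType.DEL),
            _classified("P1", "chr1", 30_000, 90_000, VariantType.DEL),
        ]
        assert shared_critical_regions(same_patient, 2) == []

    def test_type_specific_grouping(self):
        mixed = [
            _classified("P1", "chr1", 1_000, 50_000, VariantType.DEL),
            _classified("P2", "chr1", 1_000, 50_000, VariantType.DUP),
        ]
        assert shared_critical_regions(mixed, 2) == []

    def test_triple_intersection_matches_brute_force(self):
        calls = [
            _classified("P1", "chr2", 100, 1_000, VariantType.DUP),
            _classified("P2", "chr2", 500, 1_500, VariantType.DUP),
            _classified("P3", "chr2", 800, 2_000, VariantType.DUP),
        ]
        (region,) = shared_critical_regions(calls, 2)
        assert (region.region.start, region.region.end) == (800, 1_000)
        assert len(region.patients) == 3

    def test_matches_brute_force_on_random_fixtures(self):
        rng = random.Random(21)
        for _ in range(30):
            calls = [
                _classified(
                    f"P{rng.randint(1, 5)}", "chr1",
                    rng.randint(1, 400), rng.randint(401, 900),
                    VariantType.DEL,
                )
                for _ in range(rng.randint(2, 7))
            ]
            got = shared_critical_regions(calls, 2)
            expected = _brute_force_shared(calls, 2)
            got_sets = {
                tuple(sorted(calls.index(c) for c in r.calls)) for r in got
            }
            assert got_sets == {tuple(sorted(c)) for c in expected}
            for r in got:
                assert all(c.interval.contains(r.region) for c in r.calls)


def _loh(pid, start, size):
    return CnvCall(pid, GenomicInterval("chr1", start, start + size), VariantType.LOH)


class TestLohConsanguinity:
    def test_poisson_mean_recovery(self):
        rng = np.random.default_rng(17)
        patients = [Patient(f"C{i}", "male", True) for i in range(40)] + [
            Patient(f"N{i}", "female", False) for i in range(60)
        ]
        calls = []
        for p in patients:
            lam = 13.0 if p.consanguineous else 4.0
            for _ in range(rng.poisson(lam)):
                calls.append(_loh(p.patient_id, int(rng.integers(1, 10_000_000)),
                                  int(rng.integers(2_000_000, 10_000_000))))
        cmp = loh_consanguinity_burden(calls, patients)
        se_c = np.sqrt(13.0 / 40)
        se_n = np.sqrt(4.0 / 60)
        assert abs(cmp.consanguineous.mean_count - 13.0) < 3 * se_c
        assert abs(cmp.non_consanguineous.mean_count - 4.0) < 3 * se_n
        assert not cmp.underpowered
        assert cmp.welch.p_two_sided < 1e-6
        # means recomputable from the emitted per-patient vectors
        assert cmp.consanguineous.mean_count == pytest.approx(
            np.mean(list(cmp.consanguineous.per_patient_counts.values()))
        )

    def test_all_unknown_errors(self):
        patients = [Patient("P1", "male", None)]
        with pytest.raises(ValueError):
            loh_consanguinity_burden([], patients)

    def test_single_patient_groups_flagged_underpowered(self):
        patients = [Patient("C1", "male", True), Patient("N1", "male", False)]
        calls = [_loh("C1", 1_000, 3_000_000)]
        cmp = loh_consanguinity_burden(calls, patients)
        assert cmp.underpowered and cmp.welch is None
        assert cmp.consanguineous.mean_count == 1.0
        assert cmp.non_consanguineous.mean_count == 0.0

    def test_unknown_patients_excluded_and_counted(self):
        patients = [
            Patient("C1", "male", True), Patient("C2", "male", True),
            Patient("N1", "male", False), Patient("N2", "male", False),
            Patient("U1", "male", None),
        ]
        calls = [_loh("U1", 1_000, 3_000_000), _loh("C1", 1_000, 3_000_000),
                 _loh("N1", 1_000, 2_500_000)]
        cmp = loh_consanguinity_burden(calls, patients)
        assert cmp.excluded_unknown == 1
        assert "U1" not in cmp.consanguineous.per_patient_counts
        assert "U1" not in cmp.non_consanguineous.per_patient_counts


class TestImprintedLoh:
    def test_thirty_six_loh_disrupting_sixty_nine_genes(self):
        """36 LOH runs hitting 69 distinct imprinted genes in total."""
        genes = [
            _gene(f"IMP{i}", "chr1", 1_000_000 * i, 1_000_000 * i + 20_000,
                  {"imprinted"})
            for i in range(1, 70)
        ]
        calls = []
        # 33 runs covering two genes each (66), 3 covering one each (67..69)
        for j in range(33):
            start = 1_000_000 * (2 * j + 1) - 1_000
            calls.append(_loh(f"P{j}", start, 1_100_000 + 21_000))
        for j, gi in enumerate((67, 68, 69)):
            calls.append(_loh(f"Q{j}", 1_000_000 * gi - 1_000, 50_000))
        rows, union = imprinted_loh(calls, GeneIndex(genes))
        assert len(rows) == 36
        assert len(union) == 69

    def test_non_imprinted_loh_absent_and_union_dedupes(self):
        gene = _gene("IMP1", "chr1", 1_000_000, 1_020_000, {"imprinted"})
        plain = _gene("G1", "chr1", 5_000_000, 5_020_000)
        calls = [
            _loh("P1", 900_000, 2_000_000),
            _loh("P2", 950_000, 2_000_000),
            _loh("P3", 4_900_000, 2_000_000),  # hits only a non-imprinted gene
        ]
        rows, union = imprinted_loh(calls, GeneIndex([gene, plain]))
        assert [r.call.sample_id for r in rows] == ["P1", "P2"]
        assert union == {"IMP1"}
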
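import pytest

from oligotiler.config import DesignConfig
from oligotiler.dfs_optimizer import ShrinkAssignment
from oligotiler.oligo_builder import (
    DesignError,
    apply_tail,
    build_gapless,
    build_gapped,
    check_invariants,
    design,
    oligo_set_to_fasta,
    oligo_set_to_report,
)
from oligotiler.segmentation import initial_split, refine, split_count
from oligotiler.synthetic import SequenceSpec, gc_gradient_gene, random_gene
from oligotiler.thermo import reverse_complement

from conftest import random_acgt


@pytest.fixture
def seq100(rng):
    return random_acgt(rng, 100)


@pytest.fixture
def plan100():
    return initial_split(100, 25)


class TestBuildGapless:
    def test_three_oligos_alternating(self, seq100, plan100):
        oset = build_gapless(seq100, plan100)
        assert [(o.start, o.end) for o in oset.oligos] == [(0, 50), (25, 75), (50, 100)]
        assert [o.strand for o in oset.oligos] == ["sense", "antisense", "sense"]
        assert check_invariants(oset) == []

    def test_reconstruction(self, seq100, plan100):
        oset = build_gapless(seq100, plan100)
        # non-overlap prefix of each oligo plus the last oligo's tail
        rebuilt = seq100[0:25] + seq100[25:50] + seq100[50:100]
        assert rebuilt == seq100
        covered = sorted((o.start, o.end) for o in oset.oligos)
        merged = ""
        reach = 0
        for s, e in covered:
            merged += seq100[max(s, reach) : e]
            reach = max(reach, e)
        assert merged == seq100

    def test_overlap_is_reverse_complement(self, seq100, plan100):
        oset = build_gapless(seq100, plan100)
        o1, o2 = oset.oligos[0], oset.oligos[1]
        assert o1.sequence[-25:] == str(reverse_complement(o2.sequence[-25:]))

    def test_primers(self, seq100, plan100):
        oset = build_gapless(seq100, plan100)
        assert oset.forward_primer == seq100[0:25]
        assert oset.reverse_primer == str(reverse_complement(seq100[75:100]))

    def test_needs_two_segments(self, seq100):
        from oligotiler.segmentation import SegmentationPlan

        with pytest.raises(ValueError):
            build_gapless(seq100, SegmentationPlan((0, 100)))


class TestBuildGapped:
    def test_zero_assignment_equals_gapless(self, seq100, plan100):
        gapless = build_gapless(seq100, plan100)
        gapped = build_gapped(seq100, plan100, ShrinkAssignment.zeros(4))
        assert gapped.oligos == gapless.oligos
        assert gapped.gaps == []

    def test_single_internal_shrink(self, seq100, plan100):
        # shrink overlap 2 (0-based index 1) by (1, 1)
        assignment = ShrinkAssignment(((0, 0), (1, 1), (0, 0), (0, 0)))
        oset = build_gapped(seq100, plan100, assignment)
        assert check_invariants(oset) == []
        single = set()
        for gap in oset.gaps:
            single.update(range(gap.start, gap.end))
        assert single == {25, 49}
        # flanking oligos shortened accordingly
        assert (oset.oligos[0].start, oset.oligos[0].end) == (0, 49)
        assert (oset.oligos[1].start, oset.oligos[1].end) == (26, 75)

    def test_both_strands_cover_template(self, rng):
        for _ in range(5):
            n = int(rng.integers(150, 400))
            seq = random_acgt(rng, n)
            plan, _ = refine(seq, initial_split(n, 25))
            from oligotiler.dfs_optimizer import dfs_optimize

            res = dfs_optimize(seq, plan)
            oset = build_gapped(seq, plan, res.assignment)
            assert check_invariants(oset) == []
            covered = set()
            for o in oset.oligos:
                covered.update(range(o.start, o.end))
            assert covered == set(range(n))

    def test_gaps_strictly_inside_spanner(self, rng):
        seq = random_acgt(rng, 200)
        plan, _ = refine(seq, initial_split(200, 25))
        from oligotiler.dfs_optimizer import dfs_optimize

        oset = build_gapped(seq, plan, dfs_optimize(seq, plan).assignment)
        for gap in oset.gaps:
            spanner = oset.oligos[gap.spanned_by - 1]
            assert spanner.start < gap.start and gap.end < spanner.end
            assert spanner.strand != gap.missing_strand


class TestApplyTail:
    def test_odd_count_noop(self, rng):
        s = random_acgt(rng, 125)  # 125/25 = 5 segments, odd
        out, tail = apply_tail(s, 25)
        assert out == s and tail == ""

    def test_even_count_appends(self, rng):
        s = random_acgt(rng, 100)  # 4 segments, even
        out, tail = apply_tail(s, 25, seed=3)
        assert len(tail) == 25
        assert out == s + tail
        assert split_count(len(out), 25) % 2 == 1

    def test_deterministic(self, rng):
        s = random_acgt(rng, 100)
        assert apply_tail(s, 25, seed=9) == apply_tail(s, 25, seed=9)


class TestDesign:
    def test_gapless_invariants_500bp(self):
        seq = str(random_gene(SequenceSpec(length=500, seed=11)))
        oset = design(seq, DesignConfig(mode="gapless", seed=11))
        assert check_invariants(oset) == []
        assert oset.mode == "gapless"

    def test_gapped_not_worse_than_gapless(self):
        seq = str(random_gene(SequenceSpec(length=500, seed=11)))
        gapless = design(seq, DesignConfig(mode="gapless", seed=11))
        gapped = design(seq, DesignConfig(mode="gapped", seed=11))
        assert gapped.std_overlap_tm <= gapless.std_overlap_tm + 1e-9

    @pytest.mark.parametrize("target", [20, 25, 30])
    def test_length_envelope_at_b0(self, target):
        # commensurate input: every segment starts at exactly target bp
        seq = str(random_gene(SequenceSpec(length=target * 15, seed=4)))
        oset = design(seq, DesignConfig(target_len=target, budget=0, mode="gapped", seed=4))
        assert all(40 <= o.length <= 60 for o in oset.oligos)

    def test_stage_error_prefix(self):
        with pytest.raises(DesignError, match="initial_split"):
            design("ACGT" * 5, DesignConfig(allow_tail=False))

    def test_tail_recorded(self):
        seq = str(random_gene(SequenceSpec(length=100, seed=2)))
        oset = design(seq, DesignConfig(seed=2))
        assert len(oset.tail) == 25
        assert oset.sequence.endswith(oset.tail)

    def test_no_tail_flag(self):
        seq = str(random_gene(SequenceSpec(length=100, seed=2)))
        oset = design(seq, DesignConfig(seed=2, allow_tail=False))
        assert oset.tail == ""
        assert len(oset.oligos) == 3

    def test_gradient_input(self):
        seq = str(gc_gradient_gene(600, seed=5))
        oset = design(seq, DesignConfig(mode="gapped", seed=5))
        assert check_invariants(oset) == []


class TestSerialization:
    def test_fasta_output(self, seq100, plan100):
        oset = build_gapless(seq100, plan100)
        fasta = oligo_set_to_fasta(oset)
        records = [l for l in fasta.splitlines() if l.startswith(">")]
        assert len(records) == 5  # 3 oligos + 2 primers
        assert records[0].startswith(">oligo_1|sense|0-50|len=50|Tm=")
        assert records[-1].startswith(">primer_reverse|antisense|75-100|")

    def test_report_output(self, seq100, plan100):
        oset = build_gapless(seq100, plan100)
        report = oligo_set_to_report(oset)
        lines = report.splitlines()
        assert lines[0].split("\t")[0] == "index"
        assert sum(1 for l in lines if not l.startswith("#")) == 4  # header + 3
        assert any(l.startswith("# mean_overlap_tm") for l in lines)
        assert any(l.startswith("# conditions: Na=0.05 M, CT=1e-06 M") for l in lines)
        assert lines[-1] == "# tail=-"
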
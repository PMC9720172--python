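"""Turn a segmentation (plus optional shrink assignment) into an oligo set.

Geometry
--------
A plan with L segments (overlap regions) yields L - 1 oligos; oligo j
(1-based) spans segments j and j+1 on the template, so adjacent oligos
share exactly one overlap region and strands alternate starting from the
sense strand.  The forward PCR primer is the first overlap's sequence and
the reverse primer is the reverse complement of the last overlap.

In gapped mode, an internal overlap shrunk by (a, b) trims the oligo that
starts in it by ``a`` bases and the oligo that ends in it by ``b`` bases;
the excised bases are single-strand gaps filled by the polymerase using
the opposite-strand oligo, inside which every gap strictly lies.  Shrinks
of the two terminal overlaps shorten only the primers.

When the segment count implied by the target overlap length is even, the
alternating structure cannot close with a terminal overlap on the
antisense side, so a short random tail is appended to the 3' end before
splitting; the tail is removable afterwards by PCR with specific primers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .dfs_optimizer import (
    OptimizationResult,
    OptimizerConfig,
    ShrinkAssignment,
    dfs_optimize,
    overlap_std,
)
from .segmentation import (
    ConvergenceConfig,
    SegmentationPlan,
    initial_split,
    refine,
    segment_tms,
    split_count,
)
from .thermo import (
    NNParameterSet,
    NucleotideSequence,
    ThermoConditions,
    melting_temperature,
    reverse_complement,
)

__all__ = [
    "Oligo",
    "OverlapRegion",
    "Gap",
    "OligoSet",
    "DesignError",
    "build_gapless",
    "build_gapped",
    "apply_tail",
    "design",
    "check_invariants",
    "oligo_set_to_fasta",
    "oligo_set_to_report",
]

logger = logging.getLogger(__name__)


class DesignError(RuntimeError):
    """Pipeline failure, prefixed with the failing stage name."""


@dataclass(frozen=True)
class Oligo:
    """One assembly oligonucleotide.

    ``start``/``end`` are 0-based half-open template coordinates;
    ``sequence`` is written 5'->3' (antisense oligos are the reverse
    complement of the covered template region).
    """

    index: int
    strand: str  # "sense" | "antisense"
    start: int
    end: int
    sequence: str
    tm: float
    left_overlap_id: Optional[int]
    right_overlap_id: Optional[int]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OverlapRegion:
    index: int  # 1-based
    start: int
    end: int
    sequence: str
    tm: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Gap:
    """Template interval covered by only one strand's oligos."""

    start: int
    end: int
    missing_strand: str  # strand with no oligo over the interval
    spanned_by: int  # 1-based index of the opposite-strand oligo spanning it


@dataclass
class OligoSet:
    """Complete design output: oligos, overlaps, gaps, primers, stats."""

    sequence: str
    oligos: List[Oligo]
    overlaps: List[OverlapRegion]
    gaps: List[Gap]
    forward_primer: str
    reverse_primer: str
    tail: str
    mode: str
    mean_overlap_tm: float
    std_overlap_tm: float
    conditions: ThermoConditions
    plan: SegmentationPlan
    assignment: Optional[ShrinkAssignment] = None
    history: List[float] = field(default_factory=list)
    optimizer: Optional[OptimizationResult] = None


def _build(
    seq: str,
    plan: SegmentationPlan,
    assignment: Optional[ShrinkAssignment],
    params: NNParameterSet | None,
    cond: ThermoConditions | None,
    mode: str,
) -> OligoSet:
    cond = cond or ThermoConditions()
    n = len(seq)
    n_over = plan.n_segments
    if n_over < 2:
        raise ValueError("need at least two overlap segments (L >= 2)")
    if plan.length != n:
        raise ValueError("plan does not cover the sequence")
    if assignment is None:
        assignment = ShrinkAssignment.zeros(n_over)
    if len(assignment.shrinks) != n_over:
        raise ValueError("assignment length does not match plan")

    b = plan.boundaries
    eff = assignment.effective_intervals(plan)
    overlaps = [
        OverlapRegion(i + 1, s, e, seq[s:e], melting_temperature(seq[s:e], params, cond))
        for i, (s, e) in enumerate(eff)
    ]

    oligos: List[Oligo] = []
    for j in range(1, n_over):  # oligo j covers overlaps j and j+1 (1-based)
        start = b[j - 1] + assignment.shrinks[j - 1][0]
        end = b[j + 1] - assignment.shrinks[j][1]
        strand = "sense" if j % 2 == 1 else "antisense"
        region = seq[start:end]
        sequence = region if strand == "sense" else str(reverse_complement(region))
        oligos.append(
            Oligo(
                index=j,
                strand=strand,
                start=start,
                end=end,
                sequence=sequence,
                tm=melting_temperature(region, params, cond),
                left_overlap_id=j,
                right_overlap_id=j + 1,
            )
        )

    gaps: List[Gap] = []
    for i in range(1, n_over - 1):  # internal overlaps only (0-based)
        a, r = assignment.shrinks[i]
        if a > 0:
            # Missing from the oligo that starts in overlap i (1-based i+1),
            # spanned by the oligo ending there (1-based i).
            gap = Gap(b[i], b[i] + a, oligos[i].strand, i)
            gaps.append(gap)
        if r > 0:
            gap = Gap(b[i + 1] - r, b[i + 1], oligos[i - 1].strand, i + 1)
            gaps.append(gap)
    for gap in gaps:
        spanner = oligos[gap.spanned_by - 1]
        if not (spanner.start < gap.start and gap.end < spanner.end):
            raise AssertionError(
                f"gap [{gap.start}, {gap.end}) not strictly inside its "
                f"spanning oligo {gap.spanned_by}"
            )

    tms = [ov.tm for ov in overlaps]
    return OligoSet(
        sequence=seq,
        oligos=oligos,
        overlaps=overlaps,
        gaps=gaps,
        forward_primer=overlaps[0].sequence,
        reverse_primer=str(reverse_complement(overlaps[-1].sequence)),
        tail="",
        mode=mode,
        mean_overlap_tm=sum(tms) / len(tms),
        std_overlap_tm=overlap_std(tms),
        conditions=cond,
        plan=plan,
        assignment=assignment,
    )


def build_gapless(
    seq: str,
    plan: SegmentationPlan,
    params: NNParameterSet | None = None,
    cond: ThermoConditions | None = None,
) -> OligoSet:
    """Oligo set for LCR / gapless PCR assembly: overlaps tile the input."""
    return _build(seq, plan, None, params, cond, "gapless")


def build_gapped(
    seq: str,
    plan: SegmentationPlan,
    assignment: ShrinkAssignment,
    params: NNParameterSet | None = None,
    cond: ThermoConditions | None = None,
) -> OligoSet:
    """Oligo set for gapped PCR assembly under a shrink assignment."""
    return _build(seq, plan, assignment, params, cond, "gapped")


_TAIL_TM_WINDOW = 3.0  # max deg C the tail segment may sit from the mean


def apply_tail(
    seq: str,
    target_len: int,
    seed: int = 0,
    params: NNParameterSet | None = None,
    cond: ThermoConditions | None = None,
    max_tries: int = 64,
) -> Tuple[str, str]:
    """Append a 3' tail when the implied segment count is even.

    With an odd segment count L the L - 1 oligos close with a terminal
    overlap on the antisense side; an even count cannot close, so a
    ``target_len``-bp pseudo-random 50% GC tail (deterministic per seed)
    is appended, screened so the terminal segment's Tm lies within
    ``3 deg C`` of the mean of the others.  Returns (sequence, tail); the
    tail is empty when no change was needed.
    """
    n = len(seq)
    if split_count(n, target_len) % 2 == 1:
        return seq, ""
    rng = np.random.default_rng(seed)
    best_tail = None
    best_dev = float("inf")
    alphabet = np.array(list("ACGT"))
    for _ in range(max_tries):
        draws = rng.integers(0, 4, size=target_len)
        tail = "".join(alphabet[draws])
        tailed = seq + tail
        plan = initial_split(len(tailed), target_len)
        tms = segment_tms(tailed, plan, params, cond)
        dev = abs(tms[-1] - sum(tms[:-1]) / (len(tms) - 1))
        if dev < best_dev:
            best_dev = dev
            best_tail = tail
        if dev <= _TAIL_TM_WINDOW:
            break
    assert best_tail is not None
    if best_dev > _TAIL_TM_WINDOW:
        logger.warning(
            "tail screening: best terminal-segment Tm deviation %.2f C "
            "exceeds the %.1f C window",
            best_dev,
            _TAIL_TM_WINDOW,
        )
    return seq + best_tail, best_tail


def design(seq: str, config) -> OligoSet:
    """One-call pipeline: tail -> split -> refine -> (DFS) -> build.

    ``config`` is a :class:`oligotiler.config.DesignConfig` (or anything
    exposing the same attributes).  Stage failures are re-raised as
    :class:`DesignError` prefixed with the stage name.
    """
    params = getattr(config, "nn_params", None)
    cond = ThermoConditions(na_molar=config.na_molar, ct_molar=config.ct_molar)
    seq = str(NucleotideSequence(seq))

    stage = "tail"
    try:
        tail = ""
        if getattr(config, "allow_tail", True):
            seq, tail = apply_tail(
                seq, config.target_len, seed=config.seed, params=params, cond=cond
            )

        stage = "initial_split"
        plan0 = initial_split(len(seq), config.target_len, config.min_overlap_len)

        stage = "refine"
        cfg = ConvergenceConfig(
            var_threshold=config.var_threshold,
            min_len=config.min_overlap_len,
            length_bounds=getattr(config, "overlap_bounds", None),
        )
        plan, history = refine(seq, plan0, params, cond, cfg)

        if config.mode == "gapped":
            stage = "dfs_optimize"
            opt = dfs_optimize(
                seq,
                plan,
                params,
                cond,
                OptimizerConfig(
                    budget=config.budget, min_overlap_len=config.min_overlap_len
                ),
            )
            stage = "build_gapped"
            oset = build_gapped(seq, plan, opt.assignment, params, cond)
            oset.optimizer = opt
        else:
            stage = "build_gapless"
            oset = build_gapless(seq, plan, params, cond)
    except (ValueError, AssertionError) as exc:
        raise DesignError(f"{stage}: {exc}") from exc

    oset.tail = tail
    oset.history = history
    return oset


def check_invariants(oset: OligoSet) -> List[str]:
    """Structural invariant suite; returns human-readable violations.

    Checks strand alternation, template reconstruction from oligo
    projections, overlap reverse-complementarity between adjacent oligos,
    strict gap spanning, primer identity, and full two-strand coverage.
    """
    violations: List[str] = []
    seq = oset.sequence
    n = len(seq)
    oligos = oset.oligos

    for k, oligo in enumerate(oligos):
        expected = "sense" if oligo.index % 2 == 1 else "antisense"
        if oligo.strand != expected:
            violations.append(f"oligo {oligo.index}: strand {oligo.strand}, expected {expected}")
        region = seq[oligo.start : oligo.end]
        want = region if oligo.strand == "sense" else str(reverse_complement(region))
        if oligo.sequence != want:
            violations.append(f"oligo {oligo.index}: sequence does not match template")
        if k + 1 < len(oligos) and oligos[k + 1].index != oligo.index + 1:
            violations.append("oligo indices are not consecutive")

    # Coverage: union of all oligo intervals must be [0, n).
    covered = 0
    for oligo in sorted(oligos, key=lambda o: o.start):
        if oligo.start > covered:
            violations.append(f"template [{covered}, {oligo.start}) covered by no oligo")
        covered = max(covered, oligo.end)
    if covered != n:
        violations.append(f"template [{covered}, {n}) covered by no oligo")

    # Adjacent oligos: annotated shared overlap must be complementary.
    for left, right in zip(oligos, oligos[1:]):
        ov_id = left.right_overlap_id
        if ov_id != right.left_overlap_id:
            violations.append(
                f"oligos {left.index}/{right.index}: overlap ids disagree"
            )
            continue
        ov = oset.overlaps[ov_id - 1]
        if not (left.start < ov.start and ov.end <= left.end and
                right.start <= ov.start and ov.end < right.end):
            violations.append(f"overlap {ov.index} not inside both flanking oligos")
            continue
        if left.strand == "sense":
            left_part = left.sequence[-(ov.length):]
            right_part = right.sequence[-(ov.length):]  # antisense: 3' end is template-left
            # sense 3' overlap vs revcomp of antisense partner's 3' region
            if left_part != str(reverse_complement(right_part)):
                violations.append(
                    f"overlap {ov.index}: duplex regions are not reverse complements"
                )
        else:
            left_part = left.sequence[: ov.length]  # antisense 5' end is template-right...
            right_part = right.sequence[: ov.length]
            if left_part != str(reverse_complement(right_part)):
                violations.append(
                    f"overlap {ov.index}: duplex regions are not reverse complements"
                )

    # Gaps: strictly inside the spanning opposite-strand oligo; in gapless
    # mode there are none and overlaps tile the template.
    if oset.mode == "gapless":
        if oset.gaps:
            violations.append("gapless design reports gaps")
        tiling = [(ov.start, ov.end) for ov in oset.overlaps]
        expect = 0
        for s, e in tiling:
            if s != expect:
                violations.append(f"overlap tiling broken at {s} (expected {expect})")
            expect = e
        if expect != n:
            violations.append("overlaps do not tile the template")
    for gap in oset.gaps:
        spanner = oset.oligos[gap.spanned_by - 1]
        if not (spanner.start < gap.start and gap.end < spanner.end):
            violations.append(f"gap [{gap.start}, {gap.end}) not strictly spanned")
        if spanner.strand == gap.missing_strand:
            violations.append(f"gap [{gap.start}, {gap.end}) spanned by same strand")

    # Both strands together must cover the whole template.
    events = sorted((o.start, o.end) for o in oligos)
    reach = 0
    for s, e in events:
        if s > reach:
            violations.append(f"strand coverage hole at [{reach}, {s})")
        reach = max(reach, e)

    if oset.forward_primer != oset.overlaps[0].sequence:
        violations.append("forward primer is not the first overlap")
    if oset.reverse_primer != str(reverse_complement(oset.overlaps[-1].sequence)):
        violations.append("reverse primer is not revcomp of the last overlap")
    return violations


def oligo_set_to_fasta(oset: OligoSet) -> str:
    """FASTA text: one record per oligo plus the two primers."""
    lines: List[str] = []
    for o in oset.oligos:
        lines.append(
            f">oligo_{o.index}|{o.strand}|{o.start}-{o.end}|len={o.length}|Tm={o.tm:.2f}"
        )
        lines.append(o.sequence)
    lines.append(
        f">primer_forward|sense|{oset.overlaps[0].start}-{oset.overlaps[0].end}"
        f"|len={len(oset.forward_primer)}|Tm={oset.overlaps[0].tm:.2f}"
    )
    lines.append(oset.forward_primer)
    lines.append(
        f">primer_reverse|antisense|{oset.overlaps[-1].start}-{oset.overlaps[-1].end}"
        f"|len={len(oset.reverse_primer)}|Tm={oset.overlaps[-1].tm:.2f}"
    )
    lines.append(oset.reverse_primer)
    return "\n".join(lines) + "\n"


def oligo_set_to_report(oset: OligoSet) -> str:
    """TSV report with per-oligo rows and summary footer lines."""
    header = [
        "index", "strand", "start", "end", "length", "sequence",
        "oligo_tm", "left_overlap_tm", "right_overlap_tm",
    ]
    rows = ["\t".join(header)]
    for o in oset.oligos:
        left_tm = oset.overlaps[o.left_overlap_id - 1].tm
        right_tm = oset.overlaps[o.right_overlap_id - 1].tm
        rows.append(
            "\t".join(
                [
                    str(o.index), o.strand, str(o.start), str(o.end),
                    str(o.length), o.sequence,
                    f"{o.tm:.2f}", f"{left_tm:.2f}", f"{right_tm:.2f}",
                ]
            )
        )
    cond = oset.conditions
    rows.append(f"# mean_overlap_tm\t{oset.mean_overlap_tm:.2f}")
    rows.append(f"# std_overlap_tm\t{oset.std_overlap_tm:.2f}")
    rows.append(f"# conditions: Na={cond.na_molar:g} M, CT={cond.ct_molar:g} M")
    rows.append(f"# tail={oset.tail or '-'}")
    return "\n".join(rows) + "\n"
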
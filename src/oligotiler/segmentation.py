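"""Sequence segmentation into overlap regions of uniform melting temperature.

A :class:`SegmentationPlan` is an ordered list of 0-based cut positions that
partitions a sequence into L contiguous segments; each segment is one
overlap region of the eventual oligo tiling.  :func:`initial_split` produces
a near-equal split, and :func:`refine` shifts internal boundaries one base
at a time until the standard deviation of segment melting temperatures
stops improving by more than a threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .thermo import (
    NNParameterSet,
    ThermoConditions,
    melting_temperature,
)

__all__ = [
    "SegmentationPlan",
    "ConvergenceConfig",
    "initial_split",
    "split_count",
    "segment_tms",
    "refine",
    "plan_to_bed",
]

logger = logging.getLogger(__name__)

#: Hard floor on segment length (bp); also the default post-shrink floor.
DEFAULT_MIN_SEGMENT = 15

_TARGET_BOUNDS = (15, 40)


@dataclass(frozen=True)
class SegmentationPlan:
    """Strictly increasing cut positions [0, b1, ..., n] tiling a sequence.

    Segment ``i`` (0-based) is the half-open interval
    ``[boundaries[i], boundaries[i + 1])``.
    """

    boundaries: Tuple[int, ...]

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) < 2:
            raise ValueError("a plan needs at least one segment")
        if b[0] != 0:
            raise ValueError("first boundary must be 0")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_segments(self) -> int:
        return len(self.boundaries) - 1

    @property
    def length(self) -> int:
        return self.boundaries[-1]

    def segment(self, i: int) -> Tuple[int, int]:
        return self.boundaries[i], self.boundaries[i + 1]

    def segment_lengths(self) -> List[int]:
        b = self.boundaries
        return [b[i + 1] - b[i] for i in range(len(b) - 1)]


@dataclass(frozen=True)
class ConvergenceConfig:
    """Controls for :func:`refine`.

    ``var_threshold`` is the minimum per-sweep decrease in segment-Tm
    standard deviation (deg C) for a sweep's moves to be kept; sweeps
    improving by less than this are rolled back, which makes refinement
    idempotent on converged plans.  ``length_bounds``, when set, is a soft
    band on segment lengths: moves may not increase a segment's distance
    outside the band.  ``merge_resplit`` enables an experimental
    post-convergence step that merges the adjacent pair with the closest
    melting temperatures and resplits at the midpoint (off by default).
    """

    var_threshold: float = 0.001
    max_iter: int = 1000
    step: int = 1
    min_len: int = DEFAULT_MIN_SEGMENT
    length_bounds: Optional[Tuple[int, int]] = None
    merge_resplit: bool = False

    def __post_init__(self) -> None:
        if self.var_threshold <= 0:
            raise ValueError("var_threshold must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def split_count(n: int, target_len: int) -> int:
    """Number of segments for an n-bp sequence (round-half-up of n/target)."""
    return int(math.floor(n / target_len + 0.5))


def initial_split(n: int, target_len: int, min_len: int = DEFAULT_MIN_SEGMENT) -> SegmentationPlan:
    """Near-equal split into ``round(n / target_len)`` segments.

    Segment lengths differ by at most 1 bp; the leftover bases are given to
    the leftmost segments.
    """
    lo, hi = _TARGET_BOUNDS
    if not lo <= target_len <= hi:
        raise ValueError(f"target_len must be in [{lo}, {hi}], got {target_len}")
    if n < 2 * target_len:
        raise ValueError(
            f"sequence too short to split: need at least {2 * target_len} bp "
            f"for target_len={target_len}, got {n}"
        )
    n_seg = split_count(n, target_len)
    base, rem = divmod(n, n_seg)
    if base < min_len:
        raise ValueError(
            f"split of {n} bp into {n_seg} segments gives {base} bp segments, "
            f"below the {min_len} bp minimum; increase target_len"
        )
    boundaries = [0]
    for i in range(n_seg):
        boundaries.append(boundaries[-1] + base + (1 if i < rem else 0))
    return SegmentationPlan(tuple(boundaries))


def segment_tms(
    seq: str,
    plan: SegmentationPlan,
    params: NNParameterSet | None = None,
    cond: ThermoConditions | None = None,
) -> List[float]:
    """Melting temperature of each segment, in plan order."""
    if plan.length != len(seq):
        raise ValueError(f"plan covers {plan.length} bp but sequence is {len(seq)} bp")
    b = plan.boundaries
    return [
        melting_temperature(seq[b[i] : b[i + 1]], params, cond)
        for i in range(plan.n_segments)
    ]


def _pvar(values: Sequence[float]) -> float:
    n = len(values)
    mean = sum(values) / n
    return sum((v - mean) ** 2 for v in values) / n


def _pstd(values: Sequence[float]) -> float:
    return math.sqrt(max(_pvar(values), 0.0))


def _band_ok(new_len: int, old_len: int, bounds: Optional[Tuple[int, int]]) -> bool:
    # Soft band: a move may not increase a segment's excursion outside it.
    if bounds is None:
        return True
    lo, hi = bounds
    def excursion(length: int) -> int:
        return max(0, lo - length) + max(0, length - hi)
    return excursion(new_len) <= excursion(old_len)


def refine(
    seq: str,
    plan: SegmentationPlan,
    params: NNParameterSet | None = None,
    cond: ThermoConditions | None = None,
    cfg: ConvergenceConfig | None = None,
) -> Tuple[SegmentationPlan, List[float]]:
    """Greedy boundary refinement minimizing segment-Tm variance.

    Sweeps the internal boundaries left to right; each boundary may move by
    at most ``cfg.step`` bp per sweep, and only strictly variance-reducing
    moves are accepted (ties prefer no move, then the leftward move).
    Stops when a sweep improves the segment-Tm standard deviation by less
    than ``cfg.var_threshold`` (that sweep is rolled back) or when
    ``cfg.max_iter`` sweeps have run.  Returns the refined plan and the
    history of accepted per-sweep standard deviations (non-increasing,
    starting with the input plan's).
    """
    cfg = cfg or ConvergenceConfig()
    n_seg = plan.n_segments
    if n_seg < 2:
        raise ValueError("refinement needs at least two segments")
    b = list(plan.boundaries)
    tms = segment_tms(seq, plan, params, cond)
    history = [_pstd(tms)]

    converged = False
    for sweep in range(cfg.max_iter):
        prev_b = b[:]
        prev_tms = tms[:]
        moved = False
        for j in range(1, n_seg):
            cur_var = _pvar(tms)
            best_var = cur_var
            best_delta = 0
            best_pair: Tuple[float, float] | None = None
            for delta in (-cfg.step, cfg.step):
                left_len = b[j] - b[j - 1] + delta
                right_len = b[j + 1] - b[j] - delta
                if left_len < cfg.min_len or right_len < cfg.min_len:
                    continue
                if not _band_ok(left_len, b[j] - b[j - 1], cfg.length_bounds):
                    continue
                if not _band_ok(right_len, b[j + 1] - b[j], cfg.length_bounds):
                    continue
                t_left = melting_temperature(seq[b[j - 1] : b[j] + delta], params, cond)
                t_right = melting_temperature(seq[b[j] + delta : b[j + 1]], params, cond)
                trial = tms[:]
                trial[j - 1] = t_left
                trial[j] = t_right
                var = _pvar(trial)
                if var < best_var:
                    best_var = var
                    best_delta = delta
                    best_pair = (t_left, t_right)
            if best_delta != 0 and best_pair is not None:
                b[j] += best_delta
                tms[j - 1], tms[j] = best_pair
                moved = True
        new_std = _pstd(tms)
        improvement = history[-1] - new_std
        if not moved or improvement < cfg.var_threshold:
            # Roll back a below-threshold sweep so converged plans are
            # fixed points of refine().
            b, tms = prev_b, prev_tms
            converged = True
            break
        history.append(new_std)
    if not converged:
        logger.warning("refine hit max_iter=%d before convergence", cfg.max_iter)

    refined = SegmentationPlan(tuple(b))
    if cfg.merge_resplit and n_seg >= 3:
        refined, history = _merge_resplit_pass(seq, refined, history, params, cond, cfg)
    return refined, history


def _merge_resplit_pass(seq, plan, history, params, cond, cfg):
    """Merge the adjacent segment pair with closest Tm, resplit at the
    midpoint, re-refine, and keep the result only if strictly better."""
    tms = segment_tms(seq, plan, params, cond)
    pairs = [(abs(tms[i + 1] - tms[i]), i) for i in range(len(tms) - 1)]
    _, i = min(pairs)
    b = list(plan.boundaries)
    mid = (b[i] + b[i + 2]) // 2
    if mid - b[i] < cfg.min_len or b[i + 2] - mid < cfg.min_len:
        return plan, history
    b[i + 1] = mid
    candidate = SegmentationPlan(tuple(b))
    sub_cfg = ConvergenceConfig(
        var_threshold=cfg.var_threshold,
        max_iter=cfg.max_iter,
        step=cfg.step,
        min_len=cfg.min_len,
        length_bounds=cfg.length_bounds,
        merge_resplit=False,
    )
    refined, sub_history = refine(seq, candidate, params, cond, sub_cfg)
    if sub_history[-1] < history[-1]:
        return refined, history + sub_history
    return plan, history


def plan_to_bed(plan: SegmentationPlan, tms: Sequence[float], name: str = "seq") -> str:
    """Serialize a plan as BED-like TSV (name, start, end, Tm)."""
    lines = []
    for i in range(plan.n_segments):
        start, end = plan.segment(i)
        lines.append(f"{name}\t{start}\t{end}\t{tms[i]:.4f}")
    return "\n".join(lines) + "\n"
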
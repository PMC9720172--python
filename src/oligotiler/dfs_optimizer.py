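"""Depth-first minimization of overlap-Tm standard deviation by end shrinking.

Each overlap region may lose up to ``budget`` bases from its two ends;
bases removed from internal overlap ends become single-strand gaps in the
gapped assembly, while trims of the first overlap's right end and the last
overlap's left end only shorten the amplification primers.  The search
enumerates the per-overlap (left, right) shrink choices left to right and
keeps the best complete assignment by (std, total shrink, lexicographic
assignment).

Pruning bound
-------------
For L overlaps with candidate Tm sets C_1..C_L, the final sum of squared
deviations satisfies, for a prefix with k fixed Tms (sum S, sum of squares
Q),

    SS  =  min over c of [ sum_fixed (t - c)^2 + sum_rem (t_j - c)^2 ]
        >= min over c of [ Q - 2Sc + kc^2 + sum_{j>k} min_{t in C_j} (t - c)^2 ]

The right-hand side is piecewise quadratic in c with breakpoints at the
midpoints between consecutive candidate Tms of each overlap, so its exact
minimum is computed from precomputed per-depth suffix sums of the
nearest-candidate step functions.  The bound is admissible (never exceeds
any completion's SS), hence pruning cannot change the optimum; a small
epsilon keeps floating-point rounding from ever cutting an exact tie.  At
the root the bound is tight, and the assignment realizing it seeds the
incumbent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .segmentation import DEFAULT_MIN_SEGMENT, SegmentationPlan
from .thermo import NNParameterSet, ThermoConditions, melting_temperature

__all__ = [
    "ShrinkAssignment",
    "OptimizerConfig",
    "OptimizationResult",
    "shrunk_overlap",
    "overlap_std",
    "dfs_optimize",
]


@dataclass(frozen=True)
class ShrinkAssignment:
    """Per-overlap (left, right) base counts removed by the optimizer.

    Overlap ``i`` of a plan with boundaries ``b`` becomes the effective
    interval ``[b[i] + left_i, b[i+1] - right_i)``.  The first overlap's
    left shrink and the last overlap's right shrink are always zero (the
    sequence ends cannot be trimmed away).
    """

    shrinks: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.shrinks:
            raise ValueError("empty assignment")
        for i, (a, b) in enumerate(self.shrinks):
            if a < 0 or b < 0:
                raise ValueError(f"negative shrink at overlap {i}")
        if self.shrinks[0][0] != 0:
            raise ValueError("first overlap cannot be shrunk on its left end")
        if self.shrinks[-1][1] != 0:
            raise ValueError("last overlap cannot be shrunk on its right end")

    @property
    def total(self) -> int:
        return sum(a + b for a, b in self.shrinks)

    def effective_intervals(self, plan: SegmentationPlan) -> List[Tuple[int, int]]:
        b = plan.boundaries
        return [
            (b[i] + a, b[i + 1] - r) for i, (a, r) in enumerate(self.shrinks)
        ]

    @classmethod
    def zeros(cls, n_overlaps: int) -> "ShrinkAssignment":
        return cls(tuple((0, 0) for _ in range(n_overlaps)))


@dataclass(frozen=True)
class OptimizerConfig:
    """Search controls.

    ``budget`` is the maximum total bases shrinkable per overlap;
    ``ends`` restricts which end may be shrunk ("both", "left" or
    "right"); ``prune`` toggles the admissible bound (results are
    identical either way).
    """

    budget: int = 3
    min_overlap_len: int = DEFAULT_MIN_SEGMENT
    prune: bool = True
    ends: str = "both"

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValueError("budget must be >= 0")
        if self.min_overlap_len < 10:
            raise ValueError("min_overlap_len must be >= 10")
        if self.ends not in ("both", "left", "right"):
            raise ValueError("ends must be 'both', 'left' or 'right'")


@dataclass(frozen=True)
class OptimizationResult:
    assignment: ShrinkAssignment
    overlap_tms: Tuple[float, ...]
    mean_tm: float
    std_tm: float
    nodes_explored: int
    pruned: int


def shrunk_overlap(
    seq: str,
    plan: SegmentationPlan,
    i: int,
    a: int,
    b: int,
    min_overlap_len: int = DEFAULT_MIN_SEGMENT,
) -> str:
    """Overlap ``i`` with ``a`` bases removed from its left end and ``b``
    from its right end (0-based overlap index)."""
    start, end = plan.segment(i)
    if a < 0 or b < 0:
        raise ValueError(f"negative shrink at overlap {i}")
    if (end - b) - (start + a) < min_overlap_len:
        raise ValueError(
            f"shrink ({a}, {b}) at overlap {i} leaves fewer than "
            f"{min_overlap_len} bp"
        )
    return seq[start + a : end - b]


def overlap_std(tms: Sequence[float]) -> float:
    """Population standard deviation (divide by L) of overlap Tms."""
    if len(tms) < 2:
        raise ValueError("need at least two overlap Tm values")
    n = len(tms)
    mean = sum(tms) / n
    return math.sqrt(max(sum((t - mean) ** 2 for t in tms) / n, 0.0))


def shrink_candidates(
    length: int, first: bool, last: bool, cfg: OptimizerConfig
) -> List[Tuple[int, int]]:
    """Valid (left, right) shrink pairs for one overlap, ordered by total
    shrink ascending, then left shrink ascending (the DFS branch order)."""
    out: List[Tuple[int, int]] = []
    for total in range(cfg.budget + 1):
        if length - total < cfg.min_overlap_len:
            break
        for a in range(total + 1):
            b = total - a
            if first and a > 0:
                continue
            if last and b > 0:
                continue
            if cfg.ends == "left" and b > 0:
                continue
            if cfg.ends == "right" and a > 0:
                continue
            out.append((a, b))
    return out


#: Stds within this many deg C compare equal in the optimizer's key, so
#: tie-breaking (fewer gap bases, then lexicographic assignment) is stable
#: against floating-point summation noise.  Sequence-composition collisions
#: make exactly-tied overlap Tms common, and without a tolerance the search
#: would have to distinguish 1e-15-level rounding artifacts.
STD_TIE_TOL = 1e-9


def _key_better(key: Tuple[float, int, Tuple], best: Tuple[float, int, Tuple]) -> bool:
    """Is ``key`` better than ``best`` under the documented convention:
    smaller std (beyond the 1e-9 deg C tie tolerance), then fewer total
    shrunk bases, then the lexicographically smaller assignment?"""
    if key[0] < best[0] - STD_TIE_TOL:
        return True
    if key[0] > best[0] + STD_TIE_TOL:
        return False
    return key[1:] < best[1:]


class _SuffixBound:
    """Exact minimization of Q - 2Sc + kc^2 + sum_{j>=k} min_t (t - c)^2.

    Precomputes, on the global grid of nearest-candidate breakpoints, the
    per-depth suffix sums of each remaining overlap's nearest candidate Tm
    (and its square); a bound query then minimizes one quadratic per grid
    segment, vectorized.
    """

    def __init__(
        self,
        tm_lists: List[np.ndarray],
        total_lists: List[np.ndarray],
        n_over: int,
        tie_ss_tol: float,
    ):
        cuts: List[np.ndarray] = []
        for arr in tm_lists:
            s = np.unique(arr)
            if len(s) > 1:
                cuts.append((s[1:] + s[:-1]) / 2.0)
        edges = np.unique(np.concatenate(cuts)) if cuts else np.empty(0)
        self.lo = np.concatenate(([-np.inf], edges))
        self.hi = np.concatenate((edges, [np.inf]))
        all_tms = np.concatenate(tm_lists)
        span_lo, span_hi = all_tms.min() - 1.0, all_tms.max() + 1.0
        c_lo = np.clip(self.lo, span_lo, span_hi)
        c_hi = np.clip(self.hi, span_lo, span_hi)
        reps = (c_lo + c_hi) / 2.0
        m = len(reps)
        self.suf_t = np.zeros((n_over + 1, m))
        self.suf_t2 = np.zeros((n_over + 1, m))
        # Suffix minimum of total shrink over each overlap's "tie class":
        # candidates whose squared distance to the reference c can come
        # within tie_ss_tol of the overlap's minimum for some c in the
        # segment (the linear-in-c criterion is extremal at the segment
        # endpoints).  Any std-tying completion must pick inside the class.
        suf_min_tot = np.zeros((n_over + 1, m))
        for j in range(n_over - 1, -1, -1):
            s = np.sort(tm_lists[j])
            idx = np.searchsorted(s, reps)
            left = s[np.clip(idx - 1, 0, len(s) - 1)]
            right = s[np.clip(idx, 0, len(s) - 1)]
            near = np.where(np.abs(right - reps) < np.abs(reps - left), right, left)
            self.suf_t[j] = self.suf_t[j + 1] + near
            self.suf_t2[j] = self.suf_t2[j + 1] + near * near
            min_tot = np.full(m, np.inf)
            for t, tot in zip(tm_lists[j], total_lists[j]):
                f_lo = (t - c_lo) ** 2 - (near - c_lo) ** 2
                f_hi = (t - c_hi) ** 2 - (near - c_hi) ** 2
                in_class = np.minimum(f_lo, f_hi) <= tie_ss_tol
                min_tot = np.where(in_class, np.minimum(min_tot, tot), min_tot)
            suf_min_tot[j] = suf_min_tot[j + 1] + min_tot
        self._suf_min_tot = suf_min_tot
        self._tie_ss_tol = tie_ss_tol
        self.min_rem_total = np.zeros(n_over + 1, dtype=int)
        self.n_over = n_over

    def set_incumbent(self, incumbent_std: float) -> None:
        """Tighten the tie-total bound given an incumbent std.

        A tying completion's final mean c_f satisfies
        f(c_f) <= SS_completion <= L (incumbent + tol)^2, so only segments
        where the root bound clears that threshold can host a tie; the
        suffix minimum over just those segments lower-bounds any tying
        completion's remaining shrink total.
        """
        n_over = self.n_over
        tot0 = self.suf_t[0]
        c0 = np.clip(tot0 / n_over, self.lo, self.hi)
        vals0 = self.suf_t2[0] - 2.0 * c0 * tot0 + n_over * c0 * c0
        limit = n_over * (incumbent_std + STD_TIE_TOL) ** 2 + self._tie_ss_tol
        mask = vals0 <= limit
        if not mask.any():
            mask[int(np.argmin(vals0))] = True
        self.min_rem_total = self._suf_min_tot[:, mask].min(axis=1).astype(int)

    def min_ss(self, k: int, s: float, q: float) -> float:
        """Lower bound on the final sum of squared deviations, given k
        fixed Tms with sum ``s`` and sum of squares ``q``."""
        tot = s + self.suf_t[k]
        c = np.clip(tot / self.n_over, self.lo, self.hi)
        vals = q + self.suf_t2[k] - 2.0 * c * tot + self.n_over * c * c
        return float(vals.min())

    def argmin_root(self) -> float:
        """Reference temperature c minimizing the root bound."""
        tot = self.suf_t[0]
        c = np.clip(tot / self.n_over, self.lo, self.hi)
        vals = self.suf_t2[0] - 2.0 * c * tot + self.n_over * c * c
        return float(c[int(np.argmin(vals))])


def dfs_optimize(
    seq: str,
    plan: SegmentationPlan,
    params: NNParameterSet | None = None,
    cond: ThermoConditions | None = None,
    cfg: OptimizerConfig | None = None,
) -> OptimizationResult:
    """Exact minimum-std shrink assignment over the candidate space.

    The all-zero assignment (and, with pruning, the assignment realizing
    the root bound) seeds the incumbent, so the result's std never exceeds
    the unshrunk plan's.  Ties on std are broken toward smaller total
    shrink, then the lexicographically smaller assignment, making the
    result deterministic and independent of pruning.
    """
    cfg = cfg or OptimizerConfig()
    n_over = plan.n_segments
    if n_over < 2:
        raise ValueError("need at least two overlaps")

    candidates: List[List[Tuple[Tuple[int, int], float]]] = []
    for i in range(n_over):
        start, end = plan.segment(i)
        cands = shrink_candidates(end - start, i == 0, i == n_over - 1, cfg)
        if not cands:
            raise ValueError(
                f"overlap {i} ({end - start} bp) is below min_overlap_len"
            )
        candidates.append(
            [
                ((a, b), melting_temperature(seq[start + a : end - b], params, cond))
                for a, b in cands
            ]
        )

    inv_l = 1.0 / n_over

    def leaf_key(flat: Sequence[Tuple[int, int]]) -> Tuple[float, int, Tuple]:
        # Same one-pass arithmetic as the DFS leaves, so incumbent keys are
        # directly comparable with searched ones.
        s = ss = 0.0
        total = 0
        for (ab, clist) in zip(flat, candidates):
            tm = dict(clist)[ab]
            s += tm
            ss += tm * tm
            total += ab[0] + ab[1]
        mean = s * inv_l
        std = math.sqrt(max(ss * inv_l - mean * mean, 0.0))
        return (std, total, tuple(flat))

    best_key = leaf_key([(0, 0)] * n_over)

    bounder: Optional[_SuffixBound] = None
    if cfg.prune:
        # Tolerance on per-overlap squared deviations inside a std tie:
        # a completion within STD_TIE_TOL of the incumbent std can exceed
        # the per-overlap minimum by at most ~2 L std STD_TIE_TOL.
        tie_ss_tol = 2.0 * n_over * (best_key[0] + 1.0) * STD_TIE_TOL
        bounder = _SuffixBound(
            [np.array([tm for _, tm in c]) for c in candidates],
            [np.array([ab[0] + ab[1] for ab, _ in c]) for c in candidates],
            n_over,
            tie_ss_tol,
        )
        c_star = bounder.argmin_root()
        seed_flat = []
        for clist in candidates:
            # Tie-break-optimal member of the overlap's nearest-Tm class:
            # candidate order is (total shrink, left shrink) ascending.
            d_min = min(abs(tm - c_star) for _, tm in clist)
            seed_flat.append(
                next(ab for ab, tm in clist if abs(tm - c_star) <= d_min + STD_TIE_TOL)
            )
        seed_key = leaf_key(seed_flat)
        if _key_better(seed_key, best_key):
            best_key = seed_key
        bounder.set_incumbent(best_key[0])

    nodes = 0
    pruned = 0
    chosen: List[Tuple[int, int]] = [(0, 0)] * n_over

    def recurse(depth: int, s: float, ss: float, total: int) -> None:
        nonlocal nodes, pruned, best_key
        for (ab, tm) in candidates[depth]:
            nodes += 1
            s2 = s + tm
            ss2 = ss + tm * tm
            k = depth + 1
            if k == n_over:
                mean = s2 * inv_l
                std = math.sqrt(max(ss2 * inv_l - mean * mean, 0.0))
                key = (std, total + ab[0] + ab[1], tuple(chosen[:depth]) + (ab,))
                if _key_better(key, best_key):
                    best_key = key
                continue
            if bounder is not None:
                bound = math.sqrt(max(bounder.min_ss(k, s2, ss2), 0.0) * inv_l)
                if bound > best_key[0] + STD_TIE_TOL:
                    # Every completion's std is worse beyond the tolerance.
                    pruned += 1
                    continue
                if bound > best_key[0] - STD_TIE_TOL:
                    # Tie zone: completions can at best tie the incumbent's
                    # std, so the branch must also be able to win the
                    # (total shrink, lexicographic) tie-break.
                    t2 = total + ab[0] + ab[1] + bounder.min_rem_total[k]
                    if t2 > best_key[1]:
                        pruned += 1
                        continue
                    if t2 == best_key[1]:
                        prefix = tuple(chosen[:depth]) + (ab,)
                        if prefix > best_key[2][:k]:
                            pruned += 1
                            continue
            chosen[depth] = ab
            recurse(k, s2, ss2, total + ab[0] + ab[1])

    recurse(0, 0.0, 0.0, 0)

    assignment = ShrinkAssignment(best_key[2])
    tms = tuple(
        melting_temperature(seq[s0:e0], params, cond)
        for s0, e0 in assignment.effective_intervals(plan)
    )
    mean_tm = sum(tms) / n_over
    return OptimizationResult(
        assignment=assignment,
        overlap_tms=tms,
        mean_tm=mean_tm,
        std_tm=overlap_std(tms),
        nodes_explored=nodes,
        pruned=pruned,
    )
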
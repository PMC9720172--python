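"""Seeded synthetic sequence generators for tests and benchmarks.

All generators are pure functions of their arguments: the same spec always
yields the same sequence, on any platform (numpy's PCG64 generator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .thermo import NucleotideSequence

__all__ = ["SequenceSpec", "random_gene", "gc_gradient_gene"]


@dataclass(frozen=True)
class SequenceSpec:
    """Parameters for :func:`random_gene`.

    ``motif_inserts`` is a list of (position, motif) pairs spliced over the
    random background, for constructing Tm-heterogeneous stress cases.
    """

    length: int
    gc_fraction: float = 0.5
    seed: int = 0
    motif_inserts: Tuple[Tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.length < 50:
            raise ValueError("length must be >= 50")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")


def _draw(rng: np.random.Generator, gc_probs: np.ndarray) -> str:
    """Independent per-position draws: GC with the given probability, then
    a uniform choice within {G, C} or {A, T}."""
    n = len(gc_probs)
    is_gc = rng.random(n) < gc_probs
    pick = rng.integers(0, 2, size=n)
    gc_bases = np.array(["G", "C"])
    at_bases = np.array(["A", "T"])
    bases = np.where(is_gc, gc_bases[pick], at_bases[pick])
    return "".join(bases)


def random_gene(spec: SequenceSpec) -> NucleotideSequence:
    """Random sequence at a flat GC fraction, with optional motif splices."""
    rng = np.random.default_rng(spec.seed)
    text = _draw(rng, np.full(spec.length, spec.gc_fraction))
    chars = list(text)
    for position, motif in spec.motif_inserts:
        if position < 0 or position + len(motif) > spec.length:
            raise ValueError(
                f"motif at {position} (len {len(motif)}) outside sequence "
                f"of length {spec.length}"
            )
        chars[position : position + len(motif)] = list(motif.upper())
    return NucleotideSequence("".join(chars))


def gc_gradient_gene(
    length: int, seed: int = 0, gc_start: float = 0.3, gc_end: float = 0.7
) -> NucleotideSequence:
    """Sequence whose GC fraction ramps linearly along its length.

    The default 30% -> 70% ramp forces the boundary refiner and shrink
    optimizer to produce unequal overlap lengths.
    """
    if length < 200:
        raise ValueError("length must be >= 200")
    rng = np.random.default_rng(seed)
    probs = np.linspace(gc_start, gc_end, length)
    return NucleotideSequence(_draw(rng, probs))
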
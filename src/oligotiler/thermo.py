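"""Nearest-neighbor DNA duplex thermodynamics.

Duplex enthalpy and entropy are sums over adjacent dinucleotide stacks of
the unified nearest-neighbor parameter set shipped in ``data/nn_params.tsv``,
plus per-terminus initiation terms and an entropic symmetry correction for
self-complementary duplexes.

The melting temperature of an ``n``-bp duplex at total strand concentration
``ct`` (mol/L) and monovalent cation concentration ``na`` (mol/L) is

    Tm(K) = 1000 * dH / (dS_salt + R * ln(ct / x))

with ``R = 1.9872`` cal/(mol K), ``x = 4`` for non-self-complementary
duplexes (1 otherwise), and the salt correction applied to the entropy
through the duplex phosphate count (``n - 1`` is half the number of
phosphates in an n-bp duplex):

    dS_salt = dS(1 M Na+) + 0.368 * (n - 1) * ln[Na+]

Values are returned in degrees Celsius.  Divalent cations, mismatches and
dangling ends are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Dict, Tuple

__all__ = [
    "GAS_CONSTANT",
    "SequenceError",
    "ThermoError",
    "NucleotideSequence",
    "NNParameterSet",
    "ThermoConditions",
    "reverse_complement",
    "is_self_complementary",
    "gc_fraction",
    "load_nn_params",
    "default_nn_params",
    "nn_sum",
    "melting_temperature",
]

#: Gas constant in cal/(mol K).
GAS_CONSTANT = 1.9872

#: Coefficient of the entropic monovalent-salt correction, cal/(mol K)
#: per phosphate pair.
SALT_DS_COEFF = 0.368

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_VALID = frozenset("ACGT")


class SequenceError(ValueError):
    """A sequence failed validation (non-ACGT characters, empty, ...)."""


class ThermoError(ValueError):
    """A thermodynamic evaluation is impossible for the given inputs."""


def _validate_bases(bases: str) -> str:
    text = bases.upper()
    for pos, ch in enumerate(text):
        if ch not in _VALID:
            raise SequenceError(
                f"invalid character {ch!r} at position {pos}: "
                "only A/C/G/T are allowed (ambiguity codes are rejected)"
            )
    return text


class NucleotideSequence(str):
    """A validated DNA sequence over {A, C, G, T}, upper-cased on ingest.

    Behaves as a plain ``str``; coordinates throughout the package are
    0-based, half-open.
    """

    def __new__(cls, bases: str) -> "NucleotideSequence":
        return super().__new__(cls, _validate_bases(str(bases)))


def reverse_complement(seq: str) -> NucleotideSequence:
    """Watson-Crick reverse complement (an involution)."""
    text = _validate_bases(str(seq))
    return NucleotideSequence("".join(_COMPLEMENT[ch] for ch in reversed(text)))


def is_self_complementary(seq: str) -> bool:
    """True iff the sequence equals its own reverse complement."""
    return str(seq).upper() == str(reverse_complement(seq))


def gc_fraction(seq: str) -> float:
    text = str(seq).upper()
    if not text:
        raise SequenceError("empty sequence")
    return (text.count("G") + text.count("C")) / len(text)


@dataclass(frozen=True)
class NNParameterSet:
    """Nearest-neighbor stack/initiation parameters (1 M NaCl reference).

    ``stack_dh`` in kcal/mol, ``stack_ds`` in cal/(mol K); initiation terms
    keyed by terminal base-pair class ("AT" or "GC"); ``sym_ds`` is the
    self-complementarity entropy correction.
    """

    stack_dh: Dict[str, float]
    stack_ds: Dict[str, float]
    init_dh: Dict[str, float]
    init_ds: Dict[str, float]
    sym_dh: float = 0.0
    sym_ds: float = -1.4

    def __post_init__(self) -> None:
        all_stacks = {a + b for a in "ACGT" for b in "ACGT"}
        for table in (self.stack_dh, self.stack_ds):
            missing = all_stacks - set(table)
            if missing:
                raise ValueError(f"missing stacks: {sorted(missing)}")
        if set(self.init_dh) != {"AT", "GC"} or set(self.init_ds) != {"AT", "GC"}:
            raise ValueError("initiation terms must be keyed by 'AT' and 'GC'")
        for table in (self.stack_dh, self.stack_ds, self.init_dh, self.init_ds):
            for key, value in table.items():
                if not math.isfinite(value):
                    raise ValueError(f"non-finite parameter for {key!r}")


@dataclass(frozen=True)
class ThermoConditions:
    """Solution conditions entering the Tm equation.

    ``symmetry_factor`` may be pinned to 1 or 4; by default it is detected
    per duplex (4 unless self-complementary).
    """

    na_molar: float = 0.05
    ct_molar: float = 1e-6
    symmetry_factor: int | None = None

    def __post_init__(self) -> None:
        if self.na_molar <= 0:
            raise ValueError("na_molar must be > 0")
        if self.ct_molar <= 0:
            raise ValueError("ct_molar must be > 0")
        if self.symmetry_factor not in (None, 1, 4):
            raise ValueError("symmetry_factor must be 1 or 4")


def load_nn_params(path=None) -> NNParameterSet:
    """Load a parameter TSV (columns: stack, dH_kcal_mol, dS_cal_molK).

    Reserved stack names: INIT_AT, INIT_GC (per-terminus initiation) and
    SYM (self-complementarity entropy correction).
    """
    if path is None:
        source = resources.files("oligotiler").joinpath("data/nn_params.tsv")
        lines = source.read_text().splitlines()
    else:
        with open(path) as handle:
            lines = handle.read().splitlines()
    stack_dh: Dict[str, float] = {}
    stack_ds: Dict[str, float] = {}
    init_dh: Dict[str, float] = {}
    init_ds: Dict[str, float] = {}
    sym_dh = 0.0
    sym_ds = 0.0
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("stack\t"):
            continue
        name, dh_s, ds_s = line.split("\t")
        dh, ds = float(dh_s), float(ds_s)
        if name == "SYM":
            sym_dh, sym_ds = dh, ds
        elif name.startswith("INIT_"):
            init_dh[name[5:]] = dh
            init_ds[name[5:]] = ds
        else:
            stack_dh[name] = dh
            stack_ds[name] = ds
    return NNParameterSet(stack_dh, stack_ds, init_dh, init_ds, sym_dh, sym_ds)


@lru_cache(maxsize=1)
def default_nn_params() -> NNParameterSet:
    return load_nn_params()


def nn_sum(seq: str, params: NNParameterSet | None = None) -> Tuple[float, float]:
    """Total (dH, dS) of the duplex: initiation + stacks (+ symmetry).

    dH in kcal/mol, dS in cal/(mol K).
    """
    params = params or default_nn_params()
    text = _validate_bases(str(seq))
    if len(text) < 2:
        raise ThermoError("sequence too short for nearest-neighbor model (need >= 2 bp)")
    dh = 0.0
    ds = 0.0
    for terminal in (text[0], text[-1]):
        cls = "AT" if terminal in "AT" else "GC"
        dh += params.init_dh[cls]
        ds += params.init_ds[cls]
    stack_dh = params.stack_dh
    stack_ds = params.stack_ds
    for i in range(len(text) - 1):
        stack = text[i : i + 2]
        dh += stack_dh[stack]
        ds += stack_ds[stack]
    if is_self_complementary(text):
        dh += params.sym_dh
        ds += params.sym_ds
    return dh, ds


def melting_temperature(
    seq: str,
    params: NNParameterSet | None = None,
    cond: ThermoConditions | None = None,
) -> float:
    """Duplex melting temperature in degrees Celsius.

    Deterministic for fixed inputs; raises :class:`ThermoError` for
    non-physical duplexes (non-negative denominator or Tm <= 0 K).
    """
    cond = cond or _DEFAULT_COND
    dh, ds = nn_sum(seq, params)
    n = len(str(seq))
    if cond.symmetry_factor is not None:
        x = cond.symmetry_factor
    else:
        x = 1 if is_self_complementary(seq) else 4
    ds_salt = ds + SALT_DS_COEFF * (n - 1) * math.log(cond.na_molar)
    denom = ds_salt + GAS_CONSTANT * math.log(cond.ct_molar / x)
    if denom >= 0:
        raise ThermoError("non-physical duplex (non-negative Tm denominator)")
    tm_kelvin = 1000.0 * dh / denom
    if tm_kelvin <= 0:
        raise ThermoError("non-physical duplex (Tm below 0 K)")
    return tm_kelvin - 273.15


_DEFAULT_COND = ThermoConditions()
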
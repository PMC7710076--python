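"""Oligonucleotide primitives and physical properties.

Every primer/probe design and selection rule in this toolkit reduces to a
handful of per-oligo quantities: GC fraction, nearest-neighbor melting
temperature, homopolymer runs, and the composition of the 3' end. This
module computes them.

Melting temperatures use the unified SantaLucia-1998 nearest-neighbor
parameter set with the Owczarzy divalent-cation salt correction, evaluated
under PCR-like default conditions (50 mM monovalent cation, 1.5 mM Mg2+,
0.6 mM total dNTP, 50 nM oligo). These are the conditions assumed by
mainstream primer-design software, so Tm values here are comparable to the
numbers such tools print, within the usual model uncertainty of roughly
±1.5 degC.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "Oligo",
    "ThermoParams",
    "ThreePrimeReport",
    "gc_content",
    "melting_temperature",
    "reverse_complement",
    "max_homopolymer_run",
    "three_prime_report",
    "MIN_TM_LENGTH",
    "IUPAC_EXPANSION",
]

Role = Literal["forward", "reverse", "probe"]

#: IUPAC nucleotide codes -> the set of unambiguous bases each covers.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_ROLE_SUFFIX = {"F": "forward", "R": "reverse", "P": "probe"}

#: Shortest duplex the nearest-neighbor model is applied to.
MIN_TM_LENGTH = 8


def _normalize(sequence: str) -> str:
    seq = sequence.strip().upper()
    if "U" in seq:
        warnings.warn("RNA base U found; mapping U -> T", stacklevel=3)
        seq = seq.replace("U", "T")
    return seq


_ACGT_SET = frozenset("ACGT")
_IUPAC_SET = frozenset(IUPAC_EXPANSION)


def _validate_alphabet(sequence: str, *, allow_iupac: bool) -> None:
    permitted = _IUPAC_SET if allow_iupac else _ACGT_SET
    if permitted.issuperset(sequence):
        return
    for i, base in enumerate(sequence):
        if base not in permitted:
            raise ValueError(
                f"invalid character {base!r} at position {i + 1} "
                f"(permitted: {''.join(sorted(permitted))})"
            )


@dataclass(frozen=True)
class Oligo:
    """A named single-stranded DNA oligo with a PCR role.

    The name may encode the 1-based 5' template coordinate plus a role
    suffix, e.g. ``287F`` (forward primer whose 5' base sits at template
    position 287). When such a suffix is present it must agree with
    ``role``. Sequences are uppercased; ambiguity codes are rejected
    (designed oligos are always fully specified).
    """

    name: str
    sequence: str
    role: Role
    reporter: str | None = None
    quencher: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize(self.sequence))
        if not self.sequence:
            raise ValueError(f"oligo {self.name!r}: empty sequence")
        _validate_alphabet(self.sequence, allow_iupac=False)
        if self.role not in ("forward", "reverse", "probe"):
            raise ValueError(f"oligo {self.name!r}: unknown role {self.role!r}")
        m = re.fullmatch(r"(\d+)([FRP])", self.name)
        if m and _ROLE_SUFFIX[m.group(2)] != self.role:
            raise ValueError(
                f"oligo {self.name!r}: name suffix {m.group(2)} conflicts "
                f"with role {self.role!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def coordinate(self) -> int | None:
        """1-based 5' template coordinate encoded in the name, if any."""
        m = re.fullmatch(r"(\d+)([FRP])", self.name)
        return int(m.group(1)) if m else None


@dataclass(frozen=True)
class ThermoParams:
    """Solution conditions and parameter set for nearest-neighbor Tm.

    Defaults are the PCR-like conditions assumed by mainstream design
    software: 50 mM monovalent cation, 1.5 mM divalent (Mg2+), 0.6 mM
    total dNTP, 50 nM oligo (effective duplex concentration C_T/4).
    """

    monovalent_mM: float = 50.0
    divalent_mM: float = 1.5
    dntp_mM: float = 0.6
    oligo_nM: float = 50.0
    nn_set: str = "santalucia1998"

    _NN_TABLES = {
        "santalucia1998": _mt.DNA_NN3,
        "santalucia2004": _mt.DNA_NN4,
        "sugimoto1996": _mt.DNA_NN2,
        "breslauer1986": _mt.DNA_NN1,
    }

    def __post_init__(self) -> None:
        for name in ("monovalent_mM", "divalent_mM", "dntp_mM", "oligo_nM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nn_set not in self._NN_TABLES:
            raise ValueError(
                f"unknown nearest-neighbor set {self.nn_set!r}; "
                f"recognized: {sorted(self._NN_TABLES)}"
            )

    @property
    def nn_table(self) -> dict:
        return self._NN_TABLES[self.nn_set]


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement (IUPAC-aware)."""
    seq = _normalize(sequence)
    _validate_alphabet(seq, allow_iupac=True)
    return seq.translate(_COMPLEMENT)[::-1]


def _round_half_up(x: float, digits: int = 1) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def gc_content(
    oligo: Oligo | str,
    *,
    ambiguous: Literal["raise", "range"] = "raise",
) -> float | tuple[float, float]:
    """GC content as a percentage (0-100), one decimal, half-up rounding.

    ``ambiguous="range"`` returns a (min, max) pair where ambiguity codes
    count as GC only in the max (S always counts; W never does).
    """
    seq = oligo.sequence if isinstance(oligo, Oligo) else _normalize(str(oligo))
    if not seq:
        raise ValueError("empty sequence")
    _validate_alphabet(seq, allow_iupac=True)
    ambiguity = set(seq) - set("ACGT")
    if ambiguity and ambiguous == "raise":
        raise ValueError(
            f"ambiguity codes {sorted(ambiguity)} present; GC content is "
            "not defined exactly (use ambiguous='range' for bounds)"
        )
    if ambiguity:
        lo = sum(IUPAC_EXPANSION[b] <= frozenset("CG") for b in seq)
        hi = sum(bool(IUPAC_EXPANSION[b] & frozenset("CG")) for b in seq)
        return (_round_half_up(100 * lo / len(seq)), _round_half_up(100 * hi / len(seq)))
    gc = sum(seq.count(b) for b in "GC")
    return _round_half_up(100 * gc / len(seq))


def melting_temperature(oligo: Oligo | str, params: ThermoParams | None = None) -> float:
    """Nearest-neighbor duplex melting temperature in degC.

    Deterministic for fixed params; invariant under reverse complementation
    (the model describes the duplex, not a strand).
    """
    params = params or ThermoParams()
    seq = oligo.sequence if isinstance(oligo, Oligo) else _normalize(str(oligo))
    _validate_alphabet(seq, allow_iupac=False)
    if len(seq) < MIN_TM_LENGTH:
        raise ValueError(
            f"sequence of length {len(seq)} is too short for the "
            f"nearest-neighbor model (minimum {MIN_TM_LENGTH})"
        )
    # dnac1=dnac2=C_T/2 gives the effective duplex concentration C_T/4
    # used for non-self-complementary oligos.
    half = params.oligo_nM / 2.0
    saltcorr = 7 if params.divalent_mM > 0 else 5
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=params.nn_table,
            Na=params.monovalent_mM,
            K=0,
            Tris=0,
            Mg=params.divalent_mM,
            dNTPs=params.dntp_mM,
            dnac1=half,
            dnac2=half,
            saltcorr=saltcorr,
        )
    )


def max_homopolymer_run(sequence: Oligo | str) -> int:
    """Length of the longest run of a single repeated base."""
    seq = sequence.sequence if isinstance(sequence, Oligo) else _normalize(str(sequence))
    if not seq:
        raise ValueError("empty sequence")
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


@dataclass(frozen=True)
class ThreePrimeReport:
    """Composition of an oligo's 3' end (as written 5'->3')."""

    terminal_base: str
    terminal_is_gc: bool
    terminal_is_t: bool
    gc_in_last5: int


def three_prime_report(oligo: Oligo | str) -> ThreePrimeReport:
    """Report on the 3'-terminal bases driving primer-end selection rules."""
    seq = oligo.sequence if isinstance(oligo, Oligo) else _normalize(str(oligo))
    if len(seq) < 5:
        raise ValueError(f"sequence of length {len(seq)} too short (need >= 5)")
    tail = seq[-5:]
    terminal = seq[-1]
    return ThreePrimeReport(
        terminal_base=terminal,
        terminal_is_gc=terminal in "GC",
        terminal_is_t=terminal == "T",
        gc_in_last5=sum(b in "GC" for b in tail),
    )
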
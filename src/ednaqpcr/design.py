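"""Primer/probe candidate enumeration and selection-criteria scoring.

Hydrolysis-probe (TaqMan-style) assay design follows two stages that are
kept explicit here:

1. *Hard design constraints* bound the search space: amplicon length,
   oligo lengths, primer and probe melting-temperature windows, and GC
   windows. ``enumerate_candidates`` emits every forward/probe/reverse
   triple on a template that satisfies all of them.

2. *Selection criteria* rank the survivors. Eight rules of thumb from
   standard qPCR chemistry are each scored pass/fail: small primer
   Tm spread, probe Tm 8-10 degC above the primers, no homopolymer run of
   four or more, no 3'-terminal T on a primer, a 3'-terminal G/C clamp,
   at least three G/C in the last five primer bases, no 5'-terminal G on
   the probe (which would quench the reporter fluorophore), and probe GC
   above 50%. ``score_candidate`` makes the manual shortlist step an
   auditable report; ``rank_candidates`` sorts by criteria satisfied and
   then by closeness to the optima.

Coordinates are 1-based inclusive. A reverse primer's coordinate is the
plus-strand position paired with its 5' base, so product length is always
``R_coord - F_coord + 1``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .oligos import (
    Oligo,
    ThermoParams,
    gc_content,
    max_homopolymer_run,
    melting_temperature,
    reverse_complement,
    three_prime_report,
)

__all__ = [
    "DesignConstraints",
    "SelectionCriteria",
    "AssayDefinition",
    "CandidateAssay",
    "CriterionResult",
    "EnumerationResult",
    "enumerate_candidates",
    "iter_feasible_triples",
    "score_candidate",
    "rank_candidates",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Hard bounds applied during candidate enumeration."""

    product_size: tuple[int, int] = (100, 200)
    oligo_size: tuple[int, int] = (18, 27)
    oligo_size_opt: int = 20
    primer_tm: tuple[float, float] = (58.0, 63.0)
    primer_tm_opt: float = 60.0
    probe_tm: tuple[float, float] = (68.0, 73.0)
    probe_tm_opt: float = 70.0
    gc_pct: tuple[float, float] = (35.0, 65.0)
    gc_pct_opt: float = 50.0

    def __post_init__(self) -> None:
        for lo_hi, opt, label in (
            (self.oligo_size, self.oligo_size_opt, "oligo_size"),
            (self.primer_tm, self.primer_tm_opt, "primer_tm"),
            (self.probe_tm, self.probe_tm_opt, "probe_tm"),
            (self.gc_pct, self.gc_pct_opt, "gc_pct"),
        ):
            lo, hi = lo_hi
            if not lo <= opt <= hi:
                raise ValueError(f"{label}: need min <= optimum <= max, got {lo_hi}, {opt}")
        if self.product_size[0] > self.product_size[1]:
            raise ValueError("product_size min exceeds max")


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds for the eight pass/fail selection rules."""

    max_primer_delta_tm: float = 5.0          # strict less-than
    probe_delta_tm: tuple[float, float] = (8.0, 10.0)
    max_homopolymer: int = 3                  # runs longer than this fail
    forbid_primer_3prime_t: bool = True
    require_primer_3prime_gc: bool = True
    min_gc_last5: int = 3
    forbid_probe_5prime_g: bool = True
    min_probe_gc: float = 50.0                # strict greater-than

    def __post_init__(self) -> None:
        if self.probe_delta_tm[0] > self.probe_delta_tm[1]:
            raise ValueError("probe_delta_tm window min exceeds max")


@dataclass(frozen=True)
class AssayDefinition:
    """A forward/reverse/probe oligo triple plus protocol metadata."""

    name: str
    forward: Oligo
    reverse: Oligo
    probe: Oligo
    concentrations_uM: dict[str, float] = field(default_factory=dict)
    annealing_temp_c: float | None = None
    cq_threshold: float | None = None

    def __post_init__(self) -> None:
        for oligo, role in ((self.forward, "forward"), (self.reverse, "reverse"), (self.probe, "probe")):
            if oligo.role != role:
                raise ValueError(f"assay {self.name!r}: {oligo.name!r} has role {oligo.role}, expected {role}")
        for k, v in self.concentrations_uM.items():
            if v <= 0:
                raise ValueError(f"assay {self.name!r}: concentration {k}={v} must be > 0")
        if self.annealing_temp_c is not None and not 50 <= self.annealing_temp_c <= 72:
            raise ValueError(f"assay {self.name!r}: annealing temperature {self.annealing_temp_c} outside 50-72")

    @property
    def oligos(self) -> tuple[Oligo, Oligo, Oligo]:
        return (self.forward, self.reverse, self.probe)


@dataclass(frozen=True)
class CriterionResult:
    name: str
    measured: str
    passed: bool


@dataclass(frozen=True)
class CandidateAssay:
    """A scored candidate triple with 1-based template coordinates."""

    assay: AssayDefinition
    f_coord: int
    r_coord: int
    p_coord: int
    product_length: int
    criteria: tuple[CriterionResult, ...] = ()
    satisfied: int = 0
    rank: int | None = None
    tm: dict[str, float] = field(default_factory=dict)
    gc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.product_length != self.r_coord - self.f_coord + 1:
            raise ValueError("product_length must equal r_coord - f_coord + 1")


@dataclass(frozen=True)
class EnumerationResult:
    """Ranked candidates plus a per-constraint rejection histogram."""

    candidates: tuple[CandidateAssay, ...]
    rejections: dict[str, int]


def _criteria_flags(
    criteria: SelectionCriteria,
    tm_f: float,
    tm_r: float,
    tm_p: float,
    gc_p: float,
    max_run: int,
    tail_f,
    tail_r,
    probe_first_base: str,
) -> tuple[bool, ...]:
    """Boolean outcomes of the eight selection rules (single source of truth)."""
    delta_primer = abs(tm_f - tm_r)
    delta_probe = tm_p - (tm_f + tm_r) / 2.0
    return (
        delta_primer < criteria.max_primer_delta_tm,
        criteria.probe_delta_tm[0] <= delta_probe <= criteria.probe_delta_tm[1],
        max_run <= criteria.max_homopolymer,
        not criteria.forbid_primer_3prime_t
        or not (tail_f.terminal_is_t or tail_r.terminal_is_t),
        not criteria.require_primer_3prime_gc
        or (tail_f.terminal_is_gc and tail_r.terminal_is_gc),
        tail_f.gc_in_last5 >= criteria.min_gc_last5
        and tail_r.gc_in_last5 >= criteria.min_gc_last5,
        not criteria.forbid_probe_5prime_g or probe_first_base != "G",
        gc_p > criteria.min_probe_gc,
    )


def _criteria_results(
    criteria: SelectionCriteria,
    tm_f: float,
    tm_r: float,
    tm_p: float,
    gc_p: float,
    max_run: int,
    tail_f,
    tail_r,
    probe_first_base: str,
) -> tuple[CriterionResult, ...]:
    flags = _criteria_flags(
        criteria, tm_f, tm_r, tm_p, gc_p, max_run, tail_f, tail_r, probe_first_base
    )
    delta_primer = abs(tm_f - tm_r)
    delta_probe = tm_p - (tm_f + tm_r) / 2.0
    measured = (
        ("primer_delta_tm_lt", f"{delta_primer:.2f}"),
        ("probe_delta_tm_window", f"{delta_probe:.2f}"),
        ("no_homopolymer_run", str(max_run)),
        ("no_primer_3prime_t", f"{tail_f.terminal_base},{tail_r.terminal_base}"),
        ("primer_3prime_gc", f"{tail_f.terminal_base},{tail_r.terminal_base}"),
        ("gc_in_last5", f"{tail_f.gc_in_last5},{tail_r.gc_in_last5}"),
        ("no_probe_5prime_g", probe_first_base),
        ("probe_gc_gt_50", f"{gc_p:.1f}"),
    )
    return tuple(
        CriterionResult(name, value, passed)
        for (name, value), passed in zip(measured, flags)
    )


def _window_tables(template, constraints, thermo, rejections):
    """Feasible primer and probe windows with cached physical properties.

    A window's Tm and GC describe the duplex, so one pass serves both a
    forward primer and the reverse primer on the complementary strand;
    the 3'-end report depends on orientation and is cached both ways.
    """
    n = len(template)
    size_lo, size_hi = constraints.oligo_size
    primer_ok: dict[tuple[int, int], tuple] = {}
    probe_ok: dict[tuple[int, int], tuple] = {}
    for start in range(n):
        for length in range(size_lo, size_hi + 1):
            if start + length > n:
                break
            seq = template[start : start + length]
            if set(seq) - set("ACGT"):
                rejections["ambiguous_footprint"] += 1
                continue
            tm = melting_temperature(seq, thermo)
            gc = gc_content(seq)
            run = max_homopolymer_run(seq)
            gc_in = constraints.gc_pct[0] <= gc <= constraints.gc_pct[1]
            if constraints.primer_tm[0] <= tm <= constraints.primer_tm[1] and gc_in:
                rc = reverse_complement(seq)
                primer_ok[(start, length)] = (
                    tm, gc, run, seq, rc,
                    three_prime_report(seq), three_prime_report(rc),
                )
            else:
                if not gc_in:
                    rejections["primer_gc"] += 1
                else:
                    rejections["primer_tm"] += 1
            if constraints.probe_tm[0] <= tm <= constraints.probe_tm[1] and gc_in:
                probe_ok[(start, length)] = (tm, gc, run, seq)
            elif gc_in:
                rejections["probe_tm"] += 1
    return primer_ok, probe_ok


def _stream_triples(template, constraints, thermo, rejections):
    """Yield every feasible (F, P, R) placement with cached window props.

    Memory-light generator: nothing is materialized, so exhaustive
    enumeration on long templates streams in bounded memory.
    """
    primer_ok, probe_ok = _window_tables(template, constraints, thermo, rejections)
    probes_by_start = sorted(probe_ok)
    prod_lo, prod_hi = constraints.product_size
    for (fs, fl), fprops in primer_ok.items():
        f_end = fs + fl  # 0-based exclusive
        for (rs, rl), rprops in primer_ok.items():
            r_coord0 = rs + rl - 1  # 0-based plus-strand position of R 5' base
            product = r_coord0 - fs + 1
            if not prod_lo <= product <= prod_hi:
                rejections["product_size"] += 1
                continue
            if rs < f_end:
                continue  # overlapping footprints
            for ps, pl in probes_by_start:
                if ps < f_end:
                    continue
                if ps + pl > rs:
                    continue  # must sit strictly between the primer footprints
                yield (fs, fl, ps, pl, rs, rl, product, fprops, rprops, probe_ok[(ps, pl)])


def iter_feasible_triples(
    template: str,
    constraints: DesignConstraints | None = None,
    thermo: ThermoParams | None = None,
):
    """Stream 1-based footprints of every triple passing the hard constraints.

    Yields ``(f_coord, f_len, p_coord, p_len, r_coord, r_len, product)``
    without materializing candidates — useful for auditing the full search
    space on long templates.
    """
    constraints = constraints or DesignConstraints()
    thermo = thermo or ThermoParams()
    template = template.strip().upper()
    if len(template) < constraints.product_size[0]:
        raise ValueError(
            f"template of {len(template)} bp is shorter than the minimum "
            f"product size {constraints.product_size[0]}"
        )
    rejections: Counter[str] = Counter()
    for fs, fl, ps, pl, rs, rl, product, *_ in _stream_triples(
        template, constraints, thermo, rejections
    ):
        yield (fs + 1, fl, ps + 1, pl, rs + rl, rl, product)


def enumerate_candidates(
    template: str,
    constraints: DesignConstraints | None = None,
    thermo: ThermoParams | None = None,
    top_n: int | None = 10,
    criteria: SelectionCriteria | None = None,
) -> EnumerationResult:
    """Enumerate F/P/R triples on ``template`` passing the hard constraints.

    Probes are emitted on the plus strand, strictly between the primer
    footprints. Candidates are scored against ``criteria`` and ranked by
    (criteria satisfied desc, summed |Tm - optimum| asc, summed
    |GC - optimum| asc, product length asc, coordinates); at most
    ``top_n`` are returned (``None`` for all — beware that exhaustive
    materialization on long templates can run to millions of triples).
    Enumeration is deterministic — no randomness anywhere in design.
    """
    import heapq

    constraints = constraints or DesignConstraints()
    thermo = thermo or ThermoParams()
    criteria = criteria or SelectionCriteria()
    template = template.strip().upper()
    n = len(template)
    if n < constraints.product_size[0]:
        raise ValueError(
            f"template of {n} bp is shorter than the minimum product size "
            f"{constraints.product_size[0]}"
        )
    rejections: Counter[str] = Counter()
    tm_pr_opt = constraints.primer_tm_opt
    tm_p_opt = constraints.probe_tm_opt
    gc_opt = constraints.gc_pct_opt

    def keyed():
        for fs, fl, ps, pl, rs, rl, product, fprops, rprops, pprops in _stream_triples(
            template, constraints, thermo, rejections
        ):
            f_tm, f_gc, f_run, f_seq, _f_rc, f_tail, _f_rtail = fprops
            r_tm, r_gc, r_run, _r_seq, r_rc, _r_tail, r_rtail = rprops
            p_tm, p_gc, p_run, p_seq = pprops
            flags = _criteria_flags(
                criteria, f_tm, r_tm, p_tm, p_gc,
                max(f_run, r_run, p_run), f_tail, r_rtail, p_seq[0],
            )
            tm_dev = abs(f_tm - tm_pr_opt) + abs(r_tm - tm_pr_opt) + abs(p_tm - tm_p_opt)
            gc_dev = abs(f_gc - gc_opt) + abs(r_gc - gc_opt) + abs(p_gc - gc_opt)
            yield (
                (-sum(flags), round(tm_dev, 9), round(gc_dev, 9), product,
                 fs + 1, ps + 1, rs + rl),
                (fl, pl, f_seq, p_seq, r_rc,
                 (f_tm, r_tm, p_tm), (f_gc, r_gc, p_gc),
                 max(f_run, r_run, p_run), f_tail, r_rtail),
            )

    if top_n is None:
        selected = sorted(keyed(), key=lambda kp: kp[0])
    else:
        selected = heapq.nsmallest(top_n, keyed(), key=lambda kp: kp[0])
    candidates = []
    for i, (key, payload) in enumerate(selected):
        neg_sat, _tmd, _gcd, product, f1, p1, r1 = key
        fl, pl, f_seq, p_seq, r_rc, tms, gcs, max_run, f_tail, r_rtail = payload
        results = _criteria_results(
            criteria, tms[0], tms[1], tms[2], gcs[2], max_run, f_tail, r_rtail, p_seq[0]
        )
        candidates.append(
            CandidateAssay(
                assay=AssayDefinition(
                    name=f"{f1}F/{p1}P/{r1}R",
                    forward=Oligo(f"{f1}F", f_seq, "forward"),
                    reverse=Oligo(f"{r1}R", r_rc, "reverse"),
                    probe=Oligo(f"{p1}P", p_seq, "probe"),
                ),
                f_coord=f1,
                r_coord=r1,
                p_coord=p1,
                product_length=product,
                criteria=results,
                satisfied=-neg_sat,
                rank=i + 1,
                tm={"forward": tms[0], "reverse": tms[1], "probe": tms[2]},
                gc={"forward": gcs[0], "reverse": gcs[1], "probe": gcs[2]},
            )
        )
    return EnumerationResult(candidates=tuple(candidates), rejections=dict(rejections))


def score_candidate(
    candidate: CandidateAssay | AssayDefinition,
    criteria: SelectionCriteria | None = None,
    thermo: ThermoParams | None = None,
) -> CandidateAssay:
    """Evaluate the eight selection criteria on a candidate triple.

    Primer-specific rules must hold for *both* primers to pass. The probe
    Tm offset is measured against the mean of the two primer Tm values.
    Returns a copy of the candidate carrying the report; idempotent and
    independent of any other candidate.
    """
    criteria = criteria or SelectionCriteria()
    thermo = thermo or ThermoParams()
    if isinstance(candidate, AssayDefinition):
        f_c = candidate.forward.coordinate or 1
        r_c = candidate.reverse.coordinate or f_c + 99
        candidate = CandidateAssay(
            assay=candidate,
            f_coord=f_c,
            r_coord=r_c,
            p_coord=candidate.probe.coordinate or f_c + len(candidate.forward),
            product_length=r_c - f_c + 1,
        )
    assay = candidate.assay
    tm = dict(candidate.tm) or {
        role: melting_temperature(getattr(assay, role), thermo)
        for role in ("forward", "reverse", "probe")
    }
    gc = dict(candidate.gc) or {
        role: gc_content(getattr(assay, role)) for role in ("forward", "reverse", "probe")
    }
    results = _criteria_results(
        criteria,
        tm["forward"],
        tm["reverse"],
        tm["probe"],
        gc["probe"],
        max(max_homopolymer_run(o) for o in assay.oligos),
        three_prime_report(assay.forward),
        three_prime_report(assay.reverse),
        assay.probe.sequence[0],
    )
    return replace(
        candidate,
        criteria=results,
        satisfied=sum(r.passed for r in results),
        tm=tm,
        gc=gc,
    )


def rank_candidates(
    candidates: Iterable[CandidateAssay],
    constraints: DesignConstraints | None = None,
) -> list[CandidateAssay]:
    """Stable deterministic ranking of scored candidates.

    Sort key: criteria satisfied (desc), summed |Tm - optimum| over the
    three oligos (asc), summed |GC - optimum| (asc), product length (asc),
    then coordinates for full determinism under input permutation.
    """
    constraints = constraints or DesignConstraints()

    def key(c: CandidateAssay):
        tm_dev = (
            abs(c.tm.get("forward", constraints.primer_tm_opt) - constraints.primer_tm_opt)
            + abs(c.tm.get("reverse", constraints.primer_tm_opt) - constraints.primer_tm_opt)
            + abs(c.tm.get("probe", constraints.probe_tm_opt) - constraints.probe_tm_opt)
        )
        gc_dev = sum(
            abs(c.gc.get(role, constraints.gc_pct_opt) - constraints.gc_pct_opt)
            for role in ("forward", "reverse", "probe")
        )
        return (
            -c.satisfied,
            round(tm_dev, 9),
            round(gc_dev, 9),
            c.product_length,
            c.f_coord,
            c.p_coord,
            c.r_coord,
        )

    ranked = sorted(candidates, key=key)
    return [replace(c, rank=i + 1) for i, c in enumerate(ranked)]
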
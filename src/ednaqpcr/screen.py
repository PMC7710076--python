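"""In-silico specificity screening by mismatch-tolerant binding-site search.

Instead of remote database searches, an assay is screened against
user-supplied FASTA panels: every ungapped placement of each oligo on
either strand of each subject is scored by Hamming distance, hits for the
forward primer, reverse primer and probe are combined under an explicit
policy (per-oligo mismatch budgets, product-length range, orientation),
and each subject is called predicted-positive or negative with a reason.

Matching is ungapped: hydrolysis-probe oligos are 18-27 nt and indel
tolerance during annealing is far below substitution tolerance, so the
Hamming scan captures the dominant signal (a documented limitation).
Subject ambiguity codes match permissively (the oligo base need only be
in the code's expansion); oligo ambiguity codes are disallowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import AssayDefinition
from .oligos import IUPAC_EXPANSION, Oligo, reverse_complement

__all__ = [
    "BindingSiteMatch",
    "AmplificationPrediction",
    "ScreenPolicy",
    "find_binding_sites",
    "predict_amplification",
    "mismatch_summary",
]

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_CHAR_MASK = np.zeros(256, dtype=np.uint8)
for code, bases in IUPAC_EXPANSION.items():
    _CHAR_MASK[ord(code)] = sum(_BITS[b] for b in bases)


@dataclass(frozen=True)
class BindingSiteMatch:
    """One ungapped placement of an oligo on a subject sequence.

    ``start`` is the 1-based plus-strand coordinate of the footprint's
    leftmost base. ``strand`` '+' means the subject's plus strand contains
    the oligo sequence itself; '-' means it contains the reverse
    complement. Mismatch positions are 1-based in oligo coordinates
    (5'->3' as the oligo is written).
    """

    sequence_id: str
    role: str
    strand: str
    start: int
    mismatches: int
    mismatch_positions: tuple[int, ...]
    three_prime_match: bool

    def __post_init__(self) -> None:
        if self.mismatches != len(self.mismatch_positions):
            raise ValueError("mismatch count disagrees with positions")


@dataclass(frozen=True)
class ScreenPolicy:
    """How per-oligo hits are combined into an amplification call."""

    max_mismatches: dict[str, int] = field(
        default_factory=lambda: {"forward": 5, "reverse": 5, "probe": 5}
    )
    product_size: tuple[int, int] = (100, 200)
    require_three_prime_match: bool = False

    def budget(self, role: str) -> int:
        return self.max_mismatches.get(role, 5)


@dataclass(frozen=True)
class AmplificationPrediction:
    """Outcome of screening one assay against one subject sequence."""

    sequence_id: str
    positive: bool
    forward: BindingSiteMatch | None = None
    reverse: BindingSiteMatch | None = None
    probe: BindingSiteMatch | None = None
    product_length: int | None = None
    reason: str | None = None


def _subject_masks(subject: str) -> np.ndarray:
    arr = np.frombuffer(subject.encode("ascii"), dtype=np.uint8)
    masks = _CHAR_MASK[arr]
    if (masks == 0).any():
        bad = int(np.argmax(masks == 0))
        raise ValueError(f"invalid character {subject[bad]!r} at position {bad + 1}")
    return masks


def _scan(oligo_seq: str, masks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch counts and per-window mismatch boolean matrix."""
    L = len(oligo_seq)
    bits = np.array([_BITS[b] for b in oligo_seq], dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(masks, L)
    miss = (windows & bits) == 0
    return miss.sum(axis=1), miss


def find_binding_sites(
    oligo: Oligo | str,
    subject: str,
    max_mismatches: int = 5,
    *,
    sequence_id: str = "",
    role: str | None = None,
) -> list[BindingSiteMatch]:
    """All footprints on both strands within the mismatch budget.

    IUPAC ambiguity in the subject counts as a match iff the oligo base is
    in the code's expansion. Results are sorted by (mismatches, start,
    strand). An oligo longer than the subject yields an empty list.
    """
    if isinstance(oligo, Oligo):
        seq, role = oligo.sequence, role or oligo.role
    else:
        seq, role = str(oligo).upper(), role or "forward"
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    subject = subject.strip().upper()
    L = len(seq)
    if L > len(subject):
        return []
    masks = _subject_masks(subject)
    hits: list[BindingSiteMatch] = []
    for strand, probe_seq in (("+", seq), ("-", reverse_complement(seq))):
        counts, miss = _scan(probe_seq, masks)
        for idx in np.nonzero(counts <= max_mismatches)[0]:
            window_miss = np.nonzero(miss[idx])[0]
            if strand == "+":
                positions = tuple(int(p) + 1 for p in window_miss)
            else:
                positions = tuple(sorted(L - int(p) for p in window_miss))
            hits.append(
                BindingSiteMatch(
                    sequence_id=sequence_id,
                    role=role,
                    strand=strand,
                    start=int(idx) + 1,
                    mismatches=int(counts[idx]),
                    mismatch_positions=positions,
                    three_prime_match=L not in positions,
                )
            )
    hits.sort(key=lambda h: (h.mismatches, h.start, h.strand))
    return hits


def predict_amplification(
    assay: AssayDefinition,
    subject: str,
    policy: ScreenPolicy | None = None,
    *,
    sequence_id: str = "",
) -> AmplificationPrediction:
    """Combine per-oligo hits into a positive/negative amplification call.

    Positive iff a forward hit on '+' and a reverse hit on '-' bracket a
    product within the length range, with the probe matching strictly
    between the primer footprints on either strand, all within per-oligo
    mismatch budgets. Among valid combinations the minimal-total-mismatch
    one is reported (ties: shorter product, then leftmost).
    """
    policy = policy or ScreenPolicy()
    subject = subject.strip().upper()

    def sites(oligo: Oligo) -> list[BindingSiteMatch]:
        found = find_binding_sites(
            oligo, subject, policy.budget(oligo.role), sequence_id=sequence_id
        )
        if policy.require_three_prime_match and oligo.role != "probe":
            found = [h for h in found if h.three_prime_match]
        return found

    f_hits = [h for h in sites(assay.forward) if h.strand == "+"]
    r_hits = [h for h in sites(assay.reverse) if h.strand == "-"]
    p_hits = sites(assay.probe)
    if not f_hits:
        return AmplificationPrediction(sequence_id, False, reason="no forward-primer site")
    if not r_hits:
        return AmplificationPrediction(sequence_id, False, reason="no reverse-primer site")

    lf, lr, lp = len(assay.forward), len(assay.reverse), len(assay.probe)
    best = None
    pair_seen = False
    for f in f_hits:
        f_end = f.start + lf - 1
        for r in r_hits:
            r_coord = r.start + lr - 1  # plus-strand position of the R 5' base
            if r.start <= f_end:
                continue
            pair_seen = True
            product = r_coord - f.start + 1
            if not policy.product_size[0] <= product <= policy.product_size[1]:
                continue
            for p in p_hits:
                if p.start <= f_end or p.start + lp - 1 >= r.start:
                    continue
                total = f.mismatches + r.mismatches + p.mismatches
                key = (total, product, f.start, p.start)
                if best is None or key < best[0]:
                    best = (key, f, r, p, product)
    if best is not None:
        _, f, r, p, product = best
        return AmplificationPrediction(
            sequence_id, True, forward=f, reverse=r, probe=p, product_length=product
        )
    if not pair_seen:
        return AmplificationPrediction(sequence_id, False, reason="wrong orientation")
    # distinguish product-range failure from missing probe
    in_range_pair = any(
        policy.product_size[0] <= (r.start + lr - 1) - f.start + 1 <= policy.product_size[1]
        for f in f_hits
        for r in r_hits
        if r.start > f.start + lf - 1
    )
    if not in_range_pair:
        return AmplificationPrediction(sequence_id, False, reason="product out of range")
    return AmplificationPrediction(sequence_id, False, reason="no probe site in product")


def mismatch_summary(
    assay: AssayDefinition,
    panel: dict[str, list[tuple[str, str]]],
    cap: int = 5,
) -> pd.DataFrame:
    """Per-group mean minimum-mismatch counts for each oligo.

    ``panel`` maps group label -> list of (sequence id, sequence). For each
    oligo the best (minimum-mismatch) site per sequence enters the mean;
    sequences with no site within ``cap`` mismatches are tallied as
    no-hit and excluded from that oligo's mean.
    """
    rows = []
    for group, seqs in panel.items():
        if not seqs:
            raise ValueError(f"group {group!r} is empty")
        record: dict[str, object] = {"group": group, "n_sequences": len(seqs)}
        for role in ("forward", "reverse", "probe"):
            oligo = getattr(assay, role)
            mins, no_hit = [], 0
            for _sid, seq in seqs:
                hits = find_binding_sites(oligo, seq, cap)
                if hits:
                    mins.append(min(h.mismatches for h in hits))
                else:
                    no_hit += 1
            record[f"mean_mismatches_{role}"] = (
                float(np.mean(mins)) if mins else float("nan")
            )
            record[f"no_hit_{role}"] = no_hit
        rows.append(record)
    return pd.DataFrame(rows)
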
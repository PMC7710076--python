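"""Multiple-alignment consumption: identity, consensus, binding-region logos.

Assay design starts from a multiple alignment of every available target
sequence (built externally, e.g. with MUSCLE or MAFFT). This module answers
the questions asked of that alignment: how similar are the targets
(mean pairwise identity), what single template represents them (consensus
with IUPAC fallback), and how conserved is each primer/probe binding
region across a panel (position frequency matrices, the data behind
sequence-logo plots).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .oligos import IUPAC_EXPANSION, Oligo, reverse_complement

__all__ = [
    "Alignment",
    "PositionFrequencyMatrix",
    "mean_pairwise_identity",
    "consensus_sequence",
    "window_frequencies",
    "count_variable_positions",
]

GAP = "-"

# base-set -> minimal IUPAC code
_SET_TO_CODE = {v: k for k, v in IUPAC_EXPANSION.items()}


@dataclass(frozen=True)
class Alignment:
    """An ordered multiple sequence alignment with unique row identifiers."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate identifiers: {dupes}")
        width = len(self.rows[0])
        for ident, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(
                    f"row {ident!r} has length {len(row)}, expected {width}"
                )
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))

    @classmethod
    def from_pairs(cls, pairs) -> "Alignment":
        ids, rows = zip(*pairs)
        return cls(tuple(ids), tuple(rows))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-column relative base frequencies over an alignment window.

    ``no_contigs`` marks the degenerate outcome where the oligo's binding
    region could not be located in any row of the panel (a perfectly valid
    specificity result: the region simply does not exist in the non-target
    group), in which case the matrix is empty.
    """

    label: str
    frequencies: tuple[dict[str, float], ...]
    n_rows: int

    def __post_init__(self) -> None:
        for i, col in enumerate(self.frequencies):
            total = sum(col.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"column {i} frequencies sum to {total}, not 1")
            if any(not (0.0 <= f <= 1.0) for f in col.values()):
                raise ValueError(f"column {i} has a frequency outside [0, 1]")

    @property
    def n_columns(self) -> int:
        return len(self.frequencies)

    @property
    def no_contigs(self) -> bool:
        return self.n_rows == 0


def mean_pairwise_identity(alignment: Alignment) -> float:
    """Mean percent identity over all unordered row pairs.

    For each pair only columns where both rows are ungapped enter the
    denominator; a pair with no shared ungapped column contributes nothing.
    """
    if alignment.n_rows < 2:
        raise ValueError("pairwise identity needs at least two rows")
    values = []
    for a, b in combinations(alignment.rows, 2):
        both = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
        if both:
            values.append(100.0 * sum(x == y for x, y in both) / len(both))
    if not values:
        raise ValueError("no pair shares an ungapped column")
    return sum(values) / len(values)


def consensus_sequence(alignment: Alignment, threshold: float = 1.0) -> str:
    """Column-wise consensus with minimal-IUPAC fallback.

    Per column: if one base reaches relative frequency >= ``threshold``
    among ungapped rows it is emitted; otherwise the minimal IUPAC code
    covering every base with nonzero frequency. Columns gapped in at least
    half the rows are dropped; minority gaps are ignored.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    out = []
    for col in zip(*alignment.rows):
        gaps = sum(c == GAP for c in col)
        if gaps * 2 >= len(col):
            continue
        bases = [c for c in col if c != GAP]
        counts = {b: bases.count(b) for b in set(bases)}
        top = max(counts, key=counts.get)
        if counts[top] / len(bases) >= threshold:
            out.append(top)
        else:
            covered = frozenset().union(*(IUPAC_EXPANSION[b] for b in counts))
            out.append(_SET_TO_CODE[covered])
    return "".join(out)


def _best_match(query: str, subject: str) -> tuple[int, int] | None:
    """(start, mismatches) of the best ungapped placement of query in subject."""
    L, n = len(query), len(subject)
    if n < L:
        return None
    # fast path: exact, then single-mismatch, then full scan
    pos = subject.find(query)
    if pos >= 0:
        return pos, 0
    best: tuple[int, int] | None = None
    for s in range(n - L + 1):
        mm = sum(q != t for q, t in zip(query, subject[s : s + L]))
        if best is None or mm < best[1]:
            best = (s, mm)
            if mm == 0:
                break
    return best


def window_frequencies(
    alignment: Alignment,
    oligo: Oligo,
    *,
    max_mismatch_frac: float = 0.35,
) -> PositionFrequencyMatrix:
    """Base frequencies over an oligo's binding window, 5'->3' in oligo coordinates.

    Each row is searched ungapped for the oligo (reverse primers are
    searched as their reverse complement and the recovered window is
    flipped back, so every matrix reads in the direction the oligo is
    written). Rows whose best placement exceeds ``max_mismatch_frac``
    mismatches contribute nothing; if no row qualifies the result is an
    empty matrix flagged ``no_contigs`` rather than an error.
    """
    query = (
        reverse_complement(oligo.sequence) if oligo.role == "reverse" else oligo.sequence
    )
    budget = int(max_mismatch_frac * len(query))
    windows: list[str] = []
    for row in alignment.rows:
        ungapped = row.replace(GAP, "")
        hit = _best_match(query, ungapped)
        if hit is None or hit[1] > budget:
            continue
        window = ungapped[hit[0] : hit[0] + len(query)]
        if oligo.role == "reverse":
            window = reverse_complement(window)
        windows.append(window)
    if not windows:
        return PositionFrequencyMatrix(label=oligo.name, frequencies=(), n_rows=0)
    freqs = []
    for col in zip(*windows):
        counts: dict[str, float] = {}
        for base in col:
            counts[base] = counts.get(base, 0) + 1
        freqs.append({b: c / len(windows) for b, c in sorted(counts.items())})
    return PositionFrequencyMatrix(
        label=oligo.name, frequencies=tuple(freqs), n_rows=len(windows)
    )


def count_variable_positions(pfm: PositionFrequencyMatrix) -> int:
    """Number of window positions where the panel is not perfectly conserved."""
    if pfm.n_columns == 0:
        raise ValueError("empty matrix (no contigs found)")
    return sum(max(col.values()) < 1.0 for col in pfm.frequencies)
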
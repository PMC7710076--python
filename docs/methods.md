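# Methods

This note records the models, parameter choices, and numerical decisions
behind `ednaqpcr`, and what the synthetic fixtures do and do not show
about real data.

## Melting-temperature model

Oligo Tm is the unified SantaLucia-1998 nearest-neighbor model
(Allawi–SantaLucia doublet parameters) evaluated through Biopython's
`MeltingTemp.Tm_NN`. Default solution conditions are the ones mainstream
primer-design software assumes for PCR:

| parameter | default | unit | note |
|---|---|---|---|
| monovalent cation | 50 | mM | Na⁺ equivalent |
| divalent cation | 1.5 | mM | Mg²⁺; Owczarzy-2008 correction |
| total dNTP | 0.6 | mM | subtracted from free Mg²⁺ |
| oligo concentration | 50 | nM | effective duplex conc. C_T/4 |

These defaults were chosen because they reproduce the Tm values printed
for all nine published reference oligos within ±0.5 °C; a
monovalent-only condition (no Mg²⁺) sits ≈ 6 °C lower and would place
every published oligo outside its own design window. With zero divalent
cation the entropy-based SantaLucia salt correction is used instead, and
that condition is the one cross-checked in the test suite against a
hand-transcribed nearest-neighbor table plus closed-form salt
correction (an independent implementation of the same published model).
Printed instrument-software Tm values are matched only within a
documented ±1.5 °C: the exact engine behind any published table is
generally unstated, so printed Tm is never treated as ground truth
beyond that tolerance. Tm is a duplex property — invariant under reverse
complementation — and increases with monovalent salt; both are asserted
numerically.

Oligos shorter than 8 nt are rejected (the doublet model is not
meaningful there). Ambiguity codes are rejected in oligos (designed
primers/probes are fully specified) but accepted in templates and
screening subjects. GC content is rounded to one decimal, half-up,
matching the convention of published assay tables (e.g. 63.6 % for a
14/22 probe).

## Alignment consumption

Multiple alignments are consumed, never computed — practitioners build
them with MUSCLE/MAFFT and this toolkit answers questions about them.
Mean pairwise identity excludes, per pair, any column where either row
is gapped. Consensus uses threshold 1.0 by default with minimal-IUPAC
fallback, because eDNA assay targets are typically ≥ 97 % identical and
a permissive threshold is rarely stressed; columns gapped in at least
half the rows are dropped, minority gaps ignored.

Binding-region conservation (the data behind sequence-logo plots) is
computed per row by ungapped search for the oligo — exact first, then
best Hamming placement — accepting rows whose best placement has at most
35 % mismatches (configurable). Reverse-primer windows are searched as
the reverse complement and flipped back, so every matrix reads 5′→3′ in
oligo coordinates. When no row contains the region the result is an
empty matrix flagged `no_contigs`, a legitimate specificity finding (the
binding region simply does not exist in the non-target group), not an
error. No logo-glyph rendering library is used: the position frequency
matrix is written as TSV and optionally rendered as a stacked bar chart.

## Candidate enumeration and ranking

Enumeration is exhaustive and deterministic: every
forward/probe/reverse placement satisfying all hard constraints is
generated by a streaming pass (bounded memory even when a long template
admits millions of triples); `top_n` candidates are selected by heap.
Window Tm/GC are duplex properties, so each window is evaluated once and
serves both primer orientations; the 3′-end report is orientation-
specific and cached both ways. Probes are emitted on the plus strand
only, matching the three published assays (probes may still *bind*
either strand during screening). Coordinates are 1-based inclusive; a
reverse primer's coordinate is the plus-strand position paired with its
5′ base, so product length is always R − F + 1 — the convention under
which the published oligo names (287F/437R etc.) reproduce the printed
amplicon lengths (151, 176, 130 nt).

Eight selection rules are scored pass/fail; primer-specific rules must
hold for *both* primers. The probe ΔTm rule is measured against the mean
of the two primer Tm values (the symmetric reading of "8–10 °C above the
primers"; min or max are reasonable alternatives and the window is
configurable). Ranking is a stable sort by criteria satisfied
(descending), then summed |Tm − optimum| over the three oligos, then
summed |GC − optimum|, then product length, then coordinates — fully
deterministic under input permutation.

## In-silico specificity

Matching is ungapped Hamming within footprints: assay oligos are
18–27 nt, where substitution tolerance dominates and indel tolerance in
the annealed duplex is minimal. This is a documented limitation — an
off-target with a 1-nt bulge would be missed. Subject IUPAC codes match
permissively (oligo base within the code's expansion). A subject is
predicted positive when a forward hit on +, a reverse hit on −, and a
probe hit strictly between the primer footprints (either strand)
co-occur with a product length in range, each oligo within its mismatch
budget (default 5, the conventional reporting cap for binding-site
summaries); among valid combinations the minimal-total-mismatch one is
reported, ties broken by shorter product then leftmost position. A
`require_three_prime_match` toggle exists because extension is
3′-sensitive, but is off by default: combining per-oligo hits without
that requirement is the conservative (more cross-reactive) screen.
Negative calls carry a reason with precedence: no forward site → no
reverse site → wrong orientation → product out of range → no probe site.

## Plate analytics

Cq is regressed on log₁₀(concentration) — the universal standard-curve
orientation, under which slope ≈ −3.32 means 100 % efficiency. The LOQ
scan walks the dilution series downward from the highest concentration
and stops at the first level with any dropout, so every concentration
above the LOQ is fully detected by construction; within-plate
consistency is what is implemented. Standards below the LOQ are excluded
from the fit because partially detected levels censor high-Cq replicates
and bias the slope shallow. A non-negative fitted slope is flagged
invalid rather than silently accepted.

Sample calls: a replicate is positive iff its Cq is below the LOQ mean
Cq; non-detects are negative. A detected replicate at or above the LOQ
Cq is by default counted as a detection that cannot be quantified
(BLOQ) — the rule is explicit and configurable to "negative" because
published validation datasets have typically not had to decide it.
Aggregation: all replicates quantifiable → quantified; any detection →
BLOQ; none → ND. Sensitivity/specificity percentages round half-up to
integers for parity with published validation tables. NTC wells with any
Cq raise a contamination warning and never enter curves or metrics.

Environmental back-calculation inverts the curve per replicate
(pg/µL template), then multiplies by template volume, dilution factor
and extract/template volume ratio, and divides by filtered water volume
to reach pg per mL of water. The 95 % interval is Student-t with n−1
degrees of freedom on replicate-level concentrations — a choice, since
published tables print intervals without stating a method. Published
water-concentration values are not reproduced here because the
extraction and elution volumes behind them are not public.

## Synthetic fixtures

Panels plant a forward | spacer | probe | spacer | reverse-complement
cassette with exact numbers of substitutions per footprint on uniform
(optionally GC-skewed) background; the truth table is the expected
screening call by construction. Plates follow
Cq = b + m·log₁₀C + N(0, σ) with per-replicate dropout below a
full-detection threshold and a hard 40-cycle censor (an instrument never
reports Cq > run length). Defaults mirror common validation practice:
six ten-fold dilutions from 100 pg/µL extract (200 pg per 2-µL-template
reaction) down to 0.001 pg/µL, triplicate, σ = 0.15 cycles, slope −3.4
(≈ 97 % efficiency), intercept 34.5 (placing the 0.1 pg/µL level near
Cq 38, just inside the run), fully detected down to 0.1 pg/µL.

What the fixtures do not emulate: amplification kinetics, inhibition,
probe chemistry differences, inter-individual mitochondrial copy-number
variation, or cross-contamination. Passing tests therefore demonstrate
the correctness of the computations, not field performance of any assay.
All generators take an explicit seed and use a private
`numpy.random.Generator`; identical specs are byte-identical.

## Problem sizes used in tests

Oracle-equivalence tests run exhaustive brute-force enumeration on
130–200 bp templates with a 60–120 bp product window (tens to hundreds
of thousands of triples), binding-site scans against 1,000 random
subjects, 1,000 random LOQ dropout patterns, and 500 seeded
standard-curve refits — sizes chosen so the full suite documents the
claimed equivalences while finishing in well under a minute on one core.

## Known limitations

* No secondary-structure screening (hairpins, self/cross-dimers) and no
  multiplex compatibility checks.
* No thermodynamic (ΔG) off-target scoring; mismatch counts treat all
  positions equally apart from the optional 3′-terminal toggle.
* Remote sequence databases are out of scope: screening panels are
  user-supplied FASTA.
* Cq values are consumed as given; fluorescence processing and threshold
  setting belong to the instrument.
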
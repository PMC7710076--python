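# ednaqpcr

Design and validation toolkit for species-specific hydrolysis-probe
(TaqMan-style) qPCR assays targeting environmental DNA (eDNA).

Monitoring aquatic species from the DNA they shed into water requires,
for each species, a qPCR assay that is *sensitive* (detects every true
target), *specific* (stays silent on co-occurring relatives), and
*efficient* (near-perfect per-cycle doubling). Building such an assay is
a pipeline: align all available target sequences, pick a conserved
template region, enumerate primer/probe candidates under chemistry
constraints, audit them against selection rules, screen them in silico
against non-target panels, and finally validate wet-lab results —
standard curves, limit of quantification (LOQ), panel
sensitivity/specificity, and back-calculated eDNA concentrations in the
sampled water. `ednaqpcr` implements every computational step of that
pipeline for researchers developing new eDNA assays, and ships the three
published reference assays it was validated against (humpback whale
d-loop, shortbelly rockfish COI, common murre COI).

## The quantities at the core

**Oligo physics.** Melting temperatures are unified SantaLucia-1998
nearest-neighbor values with the Owczarzy divalent-cation correction at
PCR-like defaults (50 mM Na⁺, 1.5 mM Mg²⁺, 0.6 mM dNTP, 50 nM oligo,
duplex concentration C_T/4). GC content is reported to one decimal,
half-up.

**Design constraints and selection criteria.** Hard bounds (product
100–200 bp; oligos 18–27 nt, optimum 20; primer Tm 58–63 °C, optimum 60;
probe Tm 68–73 °C, optimum 70; GC 35–65 %) define the candidate space;
eight pass/fail selection rules (primer ΔTm < 5 °C; probe Tm 8–10 °C
above the primer mean; no homopolymer run ≥ 4; no 3′-terminal T on a
primer; 3′-terminal G/C clamp; ≥ 3 G/C in the last five primer bases; no
5′-terminal G on the probe; probe GC > 50 %) rank the survivors.

**In-silico specificity.** Ungapped mismatch-tolerant binding-site search
on both strands; a subject is predicted positive when a forward hit (+),
a reverse hit (−) and a probe hit strictly inside the product co-occur
within per-oligo mismatch budgets (default ≤ 5) and product-length range.

**Standard-curve analytics.** Ordinary least squares of
Cq = m·log₁₀(C) + b over detected standards at or above the LOQ;
efficiency E = (10^(−1/m) − 1)·100, so perfect doubling means
m = −1/log₁₀2 ≈ −3.32 and E = 100 %. The LOQ is the lowest standard
concentration with all replicates assigned a Cq, every higher
concentration also fully detected. Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP). Environmental concentrations follow the
dimensional chain template → reaction → extract → volume of water
filtered, with Student-t 95 % intervals over replicates.

## Worked example

Audit a published assay against the eight selection criteria:

```python
from ednaqpcr import score_candidate
from ednaqpcr.published import PUBLISHED_ASSAYS

scored = score_candidate(PUBLISHED_ASSAYS["humpback_whale"])
for c in scored.criteria:
    print(f"{c.name:22s} {c.measured:8s} {'pass' if c.passed else 'FAIL'}")
print("satisfied:", scored.satisfied, "/ 8")
```

```
primer_delta_tm_lt     0.11     pass
probe_delta_tm_window  9.71     pass
no_homopolymer_run     3        pass
no_primer_3prime_t     A,G      pass
primer_3prime_gc       A,G      FAIL
gc_in_last5            3,3      pass
no_probe_5prime_g      T        pass
probe_gc_gt_50         63.6     pass
satisfied: 7 / 8
```

The one failure is real: the humpback forward primer (287F) ends in A,
so it lacks the 3′ G/C clamp — exactly what a manual audit of the
printed sequence finds.

Simulate a standard-curve plate and validate it end to end:

```bash
ednaqpcr simulate --kind plate --seed 7 --out plate.csv
ednaqpcr validate --plate plate.csv --out report/
```

```
curve: slope=-3.4192 efficiency=96.1% LOQ=0.1
```

`report/curve.json` then holds the full fit: slope −3.4192 (true
simulated slope −3.4), intercept 34.49, R² 0.9994, efficiency 96.1 %,
and LOQ 0.1 pg/µL with mean Cq 37.9 at that level — the dilution level
below which simulated replicates start dropping out, recovered exactly.

Other subcommands: `design` (enumerate and rank candidates on a template
FASTA), `screen` (predict amplification across a FASTA panel), `logo`
(position-frequency matrix of a binding region in an alignment, the data
behind sequence-logo conservation plots).

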
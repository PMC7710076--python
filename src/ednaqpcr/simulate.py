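"""Seeded synthetic data: sequence panels with planted sites and qPCR plates.

Every generator takes an explicit seed and uses its own
``numpy.random.Generator`` — no global random state — so identical specs
give byte-identical outputs.

Panels emulate target/non-target tissue panels at the sequence level:
each subject either carries a planted forward/probe/reverse-complement
cassette (with a chosen number of substitutions per oligo footprint) on a
random background, or is pure background. The truth table records the
expected in-silico amplification call for each subject under stated
mismatch budgets.

Plates emulate a standard-curve dilution series under the usual forward
model ``Cq = intercept + slope * log10(conc) + N(0, sigma)``, with
per-replicate dropout (ND) below a full-detection threshold. The default
series mirrors common validation practice: ten-fold dilutions from
100 pg/uL of extract (200 pg per 2-uL-template reaction) down six steps
to 0.001 pg/uL (2 fg per reaction), in triplicate, fully detected down to
0.1 pg/uL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import AssayDefinition
from .oligos import reverse_complement
from .screen import ScreenPolicy

__all__ = [
    "SequencePlan",
    "PanelSpec",
    "PlateSpec",
    "generate_panel",
    "generate_plate",
    "random_panel_spec",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SequencePlan:
    """Planted configuration for one synthetic subject sequence.

    Mismatch counts are numbers of substitutions planted into the
    corresponding oligo footprint; ``present=False`` yields pure
    background. Spacers separate F|spacer1|P|spacer2|revcomp(R).
    """

    present: bool = True
    f_mismatches: int = 0
    r_mismatches: int = 0
    p_mismatches: int = 0
    spacer1: int = 20
    spacer2: int = 20
    left_pad: int = 30
    right_pad: int = 30

    def __post_init__(self) -> None:
        if min(self.spacer1, self.spacer2, self.left_pad, self.right_pad) < 0:
            raise ValueError("spacer and pad lengths must be >= 0")
        if min(self.f_mismatches, self.r_mismatches, self.p_mismatches) < 0:
            raise ValueError("mismatch counts must be >= 0")


@dataclass(frozen=True)
class PanelSpec:
    """A seeded panel of subjects with known planted configurations."""

    assay: AssayDefinition
    plans: tuple[SequencePlan, ...]
    seed: int
    gc_fraction: float = 0.5
    policy: ScreenPolicy = field(default_factory=ScreenPolicy)

    def __post_init__(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        for plan in self.plans:
            for role, count in (
                ("forward", plan.f_mismatches),
                ("reverse", plan.r_mismatches),
                ("probe", plan.p_mismatches),
            ):
                if count > len(getattr(self.assay, role)):
                    raise ValueError(
                        f"cannot plant {count} mismatches in the {role} oligo "
                        f"({len(getattr(self.assay, role))} nt)"
                    )


def _background(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p)) if length else ""


def _mutate(rng: np.random.Generator, seq: str, n: int) -> str:
    """Plant exactly n substitutions at distinct random positions."""
    if n == 0:
        return seq
    positions = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_panel(spec: PanelSpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit (records, truth table) for a planted-cassette panel.

    Records are (id, sequence) pairs. The truth table gives, per subject,
    the planted mismatch counts, the expected product length, and the
    expected positive/negative call under the spec's screening policy.
    """
    rng = np.random.default_rng(spec.seed)
    assay, policy = spec.assay, spec.policy
    records, truth = [], []
    for i, plan in enumerate(spec.plans):
        sid = f"seq{i + 1:04d}"
        if plan.present:
            f = _mutate(rng, assay.forward.sequence, plan.f_mismatches)
            p = _mutate(rng, assay.probe.sequence, plan.p_mismatches)
            r = _mutate(rng, reverse_complement(assay.reverse.sequence), plan.r_mismatches)
            seq = (
                _background(rng, plan.left_pad, spec.gc_fraction)
                + f
                + _background(rng, plan.spacer1, spec.gc_fraction)
                + p
                + _background(rng, plan.spacer2, spec.gc_fraction)
                + r
                + _background(rng, plan.right_pad, spec.gc_fraction)
            )
            product = (
                len(assay.forward)
                + plan.spacer1
                + len(assay.probe)
                + plan.spacer2
                + len(assay.reverse)
            )
            expected = (
                plan.f_mismatches <= policy.budget("forward")
                and plan.r_mismatches <= policy.budget("reverse")
                and plan.p_mismatches <= policy.budget("probe")
                and policy.product_size[0] <= product <= policy.product_size[1]
            )
        else:
            length = (
                plan.left_pad
                + len(assay.forward)
                + plan.spacer1
                + len(assay.probe)
                + plan.spacer2
                + len(assay.reverse)
                + plan.right_pad
            )
            seq = _background(rng, length, spec.gc_fraction)
            product = None
            expected = False
        records.append((sid, seq))
        truth.append(
            {
                "sequence_id": sid,
                "present": plan.present,
                "f_mismatches": plan.f_mismatches,
                "r_mismatches": plan.r_mismatches,
                "p_mismatches": plan.p_mismatches,
                "product_length": product,
                "expected_positive": expected,
            }
        )
    return records, pd.DataFrame(truth)


def random_panel_spec(
    assay: AssayDefinition,
    n_sequences: int,
    seed: int,
    *,
    max_planted_mismatches: int = 7,
    absent_fraction: float = 0.2,
    policy: ScreenPolicy | None = None,
) -> PanelSpec:
    """Randomized plans: a mix of absent, clean, and mutated cassettes."""
    rng = np.random.default_rng(seed)
    plans = []
    for _ in range(n_sequences):
        if rng.random() < absent_fraction:
            plans.append(SequencePlan(present=False))
            continue
        plans.append(
            SequencePlan(
                present=True,
                f_mismatches=int(rng.integers(0, max_planted_mismatches + 1)),
                r_mismatches=int(rng.integers(0, max_planted_mismatches + 1)),
                p_mismatches=int(rng.integers(0, max_planted_mismatches + 1)),
                spacer1=int(rng.integers(10, 40)),
                spacer2=int(rng.integers(10, 40)),
            )
        )
    return PanelSpec(
        assay=assay,
        plans=tuple(plans),
        seed=int(rng.integers(2**31)),
        policy=policy or ScreenPolicy(),
    )


@dataclass(frozen=True)
class PlateSpec:
    """Forward model for a synthetic standard-curve plate."""

    seed: int
    slope: float = -3.4
    intercept: float = 34.5
    sigma: float = 0.15
    start_conc: float = 100.0      # pg/uL extract (200 pg per 2-uL reaction)
    fold: float = 10.0
    steps: int = 6
    detection_threshold: float = 0.1   # fully detected at/above this conc
    dropout_prob: float = 0.5          # per-replicate ND probability below it
    replicates: int = 3
    template_ul: float = 2.0

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(self.start_conc / self.fold**i for i in range(self.steps))


def generate_plate(spec: PlateSpec) -> pd.DataFrame:
    """Simulate a dilution-series plate in the plate-CSV dialect.

    ``Cq = intercept + slope * log10(conc) + N(0, sigma)`` per replicate;
    below the detection threshold each replicate independently drops out
    (empty ``cq``) with the spec's probability, and any Cq beyond the
    40-cycle run length is a non-detect (the instrument never reports
    one). Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for conc in spec.concentrations:
        for rep in range(1, spec.replicates + 1):
            cq = spec.intercept + spec.slope * np.log10(conc) + rng.normal(0, spec.sigma)
            dropped = (
                conc < spec.detection_threshold and rng.random() < spec.dropout_prob
            ) or cq > 40.0
            rows.append(
                {
                    "sample_id": f"std_{conc:g}",
                    "role": "standard",
                    "replicate": rep,
                    "cq": "" if dropped else round(float(cq), 3),
                    "known_conc_pg_per_ul": conc,
                    "template_ul": spec.template_ul,
                }
            )
    return pd.DataFrame(rows)
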
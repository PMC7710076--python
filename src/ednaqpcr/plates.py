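"""Plate-level qPCR analytics: standard curves, LOQ, calls, quantification.

The workflow mirrors standard wet-lab validation of a new assay:

* A dilution series of genomic DNA (the *standards*) yields a standard
  curve — ordinary least squares of Cq on log10(concentration). The slope
  gives amplification efficiency, ``E = (10^(-1/slope) - 1) * 100``;
  a perfectly doubling reaction has slope -1/log10(2) = -3.3219 and 100%
  efficiency.
* The limit of quantification (LOQ) is the lowest standard concentration
  at which every replicate was assigned a Cq, with all higher
  concentrations also fully detected. Standards below the LOQ are
  excluded from the curve fit (partial-detection points bias the slope).
* Unknown samples are called per replicate (positive iff Cq below the
  LOQ Cq; non-detects are negative) and aggregated: all replicates
  positive -> quantified, some -> detected but below the limit of
  quantification (BLOQ), none -> ND.
* Environmental concentrations are back-calculated from Cq through the
  curve and the dimensional chain template -> reaction -> extract ->
  volume of water filtered, with a Student-t 95% confidence interval
  over replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Reaction",
    "StandardCurve",
    "LoqResult",
    "SampleCall",
    "PanelResult",
    "ConcentrationEstimate",
    "read_plate_csv",
    "fit_standard_curve",
    "determine_loq",
    "call_sample",
    "panel_metrics",
    "quantify_environmental",
    "efficiency_from_slope",
]

MAX_CYCLES = 40

RoleName = Literal["standard", "target-tissue", "non-target-tissue", "environmental", "NTC"]


@dataclass(frozen=True)
class Reaction:
    """One well: a sample replicate with a Cq or a non-detect flag."""

    sample_id: str
    role: str
    replicate: int
    cq: float | None = None
    known_conc_pg_per_ul: float | None = None
    template_ul: float = 2.0

    def __post_init__(self) -> None:
        if self.cq is not None and not 0 < self.cq <= MAX_CYCLES:
            raise ValueError(
                f"{self.sample_id} rep {self.replicate}: Cq {self.cq} outside (0, {MAX_CYCLES}]"
            )
        if self.role == "standard" and (
            self.known_conc_pg_per_ul is None or self.known_conc_pg_per_ul <= 0
        ):
            raise ValueError(f"standard {self.sample_id}: needs a positive known concentration")

    @property
    def is_detect(self) -> bool:
        return self.cq is not None


@dataclass(frozen=True)
class LoqResult:
    concentration: float | None
    cq: float | None

    @property
    def defined(self) -> bool:
        return self.concentration is not None


@dataclass(frozen=True)
class StandardCurve:
    """Cq = slope * log10(concentration) + intercept, plus derived metrics."""

    slope: float
    intercept: float
    r_squared: float
    efficiency_pct: float
    loq: LoqResult
    n_points: int
    concentrations: tuple[float, ...]

    @property
    def valid(self) -> bool:
        return self.slope < 0

    def concentration_at(self, cq: float) -> float:
        """Invert the curve: template concentration (pg/uL) for a Cq."""
        return 10 ** ((cq - self.intercept) / self.slope)


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent from a standard-curve slope."""
    return (10 ** (-1.0 / slope) - 1.0) * 100.0


def _parse_cq(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text == "" or text.upper() == "ND":
        return None
    return float(text)


def read_plate_csv(path) -> list[Reaction]:
    """Read the plate CSV dialect.

    Columns: ``sample_id,role,replicate,cq,known_conc_pg_per_ul,template_ul``;
    ``cq`` empty or "ND" marks a non-detect. Lines starting with '#' are
    comments. NTC wells with any Cq raise a contamination warning.
    """
    df = pd.read_csv(path, comment="#", dtype={"sample_id": str, "role": str})
    required = {"sample_id", "role", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    reactions = []
    for row in df.itertuples(index=False):
        conc = getattr(row, "known_conc_pg_per_ul", None)
        if conc is not None and isinstance(conc, float) and math.isnan(conc):
            conc = None
        template = getattr(row, "template_ul", 2.0)
        if isinstance(template, float) and math.isnan(template):
            template = 2.0
        reactions.append(
            Reaction(
                sample_id=str(row.sample_id),
                role=str(row.role),
                replicate=int(row.replicate),
                cq=_parse_cq(row.cq),
                known_conc_pg_per_ul=conc,
                template_ul=float(template),
            )
        )
    ntc_hits = [r for r in reactions if r.role.upper() == "NTC" and r.is_detect]
    if ntc_hits:
        import warnings

        warnings.warn(
            f"{len(ntc_hits)} no-template-control well(s) amplified "
            f"(e.g. {ntc_hits[0].sample_id} Cq={ntc_hits[0].cq}); possible contamination",
            stacklevel=2,
        )
    return reactions


def _standards_by_conc(standards: Iterable[Reaction]) -> dict[float, list[Reaction]]:
    groups: dict[float, list[Reaction]] = {}
    for r in standards:
        if r.role != "standard":
            continue
        groups.setdefault(float(r.known_conc_pg_per_ul), []).append(r)
    return groups


def determine_loq(
    standards: Iterable[Reaction], replicates_required: int = 3
) -> LoqResult:
    """Lowest fully detected standard concentration, scanning downward.

    A concentration qualifies when it has at least ``replicates_required``
    replicates and every replicate has a Cq; the scan walks down from the
    highest concentration and stops at the first failure, so every
    concentration above the LOQ is also fully detected. Returns an
    undefined (flagged) result when even the highest concentration has
    dropouts.
    """
    groups = _standards_by_conc(standards)
    if not groups:
        raise ValueError("no standard reactions supplied")
    loq_conc = None
    for conc in sorted(groups, reverse=True):
        reps = groups[conc]
        if len(reps) >= replicates_required and all(r.is_detect for r in reps):
            loq_conc = conc
        else:
            break
    if loq_conc is None:
        return LoqResult(None, None)
    cqs = [r.cq for r in groups[loq_conc]]
    return LoqResult(loq_conc, float(np.mean(cqs)))


def fit_standard_curve(
    standards: Iterable[Reaction], replicates_required: int = 3
) -> StandardCurve:
    """OLS of Cq on log10(concentration) over detected replicates at/above LOQ."""
    standards = [r for r in standards if r.role == "standard"]
    loq = determine_loq(standards, replicates_required)
    usable = [
        r
        for r in standards
        if r.is_detect and (not loq.defined or r.known_conc_pg_per_ul >= loq.concentration)
    ]
    concs = sorted({float(r.known_conc_pg_per_ul) for r in usable})
    if len(concs) < 3:
        raise ValueError(
            f"need >= 3 distinct usable standard concentrations, have {len(concs)}"
        )
    x = np.log10([r.known_conc_pg_per_ul for r in usable])
    y = np.array([r.cq for r in usable])
    fit = stats.linregress(x, y)
    curve = StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency_pct=float(efficiency_from_slope(fit.slope)),
        loq=loq,
        n_points=len(usable),
        concentrations=tuple(concs),
    )
    if not curve.valid:
        import warnings

        warnings.warn(
            f"standard curve has non-negative slope {curve.slope:.3f}; flagged invalid",
            stacklevel=2,
        )
    return curve


@dataclass(frozen=True)
class SampleCall:
    sample_id: str
    status: Literal["quantified", "BLOQ", "ND"]
    replicate_positive: tuple[bool, ...]
    n_detects: int


def call_sample(
    reactions: Iterable[Reaction],
    curve: StandardCurve,
    *,
    above_loq: Literal["detect", "negative"] = "detect",
) -> dict[str, SampleCall]:
    """Per-sample detection calls against the curve's LOQ Cq.

    A replicate is positive iff it has a Cq below the LOQ Cq; non-detects
    are negative. A detected replicate with Cq at or above the LOQ Cq is,
    by default, counted as a detection that cannot be quantified
    (``above_loq="detect"``); set ``above_loq="negative"`` to treat it as
    negative. Sample status: all replicates positive -> quantified; some
    detection -> BLOQ; none -> ND.
    """
    if not curve.loq.defined:
        raise ValueError("curve has no defined LOQ; cannot call samples")
    by_sample: dict[str, list[Reaction]] = {}
    for r in reactions:
        by_sample.setdefault(r.sample_id, []).append(r)
    calls = {}
    for sid, reps in by_sample.items():
        reps = sorted(reps, key=lambda r: r.replicate)
        quantifiable = [r.is_detect and r.cq < curve.loq.cq for r in reps]
        detected = [
            r.is_detect and (above_loq == "detect" or r.cq < curve.loq.cq) for r in reps
        ]
        if all(quantifiable):
            status = "quantified"
        elif any(detected):
            status = "BLOQ"
        else:
            status = "ND"
        calls[sid] = SampleCall(
            sample_id=sid,
            status=status,
            replicate_positive=tuple(quantifiable),
            n_detects=sum(detected),
        )
    return calls


def _pct_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal(1), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PanelResult:
    """Sensitivity/specificity over a labeled target/non-target panel."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def sensitivity_pct(self) -> int:
        if self.tp + self.fn == 0:
            raise ValueError("no target samples")
        return _pct_half_up(100.0 * self.tp / (self.tp + self.fn))

    @property
    def specificity_pct(self) -> int:
        if self.tn + self.fp == 0:
            raise ValueError("no non-target samples")
        return _pct_half_up(100.0 * self.tn / (self.tn + self.fp))


def panel_metrics(
    detected: Mapping[str, bool], labels: Mapping[str, str]
) -> PanelResult:
    """Confusion counts and rates from per-sample detections and labels.

    ``labels`` maps sample id -> "target" or "non-target"; every sample in
    ``detected`` must be labeled. Percentages round half-up to integers,
    the convention of published validation tables.
    """
    if not detected:
        raise ValueError("empty panel")
    tp = fn = tn = fp = 0
    for sid, hit in detected.items():
        if sid not in labels:
            raise ValueError(f"sample {sid!r} has no target/non-target label")
        label = labels[sid]
        if label == "target":
            tp, fn = (tp + 1, fn) if hit else (tp, fn + 1)
        elif label == "non-target":
            fp, tn = (fp + 1, tn) if hit else (fp, tn + 1)
        else:
            raise ValueError(f"sample {sid!r}: label must be target/non-target, got {label!r}")
    return PanelResult(tp=tp, fn=fn, tn=tn, fp=fp)


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Back-calculated eDNA concentration in the sampled water."""

    sample_id: str
    status: Literal["quantified", "BLOQ", "ND"]
    mean_pg_per_ml: float | None
    ci95_half_width: float | None
    n_replicates: int
    dilution_factor: float
    extract_volume_ul: float
    filtered_volume_ml: float


def quantify_environmental(
    reactions: Iterable[Reaction],
    curve: StandardCurve,
    dilution_factor: float,
    extract_volume_ul: float,
    filtered_volume_ml: float,
    *,
    above_loq: Literal["detect", "negative"] = "detect",
) -> list[ConcentrationEstimate]:
    """Per-sample water-column eDNA concentration with 95% CI.

    Per replicate the dimensional chain is: Cq -> pg/uL template (curve
    inversion), x template volume -> pg/reaction, x dilution factor and
    x (extract volume / template volume) -> pg in the whole extract,
    / filtered volume -> pg per mL of water. The mean and a Student-t 95%
    interval (n-1 df) are taken over replicates. BLOQ and ND samples never
    produce a number.
    """
    if min(dilution_factor, extract_volume_ul, filtered_volume_ml) <= 0:
        raise ValueError("dilution factor and volumes must be > 0")
    if not curve.valid:
        raise ValueError("cannot quantify against an invalid (non-negative slope) curve")
    by_sample: dict[str, list[Reaction]] = {}
    for r in reactions:
        by_sample.setdefault(r.sample_id, []).append(r)
    calls = call_sample(reactions, curve, above_loq=above_loq)
    out = []
    for sid, reps in by_sample.items():
        call = calls[sid]
        if call.status != "quantified":
            out.append(
                ConcentrationEstimate(
                    sid, call.status, None, None, len(reps),
                    dilution_factor, extract_volume_ul, filtered_volume_ml,
                )
            )
            continue
        per_rep = []
        for r in sorted(reps, key=lambda r: r.replicate):
            pg_per_ul_template = curve.concentration_at(r.cq)
            pg_reaction = pg_per_ul_template * r.template_ul
            pg_extract = pg_reaction * dilution_factor * (extract_volume_ul / r.template_ul)
            per_rep.append(pg_extract / filtered_volume_ml)
        arr = np.asarray(per_rep)
        mean = float(arr.mean())
        if len(arr) > 1 and arr.std(ddof=1) > 0:
            half = float(
                stats.t.ppf(0.975, len(arr) - 1) * arr.std(ddof=1) / math.sqrt(len(arr))
            )
        else:
            half = 0.0
        out.append(
            ConcentrationEstimate(
                sid, "quantified", mean, half, len(arr),
                dilution_factor, extract_volume_ul, filtered_volume_ml,
            )
        )
    return out
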
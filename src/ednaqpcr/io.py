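"""Shared file formats: FASTA, aligned FASTA, PFM TSV, assay YAML, config.

All writers emit a header comment naming the tool version (and a config
hash when a config is in play) so outputs are traceable. Coordinates in
outputs are 1-based inclusive and labeled as such.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from . import __version__
from .align import Alignment, PositionFrequencyMatrix
from .design import AssayDefinition, DesignConstraints, SelectionCriteria
from .oligos import IUPAC_EXPANSION, Oligo, ThermoParams
from .screen import ScreenPolicy

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_pfm_tsv",
    "read_assay_yaml",
    "write_assay_yaml",
    "RunConfig",
    "load_config",
    "config_hash",
]

_TEMPLATE_ALPHABET = set(IUPAC_EXPANSION) | {"-"}


def read_fasta(path, *, alphabet: str = "template") -> list[tuple[str, str]]:
    """Read FASTA into (id, uppercase sequence) pairs.

    ``alphabet="template"`` accepts IUPAC ambiguity codes and gaps;
    ``alphabet="oligo"`` accepts strict A/C/G/T only. Duplicate ids and
    empty files are errors. CRLF and LF line endings parse identically
    (delegated to Bio.SeqIO).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate record ids {dupes}")
    permitted = set("ACGT") if alphabet == "oligo" else _TEMPLATE_ALPHABET
    out = []
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - permitted
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} has characters {sorted(bad)} "
                f"not permitted for alphabet={alphabet!r}"
            )
        out.append((rec.id, seq))
    return out


def write_fasta(records, path, *, width: int = 70) -> None:
    with open(path, "w") as fh:
        for ident, seq in records:
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path) -> Alignment:
    """Read aligned FASTA; mixed row lengths are an error."""
    records = read_fasta(path)
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise ValueError(
            f"{path}: rows have mixed lengths {sorted(lengths)}; not an alignment"
        )
    return Alignment.from_pairs(records)


def write_pfm_tsv(pfm: PositionFrequencyMatrix, path, *, header_extra: str = "") -> None:
    """Write a PFM as TSV: rows A/C/G/T, columns 1-based window positions."""
    with open(path, "w") as fh:
        fh.write(f"# ednaqpcr {__version__} pfm label={pfm.label} n_rows={pfm.n_rows}")
        if pfm.no_contigs:
            fh.write(" no_contigs=true")
        if header_extra:
            fh.write(f" {header_extra}")
        fh.write("\n")
        cols = range(1, pfm.n_columns + 1)
        fh.write("base\t" + "\t".join(str(c) for c in cols) + "\n")
        for base in "ACGT":
            freqs = [f"{col.get(base, 0.0):.6g}" for col in pfm.frequencies]
            fh.write(base + "\t" + "\t".join(freqs) + "\n")


def read_oligo_tsv(path) -> list[Oligo]:
    """Read oligos from three-column TSV: name, role, sequence."""
    oligos = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            name, role, seq = parts
            oligos.append(Oligo(name=name, sequence=seq, role=role))  # type: ignore[arg-type]
    if not oligos:
        raise ValueError(f"{path}: no oligos found")
    return oligos


def write_oligo_tsv(oligos, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ednaqpcr {__version__} name\trole\tsequence\n")
        for o in oligos:
            fh.write(f"{o.name}\t{o.role}\t{o.sequence}\n")


def read_assay_yaml(path) -> AssayDefinition:
    """Read an assay definition (F/R/P oligos + protocol metadata) from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    oligos = {}
    for role in ("forward", "reverse", "probe"):
        if role not in data:
            raise ValueError(f"{path}: assay YAML missing {role!r}")
        entry = data[role]
        if isinstance(entry, str):
            entry = {"name": f"{role[0].upper()}", "sequence": entry}
        oligos[role] = Oligo(
            name=str(entry.get("name", role[0].upper())),
            sequence=entry["sequence"],
            role=role,
            reporter=entry.get("reporter"),
            quencher=entry.get("quencher"),
        )
    return AssayDefinition(
        name=str(data.get("name", Path(str(path)).stem)),
        concentrations_uM={
            k: float(v) for k, v in (data.get("concentrations_uM") or {}).items()
        },
        annealing_temp_c=data.get("annealing_temp_c"),
        cq_threshold=data.get("cq_threshold"),
        **oligos,
    )


def write_assay_yaml(assay: AssayDefinition, path) -> None:
    data = {
        "name": assay.name,
        **{
            role: {
                "name": o.name,
                "sequence": o.sequence,
                **({"reporter": o.reporter} if o.reporter else {}),
                **({"quencher": o.quencher} if o.quencher else {}),
            }
            for role, o in (
                ("forward", assay.forward),
                ("reverse", assay.reverse),
                ("probe", assay.probe),
            )
        },
    }
    if assay.concentrations_uM:
        data["concentrations_uM"] = dict(assay.concentrations_uM)
    if assay.annealing_temp_c is not None:
        data["annealing_temp_c"] = assay.annealing_temp_c
    if assay.cq_threshold is not None:
        data["cq_threshold"] = assay.cq_threshold
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration assembled from YAML + built-in defaults."""

    thermo: ThermoParams = field(default_factory=ThermoParams)
    constraints: DesignConstraints = field(default_factory=DesignConstraints)
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    policy: ScreenPolicy = field(default_factory=ScreenPolicy)


_SECTIONS = {
    "thermo": ThermoParams,
    "constraints": DesignConstraints,
    "criteria": SelectionCriteria,
    "policy": ScreenPolicy,
}

_TUPLE_FIELDS = {"product_size", "oligo_size", "primer_tm", "probe_tm", "gc_pct", "probe_delta_tm"}


def load_config(path=None) -> RunConfig:
    """Load a YAML config; unknown sections or keys are rejected by name."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"{path}: unknown config section(s): {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        entries = data.get(section) or {}
        allowed = set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
        bad = set(entries) - allowed
        if bad:
            raise ValueError(f"{path}: unknown key(s) in [{section}]: {sorted(bad)}")
        entries = {
            k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
            for k, v in entries.items()
        }
        kwargs[section] = cls(**entries)
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Short stable digest of a run configuration for output headers."""
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
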
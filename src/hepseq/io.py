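"""File formats and run configuration.

All tabular formats are plain UTF-8 CSV with a mandatory header row
(sequence strings, which contain en dashes, are quoted by the CSV writer
as needed): peak lists (``mz, z, intensity``), digest products
(``sequence, composition, neutral_mass, count, role``) and fragment
annotations.  Evidence records travel as JSON.  Sequence collections are
plain text, one sequence per line with ``#`` comments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .digestion import DigestResult
from .inference import EvidenceRecord
from .masses import neutral_mass
from .nomenclature import (
    CompositionCode,
    GAGSequence,
    composition_of,
    format_sequence,
    parse_code,
    parse_sequence,
)
from .nomenclature import read_sequences as _read_sequence_lines

__all__ = [
    "RunConfig",
    "load_config",
    "read_sequences",
    "read_peaklist",
    "write_peaklist",
    "products_frame",
    "write_products",
    "read_evidence",
    "write_evidence",
]

log = logging.getLogger("hepseq")


@dataclass(frozen=True)
class RunConfig:
    """Validated run parameters (loadable from YAML)."""

    tol_precursor: float = 0.01
    tol_fragment: float = 0.01
    rule_table: str | None = None  # path; None = packaged defaults
    max_residues: int = 10
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.tol_precursor <= 0 or self.tol_fragment <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_residues < 1:
            raise ValueError("max_residues must be >= 1")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"bad log level {self.log_level!r}")


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def read_sequences(path: str | Path) -> list[GAGSequence]:
    with open(path, encoding="utf-8") as fh:
        return _read_sequence_lines(fh)


def read_peaklist(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"mz", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"peak list {path}: missing columns {sorted(missing)}")
    if "intensity" not in df.columns:
        df["intensity"] = 1.0
    return df[["mz", "z", "intensity"]]


def write_peaklist(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def products_frame(result: DigestResult) -> pd.DataFrame:
    """Digest result as a flat table (stable products + partial survivors)."""
    rows = []
    for role, counter in (("product", result.products), ("partial_survivor", result.partial_survivors)):
        for seq, count in sorted(counter.items(), key=lambda kv: format_sequence(kv[0])):
            rows.append(
                {
                    "sequence": format_sequence(seq),
                    "composition": str(composition_of(seq)),
                    "neutral_mass": round(neutral_mass(seq), 5),
                    "count": count,
                    "role": role,
                }
            )
    return pd.DataFrame(rows, columns=["sequence", "composition", "neutral_mass", "count", "role"])


def write_products(result: DigestResult, path: str | Path) -> None:
    products_frame(result).to_csv(path, index=False)


def read_evidence(path: str | Path) -> list[EvidenceRecord]:
    """Evidence JSON: list of {subject, treatment, fate, companions}."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    records = []
    for item in raw:
        records.append(
            EvidenceRecord(
                subject=parse_code(item["subject"]),
                treatment=frozenset(item["treatment"]),
                fate=item["fate"],
                companions=tuple(
                    (parse_code(c["code"]), bool(c.get("trace", False)))
                    for c in item.get("companions", [])
                ),
            )
        )
    return records


def write_evidence(records: list[EvidenceRecord], path: str | Path) -> None:
    out = []
    for r in records:
        out.append(
            {
                "subject": str(r.subject),
                "treatment": sorted(r.treatment),
                "fate": r.fate,
                "companions": [{"code": str(c), "trace": t} for c, t in r.companions],
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, ensure_ascii=False, indent=2)
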
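"""Specimen-table input/output and label vocabularies.

A specimen is one lower jaw: its raw linear measurements (mm) plus three
categorical label systems used throughout the analysis — phylogenetic clade,
tooth-based feeding guild, and time-averaged assemblage (time bin).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("jawmorph")

# ---------------------------------------------------------------------------
# Label vocabularies
# ---------------------------------------------------------------------------

CLADES: tuple[str, ...] = (
    "Pliosauridae",
    "Plesiosauroidea",
    "Metriorhynchinae",
    "Geosaurinae",
    "Teleosauroidea",
    "Ophthalmosauridae",
)

#: Coarser aliases: Metriorhynchidae is the union of its two subfamilies.
COARSE_CLADE_OF: dict[str, str] = {
    "Metriorhynchinae": "Metriorhynchidae",
    "Geosaurinae": "Metriorhynchidae",
}

GUILDS: tuple[str, ...] = (
    "Cut",
    "Generalist",
    "Pierce I",
    "Pierce II",
    "Smash",
    "Crunch",
)

#: Pierce I and Pierce II collapse to a single Pierce guild on demand.
MERGED_PIERCE = "Pierce"

TIME_BINS: tuple[str, ...] = ("OCF", "KCF")

UNASSIGNED = "Unassigned"

# Canonical CSV schema (column names and order).
MEASUREMENT_COLUMNS: tuple[str, ...] = (
    "ML", "ASD", "MSL", "MSD", "TRL", "CPD", "RPL", "maL", "LCH",
    "DLT", "ILc", "eTRD", "eTRW",
)
OPTIONAL_MEASUREMENTS: frozenset[str] = frozenset({"DLT", "ILc", "eTRD", "eTRW"})
CSV_COLUMNS: tuple[str, ...] = (
    "specimen_id", "taxon", "clade", "sublineage", "guild", "time_bin",
    *MEASUREMENT_COLUMNS, "source_note",
)


class SchemaError(ValueError):
    """The file's columns do not match the specimen-table schema."""


class ValidationError(ValueError):
    """A measurement violates a hard anatomical invariant."""


class VocabularyError(ValueError):
    """A categorical label is not in the fixed vocabulary."""


def _normalize_label(value: str) -> str:
    return " ".join(str(value).split())


def _match_vocab(value: str, vocabulary: Iterable[str], kind: str,
                 specimen_id: str, coerce_unknown: bool = False) -> str:
    norm = _normalize_label(value)
    lookup = {v.casefold(): v for v in vocabulary}
    hit = lookup.get(norm.casefold())
    if hit is not None:
        return hit
    if coerce_unknown:
        logger.warning("specimen %s: unknown %s label %r coerced to %s",
                       specimen_id, kind, value, UNASSIGNED)
        return UNASSIGNED
    raise VocabularyError(
        f"specimen {specimen_id!r}: unknown {kind} label {value!r} "
        f"(expected one of {sorted(vocabulary)})"
    )


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawJawMeasurements:
    """Raw linear measurements of one mandible, in millimetres.

    Required: ML (total ramus length), ASD (gullet size: maximum lateral
    margin articular distance), MSL/MSD (symphysis length/depth), TRL (tooth
    row length), CPD (depth at the coronoid process), RPL (retroarticular
    process length), maL (adductor insertion length), LCH (largest tooth
    crown height). Optional: DLT (tip to largest tooth), ILc (explicit
    closing in-lever override), eTRD, eTRW (passthrough only).
    """

    ML: float
    ASD: float
    MSL: float
    MSD: float
    TRL: float
    CPD: float
    RPL: float
    maL: float
    LCH: float
    DLT: float | None = None
    ILc: float | None = None
    eTRD: float | None = None
    eTRW: float | None = None

    def validate(self, specimen_id: str = "?") -> None:
        problems = []
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v is None:
                if f.name not in OPTIONAL_MEASUREMENTS:
                    problems.append(f"{f.name} missing")
            elif not v > 0:
                problems.append(f"{f.name} = {v} not strictly positive")
        if not problems:
            for name in ("MSL", "TRL", "RPL", "maL"):
                if getattr(self, name) >= self.ML:
                    problems.append(f"{name} < ML violated "
                                    f"({name}={getattr(self, name)}, ML={self.ML})")
            if self.DLT is not None and self.DLT >= self.ML - self.RPL:
                problems.append(
                    f"DLT < ML - RPL violated (DLT={self.DLT}, ML-RPL={self.ML - self.RPL})")
        if problems:
            raise ValidationError(f"specimen {specimen_id!r}: " + "; ".join(problems))


@dataclass(frozen=True)
class SpecimenRecord:
    specimen_id: str
    taxon: str
    clade: str
    guild: str
    time_bin: str
    measurements: RawJawMeasurements
    sublineage: str | None = None
    source_note: str | None = None

    @property
    def coarse_clade(self) -> str:
        return COARSE_CLADE_OF.get(self.clade, self.clade)

    @property
    def merged_guild(self) -> str:
        return MERGED_PIERCE if self.guild.startswith("Pierce") else self.guild


@dataclass
class AssemblageTable:
    """An ordered collection of specimens plus provenance."""

    records: list[SpecimenRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.specimen_id for r in self.records]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise ValidationError(f"duplicate specimen_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    def labels(self, system: str) -> list[str]:
        """Group labels under a named system.

        Systems: ``clade`` (6 levels), ``clade_coarse`` (Metriorhynchidae
        merged), ``guild`` (6 levels), ``guild_merged`` (single Pierce),
        ``time_bin``.
        """
        getters = {
            "clade": lambda r: r.clade,
            "clade_coarse": lambda r: r.coarse_clade,
            "guild": lambda r: r.guild,
            "guild_merged": lambda r: r.merged_guild,
            "time_bin": lambda r: r.time_bin,
        }
        try:
            get = getters[system]
        except KeyError:
            raise KeyError(f"unknown label system {system!r}; "
                           f"expected one of {sorted(getters)}") from None
        return [get(r) for r in self.records]

    def measurement_frame(self) -> pd.DataFrame:
        rows = {}
        for r in self.records:
            rows[r.specimen_id] = {c: getattr(r.measurements, c)
                                   for c in MEASUREMENT_COLUMNS}
        return pd.DataFrame.from_dict(rows, orient="index")[list(MEASUREMENT_COLUMNS)]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, (float, np.floating)):
        return repr(float(value))  # shortest round-trip representation
    return str(value)


def _parse_float(raw: str, column: str, specimen_id: str) -> float | None:
    if raw is None or str(raw).strip() == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValidationError(
            f"specimen {specimen_id!r}: non-numeric {column} value {raw!r}") from None


def read_specimen_table(path: str | Path, *, coerce_unknown: bool = False,
                        on_invalid: str = "raise") -> AssemblageTable:
    """Read and validate a specimen CSV.

    ``on_invalid``: ``"raise"`` aborts on the first invalid row; ``"skip"``
    drops invalid rows with a logged, row-level diagnostic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    records: list[SpecimenRecord] = []
    for _, row in df.iterrows():
        sid = str(row["specimen_id"]).strip()
        try:
            meas = RawJawMeasurements(**{
                c: _parse_float(row[c], c, sid) for c in MEASUREMENT_COLUMNS
            })
            meas.validate(sid)
            rec = SpecimenRecord(
                specimen_id=sid,
                taxon=_normalize_label(row["taxon"]),
                clade=_match_vocab(row["clade"], CLADES, "clade", sid, coerce_unknown),
                guild=_match_vocab(row["guild"], GUILDS, "guild", sid, coerce_unknown),
                time_bin=_match_vocab(row["time_bin"], TIME_BINS, "time_bin",
                                      sid, coerce_unknown),
                sublineage=_normalize_label(row["sublineage"]) or None,
                source_note=str(row["source_note"]) or None,
                measurements=meas,
            )
        except (ValidationError, VocabularyError) as err:
            if on_invalid == "skip":
                logger.warning("dropping row: %s", err)
                continue
            raise
        records.append(rec)
    return AssemblageTable(records=records, provenance=str(path))


def write_specimen_table(table: AssemblageTable, path: str | Path) -> None:
    """Write the canonical CSV; ``read_specimen_table`` round-trips it."""
    path = Path(path)
    lines = [",".join(CSV_COLUMNS)]
    for r in table.records:
        row = {
            "specimen_id": r.specimen_id,
            "taxon": r.taxon,
            "clade": r.clade,
            "sublineage": r.sublineage or "",
            "guild": r.guild,
            "time_bin": r.time_bin,
            "source_note": r.source_note or "",
        }
        row.update({c: _fmt(getattr(r.measurements, c)) for c in MEASUREMENT_COLUMNS})
        lines.append(",".join(str(row[c]) for c in CSV_COLUMNS))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def summarize_composition(table: AssemblageTable) -> dict[str, dict[str, int]]:
    """Counts per clade, coarse clade, guild, merged guild and time bin.

    Every vocabulary level is listed, zero counts included; counts within
    each system sum to ``len(table)``.
    """
    out: dict[str, dict[str, int]] = {}
    systems = {
        "clade": CLADES,
        "clade_coarse": tuple(dict.fromkeys(
            COARSE_CLADE_OF.get(c, c) for c in CLADES)),
        "guild": GUILDS,
        "guild_merged": tuple(dict.fromkeys(
            MERGED_PIERCE if g.startswith("Pierce") else g for g in GUILDS)),
        "time_bin": TIME_BINS,
    }
    for system, levels in systems.items():
        counts = Counter(table.labels(system))
        out[system] = {lvl: counts.pop(lvl, 0) for lvl in levels}
        out[system].update(counts)  # e.g. Unassigned
    return out
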
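"""Ex situ conservation gap accounting per TDWG level-3 region.

Occurrence records (taxon x botanical-country region, native/introduced)
are reduced to per-region counts of native taxa, single-region endemics,
threatened taxa (IUCN band CR/EN/VU), taxa absent from ex situ collections,
and taxa underrepresented there (1-4 conserved accessions; five or more
counts as represented).  Region codes are opaque strings; no geometry is
computed — the output tables are choropleth-ready.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import pandas as pd

from .errors import DataError, SchemaError
from .trees import canonical_name

logger = logging.getLogger("cwrphylo")


class Establishment(enum.Enum):
    NATIVE = "native"
    INTRODUCED = "introduced"


class ThreatCategory(enum.Enum):
    CR = "CR"
    EN = "EN"
    VU = "VU"
    NT = "NT"
    LC = "LC"
    DD = "DD"
    NE = "NE"


#: IUCN "threatened" band
THREATENED = frozenset({ThreatCategory.CR, ThreatCategory.EN, ThreatCategory.VU})

#: accession count at or above which a taxon counts as represented ex situ
REPRESENTED_MIN = 5


@dataclass(frozen=True)
class OccurrenceRecord:
    taxon: str
    region_code: str
    establishment: Establishment

    def __post_init__(self):
        if not self.region_code.strip():
            raise DataError(f"occurrence for {self.taxon!r} has an empty region code")


@dataclass(frozen=True)
class ConservationRecord:
    taxon: str
    threat_category: ThreatCategory
    exsitu_accessions: int

    def __post_init__(self):
        if self.exsitu_accessions < 0:
            raise DataError(
                f"taxon {self.taxon!r}: negative ex situ accession count"
            )


@dataclass(frozen=True)
class RegionSummary:
    region_code: str
    n_native: int
    n_endemic: int
    n_threatened: int
    n_not_conserved: int
    n_underrepresented: int


# ---------------------------------------------------------------------------
# Elementary classifiers
# ---------------------------------------------------------------------------

def filter_native(occurrences: list[OccurrenceRecord]) -> list[OccurrenceRecord]:
    """Drop introduced-range records; the analysis concerns native ranges."""
    return [o for o in occurrences if o.establishment is Establishment.NATIVE]


def endemic_flags(native_occurrences: list[OccurrenceRecord]) -> dict[str, bool]:
    """A taxon is a single-region endemic iff its native range is exactly one
    distinct region code."""
    regions: dict[str, set[str]] = {}
    for occ in native_occurrences:
        regions.setdefault(canonical_name(occ.taxon), set()).add(occ.region_code)
    return {taxon: len(r) == 1 for taxon, r in regions.items()}


def threat_flag(category: ThreatCategory) -> bool:
    """True for the IUCN threatened band CR/EN/VU.  DD is counted separately
    as data-deficient, never as threatened."""
    if isinstance(category, str):
        try:
            category = ThreatCategory(category.strip().upper())
        except ValueError as exc:
            raise DataError(f"unknown threat category {category!r}") from exc
    return category in THREATENED


def representation_tier(exsitu_accessions: int) -> str:
    """'none' (0 accessions), 'underrepresented' (1-4), 'represented' (>= 5)."""
    if exsitu_accessions < 0:
        raise DataError("ex situ accession count cannot be negative")
    if exsitu_accessions == 0:
        return "none"
    if exsitu_accessions < REPRESENTED_MIN:
        return "underrepresented"
    return "represented"


# ---------------------------------------------------------------------------
# Regional summary
# ---------------------------------------------------------------------------

def region_summary(native_occurrences: list[OccurrenceRecord],
                   conservation: list[ConservationRecord]) -> list[RegionSummary]:
    """One summary row per region, sorted by descending native richness then
    region code.  Counts are of distinct taxa.  Taxa lacking a conservation
    record are treated as not evaluated with zero accessions, with a warning.
    """
    cons: dict[str, ConservationRecord] = {}
    for rec in conservation:
        key = canonical_name(rec.taxon)
        if key in cons:
            raise DataError(f"duplicate conservation record for {rec.taxon!r}")
        cons[key] = rec

    endemic = endemic_flags(native_occurrences)
    by_region: dict[str, set[str]] = {}
    for occ in native_occurrences:
        by_region.setdefault(occ.region_code, set()).add(canonical_name(occ.taxon))

    missing = {t for taxa in by_region.values() for t in taxa if t not in cons}
    if missing:
        logger.warning(
            "%d taxa lack conservation records; treated as NE with 0 accessions",
            len(missing),
        )

    summaries = []
    for region, taxa in by_region.items():
        n_threatened = n_none = n_under = n_endemic = 0
        for t in taxa:
            rec = cons.get(t)
            category = rec.threat_category if rec else ThreatCategory.NE
            accessions = rec.exsitu_accessions if rec else 0
            if endemic[t]:
                n_endemic += 1
            if threat_flag(category):
                n_threatened += 1
            tier = representation_tier(accessions)
            if tier == "none":
                n_none += 1
            elif tier == "underrepresented":
                n_under += 1
        summaries.append(RegionSummary(
            region_code=region,
            n_native=len(taxa),
            n_endemic=n_endemic,
            n_threatened=n_threatened,
            n_not_conserved=n_none,
            n_underrepresented=n_under,
        ))
    summaries.sort(key=lambda s: (-s.n_native, s.region_code))
    return summaries


def totals(native_occurrences: list[OccurrenceRecord],
           conservation: list[ConservationRecord]) -> dict[str, int]:
    """Global tallies over distinct native taxa (regions aside)."""
    taxa = {canonical_name(o.taxon) for o in native_occurrences}
    endemic = endemic_flags(native_occurrences)
    cons = {canonical_name(r.taxon): r for r in conservation}
    return {
        "n_taxa": len(taxa),
        "n_endemic": sum(1 for t in taxa if endemic[t]),
        "n_threatened": sum(
            1 for t in taxa
            if t in cons and threat_flag(cons[t].threat_category)
        ),
        "n_not_conserved": sum(
            1 for t in taxa
            if representation_tier(cons[t].exsitu_accessions if t in cons else 0) == "none"
        ),
        "n_underrepresented": sum(
            1 for t in taxa
            if t in cons and representation_tier(cons[t].exsitu_accessions) == "underrepresented"
        ),
    }


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def load_occurrences(path) -> list[OccurrenceRecord]:
    from .kb import _read_table

    df = _read_table(path)
    required = {"taxon", "region_code", "establishment"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    seen = set()
    for i, row in df.iterrows():
        try:
            est = Establishment(row["establishment"].strip().lower())
        except ValueError as exc:
            raise DataError(
                f"{path} row {i + 2}: unknown establishment {row['establishment']!r}"
            ) from exc
        key = (canonical_name(row["taxon"]), row["region_code"], est)
        if key in seen:
            raise DataError(f"{path} row {i + 2}: duplicate occurrence {key[:2]}")
        seen.add(key)
        records.append(OccurrenceRecord(row["taxon"], row["region_code"], est))
    return records


def load_conservation(path) -> list[ConservationRecord]:
    from .kb import _read_table

    df = _read_table(path)
    required = {"taxon", "threat_category", "exsitu_accessions"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        token = row["threat_category"].strip().upper() or "NE"
        try:
            category = ThreatCategory(token)
        except ValueError as exc:
            raise DataError(f"{path} row {i + 2}: unknown threat category {token!r}") from exc
        try:
            count = int(row["exsitu_accessions"] or 0)
        except ValueError as exc:
            raise DataError(
                f"{path} row {i + 2}: bad accession count {row['exsitu_accessions']!r}"
            ) from exc
        records.append(ConservationRecord(row["taxon"], category, count))
    return records


def save_occurrences(records: list[OccurrenceRecord], path) -> None:
    pd.DataFrame([
        {"taxon": r.taxon, "region_code": r.region_code,
         "establishment": r.establishment.value}
        for r in records
    ]).to_csv(path, sep="\t", index=False)


def save_conservation(records: list[ConservationRecord], path) -> None:
    pd.DataFrame([
        {"taxon": r.taxon, "threat_category": r.threat_category.value,
         "exsitu_accessions": r.exsitu_accessions}
        for r in records
    ]).to_csv(path, sep="\t", index=False)


def write_region_summary_tsv(summaries: list[RegionSummary], path) -> None:
    pd.DataFrame([
        {
            "region_code": s.region_code,
            "n_native": s.n_native,
            "n_endemic": s.n_endemic,
            "n_threatened": s.n_threatened,
            "n_not_conserved": s.n_not_conserved,
            "n_underrepresented": s.n_underrepresented,
        }
        for s in summaries
    ]).to_csv(path, sep="\t", index=False)
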
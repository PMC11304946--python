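"""Tabular knowledge base: taxa, cytotypes, and crop x relative cross evidence.

Cross evidence uses the four-level coding common in crop-wild-relative
compendia: Y (successful conventional cross reported), Y* (successful but
with very low success rate), N (unsuccessful, or achievable only with
biotechnology such as embryo rescue), NI (no information).  A digitized
worked-example table of crop-relative patristic distances on matK and ITS
trees ships with the package and drives the in-package worked examples.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DataError, DuplicateTaxonError, PackagingError, SchemaError
from .trees import canonical_name

logger = logging.getLogger("cwrphylo")


class Evidence(enum.Enum):
    """Cross-evidence level, ordered by strength Y > Y* > N > NI."""

    Y = "Y"
    Y_STAR = "Y*"
    N = "N"
    NI = "NI"

    @classmethod
    def parse(cls, token: str) -> "Evidence":
        t = str(token).strip().upper()
        mapping = {"Y": cls.Y, "Y*": cls.Y_STAR, "Y_STAR": cls.Y_STAR,
                   "YSTAR": cls.Y_STAR, "N": cls.N, "NI": cls.NI}
        if t not in mapping:
            raise DataError(f"unknown evidence token {token!r}")
        return mapping[t]

    @property
    def strength(self) -> int:
        return {"Y": 3, "Y*": 2, "N": 1, "NI": 0}[self.value]


class GenePool(enum.Enum):
    GP1 = "GP1"
    GP2 = "GP2"
    GP3 = "GP3"


class TaxonGroup(enum.Enum):
    TG1 = "TG1"
    TG2 = "TG2"
    TG3 = "TG3"
    TG4 = "TG4"


@dataclass(frozen=True)
class TaxonRecord:
    """One taxon with its crop status, optional CWR classification, and the
    set of reported 2n chromosome counts (cytotypes)."""

    name: str
    genus: str
    is_crop: bool
    chromosome_counts: frozenset[int] = frozenset()
    gp_class: GenePool | None = None
    tg_class: TaxonGroup | None = None

    def __post_init__(self):
        for c in self.chromosome_counts:
            if c < 4 or c % 2 != 0:
                raise DataError(
                    f"taxon {self.name!r}: 2n value {c} must be an even integer >= 4"
                )


@dataclass(frozen=True)
class CrossRecord:
    """One crop-relative pair with its evidence flag and source tag."""

    crop: str
    relative: str
    evidence: Evidence
    marker_context: str = "any"
    source: str = ""

    def __post_init__(self):
        if canonical_name(self.crop) == canonical_name(self.relative):
            raise DataError(f"self-cross record for {self.crop!r}")


@dataclass(frozen=True)
class Table1Entry:
    """One digitized crop-relative distance entry from the worked-example table.

    ``pd_low == pd_high`` for single-valued printed cells; a printed range
    (several taxa sharing one cell) gives ``pd_low < pd_high`` and
    ``ambiguous_group=True`` on every taxon of the cell.  ``is_new_cwr``
    mirrors the table's bolding of newly proposed CWRs.
    """

    crop: str
    relative: str
    marker: str
    pd_low: float
    pd_high: float
    evidence: Evidence
    is_new_cwr: bool
    ambiguous_group: bool

    def __post_init__(self):
        if not (0 <= self.pd_low <= self.pd_high <= 2.0):
            raise DataError(
                f"entry ({self.crop}, {self.relative}, {self.marker}): "
                f"need 0 <= pd_low <= pd_high <= 2"
            )


def is_genus_placeholder(name: str) -> bool:
    """True for genus-level 'spp.' placeholders, which are excluded from
    per-taxon counting."""
    return canonical_name(name).lower().endswith(("spp.", "spp"))


# ---------------------------------------------------------------------------
# Delimited-text loading
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    return df.apply(lambda col: col.str.strip())


_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


def _parse_bool(token: str, context: str) -> bool:
    t = str(token).strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise DataError(f"{context}: cannot parse boolean {token!r}")


def load_taxa(path) -> dict[str, TaxonRecord]:
    """Load taxon records keyed by canonical name.

    Required columns: name, genus, is_crop, chromosome_counts (semicolon-
    separated 2n integers; empty means unknown ploidy).  Optional: gp_class,
    tg_class.
    """
    df = _read_table(path)
    required = {"name", "genus", "is_crop", "chromosome_counts"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    taxa: dict[str, TaxonRecord] = {}
    for i, row in df.iterrows():
        counts = set()
        for token in str(row["chromosome_counts"]).split(";"):
            token = token.strip()
            if not token:
                continue
            try:
                value = int(token)
            except ValueError as exc:
                raise DataError(f"{path} row {i + 2}: bad 2n value {token!r}") from exc
            if value <= 0 or value % 2 != 0 or value < 4:
                raise DataError(
                    f"{path} row {i + 2}: 2n value {value} must be an even integer >= 4"
                )
            counts.add(value)
        gp = row.get("gp_class", "") if "gp_class" in df.columns else ""
        tg = row.get("tg_class", "") if "tg_class" in df.columns else ""
        record = TaxonRecord(
            name=row["name"],
            genus=row["genus"],
            is_crop=_parse_bool(row["is_crop"], f"{path} row {i + 2}"),
            chromosome_counts=frozenset(counts),
            gp_class=GenePool(gp.upper()) if gp else None,
            tg_class=TaxonGroup(tg.upper()) if tg else None,
        )
        key = canonical_name(record.name)
        if key in taxa:
            raise DuplicateTaxonError(f"{path} row {i + 2}: duplicate taxon {record.name!r}")
        taxa[key] = record
    return taxa


def save_taxa(taxa: dict[str, TaxonRecord], path) -> None:
    rows = []
    for rec in taxa.values():
        rows.append({
            "name": rec.name,
            "genus": rec.genus,
            "is_crop": str(rec.is_crop).lower(),
            "chromosome_counts": ";".join(str(c) for c in sorted(rec.chromosome_counts)),
            "gp_class": rec.gp_class.value if rec.gp_class else "",
            "tg_class": rec.tg_class.value if rec.tg_class else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_crosses(path) -> list[CrossRecord]:
    """Load cross-evidence records, preserving file order."""
    df = _read_table(path)
    required = {"crop", "relative", "evidence"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            evidence = Evidence.parse(row["evidence"])
        except DataError as exc:
            raise DataError(f"{path} row {i + 2}: {exc}") from exc
        try:
            records.append(CrossRecord(
                crop=row["crop"],
                relative=row["relative"],
                evidence=evidence,
                marker_context=row.get("marker_context", "any") or "any",
                source=row.get("source", "") or "",
            ))
        except DataError as exc:
            raise DataError(f"{path} row {i + 2}: {exc}") from exc
    return records


def save_crosses(records: list[CrossRecord], path) -> None:
    pd.DataFrame([
        {"crop": r.crop, "relative": r.relative, "evidence": r.evidence.value,
         "marker_context": r.marker_context, "source": r.source}
        for r in records
    ]).to_csv(path, sep="\t", index=False)


def evidence_for(crop: str, relative: str,
                 records: list[CrossRecord]) -> Evidence:
    """Strongest evidence for a pair under precedence Y > Y* > N > NI;
    NI when no record matches.  Order-independent by construction."""
    ckey, rkey = canonical_name(crop), canonical_name(relative)
    best = Evidence.NI
    for rec in records:
        if canonical_name(rec.crop) == ckey and canonical_name(rec.relative) == rkey:
            if rec.evidence.strength > best.strength:
                best = rec.evidence
    return best


# ---------------------------------------------------------------------------
# Packaged worked-example table
# ---------------------------------------------------------------------------

def load_table1_fixture() -> list[Table1Entry]:
    """Load the packaged digitized crop-relative distance table.

    Cells listing several taxa against a single printed value or range are
    expanded to one entry per taxon with the shared value/range and
    ``ambiguous_group=True``, so downstream logic can exclude them from
    exact per-taxon checks.
    """
    try:
        text = (resources.files("cwrphylo") / "data" / "table1.tsv").read_text("utf-8")
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise PackagingError("packaged table1.tsv fixture is missing") from exc
    lines = [l for l in text.splitlines() if l.strip()]
    header = lines[0].split("\t")
    expected = ["crop", "relative", "marker", "pd_low", "pd_high",
                "evidence", "is_new_cwr", "ambiguous_group"]
    if header != expected:
        raise PackagingError(f"table1.tsv header {header} != {expected}")
    entries = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != len(expected):
            raise PackagingError(f"corrupt table1.tsv line: {ln!r}")
        crop, relative, marker, lo, hi, ev, new, amb = parts
        entries.append(Table1Entry(
            crop=crop, relative=relative, marker=marker,
            pd_low=float(lo), pd_high=float(hi),
            evidence=Evidence.parse(ev),
            is_new_cwr=_parse_bool(new, "table1.tsv"),
            ambiguous_group=_parse_bool(amb, "table1.tsv"),
        ))
    return entries


def table1_crosses(entries: list[Table1Entry]) -> list[CrossRecord]:
    """Cross-evidence records implied by the worked-example table's flags.

    Crossing evidence describes the species pair, not the marker, so the
    records carry marker_context='any'.  NI entries are carried through;
    they never qualify as threshold anchors."""
    records = []
    seen = set()
    for e in entries:
        key = (canonical_name(e.crop), canonical_name(e.relative), e.evidence)
        if key in seen:
            continue
        seen.add(key)
        records.append(CrossRecord(
            crop=e.crop, relative=e.relative, evidence=e.evidence,
            marker_context="any", source="table1",
        ))
    return records


def table1_distances(entries: list[Table1Entry], crop: str, marker: str,
                     bound: str = "high") -> dict[str, float]:
    """Crop-to-relative distances for one crop and marker.

    ``bound`` picks the end of printed ranges ('low', 'high' or 'mid').
    A taxon printed in more than one cell keeps its smallest value.
    """
    if bound not in {"low", "high", "mid"}:
        raise DataError(f"bound must be low/high/mid, got {bound!r}")
    ckey = canonical_name(crop)
    out: dict[str, float] = {}
    for e in entries:
        if canonical_name(e.crop) != ckey or e.marker != marker:
            continue
        value = {"low": e.pd_low, "high": e.pd_high,
                 "mid": 0.5 * (e.pd_low + e.pd_high)}[bound]
        if e.relative not in out or value < out[e.relative]:
            out[e.relative] = value
    return out


def table1_crops(entries: list[Table1Entry]) -> list[str]:
    """Distinct crops in table order."""
    seen: dict[str, None] = {}
    for e in entries:
        seen.setdefault(e.crop, None)
    return list(seen)
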
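"""Per-crop compatibility thresholds and candidate CWR prediction.

The screen's core rule: on a height-1 ultrametric tree, the patristic
distance from a crop to its furthest relative with a documented successful
conventional cross (the *anchor*) defines that crop's compatibility
threshold tau.  Every taxon at distance <= tau is then proposed as
potentially cross-compatible; taxa with no prior cross record or gene-pool /
taxon-group classification are the *new* candidates.  Crops with no usable
anchor fall back to a maximum-congener radius, always flagged as such.
Cytotype (2n) overlap is annotated because same-ploidy crosses are the
recommended first attempt.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace

import pandas as pd

from .errors import ConfigurationError, MissingTaxonError
from .kb import CrossRecord, Evidence, TaxonRecord
from .trees import DistanceMatrix, canonical_name

logger = logging.getLogger("cwrphylo")

#: report precision for distances (matches the worked-example table)
REPORT_DECIMALS = 5


class AnchorPolicy(enum.Enum):
    """Which evidence levels qualify a relative as a threshold anchor."""

    Y_ONLY = "y_only"
    Y_AND_YSTAR = "y_and_ystar"

    @property
    def qualifying(self) -> frozenset[Evidence]:
        if self is AnchorPolicy.Y_ONLY:
            return frozenset({Evidence.Y})
        return frozenset({Evidence.Y, Evidence.Y_STAR})


class PloidyMatch(enum.Enum):
    SHARED_CYTOTYPE = "shared_cytotype"
    DISJOINT = "disjoint"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ThresholdResult:
    """A crop's compatibility radius and the anchor that set it.

    ``tau`` is None when no qualifying relative (or, in fallback mode, no
    congener) is present in the matrix.
    """

    crop: str
    marker: str
    tau: float | None
    anchor_relative: str | None
    anchor_evidence: Evidence | None
    policy: AnchorPolicy
    fallback_used: bool = False


@dataclass(frozen=True)
class CandidatePrediction:
    """One proposed crop-relative pairing with its supporting numbers."""

    crop: str
    marker: str
    candidate: str
    pd: float
    tau: float
    confidence: str  # "anchored" | "fallback"
    ploidy_match: PloidyMatch
    already_known: bool
    markers: tuple[str, ...] = ()

    @property
    def margin(self) -> float:
        return self.tau - self.pd

    @property
    def is_new(self) -> bool:
        return not self.already_known


# ---------------------------------------------------------------------------
# Threshold inference
# ---------------------------------------------------------------------------

def _pair_evidence(crop: str, relative: str, records: list[CrossRecord],
                   marker: str) -> Evidence:
    """Strongest evidence among records matching the pair and compatible
    with the marker context ('any' matches everything)."""
    ckey, rkey = canonical_name(crop), canonical_name(relative)
    best = Evidence.NI
    for rec in records:
        if canonical_name(rec.crop) != ckey or canonical_name(rec.relative) != rkey:
            continue
        if rec.marker_context not in ("any", marker):
            continue
        if rec.evidence.strength > best.strength:
            best = rec.evidence
    return best


def infer_threshold(crop: str, matrix: DistanceMatrix,
                    records: list[CrossRecord],
                    policy: AnchorPolicy = AnchorPolicy.Y_AND_YSTAR,
                    marker: str = "any") -> ThresholdResult:
    """tau = max distance from the crop to any relative whose cross evidence
    qualifies under ``policy``; undefined when no qualifying relative is in
    the matrix.  Distance ties are broken toward the lexicographically
    smallest anchor name for determinism."""
    if isinstance(policy, str):
        try:
            policy = AnchorPolicy(policy)
        except ValueError as exc:
            raise ConfigurationError(f"unknown anchor policy {policy!r}") from exc
    if crop not in matrix:
        raise MissingTaxonError(f"crop {crop!r} is not in the distance matrix")
    best: tuple[float, str] | None = None
    best_evidence = None
    for taxon, d in matrix.row(crop).items():
        if canonical_name(taxon) == canonical_name(crop):
            continue
        ev = _pair_evidence(crop, taxon, records, marker)
        if ev not in policy.qualifying:
            continue
        key = (d, taxon)
        if best is None or d > best[0] or (d == best[0] and taxon < best[1]):
            best = key
            best_evidence = ev
    if best is None:
        return ThresholdResult(crop, marker, None, None, None, policy, False)
    return ThresholdResult(crop, marker, best[0], best[1], best_evidence, policy, False)


def fallback_threshold(crop: str, matrix: DistanceMatrix,
                       taxa: dict[str, TaxonRecord],
                       policy: AnchorPolicy = AnchorPolicy.Y_AND_YSTAR,
                       marker: str = "any") -> ThresholdResult:
    """Maximum-congener radius for crops with no cross-evidence anchor.

    The result is always flagged ``fallback_used`` and downstream
    predictions carry confidence='fallback'; it is an explicit surrogate,
    not a claim of documented compatibility."""
    if crop not in matrix:
        raise MissingTaxonError(f"crop {crop!r} is not in the distance matrix")
    crop_rec = taxa.get(canonical_name(crop))
    genus = crop_rec.genus if crop_rec else canonical_name(crop).split("_")[0]
    best: tuple[float, str] | None = None
    for taxon, d in matrix.row(crop).items():
        if canonical_name(taxon) == canonical_name(crop):
            continue
        rec = taxa.get(canonical_name(taxon))
        taxon_genus = rec.genus if rec else canonical_name(taxon).split("_")[0]
        if taxon_genus != genus:
            continue
        if best is None or d > best[0] or (d == best[0] and taxon < best[1]):
            best = (d, taxon)
    if best is None:
        return ThresholdResult(crop, marker, None, None, None, policy, True)
    return ThresholdResult(crop, marker, best[0], best[1], None, policy, True)


# ---------------------------------------------------------------------------
# Ploidy matching
# ---------------------------------------------------------------------------

def ploidy_match(a, b) -> PloidyMatch:
    """Compare cytotype (2n) sets: shared_cytotype when they intersect,
    disjoint when both are known but do not, unknown when either is empty.

    Accepts :class:`TaxonRecord` objects or bare sets of 2n counts."""
    set_a = a.chromosome_counts if isinstance(a, TaxonRecord) else frozenset(a or ())
    set_b = b.chromosome_counts if isinstance(b, TaxonRecord) else frozenset(b or ())
    if not set_a or not set_b:
        return PloidyMatch.UNKNOWN
    return PloidyMatch.SHARED_CYTOTYPE if set_a & set_b else PloidyMatch.DISJOINT


# ---------------------------------------------------------------------------
# Candidate prediction
# ---------------------------------------------------------------------------

def predict_cwrs(crop: str, matrix: DistanceMatrix, threshold: ThresholdResult,
                 records: list[CrossRecord],
                 taxa: dict[str, TaxonRecord] | None = None,
                 ) -> list[CandidatePrediction]:
    """Emit every non-crop taxon at distance <= tau, sorted by ascending
    distance (ties lexicographic by name).

    ``already_known`` marks taxa with any Y/Y*/N record against the crop or
    an existing GP/TG classification; only already_known=False predictions
    count as new CWRs.  N-evidence taxa inside the radius are emitted but
    flagged: their incompatibility is documented."""
    taxa = taxa or {}
    if threshold.tau is None:
        logger.info("crop %s: threshold undefined, no predictions emitted", crop)
        return []
    crop_rec = taxa.get(canonical_name(crop))
    confidence = "fallback" if threshold.fallback_used else "anchored"
    out = []
    for taxon, d in matrix.row(crop).items():
        if canonical_name(taxon) == canonical_name(crop):
            continue
        if d > threshold.tau:
            continue
        ev = _pair_evidence(crop, taxon, records, threshold.marker)
        rec = taxa.get(canonical_name(taxon))
        classified = rec is not None and (rec.gp_class is not None or rec.tg_class is not None)
        out.append(CandidatePrediction(
            crop=crop,
            marker=threshold.marker,
            candidate=taxon,
            pd=d,
            tau=threshold.tau,
            confidence=confidence,
            ploidy_match=(ploidy_match(crop_rec, rec)
                          if crop_rec is not None and rec is not None
                          else PloidyMatch.UNKNOWN),
            already_known=(ev is not Evidence.NI) or classified,
        ))
    out.sort(key=lambda p: (p.pd, p.candidate))
    return out


def cross_marker_consensus(predictions_by_marker: dict[str, list[CandidatePrediction]],
                           mode: str = "union") -> list[CandidatePrediction]:
    """Merge per-marker prediction lists for one crop.

    ``union`` keeps every taxon predicted under any marker (annotated with
    its supporting markers, reporting the smallest distance); ``intersection``
    keeps only taxa predicted under every supplied marker."""
    if not predictions_by_marker:
        raise ConfigurationError("cross_marker_consensus needs at least one marker")
    if mode not in {"union", "intersection"}:
        raise ConfigurationError(f"unknown consensus mode {mode!r}")
    support: dict[str, list[tuple[str, CandidatePrediction]]] = {}
    for marker in sorted(predictions_by_marker):
        for p in predictions_by_marker[marker]:
            support.setdefault(canonical_name(p.candidate), []).append((marker, p))
    merged = []
    n_markers = len(predictions_by_marker)
    for preds in support.values():
        markers = tuple(m for m, _ in preds)
        if mode == "intersection" and len(set(markers)) < n_markers:
            continue
        best = min((p for _, p in preds), key=lambda p: p.pd)
        merged.append(replace(best, markers=markers))
    merged.sort(key=lambda p: (p.pd, p.candidate))
    return merged


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def thresholds_frame(results: list[ThresholdResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "crop": r.crop,
            "marker": r.marker,
            "tau": "" if r.tau is None else format(round(r.tau, REPORT_DECIMALS), f".{REPORT_DECIMALS}f"),
            "anchor": r.anchor_relative or "",
            "evidence": r.anchor_evidence.value if r.anchor_evidence else "",
            "policy": r.policy.value,
            "fallback": str(r.fallback_used).lower(),
        }
        for r in results
    ])


def predictions_frame(predictions: list[CandidatePrediction]) -> pd.DataFrame:
    fmt = f".{REPORT_DECIMALS}f"
    return pd.DataFrame([
        {
            "crop": p.crop,
            "marker": p.marker,
            "candidate": p.candidate,
            "pd": format(round(p.pd, REPORT_DECIMALS), fmt),
            "tau": format(round(p.tau, REPORT_DECIMALS), fmt),
            "margin": format(round(p.margin, REPORT_DECIMALS), fmt),
            "confidence": p.confidence,
            "ploidy_match": p.ploidy_match.value,
            "already_known": str(p.already_known).lower(),
            "markers": ";".join(p.markers),
        }
        for p in predictions
    ])


def write_thresholds_tsv(results: list[ThresholdResult], path) -> None:
    thresholds_frame(results).to_csv(path, sep="\t", index=False)


def write_predictions_tsv(predictions: list[CandidatePrediction], path) -> None:
    predictions_frame(predictions).to_csv(path, sep="\t", index=False)
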
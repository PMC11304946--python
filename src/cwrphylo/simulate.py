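"""Seedable synthetic data with known ground truth.

Every pipeline stage can be exercised without downloads: a pure-birth (Yule)
tree normalized to height 1, cross evidence generated from per-crop "true"
compatibility radii, chromosome-number evolution with whole-genome
duplication and dysploidy, and occurrence/threat/accession tables whose
marginals mirror a family-wide conservation census (about half the taxa
single-region endemics, roughly a third with any conservation assessment of
which some 27% threatened, and close to two thirds absent from ex situ
collections).

All generators are pure functions of (config, seed): one numpy Generator is
threaded through tree -> evidence -> ploidy -> conservation in that fixed
order, so identical configs give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .kb import CrossRecord, Evidence, TaxonRecord
from .gaps import (
    ConservationRecord,
    Establishment,
    OccurrenceRecord,
    ThreatCategory,
)
from .predict import AnchorPolicy, infer_threshold, predict_cwrs
from .trees import PhyloTree, canonical_name, normalize_height, patristic_matrix

#: threat-category sampling weights; chosen so that ~35% of taxa carry any
#: assessment (non-NE) and ~27% of the assessed fall in the CR/EN/VU band
DEFAULT_THREAT_PROBS = {
    "NE": 0.645, "DD": 0.095, "LC": 0.140, "NT": 0.024,
    "VU": 0.050, "EN": 0.030, "CR": 0.016,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    ``true_radius`` fixes one compatibility radius for every crop; when None
    each crop draws its own radius uniformly from ``radius_range`` (distances
    live on a height-1 tree, so radii are dimensionless in [0, 0.2]).
    ``anchor_radius_scale`` shrinks the radius within which successful-cross
    (Y/Y*) evidence is generated: at 0.5, compatible taxa between r/2 and r
    are left untested (NI), emulating literature that has only probed close
    relatives.
    """

    seed: int = 0
    n_tips: int = 200
    birth_rate: float = 1.0
    n_crops: int = 18
    true_radius: float | None = None
    radius_range: tuple[float, float] = (0.0, 0.2)
    y_star_proportion: float = 0.25
    anchor_radius_scale: float = 1.0
    evidence_missing_rate: float = 0.3
    n_regions: int = 60
    range_size_dispersion: float = 1.81
    introduced_rate: float = 0.1
    exsitu_zero_inflation: float = 0.63
    exsitu_geom_p: float = 0.15
    wgd_rate: float = 0.5
    dysploidy_rate: float = 2.0
    base_2n: int = 16
    cytotype_retention: float = 0.1
    threat_probs: dict = field(default_factory=lambda: dict(DEFAULT_THREAT_PROBS))

    def __post_init__(self):
        probs = ["y_star_proportion", "evidence_missing_rate", "introduced_rate",
                 "exsitu_zero_inflation", "exsitu_geom_p", "cytotype_retention"]
        for name in probs:
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name}={v} must be a probability in [0, 1]")
        if self.n_tips < 3:
            raise ConfigurationError("n_tips must be >= 3")
        if not self.n_crops < self.n_tips:
            raise ConfigurationError("n_crops must be smaller than n_tips")
        if self.birth_rate <= 0:
            raise ConfigurationError("birth_rate must be > 0")
        for name in ("wgd_rate", "dysploidy_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.base_2n < 4 or self.base_2n % 2:
            raise ConfigurationError("base_2n must be an even integer >= 4")
        if self.range_size_dispersion <= 1:
            raise ConfigurationError("range_size_dispersion must be > 1")
        if not 0 < self.anchor_radius_scale <= 1:
            raise ConfigurationError("anchor_radius_scale must be in (0, 1]")
        lo, hi = self.radius_range
        if not (0 <= lo <= hi):
            raise ConfigurationError("radius_range must satisfy 0 <= low <= high")
        if abs(sum(self.threat_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("threat_probs must sum to 1")


def load_config(path) -> SimConfig:
    """Read a flat key:value YAML config; unknown keys are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    if "radius_range" in raw:
        raw["radius_range"] = tuple(raw["radius_range"])
    return SimConfig(**raw)


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    crops: list[str] = field(default_factory=list)
    radius: dict[str, float] = field(default_factory=dict)
    compatible: dict[str, frozenset[str]] = field(default_factory=dict)
    anchors: dict[str, frozenset[str]] = field(default_factory=dict)
    two_n: dict[str, frozenset[int]] = field(default_factory=dict)
    regions: dict[str, frozenset[str]] = field(default_factory=dict)
    threat: dict[str, str] = field(default_factory=dict)
    accessions: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(config: SimConfig, rng: np.random.Generator | None = None) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_tips`` tips, height-normalized to 1.0.

    Forward simulation: starting from a root split, with k extant lineages
    the next split waits Exp(k * birth_rate) and hits a uniformly chosen
    lineage; after the (n-1)th split one further waiting time extends all
    tips so terminal branches are positive.  Identical seeds give
    byte-identical Newick strings.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    taxon_namespace = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = dtree.seed_node
    birth_time = {root: 0.0}
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        birth_time[child] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < config.n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * config.birth_rate))
        node = active.pop(int(rng.integers(k)))
        node.edge.length = t - birth_time[node]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth_time[child] = t
            active.append(child)
    t += rng.exponential(1.0 / (len(active) * config.birth_rate))
    for node in active:
        node.edge.length = t - birth_time[node]
    width = len(str(config.n_tips))
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon = taxon_namespace.new_taxon(f"T{i:0{width}d}")
    return normalize_height(PhyloTree(dtree))


# ---------------------------------------------------------------------------
# Cross evidence
# ---------------------------------------------------------------------------

def simulate_evidence(tree: PhyloTree, config: SimConfig,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[list[CrossRecord], GroundTruth]:
    """Designate crops and generate Y/Y*/N/NI records from true radii.

    Taxa within ``anchor_radius_scale * r`` of a crop receive Y (a fraction
    ``y_star_proportion`` of them Y*); truly compatible taxa beyond the
    anchor window stay NI; taxa beyond r receive N.  Every generated Y/Y*/N
    record is then independently blanked to NI with
    ``evidence_missing_rate``.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    matrix = patristic_matrix(tree)
    tips = list(matrix.labels)
    crop_idx = rng.choice(len(tips), size=config.n_crops, replace=False)
    crops = [tips[i] for i in sorted(crop_idx)]
    gt = GroundTruth(crops=crops)
    records: list[CrossRecord] = []
    for crop in crops:
        r = (config.true_radius if config.true_radius is not None
             else float(rng.uniform(*config.radius_range)))
        gt.radius[crop] = r
        row = matrix.row(crop)
        compatible, anchors = set(), set()
        for taxon in tips:
            if taxon == crop:
                continue
            d = row[taxon]
            if d <= r:
                compatible.add(canonical_name(taxon))
                if d <= config.anchor_radius_scale * r:
                    ev = (Evidence.Y_STAR
                          if rng.random() < config.y_star_proportion
                          else Evidence.Y)
                else:
                    ev = Evidence.NI
            else:
                ev = Evidence.N
            if ev is not Evidence.NI and rng.random() < config.evidence_missing_rate:
                ev = Evidence.NI
            if ev in (Evidence.Y, Evidence.Y_STAR):
                anchors.add(canonical_name(taxon))
            records.append(CrossRecord(crop=crop, relative=taxon, evidence=ev,
                                       marker_context="any", source="sim"))
        gt.compatible[crop] = frozenset(compatible)
        gt.anchors[crop] = frozenset(anchors)
    return records, gt


# ---------------------------------------------------------------------------
# Chromosome-number evolution
# ---------------------------------------------------------------------------

def _evolve_2n(state: int, n_wgd: int, n_dysploidy: int,
               rng: np.random.Generator) -> int:
    """Apply a branch's events in random order: WGD doubles 2n, dysploidy
    steps it by +/-2; the count never drops below 4 and stays even."""
    events = ["w"] * n_wgd + ["d"] * n_dysploidy
    order = rng.permutation(len(events)) if events else []
    for i in order:
        if events[i] == "w":
            state *= 2
        else:
            state += int(rng.choice([-2, 2]))
            state = max(state, 4)
    return state


def simulate_ploidy(tree: PhyloTree, config: SimConfig,
                    rng: np.random.Generator | None = None,
                    ) -> dict[str, frozenset[int]]:
    """Evolve 2n from ``base_2n`` along the tree; Poisson event counts per
    branch scale with branch length.  Tips occasionally retain the parental
    cytotype alongside their own (multiple cytotypes per taxon)."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    state = {tree.dtree.seed_node: config.base_2n}
    out: dict[str, frozenset[int]] = {}
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        n_wgd = int(rng.poisson(config.wgd_rate * length))
        n_dys = int(rng.poisson(config.dysploidy_rate * length))
        parent_state = state[node.parent_node]
        state[node] = _evolve_2n(parent_state, n_wgd, n_dys, rng)
        if not node.child_nodes():
            cytotypes = {state[node]}
            if (state[node] != parent_state
                    and rng.random() < config.cytotype_retention):
                cytotypes.add(parent_state)
            out[node.taxon.label] = frozenset(cytotypes)
    return out


# ---------------------------------------------------------------------------
# Occurrences, threat status, ex situ accessions
# ---------------------------------------------------------------------------

def simulate_conservation(taxa_names: list[str], config: SimConfig,
                          rng: np.random.Generator | None = None,
                          ) -> tuple[list[OccurrenceRecord], list[ConservationRecord]]:
    """Heavy-tailed range sizes (zeta-distributed region counts, so most taxa
    are single-region endemics), categorical threat status, and zero-inflated
    geometric ex situ accession counts."""
    if config.n_regions < 1:
        raise ConfigurationError("n_regions must be >= 1")
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    region_codes = [f"R{i + 1:03d}" for i in range(config.n_regions)]
    categories = sorted(config.threat_probs)
    probs = np.array([config.threat_probs[c] for c in categories])
    occurrences, conservation = [], []
    for taxon in taxa_names:
        k = min(int(rng.zipf(config.range_size_dispersion)), config.n_regions)
        native = rng.choice(config.n_regions, size=k, replace=False)
        native_set = set(int(i) for i in native)
        for i in sorted(native_set):
            occurrences.append(OccurrenceRecord(
                taxon, region_codes[i], Establishment.NATIVE))
        if rng.random() < config.introduced_rate and len(native_set) < config.n_regions:
            others = [i for i in range(config.n_regions) if i not in native_set]
            j = others[int(rng.integers(len(others)))]
            occurrences.append(OccurrenceRecord(
                taxon, region_codes[j], Establishment.INTRODUCED))
        category = ThreatCategory(categories[int(rng.choice(len(categories), p=probs))])
        if rng.random() < config.exsitu_zero_inflation:
            accessions = 0
        else:
            accessions = int(rng.geometric(config.exsitu_geom_p))
        conservation.append(ConservationRecord(taxon, category, accessions))
    return occurrences, conservation


# ---------------------------------------------------------------------------
# Full bundle and recovery experiment
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    config: SimConfig
    tree: PhyloTree
    crosses: list[CrossRecord]
    taxa: dict[str, TaxonRecord]
    occurrences: list[OccurrenceRecord]
    conservation: list[ConservationRecord]
    ground_truth: GroundTruth


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Run all generators off one seeded stream, in documented order
    (tree, evidence, ploidy, conservation)."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    crosses, gt = simulate_evidence(tree, config, rng)
    ploidy = simulate_ploidy(tree, config, rng)
    tips = tree.tip_labels
    occurrences, conservation = simulate_conservation(tips, config, rng)
    gt.two_n = {t: ploidy[t] for t in tips}
    native = {}
    for occ in occurrences:
        if occ.establishment is Establishment.NATIVE:
            native.setdefault(occ.taxon, set()).add(occ.region_code)
    gt.regions = {t: frozenset(native.get(t, set())) for t in tips}
    gt.threat = {r.taxon: r.threat_category.value for r in conservation}
    gt.accessions = {r.taxon: r.exsitu_accessions for r in conservation}
    crop_set = set(gt.crops)
    taxa = {
        canonical_name(t): TaxonRecord(
            name=t, genus=t.split("_")[0], is_crop=t in crop_set,
            chromosome_counts=ploidy[t],
        )
        for t in tips
    }
    return SimBundle(config, tree, crosses, taxa, occurrences, conservation, gt)


def ground_truth_frame(gt: GroundTruth) -> pd.DataFrame:
    rows = []
    for crop in gt.crops:
        rows.append({
            "crop": crop,
            "radius": format(gt.radius[crop], ".10g"),
            "n_compatible": len(gt.compatible[crop]),
            "compatible": ";".join(sorted(gt.compatible[crop])),
            "anchors": ";".join(sorted(gt.anchors[crop])),
        })
    return pd.DataFrame(rows)


def recovery_experiment(config: SimConfig, n_replicates: int = 100,
                        policy: AnchorPolicy = AnchorPolicy.Y_AND_YSTAR,
                        ) -> pd.DataFrame:
    """Simulate, infer thresholds, predict, and score against ground truth.

    Returns one row per (replicate, crop): the true radius r, the inferred
    tau and its anchoring distance (identical by construction), and the
    sensitivity/specificity of the predicted compatible set.  Crops whose
    threshold is undefined (no surviving anchor) carry NaN metrics.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(n_replicates) % (2**31)
    rows = []
    for rep, child_seed in enumerate(seeds):
        cfg = dataclasses.replace(config, seed=int(child_seed))
        tree = simulate_tree(cfg)
        records, gt = simulate_evidence(tree, cfg)
        matrix = patristic_matrix(tree)
        n_taxa = len(matrix.labels)
        for crop in gt.crops:
            thr = infer_threshold(crop, matrix, records, policy)
            row = {"replicate": rep, "crop": crop, "r": gt.radius[crop],
                   "tau": np.nan, "max_anchor_distance": np.nan,
                   "sensitivity": np.nan, "specificity": np.nan,
                   "n_true": len(gt.compatible[crop]), "n_predicted": 0}
            if thr.tau is not None:
                preds = predict_cwrs(crop, matrix, thr, records)
                predicted = {canonical_name(p.candidate) for p in preds}
                true = set(gt.compatible[crop])
                negatives = n_taxa - 1 - len(true)
                fp = len(predicted - true)
                row.update({
                    "tau": thr.tau,
                    "max_anchor_distance": matrix.distance(crop, thr.anchor_relative),
                    "sensitivity": len(predicted & true) / len(true) if true else np.nan,
                    "specificity": 1.0 - fp / negatives if negatives else np.nan,
                    "n_predicted": len(predicted),
                })
            rows.append(row)
    return pd.DataFrame(rows)
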
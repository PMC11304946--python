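# cwrphylo

Phylogenetic-distance screening of crop wild relatives (CWRs), with an ex
situ conservation gap analysis — built for the cultivated Brassicaceae and
their wild relatives, but generic over any rooted trees plus cross-evidence
tables.

## The problem

Breeding programmes want wild species that can be crossed with a crop by
conventional means. Direct crossing data (the Harlan & de Wet gene-pool
classification) exist only for a handful of well-studied crops; for most
minor crops nobody has tried. Phylogenetic distance offers a proxy: if a
crop has *documented* successful sexual crosses with some wild relatives,
then any species at least as close on the tree is a plausible candidate for
a crossing attempt.

`cwrphylo` implements that screen:

1. **Normalize.** Each per-marker tree (e.g. *mat*K, ITS) is transformed to
   ultrametric and rescaled so every root-to-tip path is 1.0. Patristic
   distances PD(i, j) — path-length sums between tips — are then
   dimensionless, bounded by 2, and comparable across markers.
2. **Anchor.** For each crop *c* with cross-evidence records
   (Y = successful conventional cross, Y\* = successful with very low
   success, N = unsuccessful/biotech-only, NI = no information), the
   compatibility threshold is

   τ(c) = max { PD(c, w) : w has Y (or Y\*) evidence with c },

   i.e. the distance to the furthest *known* cross-compatible relative.
3. **Predict.** Every taxon with PD(c, t) ≤ τ(c) is proposed; taxa with no
   prior record or gene-pool/taxon-group classification are the *new*
   candidates. Crops with no usable anchor fall back to a maximum-congener
   radius, always flagged `fallback`.
4. **Check ploidy.** Candidate pairs are annotated by cytotype (2n) overlap
   — shared, disjoint, or unknown — because same-ploidy crosses are the
   recommended first attempt.
5. **Gap-scan.** Occurrence, threat, and seed-bank accession tables are
   reduced to per-botanical-country (TDWG level 3) counts of native taxa,
   single-region endemics, threatened taxa (CR/EN/VU), taxa with no ex situ
   accessions, and underrepresented taxa (1–4 accessions).

A seedable synthetic-data generator (Yule trees, radius-based evidence with
missingness, chromosome-number evolution with whole-genome duplication and
dysploidy, heavy-tailed range sizes, zero-inflated accession counts)
provides full pipelines with known ground truth, so threshold recovery can
be measured. See `docs/methods.md` for the model details and assumptions.

## Worked example

The package ships a digitized version of the published crop × relative
distance table (matK and ITS markers, with Y/Y\*/N/NI flags). Running the
screen on it:

```python
from cwrphylo import (AnchorPolicy, DistanceMatrix, infer_threshold,
                      load_table1_fixture, predict_cwrs, table1_crosses,
                      table1_distances)

entries = load_table1_fixture()
records = table1_crosses(entries)

matrix = DistanceMatrix.from_crop_star(
    "Sinapis alba", table1_distances(entries, "Sinapis alba", "matK"))
thr = infer_threshold("Sinapis alba", matrix, records,
                      AnchorPolicy.Y_AND_YSTAR, marker="matK")
print(thr.tau, thr.anchor_relative)
for p in predict_cwrs("Sinapis alba", matrix, thr, records)[:3]:
    print(f"{p.candidate:30s} PD={p.pd:.5f} new={p.is_new}")
```

prints

```
0.0251 Coincya monensis
Kremeriella cordylocarpus      PD=0.00956 new=True
Brassica carinata              PD=0.01578 new=True
Brassica nigra                 PD=0.01578 new=False
```

White mustard's furthest documented cross (Y, *Coincya monensis*) sits at
PD 0.0251; *Kremeriella cordylocarpus* at PD 0.00956 is closer than every
documented cross-compatible relative and has no crossing record, so it is
proposed as a new candidate CWR. *Brassica nigra* is inside the radius too,
but its Y\* record means it is already known, not new.

The same flow is available from the shell:

```sh
cwrphylo simulate  --seed 7 --out sim/            # synthetic bundle
cwrphylo distances --tree sim/tree.nwk --out dist/
cwrphylo predict   --tree its=sim/tree.nwk --crosses sim/crosses.tsv \
                   --taxa sim/taxa.tsv --out pred/
cwrphylo predict   --fixture --out fix/           # worked-example table
cwrphylo gapscan   --occurrences sim/occurrences.tsv \
                   --conservation sim/conservation.tsv --out gap/
```

Every subcommand writes a `manifest.json` of the parameters used and is
byte-reproducible given the same inputs and seed.

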
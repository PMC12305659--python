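# phenomet

Morphology-guided prediction of bioactive metabolites: integrates
image-based morphological profiles (Cell Painting-style cell × feature
tables) with untargeted LC-MS feature tables to rank which chromatographic
features in complex extracts drive a phenotype.

The pipeline:

1. **HistDiff normalization** (`phenomet.histdiff`) — per-well signed
   scores per feature against pooled vehicle-control cells, per-sample
   phenotype-strength (CP) scores (Euclidean norm), and a vehicle-based
   activity filter.
2. **Feature reduction** (`phenomet.featsel`) — fast correlation-based
   filtering (FCBF) with symmetrical uncertainty; removes invariant and
   redundant features.
3. **Phenotype clustering** (`phenomet.cluster`) — Spearman-distance /
   Ward-linkage hierarchical clustering, gated into flat clusters at the
   lowest height at which the positive-control replicates become one
   contiguous cluster.
4. **MS annotation** (`phenomet.annotate`) — molecular-formula parsing,
   monoisotopic masses, adduct m/z ([M+H]+, [M+Na]+, neutral-loss
   adducts, …) and signed ppm matching against a compound database.
5. **Bioactivity network** (`phenomet.network`) — per-MS-feature
   *activity score* (mean of per-extract mean squared fingerprint values)
   and *cluster score* (mean pairwise Pearson correlation of containing
   extracts), thresholded (defaults 0.03 / 0.5) into a bipartite
   sample–feature graph with seeded Louvain communities, exported as
   GraphML + CSV.
6. **Synthetic data** (`phenomet.synth`) — 384-well (or compact 96-well)
   plates with vehicle borders, positive-control and 2-fold sample
   dilution series, planted multivariate phenotype effects, and LC-MS
   tables whose "active" features co-occur with planted phenotype
   classes — full ground truth for recovery testing.

## CLI

```bash
phenomet run-all --config src/phenomet/data/demo.yaml --out runs/demo
# or stage by stage:
phenomet synth    --config cfg.yaml --out runs/s
phenomet profile  --cells runs/s/cell_tables.csv --plate-map runs/s/plate_map.csv --out runs/p
phenomet select   --profiles runs/p/well_profiles.csv --cp-scores runs/p/cp_scores.csv \
                  --retained runs/p/retained_samples.csv --out runs/selected.csv
phenomet cluster  --fingerprints fp.csv --positives id1,id2 --out runs/c
phenomet annotate --features ms.csv --db compounds.csv --out runs/annotations.csv
phenomet network  --features ms.csv --profiles bioactivity.csv --out runs/n
```

`run-all` writes every stage output plus `manifest.json` (config hash,
seed, library versions); re-running the same config reproduces all CSV
outputs byte for byte.

## File formats (all plain text)

- **Plate map** CSV: `well,kind,treatment_id,concentration`
  (kind ∈ vehicle / positive_control / sample; vehicle rows have empty
  concentration).
- **Cell tables** CSV (long format): column `well`, then one column per
  raw feature; one row per cell.
- **MS feature table** CSV: first column `feature` with ids of the form
  `"<rt>_<mz>"` (e.g. `1.87_416.2431`), remaining columns per-sample
  intensities.
- **Compound DB** CSV: `name,formula[,cas]`.
- **Bioactivity profiles** CSV: first column sample id, remaining columns
  fingerprint values in [0, 1].
- Dendrograms are Newick; networks are GraphML plus `*_nodes.csv` /
  `*_edges.csv`.

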
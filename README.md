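# areaevo

Historical biogeography of large clades from barcode-style sequence data:
a tested, reusable pipeline covering

- **OTU clustering** — greedy centroid clustering at a fixed identity
  threshold with an exact affine-gap global aligner (`areaevo.clustering`);
- **area assignment** — cascade assignment of sequences and OTUs to
  biogeographic areas from country records, coordinates and manual codes,
  with introduced-occurrence overrides (`areaevo.geo_assignment`);
- **supertree assembly** — support-filtered constraint extraction and
  rescale-grafting of relatively calibrated subclade trees into a unit-root
  backbone, with absolute-time scaling under a calibration triple
  (`areaevo.supertree`);
- **ancestral areas** — the one-parameter equal-rates Markov (Mk) model over
  k areas with polymorphic/missing tips: pruning likelihood, 1-D ML rate
  fit, and marginal (relative-likelihood) reconstruction (`areaevo.mk_model`);
- **stochastic mapping** — endpoint-conditioned area histories sampled by
  uniformization, dispersal-event counting with quantile summaries,
  time-windowed immigration/emigration, and network filtering
  (`areaevo.simmap`);
- **focal lineages** — connected above-threshold lineage extraction,
  stem/crown ages with calibration uncertainty, and overlap with geological
  event windows (`areaevo.lineages`);
- **diversification partitioning** — pairing of per-branch rate posterior
  samples with stochastic maps, branch segmentation by joint regime, and
  duration-weighted per-area rate summaries through time
  (`areaevo.rate_partition`);
- **synthetic data** — birth–death trees with rate shifts, Mk tip characters
  with controlled polymorphism/missingness, sequence families with
  controlled identity, and metadata with known true areas, so the whole
  pipeline is testable offline (`areaevo.synthetic_data`).

Core formats (`areaevo.io_core`): Newick with support labels, FASTA, TSV
metadata, GeoJSON area polygons, and per-branch piecewise rate tables.

## Command-line interface

All stages are exposed under one entry point:

```sh
areaevo cluster   --fasta in.fa --threshold 0.97 --accept-mode first --out otus.tsv
areaevo assign    --metadata meta.tsv --areas areas.geojson --countries countries.yaml --out areas.tsv
areaevo graft     --backbone bb.nwk --subtree sub.nwk --shared shared.tsv --out supertree.nwk
areaevo scale     --tree supertree.nwk --age 60 --low 57 --high 64
areaevo fit-areas --tree supertree.nwk --areas areas.tsv --out marginals.tsv
areaevo simmap    --tree supertree.nwk --areas areas.tsv --q 0.05 --n 100 --seed 42 --out maps.tsv
areaevo lineages  --tree supertree.nwk --marginals marginals.tsv --areas areas.tsv \
                  --focal And,CAm,Pat,TSA --age 60 --low 57 --high 64
areaevo rates-by-area --tree supertree.nwk --rates rates.tsv --maps maps.tsv \
                  --windows 20 --max-frac 0.02 --seed 7 --out rates_by_area.tsv
```

A default nine-area scheme (And, CAm, Pat, TSA, Afr, Aus, Ind, Nea, Pal)
with a country lookup table and geological event windows ships as editable
YAML under `src/areaevo/data/`.

## Conventions

- Node ages run backward from the tips (age 0 = present); branch pieces are
  addressed by `(older_age, younger_age)`.
- Trees are relative (root crown age 1) until scaled by a calibration
  triple `(low, point, high)` in Myr; report rounding is half-up to 0.1 Myr.
- Identity = matching columns / alignment columns under match +1,
  mismatch −1, gap open −2, gap extend −1 (terminal-gap exclusion optional).
- Quantile ranges use linear interpolation between order statistics;
  dispersal events are dated where the new state begins, and events exactly
  on a time-window boundary belong to the older window.

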
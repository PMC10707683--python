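# netmod

Community detection for weighted networks by **consensus-weighted modularity
maximization**, plus:

- a seeded Louvain-style modularity optimizer with a resolution parameter
  (`netmod.modularity`),
- the two-round consensus filter (`wmm`) and a permutation-thresholded
  association-matrix baseline (`robust_mm`) (`netmod.consensus`),
- a two-level variant that subdivides each detected community only when the
  mean within-community attribute (e.g. spatial) distance drops
  significantly under a size-preserving permutation null
  (`netmod.hierarchy`),
- partition metrics: normalized mutual information and ensemble stability
  via average node entropy with overlap-based label matching
  (`netmod.metrics`),
- synthetic planted-partition benchmark generators (weighted LFR-style,
  attributed, and a nested two-level fixture) (`netmod.benchmarks`),
- group-level density-thresholded correlation-network construction from
  ROI x time matrices (`netmod.fmri`),
- paired method-comparison experiments (`netmod.study`).

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (method-comparison
directions, metric oracles, type-I control of the permutation test); the
remaining files are per-module unit and property tests.

## CLI

All functionality is exposed through one entry point:

```bash
# generate a weighted planted-partition benchmark
netmod simulate benchmark --n 300 --k 15 --maxk 75 --mu 0.4 --reps 5 \
    --seed 7 --out bench/

# detect communities (consensus-weighted; defaults L=100, M=K=50)
netmod detect wmm --input bench/net_000.edges.tsv --pool 100 --m 50 --k 50 \
    --gamma 1.0 --seed 7 --out part.tsv

# plain modularity maximization, the thresholded-association baseline
netmod detect mm --input bench/net_000.edges.tsv --seed 7 --runs 20 --out mm/
netmod detect robust-mm --input bench/net_000.edges.tsv --pool 100 \
    --alpha 0.05 --seed 7 --out rb.tsv

# two-level detection with spatial node attributes
netmod detect two-step --input edges.tsv --attrs coords.tsv \
    --permutations 10000 --alpha 0.05 --seed 7 --out hier.tsv \
    --report tests.json

# evaluate partitions
netmod evaluate nmi --a part.tsv --b bench/net_000.truth.tsv
netmod evaluate stability --parts mm/ --out stability.json
netmod evaluate study --n 100 --mu 0.2,0.4,0.6 --networks 5 --runs 5 \
    --methods mm,wmm --seed 7 --out study.csv

# correlation networks from ROI time series
netmod simulate timeseries --blocks 1,1,1,2,2,2 --subjects 10 --out subj/
netmod network build --ts-dir subj/ --density 0.10 --subset 90 \
    --resamples 100 --seed 7 --out nets/
```

Every stochastic command records its parameters, seeds and input checksums
in a `manifest.json` next to its outputs; reruns with the same seed are
byte-identical.

## File formats (all plain text)

- edge list: `node_i<TAB>node_j<TAB>weight`, one undirected edge per line
- partition: `node_id<TAB>label`
- attributes: header `node_id<TAB>x<TAB>y<TAB>...`, one row per node
- ROI time series: `roi_id<TAB>v1<TAB>v2<TAB>...`, one row per ROI
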
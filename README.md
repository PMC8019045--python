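# multisoc

Temporal social-network analysis for multi-level animal societies.

Some primates (and elephants, equids, and cetaceans) live in *multi-level
societies*: stable core units that aggregate into clans, which share a home
range as a band. Field teams study these societies with focal-follow scan
sampling — one focal core unit per day, an instantaneous scan every 2 h
recording which other units sit within an association radius. `multisoc`
turns such scan streams (plus phenology, rainfall and dispersal records)
into the standard analyses of this literature:

- **Dyadic association.** The simple association index of units A and B is

  `AI(A,B) = N_AB / (N_AB + N_A-only + N_B-only)`

  — the fraction of scans containing both among scans containing either,
  so AI = 1 means always together and AI = 0 never together. It is the
  right index when every associated unit can be positively identified.
- **Clan structure.** Agglomerative clustering of units on AI similarity
  (average / Ward / complete / single linkage), linkage selection by the
  cophenetic correlation coefficient (CCC), and clan extraction by cutting
  the dendrogram at AI = 0.05. Partitions across periods are compared by
  adjusted Rand index and a minimal set of moved units.
- **Preferred/avoided association.** Data-stream permutation test on the
  coefficient of variation (CV) of dyadic AIs: sequential swaps of
  associates between scans preserve group sizes and each unit's sighting count
  while destroying consistent partner preference; right-tailed p with the
  add-one estimator.
- **Temporal networks.** Weighted networks on a 31-day sliding window
  (degree, strength, edge density, global clustering coefficient), cosine
  similarity between windows (lag-1 and to-first stability), 95%
  highest-density bootstrap intervals, a chance-encounter density band
  from data-stream permutations, and a signal/noise window-size selector.
- **Ecological drivers.** Monthly food availability indices
  (FAI = Σ species mean phenology score × basal area) joined with
  rainfall, z-scored, and regressed against network metrics with AR1
  errors — a linear model at the network level, and a multi-level model
  with unit random intercepts and within-unit AR1 errors at the node
  level; Gelman R² effect sizes with parametric-bootstrap intervals.
- **Male dispersal.** Dispersal-month assignment from last-seen/first-seen
  ranges, Monte-Carlo Spearman correlation of monthly transfer counts with
  ecology (Bonferroni α = 0.017), and exact one-sample Wilcoxon tests of
  whether a dispersal dyad keeps associating above its baseline in the
  three post-dispersal months.
- **Synthetic societies.** `multisoc.simulate` generates complete datasets
  with known ground truth (clan partition, effect sizes, dispersal
  events) under a logistic association model with clan, fruit and
  post-dispersal-bond effects, so every stage of the pipeline is testable
  end to end without field data.

## Worked example

Simulate a two-clan society (12 units, 150 days), recover its clans, and
test for preferred association:

```console
$ multisoc simulate --preset strong-clan --seed 1 --out-dir demo/data
dataset written to demo/data
$ multisoc clans demo/data/scans.csv --cutoff 0.05 --out-dir demo/clans
selected linkage: average; 2 clans at AI >= 0.05
$ multisoc permtest demo/data/scans.csv --n-perm 1000 --seed 1 --out-dir demo/perm
CV_obs = 0.693, CV_rand = 0.284, p = 0.0010
```

`demo/clans/ccc.json` records the linkage comparison — average linkage
fits best (CCC 0.960 vs 0.944–0.951 for the others) — and
`demo/clans/clans.csv` assigns each unit to a clan; at the 0.05 AI cut the
two simulated clans are recovered exactly. The permutation test shows the
observed CV of dyadic AIs (0.693) far exceeds its expectation under 1,000
data-stream permutations (0.284): units have strongly preferred
companions, as built into the generator. Other subcommands (`networks`,
`fai`, `models`, `dispersal`) chain the remaining stages; each writes a
`manifest.json` with input digests and the seed, and identical seeds
reproduce identical outputs byte for byte.

The same surface is available as a library:

```python
from multisoc import association_matrix, build_tree, cut_clans
from multisoc.io import read_scans

scans = read_scans("demo/data/scans.csv")
matrix = association_matrix(scans)
clans = cut_clans(build_tree(matrix, "average"), cutoff=0.05)
```

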
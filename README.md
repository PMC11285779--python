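# jawmorph

Comparative functional morphology of sympatric marine-reptile lower jaws.

Jurassic seaways were shared by plesiosaurians, ichthyosaurians and
thalattosuchian crocodylomorphs. Their mandibles record how these lineages
divided prey resources: robust, short-symphysis jaws with high mechanical
advantage suit macrophagy and durophagy, while long gracile jaws with fast
opening suit small, agile prey. `jawmorph` turns a table of raw mandibular
measurements (mm) into that ecological signal: biomechanical characters, a
morphofunctional morphospace, and permutation-based tests of guild and clade
separation, disparity and classifiability. A seeded synthetic-assemblage
generator reproduces the statistical structure of a two-formation fossil
assemblage (Oxford Clay and Kimmeridge Clay style), so the entire pipeline
is testable without any external data.

## The model

The mandible is a lever with its fulcrum at the articular glenoid, a
distance RPL (retroarticular process length) from the posterior end of the
ramus. With in-lever *i* (adductor insertion length maL, or an explicit
closing in-lever ILc) and out-levers measured from the fulcrum:

```
aMA  = i / (ML − RPL)                 anterior bite point
pMA  = i / ((ML − RPL) − TRL)         posterior end of the tooth row
ltMA = i / ((ML − RPL) − DLT)         largest tooth position
oMA  = RPL / (ML − RPL)               opening; LOW oMA = fast opening
```

Eleven dimensionless characters (seven length ratios to mandibular length
ML, the tooth index TI = largest-crown height/ML, and aMA, pMA, oMA) are
z-corrected and ordinated by principal coordinate analysis on Euclidean
distances (classical scaling, identical to PCA for Euclidean input). On the
full set of PCo axes the package runs:

* **PERMANOVA** (distance-based pseudo-F, permutation null; exact
  enumeration for small samples, Bonferroni and Benjamini–Hochberg adjusted
  pairwise tables);
* **disparity** as the sum of per-axis sample variances, with bootstrap
  CIs, two-tailed permutation tests of group differences, and
  rank-sum comparisons of bootstrap distributions;
* **jackknifed LDA** (leave-one-out, equal priors) to measure how well the
  characters predict clade or feeding-guild membership;
* **univariate trait comparisons** (Welch t and rank-sum, Bonferroni
  within each metric) of size, robustness, tooth index and the functional
  metrics maL/ML, ltMA, oMA.

## Worked example

The numbered drivers under `analysis/` run the study end to end on the
default synthetic assemblage (47 specimens, 25 OCF / 22 KCF), writing
tables to `results/`:

```
$ python analysis/01_simulate_assemblage.py
wrote 47 specimens to results/specimens.csv
$ python analysis/03_morphospace.py
variance explained by PCo1-3: 50.8% / 17.2% / 15.3% (cumulative 83.4%)
$ python analysis/04_group_separation.py
[clade] one-way PERMANOVA: pseudo-F = 5.36, p = 0.0001 (9999 permutations)
  pairwise: 4/15 pairs separated at Bonferroni p < 0.05
  jackknifed LDA recovery: 63.8%
[guild] one-way PERMANOVA: pseudo-F = 35.54, p = 0.0001 (9999 permutations)
  pairwise: 14/15 pairs separated at Bonferroni p < 0.05
  jackknifed LDA recovery: 89.4%
```

Guild membership structures the synthetic morphospace strongly (all-guild
pseudo-F ≈ 36, nearly every guild pair separated after Bonferroni
correction, ~89% leave-one-out recovery); clades separate more weakly
because in the generator clades differ only through their guild
composition. The same stages are available as a CLI
(`jawmorph simulate|characters|ordinate|permanova|disparity|lda|compare|run-all`);
`run-all` emits a results bundle with a content-hashed manifest that is
identical hash-for-hash when re-run with the same seed.

To analyse real measurements, provide a CSV in the schema of
`results/specimens.csv` (column names `specimen_id, taxon, clade,
sublineage, guild, time_bin, ML, ASD, MSL, MSD, TRL, CPD, RPL, maL, LCH,
DLT, ILc, eTRD, eTRW, source_note`) and pass it to `jawmorph run-all
--input your_table.csv`.

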
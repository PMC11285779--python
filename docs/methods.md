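# Methods

## Lever model and characters

A lower jaw is modelled as a 2-D lever along its long axis. The fulcrum
sits at the articular glenoid, RPL from the posterior end of the ramus, so
the anterior out-lever is `ML − RPL`. The tooth row is assumed to begin at
the anterior tip, giving a posterior out-lever `(ML − RPL) − TRL`; the
largest-tooth out-lever is `(ML − RPL) − DLT` when the tip-to-largest-tooth
distance DLT was measured. The closing in-lever defaults to the adductor
insertion length maL — a standard proxy when the true in-lever cannot be
landmarked on fossils — and an explicit `ILc` column overrides it when
better landmark data exist. The opening in-lever is RPL itself, so
`oMA = RPL/(ML − RPL)` and low oMA reads as fast jaw opening. These
straight-line proxies ignore jaw curvature, gape-angle effects and muscle
pennation; they are comparative indices, not bite-force estimates.

Eleven dimensionless characters enter the ordination: seven length ratios
(ASD/ML, MSL/ML, MSD/ML, TRL/ML, CPD/ML, RPL/ML, maL/ML), the tooth index
TI = LCH/ML (largest crown height is used as the tooth dimension), and the
three mechanical advantages aMA, pMA, oMA. ltMA is carried as an auxiliary
metric for the univariate comparisons only, and ML (mm) is kept out of the
ordination as the separate size metric (compared on a log10 scale by
default, since sizes span roughly 250–2050 mm). Given these contracts two
characters are deterministic functions of the others
(`oMA = Ch6/(1 − Ch6)`, `pMA = aMA·(1 − Ch6)/(1 − Ch6 − Ch4)`); they are
retained in the character set because they carry the functional
interpretation, and their redundancy is harmless to distance-based methods.

Characters are z-corrected column-wise with the sample (ddof = 1) standard
deviation; constant columns raise an error rather than being silently
zeroed, and the recorded means/sds define an exact inverse transform.

## Ordination

Classical scaling (PCoA) of the Euclidean distance matrix: double-centre
the squared distances, eigendecompose, scale eigenvectors by the square
root of the positive eigenvalues. Eigenvalues within `1e−8 × λ_max` of zero
are clamped and dropped; more negative eigenvalues abort, since Euclidean
input guarantees positive semidefiniteness up to round-off. Axes are
ordered by descending eigenvalue (stable order breaks exact ties) and each
axis is oriented so its largest-magnitude score is positive, making outputs
diffable. Variance-explained fractions are taken over the positive
eigenvalues. All retained axes feed the statistics; the first three are for
plotting.

## Inference

**PERMANOVA.** Pseudo-F from squared inter-point distances
(`SS_total = Σ_{i<j} d²_ij / n`, within-group analogue by group, F =
(SS_between/(g−1))/(SS_within/(n−g))). The null permutes group labels; when
the number of distinct label arrangements is ≤ 100,000 and not larger than
the requested Monte-Carlo count the test enumerates all of them and reports
the exact fraction, otherwise it samples (default 9999 permutations) and
uses (count + 1)/(n + 1) so p is never zero. Monte-Carlo permutations are
drawn on the sorted label codes, which makes p invariant to group renaming;
exact row-order invariance holds in the exhaustive regime. Pairwise tables
carry both Bonferroni and Benjamini–Hochberg columns, with the multiplier
counting only pairs actually tested; groups under the minimum size
(default 3) are skipped with a logged diagnostic, mirroring what sparse
fossil subgroups force in practice.

**Disparity.** Sum of per-axis sample variances (= trace of the group
covariance). Over all retained PCo axes this equals the same sum on the
z-corrected characters, which is asserted by test. Bootstrap CIs are
percentile 2.5/97.5 over 1000 resamples. The permutation test pools two
groups, re-splits at the original sizes (splits are drawn on the smaller
group size over the id-sorted pool, making p invariant to swapping the
groups) and compares |ΔSoV| two-tailed. Rank-sum tests between bootstrap
distributions are reproduced for comparability but flagged as
anti-conservative: bootstrap replicates are pseudo-replicates, so the
permutation test is the primary inference. Percentile bootstrap CIs for a
variance-type statistic undercover modestly at small n (measured ≈ 0.85–0.91
at n = 20 against a nominal 0.95; BCa is no better here) — a property of
the method documented rather than hidden.

**Jackknifed LDA.** Leave-one-out linear discriminant classification with
equal priors and pooled within-class covariance (scikit-learn, svd solver;
an lsqr + shrinkage retry guards near-singular covariances, logged when it
engages). Classes below the minimum size are excluded with a warning.
Feature set defaults to the 11 z-scored characters, with full-space PCo
scores as an equivalent option.

**Trait comparisons.** Welch (unequal-variance) t-tests — group variances
plainly differ, e.g. plesiosauroid vs pliosaurid sizes — and two-sided
rank-sum tests (exact when both n ≤ 12 without ties, tie-corrected normal
approximation otherwise), Bonferroni corrected within each metric's family
of pairs rather than across metrics, matching the per-panel presentation of
guild/clade box-plot figures. The heatmap matrix reuses the same
z-correction with caller-supplied row order (e.g. informal phylogeny
order).

## Synthetic assemblage generator

The generator emulates the statistical structure the analysis assumes: six
feeding-guild archetypes (Cut, Generalist, Pierce I, Pierce II, Smash,
Crunch), clades nested into guilds with the study's composition (14/4/4/12/
8/5 across clades; 25 OCF vs 22 KCF), and a lognormal size axis. An
archetype is a mean vector over the free parameters — the eight ratio
characters, aMA, and the largest-tooth position fraction DLT/TRL — plus a
log-ML size model; pMA, oMA and ltMA are derived through the lever
contracts so that back-solved measurements reproduce the drawn characters
exactly. Archetype means encode the qualitative guild grid: macrophagous
guilds short-symphysed with high ltMA and large adductor insertions
(MSL/ML means 0.25–0.44 vs 0.50 for piercers/smashers); Pierce I smallest
bodied with the shortest symphysis and highest TI; Smash with the lowest
oMA (fastest opening) and lowest TI; Generalist the largest bodied; opening
speed ordered Smash < Pierce II < Crunch in oMA. Exact mean values beyond
these ordinal and range constraints are the package's own calibration,
held in config data rather than code constants.

Specimens are drawn from a multivariate normal around the (possibly
shrunken) archetype mean — per-parameter sds of roughly 0.01–0.04 on the
ratio scale and 0.18 on log-ML, chosen as within-guild spreads comparable
to but smaller than the between-guild mean differences — with rejection
sampling to (0.005, 0.995) on ratios and a 2%-of-ML floor on the posterior
out-lever. `effect_scale` shrinks every archetype mean toward the common
centroid (0 = exact null for calibration, 1 = full separation);
`noise_scale` multiplies all sds (0 = archetype means exactly). Identical
seed and config give byte-identical tables.

What the generator does **not** emulate: phylogenetic autocorrelation
(clades differ only through guild composition, so clade-level separation
and LDA recovery are weaker than in real assemblages where lineages carry
their own morphological signatures); measurement error and missing data
(an explicit override/optional-column mechanism exists instead); and any
covariance between characters beyond the optional archetype correlation
matrix (identity by default). Passing tests therefore demonstrate the
statistical machinery, not that real jaw evolution follows the archetype
model.

## Problem sizes and determinism

Type-I calibration runs 1000 null replicates of a balanced 30-specimen
assemblage with 199 permutations per test (a 5%-level rejection then
corresponds to an exact permutation rank, keeping the nominal level exact);
power and recovery use 100 replicates of 48 specimens with 999
permutations, enough to resolve Bonferroni-corrected p < 0.05 over 15
pairs. Default analysis runs use 9999 permutations and 1000 bootstrap
replicates. Every stochastic operation takes an explicit seed, recorded in
its output; the pipeline derives per-stage seeds from one master seed and
writes them, with content hashes of every output file, into the results
manifest.

## Known limitations

* Lever arms are straight-line proxies; curved or dorsoventrally deep jaws
  violate the 2-D idealization in ways the characters cannot express.
* The tooth row is assumed to reach the anterior tip; taxa with edentulous
  symphyseal tips would need the explicit override columns.
* Monte-Carlo permutation p-values are seed-reproducible but not invariant
  to specimen row order (the exhaustive regime is).
* The Wilcoxon-on-bootstrap disparity matrix inherits pseudo-replication;
  its p-values are presentation-compatible, not primary evidence.
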
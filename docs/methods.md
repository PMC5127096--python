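# Methods

## Scope

`guttype` implements a distance-based enterotyping and cohort-statistics
workflow for taxon count tables, and a generator of synthetic cohorts with
the structure that workflow assumes. Upstream read processing (QC, OTU
picking, taxonomic classification) and phylogeny-dependent metrics
(phylogenetic diversity) are out of scope: the package starts from a count
table, a taxonomy map and sample metadata.

## The synthetic cohort generator

Each sample i is generated as

1. archetype zᵢ ~ Categorical(mixing proportions);
2. composition pᵢ ~ Dirichlet(θ · m_z), where m_z is the archetype's mean
   composition (a probability vector over the taxa) and θ > 0 is the
   concentration — the Dirichlet precision; the larger θ, the tighter the
   cloud around the archetype mean;
3. library depth Nᵢ = max(100, round(Normal(μ_d, σ_d))); the defaults
   μ_d = 10,252 and σ_d = 2,406 reads match a typical MiSeq 16S cohort, and
   the floor avoids degenerate libraries that a real pipeline would discard;
4. counts cᵢ ~ Multinomial(Nᵢ, pᵢ). Row sums equal the drawn depths exactly.

The default configuration emulates a nationwide adult cohort: 516 subjects,
66 bacterial families, seven regions of residence with fixed subject counts
(38, 40, 193, 49, 49, 48, 99) and a 325:191 female:male split. Region and
gender are allocated *without replacement* so the per-stratum counts are
exact (scaled by largest remainder when `n_samples` differs from 516); ages
are drawn from Normal(52.4, 13.4) clipped to 21–88 and BMI from
Normal(22.0, 4.0) clipped to 14–45, which puts roughly 80 % of subjects
below BMI 25 and about 2.5 % above BMI 30 — enough to exercise the
lean/obese stratification at realistic imbalance.

The first ten taxon labels are the families that carry named roles in this
kind of analysis (Bacteroidaceae, Lachnospiraceae, Ruminococcaceae,
Prevotellaceae, Bifidobacteriaceae, Christensenellaceae, Mogibacteriaceae,
Rikenellaceae, Lactobacillaceae, Bacillaceae); the rest are synthetic
fillers. `archetype_composition` fixes the dominant families' fractions and
spreads the remaining mass over the other taxa with geometrically decaying
weights — a crude stand-in for the long tail of rare families. The default
mixture has two archetypes (73 % Bacteroides-type, 27 % Prevotella-type,
θ = 35) with the three bowel-movement-associated families jointly elevated
in the Bacteroides-type archetype, so their abundances correlate positively
across the cohort, as they do in real data.

### Questionnaire coupling

An ordinal item coupled to a taxon set at target Kendall τ is generated by a
Gaussian copula: the per-sample mean rank of the coupled taxa's relative
abundances is mapped to standard-normal scores z_x (standardized, because
ties from undetected taxa compress midrank scores), a latent
z = ρ·z_x + √(1−ρ²)·ε is drawn with ρ = sin(πτ/2) (Greiner's relation), and
z is cut at equal-probability normal quantiles into the requested number of
levels. Discretization attenuates the realized tau-b slightly — strongly for
2-level items (a τ→1 coupling dichotomized still yields tau-b ≈ 0.7) and by
only a few hundredths for 5-level items; the calibration target is met
exactly on the continuous (many-level) side, and the tests assert it there.
The number of levels per item is a configuration parameter (default 5),
since real questionnaire instruments vary.

### What the generator does not emulate

Real 16S data has overdispersion beyond Dirichlet-multinomial (zero
inflation, taxon-specific variance), compositional correlation structure
richer than a two-archetype mixture, and metadata that covaries with
composition (the generator assigns region/gender/BMI independently of the
archetype). Tests passing on synthetic cohorts therefore demonstrate the
correctness and calibration of the *analysis machinery*, not biological
conclusions about any real cohort. Notably the default two-archetype
mixture, even at the loose default concentration, remains more separable
than a typical real national cohort, where whole-cohort enterotype
partitioning is ambiguous; single-archetype configurations are provided to
emulate that ambiguous regime.

## Distances, clustering and validation

* **Distance.** Square root of the Jensen-Shannon divergence with natural
  logarithms (the convention of the enterotyping literature this workflow
  descends from), computed in closed form from row entropies; plain JSD is
  available via a flag. √JSD is a metric bounded by √(ln 2) ≈ 0.8326.
* **PAM.** For instances with at most 300 candidate medoid sets the global
  optimum is found by enumeration (lexicographic tie-break); larger
  instances use the classic BUILD + best-improvement SWAP heuristic. Both
  routes end swap-optimal — no single medoid↔non-medoid exchange lowers the
  sum of distances to nearest medoids — and all ties break toward the lowest
  sample index, so results are deterministic. The exact small-instance path
  exists because BUILD+SWAP (in ours and in reference implementations alike)
  can terminate in a genuinely suboptimal swap-local optimum on a few
  percent of tiny instances; enumeration is cheap there and removes the
  ambiguity.
* **UPGMA.** Average linkage via `scipy.cluster.hierarchy`; node heights are
  half the merged distance, so the tree is ultrametric, and it serializes to
  newick with branch lengths.
* **CH index.** Computed in the principal-coordinates embedding of the
  distance matrix (positive-eigenvalue axes), where it coincides with the
  classic coordinate formula for Euclidean input. W = 0 is reported as a
  capped sentinel (10¹²) so argmax over k stays well defined. k is searched
  over 2–10 by default; ties go to the smaller k.
* **Prediction strength.** 100 random 50/50 splits by default; PAM is run on
  each half, test samples are classified to the nearest training medoid, and
  each repeat scores the minimum over test clusters (size ≥ 2; singletons
  carry no pairs) of the co-assigned pair fraction. Both fold directions are
  used and the mean over 2×repeats is returned; the seed is a required input
  wherever PS is exposed.
* **Silhouette.** Mean of (b−a)/max(a,b); singleton clusters score 0.
* **Thresholds.** PS ≥ 0.9 ⇒ "strong clustering"; SI bands ≤ 0.25 / ≤ 0.5 /
  ≤ 0.75 / > 0.75; "reliable" ⇔ PS ≥ 0.9 and SI > 0.25. PS and SI are
  evaluated at the CH-selected k by default; `force_k` pins them to a fixed
  k for sensitivity analysis, since published workflows differ on this
  point.

## Ordination

PCA operates on the column-centered (unscaled) relative-abundance matrix —
fractions, not percentages; the biplot geometry is identical up to axis
units. PCoA applies Gower double-centering to squared distances and keeps
positive-eigenvalue axes; since √JSD is metric but not guaranteed Euclidean,
the discarded negative-eigenvalue mass is recorded on the result. Axis signs
are fixed (largest-magnitude loading/coordinate positive) for reproducible
outputs; explained-variance fractions are reported to one decimal in
percent.

## Statistics

* Welch's t (Welch–Satterthwaite df) for numerical data; Mann-Whitney U for
  ordinal data with the tie-corrected normal approximation and continuity
  correction, switching to exact enumeration for untied samples of n ≤ 8;
  an all-tied comparison is reported as p = 1. Fisher's exact test uses the
  two-sided probability-mass rule. These are delegated to `scipy.stats` and
  cross-checked in the tests against enumeration oracles.
* Holm's step-down correction (via `statsmodels`) for families of pairwise
  tests; compact letter displays are built as a minimum edge-clique cover of
  the "not significantly different" graph — exhaustive over maximal cliques
  up to 12 groups (verified minimal against brute force in tests), greedy
  beyond.
* Kendall tau-b with tie-corrected denominator; p-values from the
  tie-adjusted normal approximation (cohorts of hundreds of samples make
  exact enumeration unnecessary). A constant variable makes tau undefined
  and is reported as missing, never as zero, so it can never pass a network
  filter spuriously.
* Correlation networks test all taxon-taxon (and optionally item-taxon)
  pairs and keep edges with p < 0.001 and |τ| > 0.2 — both thresholds are
  configuration, not constants. Untransformed relative abundances are used
  throughout (the rank-based tests are invariant to monotone transforms).
* BMI stratification: lean = BMI < 25, obese = BMI > 30, the middle band
  excluded; abundances compared by Welch's t (as percentages), prevalences
  by Fisher's exact test, the bowel-movement item by Mann-Whitney U, with
  stars at 0.05/0.01.

## Pipeline

`run_pipeline` executes ingest/simulate → collapse → relative + prevalence →
diversity → √JSD + UPGMA → PCA/PCoA → cluster validation (whole cohort and
per stratum, with the k-range clamped to k ≤ n/2 per stratum as prediction
strength requires) → group comparisons with letters → tau-b network → BMI
report. Every file carries a header with package version, seed and a config
hash (which deliberately excludes the output directory, so the same analysis
in two locations is byte-identical); re-running with an unchanged config and
an existing manifest is a no-op unless forced. All thresholds live in the
config with the conventional values as defaults.

## Numerical and testing choices

* Determinism everywhere a seed appears: the same seed yields bit-identical
  cohorts, splits and outputs.
* Good's coverage and Chao1 demand integer counts; Chao1 defaults to the
  bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) (defined when F2 = 0), with
  the classic form behind a flag. Shannon defaults to log base 2, the
  convention of the common amplicon pipelines, with the base configurable.
* Simulation-backed tests use cohorts of n = 120–200 at depth 10⁴ (n = 5000
  only for tau-recovery checks) and 20-seed ensembles for the
  recovery-rate properties; these sizes give comfortable statistical margins
  for every asserted bound while keeping the suite quick.
* Test oracles are independent routes: exhaustive medoid search,
  hypergeometric enumeration, hand silhouette/CH computation,
  `scipy.spatial.distance.jensenshannon`, scikit-learn's silhouette/CH on
  Euclidean data, and scikit-bio's PCoA.

## Known limitations

* The BUILD+SWAP PAM path is a local optimizer; only the small-instance path
  guarantees global optimality.
* PS with 50/50 splits needs k ≤ n/2 and loses resolution in small strata.
* The dense BIOM-style JSON reader/writer covers the simple interchange case
  only (no sparse matrices, no metadata payloads).
* The generator's independence of metadata and composition means
  region/gender comparisons on default synthetic cohorts are null by
  construction — useful for calibration tests, not for effect-size studies.
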
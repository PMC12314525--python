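# Methods

`clonearch` implements the quantitative core of a lineage-barcoded
drug-resistance evolution analysis: fitness inference from longitudinal
barcode abundances, classification of the resistance mode from replicate
concordance, classical and deep archetypal analysis of single-cell feature
matrices, TF-IDF/LSI featurization of binary accessibility matrices, and
absolute copy-number calling from low-pass log2-ratio tracks. Because the
experiments it targets involve restricted-access sequencing data, the package
ships a first-class synthetic-data module that generates every input with the
statistical structure the downstream methods assume; all guarantees in the
test suite are statements about that generator.

## Lineage dynamics and the synthetic experiment

Lineages evolve by a discrete-time branching process (step 0.1 day): a
lineage of size `n` gains `Poisson(n·b·dt)` cells and loses
`Poisson(n·d·dt)` cells per step, with per-day birth rate `b` and death rate
`d`. This is simple, seed-stable and reproduces the fluctuation behaviour
that matters here (drift to extinction, jackpot growth, power-law cumulative
clone sizes). Read counts at each sampling are multinomial over lineage
frequencies at a Poisson-realized depth (default expectation 5,000 reads per
timepoint, matching typical amplicon sequencing depth for these libraries).

Defaults follow the experimental design being emulated: 3,000–5,000 lineages
in a parental pool (simulations use 1,000–10,000 depending on the check),
sampling every 2 days, and "floating" barcode samples drawn from the death
flux between consecutive samplings — the medium is exchanged at every
sampling, so supernatant DNA reflects only deaths since the previous sample,
not a cumulative debris pool. Baseline turnover rates are not published for
these organoids; the defaults (`b = 0.6`, `d = 0.1` per day for selection
experiments, i.e. a ~1.4-day net doubling; critical `b = d = 0.5` for
neutral-drift nulls) are configurable and chosen as typical organoid culture
kinetics.

The selection scenario wires resistance into the lineages in one of three
ways:

* **preexisting** — one lineage subset (fraction `resistant_fraction`,
  default 1%) gains `selection_coefficient` (default 0.5/day) of birth rate
  inside the drug window, and the *same* subset is resistant in every
  replicate;
* **de_novo** — an independently drawn subset per replicate becomes
  resistant at `drug_start` (resistance acquired under treatment);
* **plastic** — no lineage carries a heritable fitness difference; drug
  exposure is a uniform binomial survival thinning at `drug_start`
  (survival fraction = `resistant_fraction`), which shrinks the population
  without enriching any barcode.

Sensitive lineages additionally suffer `drug_kill_rate` (default 0.3/day)
extra death inside the window in the heritable modes, so the bulk population
contracts under treatment. De-novo resistance is activated exactly at
`drug_start`; staggering acquisition times within the window would blur
enrichment magnitudes but not the replicate-concordance signature the
classifier uses, so the simpler convention is kept.

## Fitness inference

Under exponential growth the relative abundance of lineage *i* obeys
`f_i(T) = f_i(0)·exp(Δω_i·T)` with `Δω_i` the difference between the
lineage's effective growth rate and the population average, so `ln f_i(T)`
is linear in time and `Δω` (day⁻¹) is an OLS slope. Zeros are handled by a
pseudo-count (default 0.5 read) added before normalization — the log model
needs positivity and no zero-handling rule is standard, so the convention is
explicit and configurable. Fits are per contiguous experimental phase by
default (`by_phase=False` fits one line across phases); lineages with fewer
than two usable timepoints are reported with missing `Δω`, never dropped.

A known small-sample artifact, quantified by the acceptance suite: on a
critical-drift population of 10⁴ single-cell founders sampled at 5,000 reads
per timepoint, the across-barcode mean `Δω` is ≈ −0.0095/day rather than 0.
Lineages that drift to extinction hit the pseudo-count floor (their
log-frequency falls by ~ln 2 and stays there), while most never-observed
lineages contribute slope ≈ 0; the asymmetry leaves a negative bias of order
0.01/day at these settings. The bias shrinks with deeper sequencing or
larger founder sizes and does not affect the selection analyses, which are
driven by strongly positive outlier slopes.

## Power-law clone-size null

Neutral drift is the null model against which selection is judged. For a
critical branching process the *snapshot* size distribution at a fixed time
is geometric (exponential tail) — it is the *cumulative* clone size (total
progeny) whose tail follows the classical power law with exponent ≈ 3/2,
and cumulative size is exactly what floating-barcode sampling integrates
over the experiment. The null fit is therefore performed on cumulative
clone sizes. `powerlaw_null_fit` computes the discrete maximum-likelihood
tail exponent (Hurwitz-zeta normalization, `x_min` default 5) and a
Kolmogorov–Smirnov distance; `powerlaw_bootstrap` runs a parametric
bootstrap (refit per resample) for a goodness-of-fit p-value. The finite
experiment duration imposes a cutoff near `(b·t)²`, so the null is evaluated
at the experiment's own scale — 4,000 lineages over 120 days (≈ 60
floating samples every 2 days); at that scale the bootstrap accepts the
power law in ~85–100% of seeds, and the acceptance test requires ≥ 7 of 10
seeds (a 5%-level test cannot be demanded to pass always).

## Enrichment and resistance-mode classification

A barcode is *enriched* when its treated/parental frequency ratio is at
least `fold_threshold` (default 5×) and its treated frequency is at least
`min_final_freq` (default 2%, echoing the convention of greying out
sub-2% barcodes in trajectory plots). Both thresholds are configurable since
the underlying decision framework is qualitative. The mode call is then a
deterministic function of the per-replicate enriched sets: all sets empty →
plastic; mean pairwise Jaccard overlap ≥ `overlap_threshold` (default 0.5)
→ preexisting heritable; otherwise de-novo heritable. A per-replicate
Mann–Whitney test comparing final against parental log-frequencies is
recorded in the call summary as a population-level frequency-change
diagnostic but deliberately does not gate the decision, keeping the call
reproducible from the recorded statistics alone. Under the generator's
default scenarios the classifier recovers the generating mode in ≥ 95% of
seeded runs for all three modes (measured 100% at the acceptance settings).

Trajectory plots use a centered rolling mean (window 7, shrinking at the
edges); smoothing is presentation-only and is never applied before fitting.

## Archetypal analysis

Cells are modeled as convex combinations of K extreme expression states:
`X ≈ A·Z` with `Z = B·X`, `A` (N×K) and `B` (K×N) row-stochastic. Note on
orientation: cells are rows throughout, which makes `A` the cell-by-archetype
weight matrix and `B` the archetype-by-cell composition matrix — the
convention that renders the reconstruction `A·B·X` dimensionally consistent.

**Classical fit.** Alternating exact block minimization: every row of `A` is
an exact simplex-constrained least-squares solve against the current
archetypes, then each row of `B` is updated by exact block-coordinate
minimization of the full objective `‖X − A·B·X‖²_F` (update candidates that
would increase the objective are rejected, so the recorded loss history is
non-increasing by construction). The simplex solves use nonnegative least
squares with a heavily weighted sum-to-one row followed by renormalization
(constraint violation O(penalty⁻²) with penalty 200). Initialization is
furthest-sum vertex seeding with a seeded start; unused archetypes
(`‖A[:,k]‖ ≈ 0`) retain their previous profile. Convergence: relative
improvement < `tol` (default 1e-8) or `max_iter` (200).

**Deep fit.** A feedforward encoder (shared two-hidden-layer trunk, default
width 128 — tests use 16–64) produces `A` by a per-cell softmax over K and
`B` by a per-archetype softmax over the cells of the batch, so both are
row-stochastic by construction. The latent simplex `Z*` is fixed to the
standard simplex (identity vertices), a decoder reconstructs `X` from
`A·Z*`, and the loss is the sum of two mean-squared terms: reconstruction
`‖X − dec(A·Z*)‖²` and archetype consistency `‖Z* − B·A·Z*‖²` (with
`Z* = I`, `‖I − B·A‖²`), weighted 1:1. Hidden layers use tanh activations —
with ReLU, dead units made roughly half of random initializations collapse
two archetypes onto one vertex; tanh removes most of those failures.
Because the problem remains non-convex, up to `n_restarts` (default 3)
seeded runs are made and the lowest-loss one kept, with an immediate accept
when a run's final loss falls below 1e-4 of its initial loss; collapsed
optima are easily detected this way since they sit orders of magnitude
above a converged fit. Training is Adam (default lr 5e-3)
on mini-batches (full batch by default), fully seeded; the implementation
rides on a minimal in-package reverse-mode autodiff engine
(`clonearch/_autodiff.py`) that is gradient-checked against finite
differences in the test suite. Archetype profiles are the decoded simplex
vertices `dec(e_k)`. A non-finite loss raises an error naming the epoch and
learning rate. Whether `A` and `B` share an encoder trunk is not dictated by
the model; two heads on one shared trunk is the implemented choice.

On exact-vertex data the classical fit reaches machine-zero loss with
one-hot `A`; the deep fit reaches a loss below 10⁻³ of its initial value
with max weights > 0.95. On noiseless Dirichlet-mixture data the classical
fit recovers the planted archetypes with permutation-matched cosine
similarity > 0.99 — note the optimal loss there is small but nonzero,
because archetypes are constrained to the convex hull of the data and
Dirichlet-drawn cells only approach the true vertices.

**K selection** is left to the user; the classical loss is non-increasing in
K (asserted over K = 1…5), so an elbow on reconstruction loss is the
recommended heuristic.

**Preprocessing.** `select_features` intersects per-phase top-variance gene
sets (defaults 2,000 under drug, 1,000 in regrowth, 500 parental) and
Z-scores the retained genes across all cells; provenance records the set
sizes. `qc_filter_cells` removes cells with mitochondrial read fraction
strictly above 0.30 or strictly fewer than 1,000 expressed genes (both
boundaries retained); doublet removal is accepted as a precomputed flag
column since doublet detection itself is out of scope.

## Accessibility featurization

The binary cell×window matrix (500-bp windows, 0-based half-open BED) is
transformed as `TFIDF_ij = (X_ij/Σ_j X_ij) · ln(N/(1+Σ_i X_ij))` — natural
log, and the `+1` in the IDF denominator implemented exactly as defined,
which makes ubiquitous windows slightly negative rather than zero.
Zero-coverage cells are rejected by default (they are upstream QC failures);
a flag drops them with a warning instead. No depth normalization beyond the
TF term is applied: the input is binarized, which is also why copy number is
not a major confounder of this featurization. LSI is a single-pass rank-d
truncated SVD (ARPACK with a seeded start vector; exact SVD when d equals
the full rank), embedding cells as `U·S` with a deterministic sign
convention (largest-magnitude right-singular loading positive). Iterative
LSI refinement rounds are not implemented.

## Absolute copy number

Observed log2 ratios are median-centered on autosomes (the shift applied to
all bins including X). Given a segmentation (segments are inputs; multi-
sample segmentation is out of scope), the purity/ploidy grid search converts
each autosome bin's segment-mean ratio to a continuous copy number

    n_b = ( 2^{r_b}·(ρψ + 2(1−ρ)) − 2(1−ρ) ) / ρ

— the standard two-state purity mixture with diploid normal contamination;
this inversion is this package's declared convention — and scores
`SSD = Σ_b (n_b − round⁺(n_b))²` where `round⁺` rounds to the nearest
integer ≥ 1 ("nearest positive integer"; homozygous-deletion calls are
clamped to 1 and flagged, with a switch to allow 0). Defaults: purity grid
0.98–1.0 step 0.002 (these organoid samples are essentially pure), ploidy
step 0.005 (0.01 in the bundled fixtures).

A solution is a grid point strictly smaller than all of its existing
8-neighbors. Points on the ploidy-range boundary are ineligible (a minimum
there means the range is wrong); points on the purity boundary are eligible
and compete against the neighbors they have — purity 1.0 is necessarily a
boundary and is the correct answer for pure samples. Neighbor values equal
within 1e-9 relative tolerance block strict minimality: a flat genome makes
the SSD surface constant in purity, so no strict minimum exists and the
declared fallback (default ploidy 3.1 at purity 1, flagged `used_fallback`)
is returned. Ties among multiple strict minima break toward higher purity,
then toward the ploidy-range midpoint. The X chromosome is excluded from the
search and converted afterwards at the selected solution; its continuous
value is reported without a sex-specific expectation, left to the caller to
interpret.

On noiseless synthetic tracks the search recovers the generating
(purity, ploidy) grid point with SSD < 1e-10 and bin-exact integer calls;
with log-ratio noise of 0.05 the selected ploidy stays within ±0.05 of
truth in ≥ 9/10 seeds. Beware one interaction: median-centering redefines
the baseline so the fitted ploidy corresponds to the median copy-number
state; the bundled demo uses a layout whose median bin sits at the modal
state so the centering is neutral.

## Barcode extraction

Amplicon reads are assigned by locating the fixed 5' flank at bounded
Hamming distance (leftmost hit) and matching the fixed-length insert against
the barcode library, again at bounded Hamming distance, requiring a unique
nearest barcode. Hamming rather than edit distance because the cassette is
fixed-length and indel-free by design; reads are scanned on the given strand
with an optional both-strands mode (amplicon orientation is fixed by the PCR
primers). Ambiguous ties and unmatched reads are tallied with reasons, and
assigned + unassigned always equals the number of input reads.

## What the generator does not emulate

No read-level sequencing error, PCR jackpots or chimeras; no cell-cycle,
spatial, or microenvironment structure; no doublets or ambient RNA; no
GC/mappability bias in the copy-number bins; accessibility windows are
i.i.d. Bernoulli given the clone profile rather than genomically
autocorrelated. Passing tests therefore demonstrate correctness of the
computations under the stated statistical models, not robustness to every
artifact of real sequencing data.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed and is reproducible
bit-for-bit on one thread; the pipeline embeds a configuration hash in every
report and reruns are byte-identical. Test and acceptance problem sizes
(10³–10⁴ lineages, 100-run mode-recovery batches, 500-cell archetype fits,
60–100 bin genomes) were chosen so the full suite and the acceptance script
each complete in a few minutes on a single CPU while keeping every check
statistically well-powered.
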
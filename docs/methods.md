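# Methods

## The data model

The pipeline assumes the FACS-resolved cell-cycle design: 16 populations
(P1–P16, eight interphase and eight mitotic states ordered by cell-cycle
progression), four biological replicates, two technical repeats — 128
samples. Each technical repeat, ordered biorep-major (biorep 1: P1…P16,
biorep 2: P1…P16, …), is a 64-point *pseudotimecourse* in which a protein
regulated by the cell cycle completes exactly one oscillation per 16 points
(frequency 1/16 on the 64-point series) — or two, for proteins peaking
twice per cycle.

Intensities are label-free and strictly positive; zeros denote missing
values. ppm normalization (each sample scaled to sum to 10⁶ over its
nonmissing values) removes between-sample differences in total protein
amount and makes the periodicity test insensitive to per-sample depth.

## Periodicity screening

**Test.** Classical Fisher g: periodogram on the mean-centred series at the
Fourier frequencies k/N, k = 1…m, m = ⌊(N−1)/2⌋ (m = 31 at N = 64; the
Nyquist ordinate is excluded), g = max I(k)/Σ I(k), and the exact null

p = Σ_{j=1}^{min(m,⌊1/g⌋)} (−1)^{j−1} C(m,j) (1−jg)^{m−1}.

The alternating series is accumulated from log-magnitude terms (log-gamma
binomials, `(m−1)·log1p(−jg)`) to control cancellation, clipped to [0, 1];
m = 1 returns p = 1 (the 0⁰ limit). Exactness is verified against
Monte-Carlo white-noise nulls at m ∈ {7, 15, 31}.

**Missing data.** A series is testable only if ≥95% complete; remaining
gaps are imputed with the series mean, which contributes zero to the
centred periodogram at every frequency and therefore perturbs the null less
than zero-imputation of left-censored values would. The 95% rule is this
package's own threshold: strict enough that mean imputation cannot
manufacture or destroy periodicity, loose enough not to discard proteins
with sporadic dropout.

**Multiple testing.** Storey q-values with smoother-based π₀: π₀(λ) on the
grid λ = 0.05…0.95 (step 0.05), cubic smoothing spline evaluated at
λ = 0.95, clipped to (0, 1]. Below 100 p-values the π₀ fit is unstable and
the code falls back to π₀ = 1 (plain Benjamini–Hochberg) with a warning.

**Calling.** A protein is pseudoperiodic iff q < 0.10 in *both* technical
repeats and its dominant frequency is 1/16 or 1/8 in *both* repeats. The
frequency condition is applied symmetrically with the q condition; dominant-
frequency ties break toward the smaller index (longer period).

## Clustering and motif enrichment

Mean 16-point profiles (plain mean over all 8 replicate series per
population, nonmissing values only) are z-standardized (n−1 denominator)
and clustered by Ward minimum-variance agglomeration on Euclidean distances
(the ward.D2 convention; the agglomeration is deterministic and
input-order-invariant up to exact distance ties). The elbow curve is the
within-cluster sum of squares versus k from the same linkage; the suggested
k is the maximum-curvature point (largest second difference). Clusters are
relabeled 1…k by ascending peak position of the cluster-mean profile — a
reproducible replacement for manual dendrogram leaf swapping.

Degron scanning uses position-restricted patterns (KEN; D-box `R..L`; ABBA
`F.[ILV][FHY].[DE]`, the consensus literature definition — the source
analysis names the motif but prints no pattern). The `.` wildcard matches
amino acids only. No structural-disorder filter is applied (that would
require an external disorder predictor), so hit frequencies are
sequence-only and upward-biased relative to disorder-filtered scans; the
enrichment *comparison* between a cluster and its background is unaffected
because both are scanned identically. Enrichment is a one-sided exact
hypergeometric test of cluster versus background (default background: all
tested proteins, making the analysis self-contained), significant at
p < 0.01.

## CCS signature and assignment

Signature matrix: per-protein z-scaled abundances of the PsPs over the 128
samples; residual missing values sit at the protein's scaled mean (0). PCA
is centred SVD; component signs are fixed so PC1 is positive on the mean of
the interphase samples (PCA is otherwise sign-ambiguous). The wheel
property — populations ordered by angle in (PC1, PC2) recover the true
cyclic order — is measured with a circular–circular rank correlation
(U-statistic over pairwise angle differences), reported as an absolute
value since the wheel's rotation direction is arbitrary.

k-NN classification uses k = 6, Euclidean distance, majority vote; vote
ties break toward the smallest mean neighbor distance, then the lowest
population index. Training uses both technical repeats of three biological
replicates (96 samples); the held-out replicate (32 samples) is the test
set.

CCS aggregation: k-means (best inertia of 100 restarts at a fixed seed) on
the 16 population-mean vectors, k = 8. CCS labels are renumbered by each
cluster's earliest member population (the cluster containing P1 becomes
CCS1), and profiles are the means of member populations. Temporal
contiguity of members is typical but *reported, not enforced* — k-means
does not guarantee it.

Query assignment: Spearman's ρ between the query's values and each CCS
profile over pairwise-complete signature proteins; queries overlapping
fewer than 30 signature proteins are unassigned. The best CCS is the argmax
ρ; its one-sided p-value uses the t approximation at the overlap size, and
across a batch "assigned" means BH-adjusted p < 0.05. Rank correlation
makes the assignment invariant to any monotone transform of the query, the
reason it transfers across quantitation schemes (label-free ratios, SILAC).

## Match-FDR estimation and filtering

Estimate: FDR = mean over decoy runs of (decoy matched fraction)/(target
matched fraction), fractions taken over each run's total features. Matched
fractions rather than raw counts normalize for different run sizes; raw
counts can be substituted by the caller. σ per error dimension
(retention-time difference, m/z difference, m/z error) is 1.4826 × MAD of
the matched target features — consistent for the Gaussian core of true
matches and resistant to the broad false-match tail (analytically, 10%
uniform contamination inflates the MAD-σ by only ~12%). Filters keep
matches within 2.5 σ (retention time) and 3 σ (both m/z dimensions) of the
per-dimension median, boundaries inclusive; filtered-out matches revert to
unmatched so post-filter fractions share the original denominators.
Independent Gaussian dimensions give an expected true-match retention of
0.9876 × 0.9973² ≈ 0.982.

## Synthetic data: what it emulates, what it does not

The abundance generator plants `round(frac_periodic × n)` periodic proteins
on five profile templates (peaks in early interphase, G1/S, S/G2,
mid-mitosis, late mitosis), each a fundamental cosine over the 16-population
cycle plus a weak second harmonic for shape variety — so the dominant
Fourier frequency is 1/16 by construction and cluster recovery has a known
answer. Defaults (chosen once as the study conditions): amplitude uniform
in [1.5, 4]-fold, multiplicative log-normal noise at CV 0.2, per-sample
depth factors at CV 0.15, per-protein baselines log10-normal (mean 6,
sd 1). Missingness is missing-not-at-random: a logistic in log10 intensity
with midpoint at the 0.02 abundance quantile and scale 0.15 — emulating the
high data completeness of MS1-match-based quantitation, which leaves only
the lowest-abundance tail censored. Overall missingness is then ~2–3%,
concentrated in the bottom baseline decile; proteins there become
untestable and bound the achievable PsP sensitivity at roughly 0.93–0.97.

Not emulated: peptide-level quantitation and rollup, biorep batch effects,
correlated noise between technical repeats, non-periodic trends, or real
biological cluster structure beyond the five templates. Passing recovery
tests therefore demonstrates the statistical machinery is correct and
calibrated under the stated noise model, not that real data meet that
model.

The match-table generator draws true-match errors from centred Gaussians
and false-match errors uniformly over wide windows; matched fractions are
set directly. In recovery sweeps the decoy matched fraction is set to
(target fraction × true FDR), i.e. decoys share the target's false-match
propensity, making the ratio estimator unbiased there. In real target/decoy
experiments decoys lack true matches that could occupy features, so the
empirical estimate tends to overestimate — the generator can represent that
regime by raising the decoy fraction.

The FASTA generator plants motifs per sequence with stated probabilities
and re-rolls chance background occurrences of listed motifs so ground-truth
labels are exact (two motifs planted at overlapping positions can, rarely,
destroy one another — below the binomial tolerance the tests use).

## Numerical and design notes

- One master seed fans out to per-stage substreams via `SeedSequence.spawn`,
  so adding a stage never perturbs another's randomness; all generators are
  bit-reproducible under a fixed seed.
- Problem sizes in tests and in `scripts/acceptance.py` (5000 proteins,
  50k–200k match features, 10⁵ Monte-Carlo draws, 200 assignment trials)
  were chosen so every recovery estimate has sampling error well inside its
  tolerance while the whole suite runs in seconds.
- k-NN prediction robustness to removing two signature proteins is asserted
  per prediction (mean agreement ≥ 95%), not as bit-identity of whole
  32-prediction vectors: adjacent cell-cycle populations are genuinely
  similar, so one or two boundary samples sit on vote/distance knife edges
  and flip under any small perturbation. Per-prediction stability is the
  meaningful robustness claim — the classification does not hinge on
  individual proteins.
- Degenerate inputs: constant series are untestable (flagged, never PsPs);
  constant mean profiles are dropped from clustering with a warning;
  constant PCA features are dropped with a warning; zero-spread match-error
  dimensions are errors.

## Known limitations

- The periodicity null assumes exchangeable (approximately Gaussian) noise;
  the exact p-value is mildly miscalibrated for strongly skewed intensity
  noise (at log-normal CV 0.2 the observed type-I error stays within
  [0.04, 0.06] at α = 0.05).
- With 16 populations the frequency grid is coarse; periods other than 16
  or 8 populations per cycle are deliberately excluded by the calling rule.
- CCS assignment reports relative correlation; a query mixing several cell
  cycle states (bulk, partially synchronized material) gets the dominant
  state only, with correspondingly weaker ρ.
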
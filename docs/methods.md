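# Methods

This note records the models, algorithms and numerical choices behind
`metaspectra`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the known limitations.

## Spectrum ingestion and quality filtering

Input is centroided MS2 data. The mzML reader is a purpose-built streaming
parser (lxml `iterparse`) covering what MSConvert-style centroided files
carry: ms level, selected-ion m/z and charge state, scan start time, and
base64-encoded peak arrays (32- or 64-bit float, zlib-compressed or plain).
MGF is read and written through pyteomics with m/z printed to 5 decimals,
so a write/read cycle is an identity on every field the pipeline uses.

Spectra unlikely to be peptide fragment spectra are removed before
clustering. The filter is a declared approximation — the upstream spectral
clustering tools do not publish their exact criterion — with three tests,
all configurable (`QualityParams`):

- at least `min_peaks` = 10 peaks;
- at least `min_signal_peaks` = 5 peaks at ≥ `signal_fraction` = 1% of the
  base peak (rejects spectra whose apparent richness is baseline noise);
- precursor m/z within 300–1500 Th, the full-scan range of the Orbitrap
  acquisition this pipeline targets.

Spectra without a reported precursor charge are kept, assigned a default
charge of 2 (the most common tryptic peptide charge) and flagged, because
charge is required for neutral-mass computation and, optionally, cluster
compatibility.

## Spectral similarity and greedy clustering

Each spectrum is reduced to a sparse unit vector: the 50 most intense peaks,
square-root-transformed intensities (compresses the dynamic range so the
score reflects shared peak pattern rather than a single base peak), summed
into 1 Th bins (`bin = floor(mz / width)`), L2-normalized. Similarity is the
inner product, in [0, 1].

Clustering is greedy and deterministic. Spectra are inserted in ascending
precursor-m/z order (ties by spectrum id): a spectrum joins the
best-scoring existing cluster whose consensus precursor lies within 20 ppm
and shares its charge state and whose similarity reaches the 0.7 threshold,
otherwise it founds a singleton. During the build pass a cluster is
represented by its founding spectrum; consensus spectra are rebuilt when
the pass completes. Each further pass (default: one) re-seats every
spectrum against the frozen consensus list and rebuilds. The thresholds
(bin width 1 Th, top-50 peaks, similarity 0.7, 20 ppm, 2 passes) are
conventional for HCD/Orbitrap data; whether clustering should cross charge
states or use an absolute m/z tolerance is genuinely open, so both
behaviors sit behind `ClusterParams`.

## Consensus spectra

Replicate peaks are aligned by an ascending-m/z sweep: a peak extends the
nearest open aligned group within 0.05 Th of the group's running
intensity-weighted mean — at most one peak per replicate per group — or
opens a new group. A group is retained iff it occurs in at least
`ceil(0.5 × rn)` members, suppressing noise peaks that appear in a minority
of replicates. The consensus peak's m/z is the intensity-weighted mean of
the group; its intensity is the arithmetic mean over all `rn` members with
absent peaks counted as zero, so consensus intensities are comparable
across clusters of different sizes. The consensus precursor is the median
member precursor; a singleton's consensus is the spectrum itself. The sweep
orders peaks by (m/z, intensity), which makes the construction invariant to
the order the member list is supplied in.

Neutral mass is `charge × (precursor_mz − 1.00728)` with the proton mass
fixed at 1.00728 Da.

## Quantification

**SC.** Raw SC(c, s) counts cluster c's members from sample s; the profile
divides each column by its sum (columns of non-empty samples sum to 1).

**SI / SI_N.** SI sums, over a sample's replicates of a cluster, the
intensities of replicate peaks lying within a closed ±0.4 Th window of at
least one consensus peak, each replicate peak counted once. The window is
deliberately wide (matching fragment-tolerance practice in spectral-count
quantification tools) because it collects intensity, not identity. SI is
normalized by the pseudo-length MW/110 — the consensus neutral mass divided
by the weighted average amino-acid residue mass — making values comparable
between short and long peptides. The defining sum runs over all replicates
of a cluster; per-sample profiles restrict it to the sample's members,
which is what "in each sample" requires. MW is computed from the consensus
precursor and charge, the only mass information available without
identification.

**TMM.** Between-sample scaling follows the published trimmed-mean-of-M
estimator: reference sample chosen by the 75th-percentile proportion
closest to the mean of those; per sample, M (log2 proportion ratio) and A
(mean log2 proportion) over features positive in both sample and reference;
symmetric trims of 30% on M-ranks and 5% on A-ranks (mid-ranks, so ties are
kept or dropped together); factor = 2^(precision-weighted mean of the
surviving M), with inverse delta-method variances as weights; factors
rescaled to geometric mean 1. Zero-count features are excluded pairwise.
By default TMM is applied to SI_N profiles only; SC is already a
composition and is reported sum-normalized (TMM optional).

## Sample comparison

Zeros in the profile are structural missingness (a peptide not sampled),
so the matrix is augmented by its smallest strictly positive entry as a
global pseudo-count before log2 — adding to *all* cells keeps the transform
strictly monotone, whereas substituting only the zeros (available as
`shift_all=False`) does not. Samples are clustered by UPGMA on Euclidean
distances, implemented directly (O(n³), ties broken by the smaller node-id
pair) so the merge list, flat cuts and newick export are exact and
deterministic; it matches scipy's average-linkage on tie-free input. PCA
centers features, does not scale, and fixes each axis sign by making its
largest-magnitude loading positive.

## Identification reconciliation

Per spectrum, the sequence comes from the highest-priority engine with an
accepted hit: database search (most reliable when a database exists), then
open-modification search, then de novo (error-prone, short sequences).
Acceptance is delegated to the table's `passes` column so any
engine/threshold combination plugs in; typical preparation thresholds are
1% FDR for database search and ALC ≥ 60% for de novo. Per cluster, member
sequences plus the consensus spectrum's sequence vote; plurality wins; on a
tie the consensus spectrum's sequence wins. The consensus spectrum thus
casts a full ballot *and* is the tie-breaker — the reading that satisfies
both roles it is described as playing. Residual ties (no consensus ballot
among the tied) fall to the method priority of each sequence's best
supporting ballot, then lexicographic order; this residual rule is this
package's own addition, needed only for determinism. Peptides compare as
exact strings after canonicalizing bracketed modification masses to two
decimals; I/L are distinct unless `equate_il` is set. Clusters whose
consensus spectra match a host proteome (an externally produced exclusion
list) can be dropped before profiling.

## Differential abundance and enrichment

Welch's heteroscedastic ANOVA is used because cluster abundances have no
reason to share variances across sample groups. The null distribution of F
is obtained by bootstrap: each group is centered at its own mean (enforcing
the null while keeping each group's variance), groups are resampled within
themselves with replacement, and

    p = (1 + #{F* ≥ F_obs}) / (n_valid + 1),

with n_boot = 10,000 by default. Resamples in which any group collapses to
zero variance leave F undefined and are excluded, with the denominator
reduced accordingly; for realistic group sizes this is negligible.
Within-group (rather than pooled-residual) resampling was chosen because it
preserves heteroscedasticity, which is the reason for using Welch's statistic
in the first place. BH adjustment controls FDR at 0.05; significant features
get Games–Howell pairwise comparisons (Welch t, Welch–Satterthwaite df,
p from the studentized-range distribution at q = |t|·√2). Fisher enrichment
builds, per pathway, the 2×2 foreground/background table over a flat
feature→pathway map and sums hypergeometric point probabilities not
exceeding the observed one (the standard two-tailed exact test), BH-adjusted
across pathways.

Small-sample behavior, measured by the calibration suite: at 3 groups of
n = 10 the bootstrap test holds its size (type-I rate ≈ 0.04 at α = 0.05
over 1,000 null datasets with n_boot = 500); at n = 6 it is conservative
(≈ 0.026); at n = 2 per group the within-group bootstrap degenerates — every
valid resample is a mirror image with group means zero — so p-values
saturate at their minimum and differential calling is liberal. Two samples
per group is below what this test needs; features with zero within-group
variance are skipped and reported rather than failing the run.

## The synthetic study

The generator emulates the data the pipeline consumes, not mass-spectral
physics. Templates are random tryptic-like peptides (length 8–16, C-terminal
K/R) with singly charged b/y fragment ladders from monoisotopic residue
masses and per-template log-normal fragment intensities fixed across
replicates. The default study has 20 templates across 3 groups × 2 samples.
Designed expected replicate counts are log-uniform over [2, 16] rescaled to
a mean of 5 — a spread wide enough that the designed abundance gradient is
recoverable above Poisson counting noise — and each group has 3 marker
templates at 6-fold elevated abundance, giving the groups a recoverable
signature. Replicates receive Gaussian m/z jitter (σ = 0.002 Th),
multiplicative intensity noise (CV 20%), 10% uniform noise peaks, and the
stream carries 5% junk spectra (≤ 3 random peaks). Identification tables
assign the true sequence with a 10% default error rate (fresh random decoys,
so errors rarely coincide). All randomness flows from one seed; output files
are byte-identical across runs.

What the generator does **not** emulate — and what passing recovery tests
therefore do not show about real data: realistic HCD fragment intensities,
higher fragment charge states, co-eluting chimeric spectra, retention-time
structure, modified peptides, and the scale (hundreds of thousands of
spectra) of a real study. Recovery gates (clustering purity ≥ 0.95,
completeness ≥ 0.90, group-recovery ARI ≥ 0.9, designed-marker sensitivity
≥ 0.8) are this repository's acceptance conditions on the simulated study,
not claims about any real dataset.

## Problem sizes in the checks

The shipped test suite and `scripts/acceptance.py` run the full pipeline on
the default ~1,000-spectrum simulated study, the UPGMA oracle comparison on
200 random 8-leaf matrices, vote-accuracy on 300 simulated clusters,
bootstrap calibration on 1,000 null datasets at n_boot = 500, and the
Fisher enumeration over all 1,364 tables with N ≤ 12; the whole acceptance
run takes a few seconds on one CPU.

## Known limitations

- The greedy single-pass-plus-reassignment clustering is order-dependent by
  construction (deterministically so); it is not a global optimum, and very
  abundant peptides can occasionally split across two clusters.
- MW of a consensus spectrum relies on the reported (or defaulted) charge;
  a wrong charge propagates into SI_N through the pseudo-length.
- TMM assumes most features are not differential; with few clusters and
  strong designed effects the factors absorb some real signal.
- The bootstrap ANOVA needs ≥ 3 samples per group to be meaningful (see
  above); the Games–Howell p relies on the studentized-range asymptotics
  and is approximate for very small groups.
- Open-modification-aware clustering (grouping modified with unmodified
  forms) is out of scope; modified peptides form their own clusters.
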
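# Methods

This note documents the models and procedures implemented in `porebias`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data validation does and does not demonstrate.

## Per-read metrics

Two mean-Q conventions are computed for every read and both are reported.
The error-probability-domain mean, `-10·log10(mean 10^(-Q/10))`, is the
platform convention for whole-read quality and drives the default pass/fail
call; the arithmetic mean is retained because the per-base analyses
(transition, emission, positional profiles) operate on raw per-base scores.
By Jensen's inequality the error-domain mean never exceeds the arithmetic
mean, with equality only for constant scores — this is asserted as a
property test.

Pass thresholds are strict inequalities (`Q > 9` for 2D-consensus reads,
`Q > 6` for template/complement/1D), both configurable.

Percent identity is computed over alignment columns (matches + mismatches +
inserted + deleted bases), i.e. BLAST-like identity of the aligned portion,
not matches over read length. Mismatches are derived from the SAM NM tag as
`NM − I − D`; a record with `NM < I + D` is rejected as inconsistent.
Soft-clipped bases are excluded from identity but retained in read length;
hard-clipped bases never appear in per-base statistics. N bases inside M
ops count as mismatch columns (they inflate NM in typical aligners); there
is no special-casing.

## Decile-based Q-score structure

Q-scores are pooled per dataset and discretized into `n_bins = 10`
equal-occupancy bins at nearest-rank empirical quantiles with right-closed
assignment. Integer Phred scores are heavily tied, so exactly equal bins
are generally impossible; the fit records the achieved occupancies, and a
distribution too degenerate to support the requested bin count (duplicate
quantile edges) is a hard error rather than a silently merged binning.
Binnings can also be constructed explicitly from known edges, which the
validation suite uses when the simulated Q-level grid is known.

The transition matrix counts consecutive-base decile pairs within reads
only — each read (and each strand of a 2D molecule) is a separate chain;
nothing is counted across read boundaries. The emission matrix tallies
called bases per decile, skipping N bases (counted separately). Both are
reported as counts plus row-normalized probabilities; rows with zero counts
stay all-zero rather than being imputed.

No latent-state model is fitted: the transition/emission decomposition here
is the directly observable Markov chain on deciles with conditional base
frequencies, which is exactly what run-diagnostic heat maps display.
Latent-state fitting (Baum–Welch) is deliberately out of scope.

## Positional quality

Base k of a read of length L maps to relative-position bin
`⌊n_bins·k/L⌋`; the default `n_bins = 100` resolves 1–2% end effects on
kb-scale reads without over-fragmenting short ones. Means are pooled over
bases (every base carries equal weight); a per-read variant (average of
per-read bin means) is available behind a flag, since the two differ when
read lengths vary within a group. Reads shorter than the bin count still
contribute (some bins receive no observation from such reads; means are NaN
only where a bin has no observations at all). Length deciles are computed
within each strand class at nearest-rank quantile edges, ties lumping as in
the Q binning.

## K-mer representation bias

Read k-mers are tallied from the aligned (non-clipped) portions of mapped
reads; minus-strand reads are reverse-complemented into reference
orientation first so read and reference tallies share a frame — this makes
a unit ratio attainable for unbiased data. The reference tally covers only
the union of regions reached by at least one read in any replicate, so both
sides describe the same genomic material. Event-level (signal) k-mer
tallies are out of scope; the sequence-level tally measures the same
representation bias.

Three screens operate on the tables:

1. **Ratios.** Frequencies are pseudocounted, `(c + 0.5)/(total + 4^k·0.5)`,
   before dividing, keeping ratios finite and positive for k-mers absent on
   one side. The pseudocount affects ratios only, never the regression.
2. **Z-scores.** log2 ratios standardized by their own mean and sample SD;
   |z| > 3 flags an outlier by default. A zero-variance ratio vector yields
   all-zero z-scores and no outliers.
3. **Negative-binomial regression.** Per k-mer, replicate read counts and
   the single reference count form a two-group NB2 GLM with log link and
   `log(total)` offset. Because the groups are parameter-orthogonal, the
   fit reduces to two group rates: the reference group (one observation) is
   fitted exactly, and the read-group rate solves a one-dimensional score
   equation by Newton iteration, vectorized across all 4^k k-mers. The
   dispersion is profiled out per k-mer by maximum likelihood (envelope-
   theorem bisection on the profile gradient) with a floor at 1e-8, the
   Poisson limit. β1 is tested with a two-sided Wald test using the Fisher
   information at the fitted dispersion, and p-values are BH-adjusted over
   all k-mers. The unit tests verify that this vectorized fit reproduces
   statsmodels' joint NB maximum likelihood (coefficient and dispersion) on
   individual k-mers; the vectorized path exists because fitting 1024
   separate GLM objects per analysis is needlessly slow for repeated
   simulation studies.

   Degenerate k-mers: counts zero everywhere get p = 1 by convention; a
   k-mer with one all-zero group is Haldane-adjusted (0.5 added to each of
   its cells) and flagged `zero_adjusted`. With 2–3 replicates the per-k-mer
   dispersion estimate is noisy; modelling the fixed reference tally as an
   NB observation also makes the Wald test conservative when read tables
   are resampled from the realized reference composition — the null
   simulations confirm FDR control with margin rather than exactness.

Annotation marks k-mers that are BH-significant and have at least the
configured fold change (default 2) in either direction. Replicate
concordance is the mean pairwise Spearman correlation of k-mer counts;
constant tables make it undefined (NaN).

## Basecaller comparison

Reads are joined on their class-qualified id (suffix convention below),
optionally normalized by a caller-specific regex; duplicate ids within one
set are an error. Read-versus-read identity uses banded global alignment
with unit scores (match +1, mismatch −1, gap −1); the effective band
half-width is `band + |len_a − len_b|`, auto-widened so the diagonal
corridor is always inside the band, and the result equals the unbanded
optimum whenever `band ≥ max(len)`. Ties in the DP are broken
diagonal > up > left, and identity is matches over columns of that
alignment. Note that with unit scores, co-optimal and strictly better
gapped alignments exist around clustered substitutions, so the closed form
`100(L−m)/L` for m substitutions holds only when substituted sites are
isolated — the oracle tests use the full dynamic program, not the closed
form, for exact comparisons.

## Synthetic data generator

The generator emulates the statistical structure of a 2D nanopore run; all
parameters are explicit in `SimulationConfig`:

- **Lengths**: log-normal with median 1500 bp and sigma 0.55, truncated to
  [100 bp, 100 kb] — mode near 1.1 kb, mean near 1.7 kb, matching the
  1–2 kb averages and 100 bp–100 kb span typical of such runs.
- **Q-scores**: a first-order Markov chain over a level grid (default ten
  levels 2–20, one Phred unit apart in occupancy), with a sticky
  transition kernel `∝ exp(−|i−j|/1.2)` Sinkhorn-balanced to doubly
  stochastic so the stationary distribution is exactly uniform over levels.
  Per-base offsets (default A/G −2, C/T +2), an end dip (−3 over the
  terminal 2% of positions), a short-read penalty (−4 for reads ≤ 200 bp),
  a complement-strand offset (−1), and a consensus boost (+4) are added
  afterwards, then scores are rounded and clamped to [0, 40]. Because
  clamping at 0 truncates planted effects, recovery studies use level grids
  that keep the dipped scores above the floor.
- **Errors**: i.i.d. per-base substitution (0.06), single-base insertion
  (0.03) and deletion (0.05) channels give single-strand identities near
  86%, in the 81–89% range seen on real data; the 2D consensus uses the
  same channel scaled by 0.25. True placement, CIGAR and NM are recorded in
  a truth SAM (boundary deletions are trimmed from CIGARs, as no aligner
  reports them).
- **Q/error coupling**: off by default — quality structure and identity are
  treated as separate phenomena, as the analyses do. With
  `couple_errors_to_q=True` the segment's Q chain is drawn first and
  substitution odds are tilted by the per-position error probability.
- **K-mer spikes**: at sequence level, a spiked k-mer multiplies the
  substitution odds at matching true-sequence positions (a miscall-prone
  context); for exact fold-change studies, `simulate_read_kmer_tables`
  resamples k-mer tables multinomially from the reference composition with
  spiked probabilities scaled — the exact generative model of the NB null.
- **Replicates**: same configuration with seeds `seed + i` over one shared
  reference; identical configurations are byte-identical on disk.

Read ids carry `.template`/`.complement`/`.2d` suffixes (no suffix = 1D),
the convention the FASTQ reader parses; it is configurable because real
FAST5-to-FASTQ converters differ.

### What the validation shows — and does not

Every analysis stage is validated by parameter recovery at simulation sizes
chosen so sampling error is several times smaller than the stated
tolerances (≈1.1M transitions for the 10×10 transition matrix within 0.02;
≈1.1M bases for the ±2 base offsets within 0.1; 8000 molecules for the end
dip within 0.2 and the complement offset within 0.1; 20 spiked and 50 null
k-mer analyses at 1M k-mers × 3 replicates). Replicate k-mer concordance is
checked on a 28%-GC genome because rank concordance is only informative
when the composition spread exceeds multinomial sampling noise — at 50% GC
an i.i.d. genome's 5-mer frequencies are nearly flat and the correlation is
dominated by noise.

The generator's i.i.d. reference, context-free error channel, and
first-order Q chain do not reproduce real-genome repeat structure,
homopolymer-length errors, signal-level context effects, or pore-occupancy
dynamics. Passing recovery therefore demonstrates the correctness of the
estimators and their statistical calibration under the stated model, not
that real runs will show effects of these exact magnitudes.

## Numerical choices

- Nearest-rank (`inverted_cdf`) quantiles everywhere bins are fitted;
  right-closed assignment; ties lump rather than split.
- Transition/emission rows are exact to 1e-9 after normalization; empty
  rows are zero, never NaN.
- NB Newton iterations cap step size at 5 on the log scale; dispersion
  bisection runs in log space over [1e-8, 1e6].
- The banded alignment stores scores and pointers in band coordinates;
  out-of-band cells are −1e15 so no optimal path can leave the band.
- All simulation randomness flows through one `numpy.random.Generator`
  seeded from the configuration; batch Markov sampling advances all active
  chains column-wise, so runtime is linear in total bases.
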
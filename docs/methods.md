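# Methods

## Signal model

A transcription-terminating riboswitch in its OFF state truncates
transcripts near its own 3′ end; in the ON state RNA polymerase reads
through into the downstream gene. After library fragmentation, every
*internal* fragmentation event creates a matched pair of neighboring
fragment termini — a 3′ end at base *b*−1 and a 5′ end at base *b* —
while genuine transcript ends create unmatched termini. Paired-end
sequencing observes both termini of each sequenced fragment: the
forward-oriented (F) read's left-most mapped base is a fragment 5′ end
(scored −1) and the reverse-oriented (R) read's right-most mapped base
is a fragment 3′ end (+1). Convolving the per-base signed sum with a
smoothing kernel therefore cancels fragmentation noise and leaves
transcript starts as negative peaks and termination sites as positive
peaks. The method's job is to decide, per locus, whether a positive
peak near the riboswitch 3′ end (i) rises above that locus's own noise
and (ii) changes with experimental condition the way conditional
termination must: a more negative mean and a larger variance of the
fractional coverage change than baseline, because a dataset capturing
both ON and OFF states mixes large drops with near-zero drops at the
same position.

Key quantitative properties of the default kernel (σ = 1.5 nt,
51 elements, unit sum): a lone unit terminus produces a summit of
1/S ≈ 0.2660 amplitude units, where S = Σ exp(−k²/4.5) over |k| ≤ 25;
an adjacent +1/−1 fragmentation pair is attenuated to a maximum of
max|Δw| ≈ 0.1036 (the largest consecutive-weight difference, reached at
the Gaussian inflection), with the response at the spike positions
themselves w₀−w₁ ≈ 0.0530. Attenuation of matched pairs relative to a
lone spike is thus ~2.6×, and pileups of even a few co-located
unmatched termini dominate the track.

## Pipeline stages and parameters

All coordinates are 0-based half-open internally; 1-based inclusive
conventions of Infernal/Prodigal are converted at the parser boundary.
Defaults (all in `PipelineConfig`, serialized with every run):

| parameter | default | meaning |
|---|---|---|
| `flank` | 1000 nt | reference-window flank each side of the riboswitch |
| `min_cov_depth` | 15 | min mean total coverage across the riboswitch |
| `sigma`, `kernel_half_width` | 1.5 nt, 25 | discretized-Gaussian kernel (51 weights) |
| `zero_band` | 0.1 | open zero region (−0.1, 0.1) in amplitude units |
| `ext_prop` | (−0.3, 1.0) | noise region: skip first 30 % of the riboswitch, extend one riboswitch length past the 3′ end |
| `roi_half_width_prop` | 0.5 | clustering region: ±0.5 × size around the 3′ end |
| `alpha_peak`, `min_drop` | 0.05, 0.20 | per-peak significance and coverage-drop thresholds |
| `cophenetic_threshold` | 0.04 | complete-linkage flat cut on relative positions |
| `alpha_mean`, `alpha_variance` | 0.05 | cluster-level test thresholds |
| `n_levene_comparisons` | 60 | resampled Levene comparisons per cluster (median p) |
| `min_noise_set` | 3 | smallest noise set that supports a 2-D covariance |
| `allow_single_reads`, `allow_soft_clips` | off | orphan reads count toward coverage / clipped pairs contribute termini |

Pair orientations: EQ (identical spans on opposite strands) and FR
(left-most base shared or exclusively F, right-most base exclusively R)
are valid; same-strand (tandem), R-left (RF) and all other
configurations are discarded as likely artifacts. Mates mapping to
different locus windows are treated as orphans within each window,
since windows are analyzed independently. No duplicate-pair removal is
performed. Within each retained pair, category precedence is
termini > overlapped > read > inferred gap > soft-clipped, so the five
categories partition the pair footprint exactly; the depth filter uses
their sum.

## Statistical decisions

**Pseudo p-value.** The per-peak test statistic is the probability that
a draw from the fitted bivariate normal over (width, |amplitude|) is
*less likely* than the observed peak. For squared Mahalanobis distance
d² this is exactly exp(−d²/2) in two dimensions — a proper tail
probability in (0, 1], unlike a raw density. The noise set contains all
peaks of both signs in the noise region (absolute amplitudes), except
the peak under test; sets smaller than 3 fail the peak rather than
aborting the locus. Degenerate (singular) covariances get 1e-9 added to
the diagonal.

**Coverage drop.** (total[right_bound] − total[left_bound]) / mean
riboswitch total coverage, using the exclusive right bound (clipped to
the last window base). Termination requires a drop ≤ −`min_drop`.

**Clustering.** Complete-linkage on 1-D relative positions via
`scipy.cluster.hierarchy`, flat-cut at the cophenetic threshold, so a
cluster's diameter never exceeds 0.04 relative units. Merge ties are
resolved deterministically (first minimal pair in scipy's traversal,
which prefers the lower-indexed/lower-position pair for 1-D input).

**Mean test.** The cluster's fractional coverage changes against those
of all other region-of-interest peaks at the locus, one-tailed
Mann–Whitney U (alternative: cluster smaller). The comparison is
sample-vs-sample, since a rank test against a single summary mean is
not defined; scipy's exact null is used automatically for small untied
samples.

**Variance test.** Classical mean-centered Levene tests of the size-*n*
cluster against size-*n* samples drawn without replacement from all
other peaks at the locus, pass by pass (⌊N/n⌋ comparisons per pass,
reshuffling between passes) until 60 comparisons are collected; the
median p is reported. The superset spans all conditions that passed the
depth filter. Resampling uses a dedicated seeded generator
(`PipelineConfig.seed`, default 1729), so reruns are bit-identical.

**Locus verdict.** `termination_evidence` iff some cluster holds a
passing termination peak *and* passes both cluster tests; otherwise
`inconclusive` (peaks exist but no cluster qualifies),
`no_candidate_peaks` (nothing in the region of interest), or
`low_coverage` (no readset met the depth filter). No multiple-testing
correction is applied across loci — each stage uses raw p < 0.05, and
users scanning many loci should keep that in mind.

Peak-bound tie-break: when two same-sign peaks share a monotone valley,
the shared base is assigned to the left peak (left-to-right scan), so
peak regions never overlap. A value of exactly ±0.1 lies on the closed
boundary of the open zero region and does not stop extension.
Convolution boundaries are zero-padded; with ≥ 1000 nt flanks the edge
effects cannot reach the riboswitch neighborhood.

## Synthetic data: what it does and does not emulate

The generator (`riboterm.simulate`) draws transcripts that start at a
fixed TSS and either stop at the terminator position (+ rounded
N(0, 2 nt) jitter) with the condition's termination efficiency, or read
through to the window end. Transcripts are fragmented sequentially with
truncated-lognormal lengths (meanlog = log 300, sdlog = 0.35, truncated
to [100, 1000] nt — a biased size distribution typical of short-read
libraries), so adjacent fragments share breakpoints exactly as the
signal model assumes. Fragments shorter than 100 nt are discarded
(size selection); the unmatched R termini this leaves behind are the
realistic source of per-locus noise peaks that the noise model is
fitted to. Each retained fragment yields an F/R pair of 150 nt reads
(an EQ pair when the fragment is no longer than a read), written as
coordinate-sorted SAM against a random-sequence window with full-match
CIGARs.

Default study conditions: a 100-nt riboswitch at [1000, 1100) in a
2600-nt window, TSS at 500, terminator at 1105 (relative position
+0.05), and two conditions at termination efficiencies 0.9 and 0.1 with
four replicate readsets of 50 transcripts each (~50× coverage). These
sizes keep a full 20-run recovery experiment under a minute on one CPU
while giving the statistics realistic sample sizes.

Not emulated: sequencing errors and quality variation, PCR duplicates,
rRNA contamination, multi-locus genomes with shared mappings, spliced
alignments, strand-specific library artifacts, and genuine biological
heterogeneity in termination position beyond Gaussian jitter. Passing
the end-to-end tests therefore demonstrates that the statistical
machinery recovers the programmed signal under the stated generative
assumptions — not that real libraries satisfy those assumptions.

Two quantitative caveats of the generator, found while testing: the
realized lengths of fully internal fragments deviate slightly from the
truncated lognormal (KS D ≈ 0.026) because sequential fragmentation
conditions completed draws on fitting before the transcript end; and
fragmentation noise in the convolution regularly exceeds the ±0.1 zero
band at ≥ 30× depth (a single isolated fragmentation pair already
reaches 0.1036), which is precisely why calling is based on the
per-locus noise model rather than the zero band alone.

## Numerical and design choices

- The depth filter uses the sum of all five coverage categories (the
  per-pair footprint depth), the reproducible quantity implied by the
  partition identity, rather than read coverage alone.
- Overlapping riboswitch hits from different covariance models are kept
  as distinct loci; no deduplication is attempted.
- The downstream gene is the first same-strand ORF whose reading-
  direction start is at or past the riboswitch 5′ end, which
  deliberately admits ORFs overlapping the riboswitch.
- Summit plateaus resolve to their left-most base; all tie-breaks are
  order-independent so results are permutation-invariant in input
  order.
- The per-condition ON/OFF readout (`per_condition_state`) is the OR of
  per-peak termination calls over that condition's readsets; it
  supports interpretation but never feeds back into the locus verdict
  beyond criterion (i).
- With a single experimental condition the variance criterion cannot be
  met by design: the method requires data sampling both regulatory
  states, and the verdict stays `inconclusive`.

## Known limitations

- Requires paired-end data; single-end termini are too noisy for the
  signed-sum construction.
- Absence of evidence is not evidence of another mechanism: a dataset
  may simply never evoke the OFF (or ON) state.
- Rho-dependent termination, which releases transcripts over a diffuse
  region, will produce broader, weaker peaks and may be missed.
- Raw p-value thresholds at three stages mean genome-scale scans should
  treat single-locus calls as candidates for inspection (the plots and
  `peak_log.csv` exist for exactly that).
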
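# Methods

## The problem

Mismatch-repair-deficient (MMRd) cells leave replication-slippage errors
uncorrected, so mononucleotide repeats (MNRs) acquire somatic 1-bp
frameshifts and microsatellite marker panels drift from their wild-type
product length.  Both readouts are confounded by PCR stutter: slippage
during amplification itself produces reads and electrophoresis products
offset by ±1 (occasionally ±2, ±3 …) repeat units from the template
allele.  Distinguishing a real somatic −1 frameshift from the stutter
background is the statistical core of this package.

## Read model and counting

Amplicons are modelled as `fwd_primer + left_flank + unit×n + right_flank
+ rev_primer` with the repeat run maximal (flanks cannot extend it), so a
read's repeat length is unambiguous.  Reads are single-end and span the
whole amplicon; assignment is by forward-primer prefix within a Hamming
mismatch budget (default 1, ambiguous assignments discarded), and the
repeat length is the distance between a 6-bp anchor at the end of the left
flank and one at the start of the right flank.  The spanned sequence must
be a pure run of whole units; anything else (anchor failures, in-tract
sequencing errors, partial units) marks the read unusable and it is
excluded rather than rescued — amplicon structure makes anchoring
deterministic and a genome aligner unnecessary.

The per-indel table keeps, for each sample × locus × offset ≠ 0, the
mutant read count (observations at WT+offset), the WT read count, and
VAF = mutant/(mutant+WT).  The denominator is deliberately the two-allele
count rather than total coverage, matching the "mutant and WT reads"
convention; offsets observed in any sample produce zero-filled rows for
every covered sample, so controls contribute explicit zeros for
tumor-only offsets.

## Weibull background model

For each (locus, offset), the VAFs of the wild-type control samples are
fitted by a two-parameter Weibull distribution, location fixed at zero.
Given the shape k the scale MLE is closed-form, `λ = (mean xᵢᵏ)^(1/k)`,
and k solves the profile score `1/k + mean(log x) − Σxᵏlog x / Σxᵏ = 0`,
found by bracketed root finding (tolerance 1e-10) on k ∈ [1e-3, 50].
Controls with zero mutant reads are floored at ε = 1/(2·median control
depth) — half a read at typical coverage — since Weibull support is
x > 0.  Degenerate samples (all controls equal) drive k → ∞; the estimate
is capped at k = 50 and flagged.

Two upper-tail probabilities are provided for a tumor VAF v:

* **plug-in**: `p = exp(−(max(v, ε)/λ̂)^k̂)`.  With few controls this is
  strongly anticonservative: the sampling noise of k̂ at n = 8 inflates
  rejection to ~2× nominal at p = 0.05 and by orders of magnitude in the
  far tail (an overconfident k̂ of 10–50 turns a 1.5× background
  elevation into p ≈ e⁻⁵⁰).
* **predictive** (calling default): the tail probability averaged over
  parameter uncertainty.  Given k, xᵏ is exponential, so with a
  scale-invariant prior the predictive survival is
  `(S_k/(S_k+vᵏ))ⁿ`, `S_k = Σxᵢᵏ`; k is then marginalised numerically
  over a 240-point log-spaced grid on [0.05, 50] weighted by its marginal
  likelihood under a log-uniform prior.  On truly Weibull background this
  is calibrated essentially exactly at every level we measured (rejection
  ratio 1.02 at α = 0.05, 0.95 at 1e-3, n = 8 controls).

A two-parameter fit needs at least two informative observations: when a
background has fewer than 2 nonzero controls (or zero variance, or fewer
than 5 controls), the model is flagged and calling falls back to an exact
binomial test of the tumor's mutant reads against max(ε, pooled control
rate).  This generalises the natural rule for the all-zero case and
avoids meaningless continuous fits to imputed pseudo-counts.

Positivity: all tumor × indel tests are pooled into one
Benjamini–Hochberg batch (per-sample batching behind a flag) and a call
requires q < α (default 0.05, the one-sided "above background" reading).
An optional `min_vaf` effect-size floor (0 by default; 0.05 in the demo
pipeline) additionally requires the VAF itself to be reportable —
significance alone at depth 2000 admits 1.3× background elevations that
no assay would report as a somatic frameshift, and clinical amplicon
assays conventionally carry a ~5% reporting floor, comfortably above the
≤2% background VAFs the generator produces.

Testing can be restricted to a target list (the demo tests the five
coding −1 indels, as a targeted frameshift assay does); by default every
offset in the table is tested.

## Synthetic-data generator

The generator defines the study conditions and emulates three things:

* **WT background**: each read's observed repeat length slips with
  probability `stutter_rate` (default 0.02); slip sign is equiprobable and
  the magnitude geometric with decay 0.3, so P(|slip| = m) ∝ 0.3^(m−1).
  This yields a −1 background VAF of ~0.7% at the defaults, in the
  sub-percent range stated for the assay conditions (mean background VAF
  ≤ 2%), and the dominant ±1-bp artifact structure the background model
  must absorb.  Slippage applies identically to WT and mutant templates,
  so a high-VAF mutant carries its own stutter ladder — in particular the
  −2 offset of a planted −1 allele is genuinely elevated in tumors, a
  real (and detectable) signal, not an artifact of the generator.
* **Somatic frameshifts**: each read derives from the mutant template
  with probability `true_vaf` (binomial sampling, so realised VAFs
  fluctuate around the planted value).
* **Sequencing noise**: uniform substitution errors (default 1e-3/base),
  never inside the 6-bp flank-anchoring windows (a stated simplification
  that decouples anchoring from the error model; in-tract errors do occur
  and are dropped by the purity check).

Electropherograms are impulse trains on a 1-bp grid spanning ±15 bp of
the WT product: each allele contributes its fraction as a main peak plus
a symmetric stutter ladder at ±k bp scaled by
`stutter_rate·decay^(k−1)` (trace defaults 0.1/0.5 — fragment analysis
of long MNRs shows much stronger stutter than sequencing of short coding
repeats), plus zero-clipped Gaussian baseline noise.  The generator does
not emulate: PCR-cycle-explicit chemistry, paired-end reads, quality
score structure, sub-bp peak widths/size-calling error, dye pull-up, or
depth variation across loci.  Passing tests therefore demonstrate the
statistical machinery under the stated noise model, not performance on
real instrument output.

All randomness flows from explicit integer seeds (per-sample seed plus a
CRC-derived per-locus stream); identical seeds give byte-identical
FASTQ/TSV outputs, which the run manifest verifies by SHA-256.

The bundled demo cohort is shaped like an MMRd characterisation study — 10
organoid-like, 18 end-stage-tumor-like, 16 mucosa-like samples against 8
WT controls at depth 2000 — with −1 frameshifts planted so the truth
frequency table matches the demo plan by construction.
Three planned cells imply denominators smaller than the group (75%,
12.5%, 7.1%); these are realised as per-locus coverage dropouts (6/8,
2/16, 1/14), and frequency denominators count covered samples.

## MSI scoring

Peak calling treats every grid point at ≥ `min_rel_height` (default
0.10) of the trace maximum as a candidate product — on an integer grid
each size is a distinct PCR product, and stutter shoulders adjacent to a
tall allele must be reportable for stutter handling to act on them —
then accepts candidates tallest-first subject to a minimum separation.
The dominant peak is the tallest, ties broken toward the smaller size
(slippage is deletion-biased).

A marker is unstable when the dominant peak shifts ≥ 1 bp against the
matched control, or when a non-stutter sample peak has no control peak
within `tolerance_bp` (default 0 on the integer grid; ±1 available for
noisy real traces).  Stutter suppression removes peaks within 2 bp of a
taller peak and below 50% of its height, on **both** sides: plus-stutter
products are real, and with a symmetric ladder a below-only rule miscalls
+1 shoulders as new peaks whenever noise flickers them across the
detection threshold (measured: 82% → 100% label accuracy at 2% noise).
Both thresholds are configurable; the suppression rule is a
reconstruction, as no published peak-height convention exists for the
new-peak criterion.

Classification: MSI-H with ≥ 2 unstable evaluable markers, MSS otherwise;
fewer than 2 evaluable markers is unevaluable.  Profile comparison
reports per-marker shift deltas and flags increased instability when the
median delta is positive.

## Hotspot caller

Distinct read sequences are ranked by count (ties lexicographic, dense
ranks); frequencies are computed over **all** assigned reads of the
sample, with discovery restricted to the top K (default 300, the
assay-typical 100–300 window) — an edit present only below rank K is
undiscoverable by construction.  Alignment is global Needleman–Wunsch
with unit costs; tie-breaking prefers substitution over gap and deletion
over insertion, and indels are normalised to their leftmost equivalent
placement (the standard left-alignment convention, verified against
brute-force enumeration of all optimal alignments).  An edit is reported
when its supporting read frequency strictly exceeds 4%.

## Numerical and design choices

* Shape-equation root finding is bracketed (brentq) rather than Newton:
  identical solution, unconditionally convergent on the bracket.
* Predictive marginalisation runs in log space throughout; S_k is
  computed by logsumexp so tract-level VAFs (~1e-3) at k = 50 cannot
  underflow.
* BH adjustment uses the standard step-up with monotonicity enforcement;
  adjusted values cap at 1, so "positive ⇔ q < α" leaves zero-evidence
  rows (exact-test p = 1) negative even at α = 1.
* The binomial fallback is the exact (conservative) test; discrete
  tests at sub-read expected counts cannot have size near nominal, which
  is why family-averaged raw rejection on mixed sparse/populated families
  sits below 0.05 even when every component test is valid.
* Offsets are measured in repeat units; non-integral anchor spacing
  marks a read unusable rather than calling a partial-unit indel.
* Problem sizes in the validation studies (100 null cohorts, 50-seed
  power sweeps at depth 2000, 200 trace panels) were chosen to give
  Monte-Carlo standard errors well below the margins being checked while
  completing in about a minute on one core.

## Known limitations

* The Weibull family approximates binomially-sampled VAFs only roughly:
  at CV ≈ 0.27 the best-fit Weibull's 95th percentile sits slightly left
  of the binomial's, so even a perfectly calibrated-under-the-model test
  over-rejects by ~10–30% relative at α = 0.05 on populated stutter
  offsets.  Censored MLE for the zero-inflated controls is documented
  future work.
* With 8 controls the plug-in tail should not be used for calling; it is
  retained for transparency and comparison.
* Fragment traces are idealised impulse trains; no size-standard
  calibration, raw FSA parsing, or sub-bp resolution.
* No tumor purity modelling, germline joint genotyping, UMI handling or
  base-quality filtering.
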
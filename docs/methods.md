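# Methods

## Sequencing arm: trimming and tailing profiles

### Reference preparation

miRBase-style hairpin spans are extended by `extension_nt` (default 10)
genomic flank bases per side, clamped at contig boundaries, so that reads
running past the annotated hairpin end (untrimmed Drosha products,
templated extensions) still align without edge artifacts. Coordinates are
0-based half-open; every reported 3′-end position is the 0-based index of a
last base on the *extended* sequence. Only the hairpin-sense strand is
stored and searched — the targeted library is strand-specific by primer
design. U is canonicalized to T on input; tails are reported back in the
RNA alphabet.

### Read preprocessing

The first 15 bases of each read are primer-derived and removed. The 3′
adapter is located as the leftmost approximate occurrence after the trim
point: Hamming distance over the overlapping adapter prefix (truncatable at
the read 3′ end down to 5 nt), accepting up to ⌊0.1 × overlap⌋ mismatches.
Reads without an adapter hit, or with inserts shorter than 15 nt, are
dropped with a reason code. Quality strings are carried through but never
used: no quality filter is part of the procedure.

### Alignment, tail calling and the A/U rescue

Inserts are aligned locally against every hairpin with
`Bio.Align.PairwiseAligner` (match +1, mismatch −1; a gap of length k
scores −2 − (k − 1); the affine convention where the opening base costs
−2). Candidates below 70% identity (matched / aligned pairs) are dropped.
One best alignment is chosen across all hairpins by six ordered criteria —
maximum matched bases, minimum mismatches, minimum gap openings in query,
minimum gap openings in target, minimum gapped bases in query, minimum
gapped bases in target — with residual ties resolved deterministically
(lexicographically smallest hairpin id, then 3′-most target span).

All insert bases 3′ of the alignment's last aligned query base form the
non-templated addition (NTA). Because a tail base that happens to match the
template is absorbed as templated, the maximal A/U-only suffix of the
insert is re-examined: scanning its aligned portion 5′→3′, the first
disagreement with the reference (a query insertion counts as a
disagreement; positions deleted from the query have no query base and are
skipped) and everything 3′ of it are reclassified as tail. A pure-A/U
suffix matching the reference perfectly stays templated, so tailing rates
are deliberately conservative. The rescue is idempotent and never lengthens
the templated region.

Two numerical notes. First, the C aligner prunes co-optimal alignments
whose trailing columns add zero net score (mismatch-then-match tails); such
tails are then already part of the NTA and the rescue is a no-op — the
final call is identical either way, which the tests verify from both
directions. Second, the selection criteria form a total order, so the best
alignment is invariant under candidate ordering.

### End profiling and statistics

The trimming zero point of each hairpin is the modal templated 3′ end of
the control sample's reads (ties toward the 3′-most position, biasing
toward the unprocessed end). Hairpins whose learned end is more than 3 nt
from the annotated mature-3p 3′ end are excluded as artifacts. Per read,
trim length = reference end − templated end (negative values mean templated
extension into the flank; such reads are retained and classed Other), and
the U-tail length is the tail length for pure-U tails, 0 otherwise.
Classes: Trimmed (trim > 0), Intact (trim = 0, no tail), Mono-U (trim = 0,
tail "U"), Other.

"Uridylated" means a non-empty pure-U tail, mirroring the U-tail length
definition; `tail_mode="any_u"` counts any tail containing U instead, for
sensitivity analysis. Cohort summaries keep hairpins with strictly more
than 400 reads and report medians of the trimmed, uridylation and
trimmed-uridylation ratios. Group mono-uridylation percentages pool reads
across the group's hairpins and normalize by the pooled total. Knockdown
fold changes divide the treatment proportion by the control proportion and
are reported missing when the control proportion is zero.

## Gel arm: densitometry

Lanes are 1-D intensity profiles at 20 px/mm. Background is the mean of
the lane's 25th and 50th intensity percentiles, subtracted and clipped at
zero. Marker bands are positions where the Savitzky–Golay (window 31,
order 3) first derivative crosses + → − and the second derivative is below
−100. That curvature threshold is in raw scanner units and therefore
scale-dependent; it is exposed as a parameter, and the synthetic lanes
default to a phosphorimager-like scale (band peaks ≈ 2.5 × 10⁴ counts)
where the default is meaningful. Detected positions (ascending) are paired
with marker sizes in descending order — smaller RNA migrates further.

Position↔size calibration is a cubic spline through the marker knots; the
inverse map solves the same spline's cubic pieces rather than fitting a
second spline, so round trips are exact and whole-lane intensity is
conserved through resampling to machine precision. Lane density in size
space is the first difference of the cumulative intensity evaluated at the
positions of a 0.1-nt size grid. The average extension is the
intensity-weighted mean of (size − r) over bins with size ≥ r − 3 nt,
where r is the size at the 0-min lane's intensity maximum; bins more than
3 nt below r are degradation products and excluded. When the included mass
is zero — or below 0.1% of the lane total, which in practice is Gaussian
far-tail and interpolation dust — the result is reported missing rather
than computed from noise.

## Single-molecule arm: binding kinetics

Binding events are maximal runs of frames above an intensity threshold
lasting at least 2 frames; runs touching a trace boundary are censored —
excluded from dwell fits but counted for binding frequency. The dwell-time
constant of single-step dissociation, Δτ = 1/k_off, is the maximum-
likelihood estimate for a left-truncated exponential: τ = mean(dwell) −
truncation, SE = τ/√n, requiring ≥ 10 uncensored dwells. No dead-time
correction beyond the truncation is applied. The optional two-color
anticorrelation filter (keep traces with channel correlation below a
cutoff) is a simplified stand-in for interactive trace curation and is off
by default.

Relative binding frequency divides each construct's event count by its
surface-density correction factor (mean spot counts from a poly-L-lysine
adsorption series) before normalizing to the reference construct. The
energy-landscape statistic is ΔΔG = −RT ln(k_on ratio) with
R = 8.314 J mol⁻¹ K⁻¹ at the imaging temperature, 23 °C (296.15 K) by
default, reported in kJ/mol; it is antisymmetric under ratio inversion and
zero at ratio 1.

## Synthetic data

Generators are seed-deterministic (same seed ⇒ byte-identical output) and
return truth tables sufficient to express every recovery test.

**Reads.** Default conditions: 10,000 reads over 3 hairpins; 36.2% of
reads mono-uridylated at trim 0; 30% trimmed (truncated-geometric trim
lengths 1–12), of which 30% carry pure-U tails, 5% pure-A, 5% mixed;
2% of the remaining untrimmed reads pure-A-tailed; substitution errors at
0.1% per hairpin-derived base (errors are confined to the hairpin-derived
portion so the truth table stays exact for tail bases); geometric tail
lengths 1–8; 110-nt reads = fixed 15-nt primer + recessed hairpin + tail +
adapter + constant fill. Test hairpins have G/C-only 3′-terminal regions so
that added A/U tails mismatch the template immediately and the truth is
exactly identifiable. Real pre-miRNAs often end in genomic A/U runs, where
terminal U's are indistinguishable from template — on real data tail rates
are systematically conservative, and passing recovery tests here does not
bound that bias. PCR/ligation bias and quality-dependent errors are not
modelled.

**Traces.** Alternating renewal per molecule: exponential unbound waits
(rate k_on, default 0.2 s⁻¹), exponential dwells (rate k_off, default
2.78 s⁻¹), 0.1-s frames over 300 s, intensity = baseline + amplitude ×
occupancy + Gaussian noise. Frame quantization rounds partial frames up
(≈ one extra frame per event), and dwells shorter than the 2-frame
detection minimum are lost from dwell fits — both effects cancel in
relative frequencies between constructs sharing k_off. Arrivals during a
bound period do not occur (single-site model), so event rates estimate
k_on only when occupancy is low, as in the sparse-binding regime the assay
operates in.

**Lanes.** Gaussian bands of chosen sizes/mass fractions (σ = 4 px) on a
constant baseline, with the marker lane generated through the same
position–size model; migration is affine in size by default
(position = origin − 12 px/nt × size), with a logarithmic alternative.
Band shape, gel smiling and lane distortion are not modelled.

## Problem sizes and determinism

The test suite runs the full sequencing arm once per session at n = 10,000
reads, compares the production aligner against a brute-force Gotoh DP on
1,000 random instances (inserts ≤ 30 nt, references ≤ 80 nt), refits the
dwell constant at the published event count (8,943), and recovers gel
mixtures to < 0.1 nt. All randomness flows through seeded
`numpy.random.default_rng` generators.
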
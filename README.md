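# tailprofiler

Terminal uridylyl transferases (TUT7/TUT4/TUT2) mark microRNA precursors by
adding non-templated uridines to their 3′ ends: a single U repairs group II
pre-let-7 hairpins for Dicer processing, while oligo-U tails on 3′-trimmed
precursors flag them for decay. `tailprofiler` implements the three
computational analyses used to study this system, as one tested Python
package:

1. **Sequencing arm** — profile 3′ trimming and non-templated tailing of
   pre-miRNAs from targeted small-RNA sequencing: extend hairpin references
   by 10 bp of genomic flank, trim the 15-nt primer prefix and clip the 3′
   adapter, align each insert locally (affine gaps, identity ≥ 0.70) against
   every hairpin, pick the single best alignment by six ordered criteria
   (max matched bases; min mismatches; min gap openings in query, then
   target; min gapped bases in query, then target), call the unaligned 3′
   suffix as the non-templated addition, and *rescue* reference-matching
   A/U-rich suffixes from the first mismatch onward. Reads are then classed
   against the control sample's modal 3′ end as Intact, Mono-U
   (trim = 0, tail = one U), Trimmed (trim > 0) or Other, and aggregated
   into uridylation/adenylation/trimming ratios, dot-plot matrices over
   (trim length × U-tail length), and knockdown fold changes.
2. **Gel arm** — quantify in vitro uridylation time courses from denaturing
   gel densitometry: percentile background subtraction, Savitzky–Golay
   marker detection, cubic-spline position↔size calibration, 0.1-nt
   resampling of lane intensity into size space, and the average extension
   length L̄ = Σₚ Iₚ(sₚ − r) / Σₚ Iₚ over sizes sₚ ≥ r − 3 nt.
3. **Single-molecule arm** — extract binding events from fluorescence time
   traces, fit the dwell-time constant Δτ = 1/k_off by truncated-exponential
   maximum likelihood, form concentration-corrected relative binding
   frequencies k_on(variant)/k_on(reference), and convert them to
   energy-barrier changes ΔΔG = −RT ln(k_on ratio) at 23 °C.

A synthetic-data module generates reads, traces and gel lanes with known
ground truth, so every stage is testable without external downloads.

## Worked example

```python
from tailprofiler import end_profile, pipeline, read_preprocess, synthetic_data
from tailprofiler.sm_kinetics import delta_delta_g

refs = synthetic_data.make_test_references(seed=7)
truth = synthetic_data.LibraryTruth(n_reads=10_000)   # mono-U 0.362, trimmed 0.3
reads, table = synthetic_data.simulate_library(refs, truth, seed=7)

processed = [read_preprocess.preprocess_read(seq, synthetic_data.DEFAULT_ADAPTER,
                                             read_id=rid) for rid, seq in reads]
calls = pipeline.call_processed_reads(processed, refs)
ends = end_profile.learn_reference_ends(
    calls, {r.hairpin_id: r.mature_3p_end for r in refs})
annotated = end_profile.annotate_sample(calls, ends)

n = len(annotated)
print("Mono-U fraction:", sum(a.read_class == "Mono-U" for a in annotated) / n)
print("Trimmed fraction:", sum(a.read_class == "Trimmed" for a in annotated) / n)
print("ddG(+U), kJ/mol:", round(delta_delta_g(0.44), 2))
```

prints

```
Mono-U fraction: 0.3558
Trimmed fraction: 0.2979
ddG(+U), kJ/mol: 2.02
```

The recovered fractions match the generating truth (0.362 / 0.3) to within
binomial sampling error at n = 10,000, and the energy-barrier change says
that a single added uridine raises the apparent binding-activation barrier
of the enzyme–RNA encounter by about 2 kJ/mol.

The same workflows are available from the shell:

```bash
tailprofiler simulate reads --seed 7 --out sim/
tailprofiler preprocess --reads sim/reads.fastq --adapter TGGAATTC... --out inserts.fastq
tailprofiler align --refs sim/refs --reads inserts.fastq --out calls.tsv
tailprofiler profile --refs sim/refs --control calls.tsv --out tables
tailprofiler gelquant --lanes lanes.tsv --marker-lane marker.tsv --markers 60,70,80,90,100 --out ext.tsv
tailprofiler smfit --traces traces.tsv --threshold 350 --out kinetics.tsv
```

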
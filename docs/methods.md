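# Methods

## Model and assumptions

clonesift assumes one patient's samples were amplified with the same IGH
primer scheme, so every read is a (noisy) copy of some VDJ rearrangement in
a fixed orientation. The tumour clone is modelled as a single rearranged
sequence whose relative abundance differs strongly between the diagnostic
sample and follow-ups/dilutions, while the polyclonal repertoire
contributes junctions that are essentially unique per cell. Detection is
alignment-free: no germline reference enters the analysis until the final
annotation step, so novel or heavily mutated rearrangements are not
penalised.

The pipeline is the composition

1. per-sample sliding-window k-mer counting (occurrence semantics: a k-mer
   repeated inside one read counts once per window, which gives the
   conservation law Σ_α C(α)[i] = Σ_reads max(len − k + 1, 0) that the
   tests verify);
2. significance selection over all samples (the three-case order-of-
   magnitude criterion with threshold τ);
3. per-read signature construction (interval union of significant k-mer
   positions; maximal covered segments concatenated in read order) and
   within-sample merging of similar signatures under the length-dependent
   Smith-Waterman threshold, lower frequency absorbed into higher;
4. cross-sample accumulation into clones with per-sample frequency
   vectors, using the same similarity predicate;
5. germline V/D/J annotation by local alignment against a user-supplied
   IMGT-style FASTA, identity = matches / (matches + mismatches + gap
   columns) over the aligned region;
6. Phase-A (diagnostic read count strictly > 100) and Phase-B (best
   identity strictly > 0.80 in V, D and J simultaneously) filtering;
7. major-clone selection and MRD scaling mᵢ = baseline · aᵢ / a_diag,
   with aᵢ the clone's reads over the sample's total reads.

The major clone and its MRD series are taken from the **Phase-A** output.
Phase-B is a germline-homology quality filter for the reported clone
list; on heavily N-masked data even the true clone's identities can fall
below 80% while its frequency trajectory remains perfectly usable, so MRD
tracking deliberately does not depend on Phase-B.

## Parameters

| parameter | default | meaning / why |
|---|---|---|
| k | 25 | window length; long enough that a k-mer overlapping the junction is clone-specific, short enough to survive realistic error rates. Configurable 1–27 on the packed fast path. |
| τ | 1.0 | significance threshold in log₁₀ units; see selection rule below. |
| M, MM, IN | 2, 2, 3 | Smith-Waterman match/mismatch/indel scores; N never scores as a match, even against N. |
| length ratio | 0.7 | pairs whose shorter member is below 70% of the longer are never similar (their threshold branch is unattainable). |
| min_diag_reads | 100 | Phase-A predominance cut (strict >), the read-count equivalent of a ~5%-of-reads rule at these amplicon depths. |
| min_identity | 0.80 | Phase-B homology cut (strict >, all three classes). |
| baseline | 1.0 | diagnostic anchor on the qPCR scale (e.g. 1E0 for high infiltration, 1E−1 for low). |

**Choosing τ.** τ compares per-sample k-mer counts on a log₁₀ scale, and
*everything* whose abundance shifts by ≥ τ logs between some sample pair
becomes significant — including the polyclonal background itself. In a
dilution design where the diagnostic is ~90% tumour and follow-ups are
~100% background, germline V k-mers shift by ~1 log, so τ = 1 floods the
signature stage with background (measured on the packaged generator: the
major clone's follow-up counts inflate several-fold). The working window
is

  (largest log₁₀ background shift between samples) < τ < (log₁₀ clone
  enrichment between diagnostic and the most dilute sample),

here 1 < τ < 3 for a 10⁻³ series; the end-to-end tests and the acceptance
script use τ = 2. The package default stays at 1.0, which is appropriate
when background composition is stable across samples.

## The synthetic-data generator

`clonesift.simulate` emulates the artificial-dilution validation design:
one fixed clone (V trimmed 3′, D trimmed both ends, J trimmed 5′, two
uniform-random N-region inserts) spiked at controlled fractions into a
polyclonal background in which **every read is a fresh random
rearrangement** over the same toy germline (5 V × 250 nt, 4 D × 15–30 nt,
4 J × 50 nt, uniform-random sequences, IMGT-dialect headers). Reads are
assigned to clone or background independently per read, so realised
counts are binomial around the intended fractions and the manifest
records the realised truth.

Noise model: per-base substitutions (uniformly random different base)
followed by N-masking applied in geometric-length bursts (mean 8 bases)
whose start rate is calibrated so the **marginal** per-base N rate equals
`n_rate` exactly (Boolean-model identity: P(uncovered) = exp(−rate·mean)).
Bursts reproduce the run structure of quality crashes in degraded
libraries; an i.i.d. N model with the same marginal rate would leave
almost no clean k-length window at a 20% rate (0.8²⁵ ≈ 0.4%) and is not
how base-caller failures present. Everything is driven by a seeded numpy
Generator; a fixed seed reproduces the FASTQ byte for byte.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: PCR amplification bias and chimeras,
platform-specific error spectra (no indel sequencing errors; indel
tolerance is exercised through the similarity-threshold tests instead),
paired-end structure, somatic hypermutation of the clone between samples,
and the true sequence similarity of real IGH alleles (toy V segments are
random, so V assignment is easier than with real IGHV families).

## Numerical and algorithmic choices

- **Merge order.** Correction ranks signatures by (frequency descending,
  sequence lexicographic) and greedily absorbs each into the first
  higher-ranked similar survivor, repeating passes to a fixed point;
  frequency ties absorb the lexicographically larger into the smaller.
  Deterministic, and dominant clones act as attractors.
- **Accumulation.** Signature sets are processed in sample order,
  signatures within a set in descending-frequency order; a signature
  joins the highest-scoring similar clone (ties: higher total frequency,
  then lexicographic). A clone's representative sequence is fixed by its
  first contributor.
- **Strictness.** Score > T, Phase-A > 100, Phase-B > 0.80 are all strict
  comparisons; non-integer T is compared against integer scores without
  rounding.
- **Alignment.** Linear gap penalties; the traceback prefers diagonal
  over up over left and ends at the first maximum in row-major order, so
  identities are deterministic. D segments are searched between the best
  V and J alignments on the clone when that region is non-empty.
  Annotation runs on the clone's exemplar read (the first full read that
  produced the signature) since it carries V/J context the junction
  signature lacks.
- **Scale path.** K-mers are packed into base-5 uint64 codes (valid for
  k ≤ 27) and counted with vectorised unique/searchsorted operations.
  The pipeline's significance step uses a two-pass candidate prune — any
  significant k-mer must reach a count of 10^τ in some sample — so the
  full multi-sample table is never materialised; the pruned path is
  property-tested equal to the literal table-then-filter path. Similarity
  scans skip pairs whose threshold exceeds M·min_len (provably
  unmergeable) before running the numba Smith-Waterman kernel.
- **Degenerate inputs.** Reads with characters outside {A,C,G,T,N} are
  skipped with a logged count; a sample with zero total reads yields
  NaN/`undefined` MRD entries rather than 0; a single-sample run is valid
  and returns an empty clone table (significance needs a sample pair).

## Problem sizes

The acceptance script simulates 4 × 20 000 reads per series (clean and
20% N-burst regimes) and completes in well under a minute; the test suite
additionally runs the same design at 4 × 100 000 reads per sample, the
depth regime of real amplicon runs, in a few minutes. MRD recovery at the
10⁻³ point is Poisson-limited by the ~100 expected clone reads there.

## Known limitations

- τ must be chosen per study design (see the rule above); there is no
  auto-calibration yet.
- Correction/accumulation are greedy and order-dependent by design; a
  globally optimal clustering is out of scope.
- Reverse-complement reads are not searched by default (amplicon
  orientation is assumed fixed by the primers).
- Identity from local alignment is permissive for very short D segments;
  Phase-B therefore rarely discriminates on D in fragment-length clones.
- One patient per run: cross-patient pooling is intentionally not
  supported.
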
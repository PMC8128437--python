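# Methods

## Coordinate and strand conventions

All positions are 1-based, inclusive, anchored at the A of the ATG start
codon, so codon *n* occupies CDS positions 3n−2…3n (codon 12 at 34–36, codon
61 at 181–183; the driver substitutions are G**G₃₅**T>G**A**T = G12D,
G**G₃₈**C>G**A**C = G13D, C**A₁₈₂**A>C**T**A = Q61L). Positions upstream of
the ATG are labelled `-1, -2, …` and positions in the intron downstream of
exon 1 `111+1, 111+2, …`; these labels appear in MDS frequency tables and
signature-matrix columns. Every reported substitution is on the coding
strand. MDS libraries sequence the non-transcribed strand, so family
consensus sequences are reverse-complemented before comparison; the
simulator emits reads in the same orientation.

## Reference model

`ReferenceLocus` stores the coding sequence (native allele, 129 strain by
convention — both are validated against the configured discriminator and SNP
bases), exon intervals, hotspot codons, the 8-nt exon-3 allele discriminator
(native vs ex3op) and the strain SNP at CDS 96. The real discriminator and
SNP bases are not published, so they are mandatory configuration;
`synthetic_locus()` is a deterministic, stop-free synthetic 321-nt ORF with
the genuine landmarks (GGT/GGC at codons 12/13, CAA at codon 61, a T/C SNP
at nt 96, an 8-nt discriminator at CDS 299–306) and arbitrary sequence
elsewhere. It exists so simulations and tests have a fully specified locus;
it is not the mouse *Kras* sequence.

Missense enumeration tries the nine single-nucleotide substitutions of each
hotspot codon and keeps changes that alter the amino acid, excluding stops
(the analysis screens for activating missense drivers; a read matching no
enumerated variant — including nonsense codons — is "unassigned"). On
GGT/GGC/CAA this yields 6+6+7 = 19 variants covering 6 distinct amino-acid
changes per site, the per-gene third of the canonical 54-mutation RAS
hotspot space.

## Read processing

* **Merging** — ungapped overlap of read 1 against the reverse complement of
  read 2, accepting the longest overlap with mismatch fraction ≤ 20% and
  length ≥ 10 nt. The merger's behaviour at disagreeing bases is not
  specified by the upstream tooling we mirror; we take the higher-quality
  base (read 1 on ties) and the larger of the two qualities — the common
  merger semantics.
* **Quality filter** — keep reads with ≥ 75% of bases at Q ≥ 20 (amplicon
  mode) or ≥ 90% (MDS mode); both thresholds inclusive. Phred+33 only;
  other encodings are rejected rather than guessed.
* **Demultiplexing** — exact (0-mismatch) match of 0–7-nt sample indexes at
  the read ends, longest index first, so a zero-length index only claims
  reads nothing else matches. Exact matching is conservative and
  collision-free for indexes this short; matched bases are trimmed. Exon-1
  genomic libraries use read 1 only and are demultiplexed on the 5′ index
  alone (the 3′ index is beyond read 1's reach).
* **Length filter** (MDS) — inclusive [min, max] window, defaulting to the
  exact expected barcode+region length after index stripping.

## Hotspot calling

Reads are reduced to extracted sub-regions (codons 12/13/61; plus nt 96 and
the discriminator 8-mer in cDNA mode) and assigned exactly: all codons at
reference → WT; exactly one codon equal to one enumerated variant codon →
that variant; anything else → unassigned. Fractions use the full sample
denominator including WT and unassigned reads — this matters for borderline
8% decisions and is the literal reading of "counts ÷ total counts per
sample". Samples under 30 reads are excluded ("low depth"); variant
categories strictly below 8% are dropped; WT is never dropped. Two passing
variants flag the sample "multi-variant" rather than forcing a choice.

The mutant:wildtype ratio divides reads assigned to the single passing
variant by reads assigned WT, excluding reads whose discriminator matched
neither allele (they count toward totals but cannot be phased). Zero WT
reads yields an infinite ratio, flagged instead of raised. Binning is
"high" strictly above 1.5; the filters run before the ratio is computed.

## MDS calling

Families are grouped by exact 14-nt barcode (opaque keys; no UMI error
correction, matching the published workflow). "≥ 90% of reads identical" is
interpreted as the modal-sequence fraction, the simplest reading under which
a consensus is well defined; modal ties break lexicographically and are
flagged. Accepted consensus sequences are compared against the reference
and all single-substitution references over the region: one difference is a
mutant family, two or more (or a length mismatch) is "complex" — excluded
from every numerator but retained in the denominator, matching "families
containing the mutation ÷ total number of families" literally.

The heatmap floor is tied to barcode recovery (1/N families), default 10⁻⁵
for the nominal 10⁵-family recovery, added before log₁₀. Signature matrices
have one column per reference base of the class (e.g. every A for A>T) with
5′/3′ context labels; class means (CA>CT over exon 2, GG>GA over exon 1)
average over **all** class sites including zeros, so one mutated site
contributes its frequency divided by the class size. Group comparison of
class means uses one-way ANOVA with Holm-Šidák-adjusted pairwise t tests.

## qPCR and cohort statistics

Amplification efficiency is assumed exactly 2 per cycle, as the 2^ΔCt
formulas imply. Replicate Ct values are averaged on the Ct scale before any
ΔCt (the dominant convention). Without a configured calibrator, expression
is reported as 2^−ΔCt vs actin — the calibrator sample used upstream is not
identified, so none is silently invented.

Tumor volume is ½·L·W² (length ≥ width, swapped on load if violated);
burden is the per-mouse sum, multiplicity the count, and the size bin is
≥ 100 mm³ inclusive. Mann-Whitney uses SciPy's automatic exact/asymptotic
switch (exact for small tie-free samples, tie-corrected normal
approximation otherwise). Dunn's post-hoc z tests after Kruskal-Wallis are
implemented directly (tie-corrected rank variance, two-sided normal p) since
no installed package provides them; both raw and Holm-Šidák-adjusted p
values are reported, the family being the panel's pairwise comparisons.

## Synthetic data: what it emulates, and what it does not

* **Amplicon libraries** — full-CDS amplicons flanked by the sample's 5′/3′
  indexes; a Binomial(n, mutant fraction) subset of molecules carries the
  variant (the draw is the generator's first, so tests can replay it);
  substitution errors i.i.d. per base, uniform over the three alternates;
  constant Q30 qualities. No PCR jackpots, indels, chimeras or quality
  profiles — so pipeline tests demonstrate correctness of the calling
  logic, not robustness to those artefacts.
* **MDS libraries** — reads laid out `[5′ index][14-nt barcode][target]` on
  the non-transcribed strand; family sizes from a truncated geometric
  (default mean 4, minimum 1, so both the ≥ 2-read and 90% rules are
  exercised; the upstream protocol states no size distribution — this is a
  declared default, not an inference). Barcodes are uniform over 4¹⁴ with
  collisions allowed (a collision merges two molecules into one family, as
  in real data). Per-read errors perturb the target region only: a barcode
  read error would move a read between families — family attrition, a
  different phenomenon from the within-family consensus behaviour the error
  rate is meant to exercise — and the error-suppression property of the
  consensus rule is defined over target errors.
* **qPCR** — Ct = baseline − log₂(relative abundance) + Gaussian noise, so
  zero-noise designs invert exactly through the ΔCt formulas.
* **Cohorts** — per-mouse tumor counts (Poisson or fixed) and sizes
  (fixed, lognormal, or a two-class mixture whose "large" fraction controls
  the ≥ 100 mm³ bin).

Identical truth + seed reproduces byte-identical FASTQ/TSV output.

## Problem sizes and numerical choices

The error-suppression measurement uses twenty independent 10⁵-family
libraries (family sizes ≥ 3, per-base error 10⁻³); frequency recovery uses
one 10⁵-family library with a 10⁻³ truth at the Q61L site, judged within
three binomial standard errors of the accepted-family count; the simulated
tumor uses 10⁴ read pairs at error 10⁻³, sizes at which the binomial
standard error (≈ 0.005 on the fraction) is well inside the tolerances
checked. Signature summaries use 2 × 10⁴ families per sample and region —
large enough that the boosted CA>CT class mean stands clear of its sampling
noise. Brute-force oracle comparisons (quadratic grouping, enumeration of
all nine substitutions per codon) run at ≤ 1,000 reads where the quadratic
cost is negligible.

Known limitations: no indel or multi-nucleotide variant support anywhere
(the callers treat them as unassigned/complex, by design); no duplex
consensus; no gapped merging; hotspot logic is generic over the configured
codons but only single-amplicon phasing via the exon-3 discriminator is
implemented; genomic copy number comes from qPCR, never from read depth.
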
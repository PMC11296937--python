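# Methods

This note documents the models, numerical choices and limitations behind
`spliceform`, in the order the pipeline runs.

## Junction filtering and in-silico translation

Splice events arrive as a flat TSV, one row per event, with 1-based
inclusive genomic intervals (GTF convention) for the two flanking exons
and the event-specific targets: the cassette exon (SE), the two mutually
exclusive exons (MXE), the long/short forms of the alternative-splice-site
exon (A5SS/A3SS), or the retained intron (RI). This deliberately
simplified dialect carries the same information as rMATS output for the
operations implemented here; adapting real rMATS tables is a columns-only
transformation.

Low-read junctions are removed by a fixed inclusive threshold on
inclusion + skip reads, default 16. A two-component Gaussian mixture on
log1p counts is available (`filter_junctions_mixture`) but is not the
default: the fixed threshold is the operative, auditable rule, and the
mixture's posterior cutoff is a free parameter with no canonical value.

Translation proceeds from the annotated CDS start in the annotated frame
(offset 0/1/2). Tier assignment is relative to the reference transcript:
let Δ be the nucleotide-length change the event form introduces.

* Δ ≢ 0 (mod 3) → rejected, `frameshift` (also when no stop is reached).
* Δ ≡ 0 and the first stop appears before the reference stop mapped into
  the new transcript → rejected, `premature_stop`.
* a form whose protein equals the supplied canonical sequence →
  `canonical_redundant`, excluded from the non-canonical FASTA.
* otherwise tier 1.

Only tier 1 is emitted; frame-recovery tiers are out of scope. Codons
containing N translate to X under the optional `n_policy="x"`; the default
rejects non-ACGT input outright. `-J<n>` suffixes are assigned per gene in
ascending genomic coordinate of the source events, after exact-sequence
deduplication (provenance lists every contributing event), so accessions
are deterministic across runs.

## Pairwise isoform alignment

Canonical/alternative pairs are aligned globally with BLOSUM62, affine
gap penalties (existence 11, extension 1, i.e. a length-L gap costs
11 + L) and **free end gaps**, so N-/C-terminal truncations score as
terminal variant regions instead of forcing internal gaps. The alignment
literature would call the underlying intent "local"; free-end-gap global
alignment realizes it while guaranteeing every residue is assigned.

Determinism: the aligner's first traceback is post-processed by shifting
every gap run to its leftmost score-neutral position (a character move is
neutral when the displaced and absorbing residues on the opposite row are
equal). This pins down a canonical alignment without enumerating
co-optimal tracebacks.

Variant regions are maximal runs of non-match columns; runs containing
only canonical-row gaps are insertions, only alternative-row gaps
deletions, anything else a substitution. `merge_gap` (default 0) can fuse
regions separated by fewer matched columns than the cutoff. A pair is a
*simple variant* when exactly one internal region exists, it is an indel,
and its length is ≥ 10 (inclusive by default; an exclusive "> 10" reading
is a flag, since both conventions appear in practice). Terminal
truncations are excluded from that count by default because long
alternative isoforms commonly combine an internal indel with a spurious
terminal difference.

## Digestion, uniqueness, razor

Tryptic digestion follows the K/R-not-before-P rule (pyteomics' expasy
trypsin rule) with up to 2 missed cleavages, length bounds 7–50, and an
N-terminal-Met-cleaved variant of each protein-initial peptide.
Uniqueness is exact substring membership over the canonical + isoform
database; I and L are distinct by default (`equate_il` folds them), a
convention that must match the upstream search engine's. Razor peptides
go to the candidate parent with the most unique peptides; ties prefer the
canonical isoform — canonical forms are almost always the more abundant —
then the lexicographically smallest accession. Both `unique` and
`unique_razor` roll-up modes are first-class because isoform-level
conclusions can differ between them.

## Normalization and the differential model

Intensities are log2-transformed (nonpositive → missing) and per-sample
median-centred. This is a deliberate, documented stand-in for the arcsinh
variance-stabilizing calibration used by vsn: it is monotone, removes
sample-loading shifts exactly (the tests assert shift invariance of all
fold changes), and keeps the transform invertible for reporting. It does
not equalize the variance of low-intensity peptides the way vsn does.

Per protein, samples with observed values enter a no-intercept least
squares fit with one mean per chamber plus donor indicators; the contrast
is ventricle − atrium. Proteins with fewer than two observed samples in
either chamber are skipped with a reason. Variance moderation follows the
scaled-F empirical-Bayes idea: residual variances s² are modelled as
s₀²·F(d, d₀), with (d₀, s₀²) estimated by method of moments from the
mean and variance of s² at the common residual df. Posterior variances
(d₀s₀² + d s²)/(d₀ + d) feed t statistics on d + d₀ df (normal when the
observed spread collapses, d₀ → ∞). This reproduces the practical
behaviour of limma's moderated t without its full fitFDist machinery;
plain OLS is a flag. Under the global null the p values are uniform and
at study conditions (7 donors × {LA, LV, RA}, residual sd 0.3, donor sd
0.2, 10% planted |log2FC| = 1) the BH 5% list is calibrated with
sensitivity ≈ 1 — both are asserted by the test suite, which is a
statement about the model on data satisfying its assumptions, not about
any real dataset.

BH adjustment is the standard step-up with monotonicity enforcement,
matching statsmodels to < 1e-12.

The junction-peptide z-score uses pooled per-chamber mean intensities
(per-donor pairing is a flag; the pooled form is the default because the
pairing convention of the figure it mirrors is not stated), an intensity
floor of 1e8, and requires ≥ 3 shared peptides with positive spread —
otherwise it signals an undefined statistic rather than returning a
number.

## Feature intersection

Disorder calls are strict (score > 0.5). Variant-region residues are
scored each on their own sequence (insertions on the alternative track,
deletions on the canonical track, substitutions on both); invariant
residues are the aligned non-variant canonical residues. The per-isoform
Kolmogorov–Smirnov comparison contrasts the distribution of variant vs
invariant disordered fractions across isoforms; a residue-pooled mode
exists because the figure being mirrored does not state which pooling it
used. The KS p is exact for m·n ≤ 10,000 and tie-free data — computed by
lattice-path counting in exact integer arithmetic — and otherwise uses
the Kolmogorov limiting distribution (alternating series for large
arguments, Jacobi-theta dual form below x ≈ 1.18 where the alternating
series converges too slowly).

Binding-function classes require a variant-region residue inside the IDR
mask to exceed the propensity threshold (default 0.5, min run 1, both
configurable — the "confident assignment" cutoff of the upstream
predictor is not published). N-glycosylation motifs default to the
literal N-X-S/T rule with the standard no-proline sequon as the
alternative; a motif intersects a region when its N lies inside it.
Phosphosite classification through the coordinate map is exhaustive and
mutually exclusive: `lost_by_deletion` (no alternative image),
`in_variant_region` (substituted but mapped), `mapped_to_alternative`.

## Synthetic study generator

The generator's defaults are the study conditions the pipeline is
validated under:

| parameter | default | meaning |
|---|---|---|
| cohort | 7 donors × {LA, LV, RA} | LA/RA pooled as atrium, LV ventricle |
| junction reads | NB(mean 100, size 10); contaminant NB(mean 3), weight 0.25 | two-component read model around the 16-read filter |
| frame-preserving fraction | 0.8 | remainder frameshift by a 1-nt boundary shift |
| PTC fraction | 0.15 | of frame-preserving MXE/RI events, a planted in-frame stop |
| planted indels | length U{10..60}, insertion prob 0.5 | single internal indel per pair |
| effects | 10% of isoforms, &#124;log2FC&#124; = 1, donor sd 0.2, residual sd 0.3, MCAR missingness 0.1 | log-normal LFQ model |
| disorder | Beta(8,2) in variant regions, Beta(2,8) elsewhere, moving-average window 3 | reproduces the "over two-thirds mostly-disordered variant regions" regime |
| binding bumps | protein 0.55 / RNA 0.5 of pairs, height 0.7–0.95, width 10 | planted inside variant regions |
| phosphosites | 2 per 100 S/T/Y residues, ×3 inside deleted blocks | canonical-sequence annotations |

Construction guarantees worth knowing:

* ORFs are built by back-translating random proteins, so reference
  transcripts are stop-free in frame by construction; internal coding
  exon boundaries are codon-aligned, so frame-preserving events cannot
  create junction-spanning codons, and frameshift/PTC cases are planted
  explicitly. Each simulated gene carries one event; the five types cycle
  across genes and strands are random.
* Planted indels are redrawn until their placement is alignment-
  unambiguous (no score-neutral one-residue shift) and until both flanks
  exceed a margin of max(12, (28 + L)/3) residues — with free end gaps, an
  indel closer to a terminus than its own gap cost can be expressed more
  cheaply as a terminal gap, which would make "exact planted boundaries"
  ill-defined rather than merely hard.
* Donor effects are additive log-scale random intercepts, matching the
  fixed-effect adjustment the model fits. Missingness is MCAR by default.
* Everything is deterministic under a fixed seed (single `numpy`
  Generator per stage, fixed iteration order); two runs of the full
  pipeline produce byte-identical numeric outputs.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: correlated peptide ionization efficiencies,
intensity-dependent missingness (an option exists but is off), shared
peptides between unrelated genes, search-engine identification errors
(inputs arrive as if post-FDR), isoform families with more than one
alternative form per gene, and real disorder-score autocorrelation beyond
a short moving average.

## Null-calibration caveat

Per-isoform disordered *fractions* are discrete (region lengths of tens of
residues) and tie-rich, so under a matched null their KS p is not exactly
uniform; the generator-level uniformity checks therefore use the pooled
per-residue statistic with smoothing disabled, where exchangeability holds
exactly. The enrichment direction of the per-isoform test is unaffected.

## Problem sizes

The shipped tests and the acceptance script run the pipeline at desk
scale — tens of genes, hundreds to a thousand isoform pairs or features
per experiment, 21-sample cohorts — which exercises every code path in a
few seconds while keeping the statistical assertions (calibration
envelopes, uniformity checks, 100% planted-recovery requirements) well
powered. Counts reported by the acceptance script scale with these sizes
and are not comparable to any published cohort's totals.

## Known limitations

* The read filter approximates an upstream mixture-model filter by its
  operative fixed threshold; the optional mixture filter is a
  convenience, not a reconstruction.
* One transcript per gene is assumed when resolving an event (the first
  transcript containing both flanking exons); genes where the event flanks
  span different transcripts are a structural error, not a merge.
* vsn and limma are approximated as described above, by design.
* MXE events emit both forms; whether one or two isoforms per form should
  be emitted is left to the caller's downstream dedup (exact-sequence
  dedup already collapses identical products).
* The confidence filter (`filter_confident_features`) expects
  probability/PEP columns produced by an upstream search pipeline; no
  spectrum-level validation is performed here.
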
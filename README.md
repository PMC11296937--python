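# spliceform

Proteogenomic analysis of alternative-splicing-derived proteoforms.

Alternative splicing lets one gene encode several protein isoforms, but
whether spliced transcripts yield stable, functionally distinct proteins is
hard to establish from transcripts alone. `spliceform` implements the
proteogenomic route to that question, as used in isoform-resolved studies
of the human heart: translate RNA-seq splice junctions into candidate
protein isoforms, identify and quantify them from bottom-up proteomics
peptide tables, test whether their usage differs between tissue
compartments (here: cardiac atria vs ventricles), and ask what protein
features — intrinsically disordered regions (IDRs), predicted binding
function, N-glycosylation sequons, phosphosites — the isoform-specific
variant regions remodel.

It is a library plus a thin CLI, aimed at computational proteomics /
proteogenomics researchers who have junction tables (rMATS-style), a
genome + GTF, canonical protein FASTA, and peptide-level label-free
quantification (LFQ) tables from a search engine, and want an auditable,
fully scriptable analysis rather than a GUI pipeline.

## What it computes

**Junction translation.** Splice events (SE, MXE, A5SS, A3SS, RI) with at
least 16 total junction reads (inclusive, configurable) are spliced into
event-specific transcripts and translated in the annotated reading frame.
An isoform is *tier 1* when translation reaches the stop codon mapped from
the reference transcript without a frameshift (event length change ≢ 0
mod 3) or a premature termination codon. Tier-1 isoforms are written as a
protein FASTA with per-gene `-J1, -J2, …` accessions.

**Variant regions.** Each alternative isoform is aligned to its canonical
counterpart (BLOSUM62, affine gaps 11/1, free end gaps, deterministic
leftmost gap placement). Maximal non-matching runs become insertion /
deletion / substitution variant regions; a pair is a *simple variant* when
it differs by a single internal indel of ≥ 10 residues (terminal
truncations are tracked but not counted). A canonical↔alternative
coordinate map supports feature transfer.

**Isoform-resolved quantification.** Tryptic digestion (K/R, not before P,
missed cleavages), uniqueness by exact substring search against the
canonical + isoform database, razor assignment of shared peptides to the
parent with the most unique peptides (ties prefer the canonical form), and
junction-spanning flags for peptides that cross a variant region.
Intensities are log2-transformed and per-sample median-centred, rolled up
to proteins (`unique` or `unique_razor` mode), and tested per protein with
a no-intercept linear model

    y ~ 0 + chamber + donor

whose ventricle − atrium contrast is the log2 fold change; variances are
moderated by method-of-moments shrinkage across proteins and p values are
Benjamini–Hochberg adjusted (5% and 10% FDR reported side by side). The
junction-peptide deviation statistic z = (target − mean(shared)) /
SD(shared), on log2 V/A ratios of peptides above an LFQ intensity floor
(default 1e8), corroborates isoform-specific regulation at the peptide
level.

**Feature intersection.** Per-residue disorder and binding-propensity
tracks (MetaPredict-/flDPnn-style scores in [0, 1], supplied as input) are
intersected with variant regions: disordered fraction of variant vs
invariant residues (score strictly > 0.5), two-sample Kolmogorov–Smirnov
tests (exact small-sample p by lattice-path enumeration, asymptotic
otherwise), binding-function classes {protein_binding, rna_binding, both,
none}, N-glycosylation motif scans (literal N-X-S/T, optional no-proline
sequon), and phosphosite mapping through the coordinate map (sites inside
deleted blocks are `lost_by_deletion`).

**Synthetic study generator.** Because the real inputs are large external
deposits, the package ships a first-class generator that emulates their
statistical structure end to end — genes with stop-free ORFs and planted
events of all five types on both strands, overdispersed junction reads
with a low-read contaminant component, a 7-donor × {LA, LV, RA} cohort
with log-normal peptide intensities, donor random effects, chamber
effects and missingness, Beta-distributed disorder tracks elevated inside
variant regions, and phosphosites enriched in deleted regions — together
with a complete ground-truth record for every emitted object.

## Worked example

```python
from spliceform import SimulationConfig, simulate_study, PipelineConfig, run_pipeline
import json, pathlib

workdir = pathlib.Path("heart_demo")
simulate_study(SimulationConfig(seed=7, n_genes=40), workdir / "inputs")

config = PipelineConfig(
    gtf=str(workdir / "inputs/genes.gtf"),
    genome=str(workdir / "inputs/genome.fasta"),
    junctions=str(workdir / "inputs/junctions.tsv"),
    canonical_fasta=str(workdir / "inputs/canonical.fasta"),
    peptides=str(workdir / "inputs/peptides.tsv"),
    design=str(workdir / "inputs/design.tsv"),
    tracks=str(workdir / "inputs/tracks.tsv"),
    ptm=str(workdir / "inputs/ptm.tsv"),
    outdir=str(workdir / "run"),
    quant_mode="unique_razor",
)
manifest = run_pipeline(config)
report = json.loads((workdir / "run/enrichment_report.json").read_text())
print("junctions kept       :", manifest["stages"]["junction_filter"]["out"],
      "of", manifest["stages"]["junction_filter"]["in"])
print("tier-1 isoforms      :", manifest["stages"]["translation"]["tier1"])
print("simple variants      :", manifest["stages"]["alignment"]["simple_variants"])
print("chamber-biased (5%)  :", manifest["stages"]["differential"]["significant_fdr_0.05"])
print("variant IDR fraction >= 0.5:", report["n_variant_frac_ge_half"], "of", report["n_pairs"])
print("disorder KS p        : %.3g" % report["ks_disorder_p"])
```

prints

```
junctions kept       : 28 of 40
tier-1 isoforms      : 20
simple variants      : 12
chamber-biased (5%)  : 2
variant IDR fraction >= 0.5: 20 of 20
disorder KS p        : 4.12e-09
```

Of 40 simulated splice events, 28 pass the 16-read filter and 20 yield
tier-1 proteins (the rest are frameshifted, contain a premature stop, or
reproduce the canonical sequence). Twelve isoforms differ from canonical
by a single ≥ 10-residue indel; two isoforms are chamber-biased at 5% FDR
under the donor-adjusted model; and all 20 variant regions are mostly
disordered, giving a vanishing KS p for disorder enrichment of variant
over invariant regions — the generator's planted regime, recovered by the
pipeline.

The same stages are available from the shell:

```bash
spliceform simulate --seed 7 --out inputs/
spliceform translate --gtf inputs/genes.gtf --genome inputs/genome.fasta \
    --junctions inputs/junctions.tsv --canonical inputs/canonical.fasta \
    --min-reads 16 --out db.fasta
spliceform align --canonical inputs/canonical.fasta --alternative db.fasta \
    --out regions.tsv
spliceform run --config run.yaml
```

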
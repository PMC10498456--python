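# Methods

## The locus model

The package models a functional gene ("gene B", 44 exons, forward strand)
whose exons 32–44 are nearly identical to a downstream pseudogene
("pseudogene A"), separated by an intervening unit that carries a marker
gene ("marker gene C").  The pseudogene constitutively differs from the gene
by seven index features: a 120-bp deletion spanning exon 35 and the first 30
intronic bases (**a**), four substitutions in exon 40 / intron 40 / intron
43 (**b**, **c**, **e**, **f**), a single-base duplication in intron 40
(**d**), and — at the haplotype level — loss of marker gene C when the unit
is deleted (**g**).  Only **a** and **c** are treated as pathogenic.

Recombinant alleles are modeled as exact splices of pseudogene-derived
sequence into the gene:

| allele class       | structure                                             | indices        |
|--------------------|-------------------------------------------------------|----------------|
| `fusion_type1`     | gene 5′ + pseudogene from intron 34; unit deleted     | a–g            |
| `fusion_type2`     | gene 5′ + pseudogene from intron 39; unit deleted     | b–g            |
| `conversion_type1` | tract over exon 35 ± flanks; unit retained            | a              |
| `conversion_type2` | tract over exon 40 – exon 44 start; unit retained     | b–f            |
| `point_variant`    | gene with one or more small variants                  | —              |

The type 1 conversion tract covers only the 120-bp deletion by default
because that is the only index its carriers in the packaged cohort show; the
tract is an explicit, overridable parameter, since true per-allele tract
extents are generally unknown.

### Desk-scale geometry

Exon cDNA lengths are chosen so that the anchor coordinates of the real
transcript hold literally: exon 35 spans c.11435–11524 (90 nt, so the
c.11435_11524+30del deletion is exactly 120 bp), exon 40 ends at c.12204 and
contains c.12150/c.12174, exon 44 starts at c.12628, and the recurrent
unique-region variant positions fall in their annotated exons.  Introns
default to 60 bp and the intervening unit to 3 kb (standing in for the real
~30 kb), so a full screen runs in about a second; every length is
configurable and no calling logic depends on the scale.

### Divergence placement

Pseudogene identity defaults to 0.97 over the homologous region, counting
substitutions only (the 120-bp deletion and the 1-bp duplication are
structural).  Divergent sites (PSVs) are placed randomly with a minimum
spacing of 20 bp, avoiding primer sites, index positions, and the four
3′-panel amplicon windows.  The last exclusion is deliberate: in those
windows the clustered index variants themselves are the local divergence,
and stacking further random differences into a 150-bp read window would make
recombinant-tract reads unmappable under any reasonable mismatch budget —
misrepresenting the assay rather than stressing it.  Elsewhere PSV density
is unconstrained by the aligner because those regions are masked or matched
exactly.

## Read simulation

Single-end amplicon reads (150 nt default) are drawn per amplicon with
Poisson(mean depth) totals split evenly across templates, with independent
per-base substitution errors (default 0.5%).  Indel sequencing errors,
paired ends, PCR chimeras and platform-specific homopolymer artifacts are
not modeled; passing tests therefore demonstrate the logic of the screen,
not robustness to platform-specific noise.  All randomness flows through
explicit seeds and identical seeds reproduce byte-identical FASTQ.

Long-PCR enrichment is modeled as template extraction between a gene-specific
exon-31 forward site and a common exon-44 reverse site: free pseudogene
copies are never amplified, fusion alleles are.  The allele-specific phasing
product anchors inside the sequence removed by the 120-bp deletion, so only
normal-exon-35 haplotypes amplify, bounded downstream at the common exon-44
site.

## Alignment and masking

The aligner seeds with exact k-mers (k = 15) tiled every k bases along the
read and extends ungapped.  Because the number of seeds (10 on a 150-nt
read) exceeds the mismatch budget (⌊0.05·150⌋ = 7), any placement within
budget is guaranteed a clean seed — this makes the seeded search provably
equivalent to an exhaustive Hamming scan wherever the best placement is
unique, which the test suite checks against a brute-force oracle.  Numerical
choices: `N` matches nothing and a mapped read may not overlap a masked
base; equal-best placements at distinct locations are reported unmapped
(ambiguous), the same conservatism that motivates masking; reads failing the
ungapped budget are rescued by a single 1–2 bp indel if that brings them
within budget, which is what lets the caller genotype the 1-bp duplication
index and small frameshift variants without a general gapped aligner.

Standard mode masks the gene's exon 32–44 region *and* the whole pseudogene;
modified mode masks only the pseudogene except its exon-35 homolog.  Reads
spanning the deletion junction cannot sit on the gene without a 120-bp gap
but match the pseudogene segment contiguously, so they map there — coverage
appearing on the pseudogene's exon-35 homolog *is* the deletion signal.

## Calling thresholds

Hotspot sites no-call below 20× depth.  Allele-fraction bands are 0.15 (min
alt) and 0.85 (hom); they are not part of the published strategy (the
production variant caller's internals are proprietary) but separate het/hom
cleanly at ≥100× with ≤1% error, and are configurable.  The same bands drive
the unique-region pileup scan for novel substitutions and 1–2 bp indels;
detected insertions equal to an adjacent reference base are normalized to
duplications (placement inside repeats is ambiguous by a base or two, so
event aggregation tolerates ±3).

Copy number uses median-normalized log2 ratios against ≥3 wild-type
controls, with bands ≤−2.0 → 0 copies, (−2.0, −0.42] → 1, (−0.42, 0.32) → 2,
≥0.32 → 3+ (log2 ½ = −1 sits mid-band).  Median normalization presumes a
mostly-diploid panel; the exon-35 copy estimate in the modified run is
therefore taken relative to the exon-36 reference amplicon.  MLPA ratios map
0.25/0.75/1.3 to 0/1/2/3+ copies, following common diagnostic practice and
configurable per kit.  The published CNV analysis for this assay used a
dedicated visualization method described elsewhere; this package substitutes
the standard log2-ratio estimator above.

## Classification

`classify_alleles` is an exhaustive decision table over discretized
evidence: deletion zygosity × index-c zygosity × marker-C copies ×
point-variant/CNV findings, with internal consistency checks (homozygous
deletion must co-occur with zero exon-35 copies, etc.) that produce explicit
conflict reports rather than silent repairs.  The table keys type 2 calls on
index **c** alone, treating **b**, **d**, **e**, **f** as supporting
evidence, because whether a type 2 allele must carry all of b–f is not
settled.  One combination is genuinely ambiguous — heterozygous deletion +
heterozygous c + one marker-C loss — and is returned as an explicit
candidate set `{fusion_type1 + X, conversion_type1 + fusion_type2}`; phasing
evidence (allele-specific PCR in the workflow, or trio genotyping supplied
through the same interface) prunes it.  Truncation of point variants is
judged syntactically (nonsense/frameshift annotations, small out-of-frame
indels); missense changes other than index c are variants of unknown
significance and never count toward the biallelic-null verdict.

## Cohort statistics

Feature frequencies use N/A-aware denominators; percentages round half-up at
one decimal.  Qualified entries count by their leading sign ("− (only
fingers and elbows)" is negative) with the qualifier retained.  Composite
gastrointestinal categories are derived from prose via an editable keyword
mapping (`data/composite_keywords.yaml`); with the shipped rules the
gastrointestinal-bleeding count is 1 rather than the 2 sometimes quoted for
this cohort — which prose entries count as "bleeding" is editorially
ambiguous, so the mapping is data, not code.  The MLPA fixtures under
`data/mlpa/` are synthetic stand-ins constructed to show the two canonical
signatures (homozygous exon-35 loss with marker intact; single-copy loss of
both).

## Problem sizes used in the tests

The stochastic suites run at the scales the screen is designed for: 200
seeded simulations per deletion-zygosity class at 200× depth and 0.5% error;
20 end-to-end runs for each of the fifteen distinct allele-class pairs plus
the nine packaged family scenarios; 100 seeded copy-number simulations with
six amplicons per target over a mostly-diploid background; 500 random reads
against a ≤20-kb locus for the aligner-versus-oracle check.  The whole suite
completes in about a minute on one CPU.

## Known limitations

* The simulator's error model is substitution-only; indel-heavy platforms
  would need the aligner's gap rescue generalized.
* The aligner is a teaching/validation-scale implementation (dictionary
  k-mer index, per-read Python loop); it is not a production mapper.
* Breakpoint positions of fusions and conversion tracts are configurable
  but the defaults are conventions, not measurements; real tract extents
  vary and are mostly unobservable from short reads.
* Marker-gene copy number is the only evidence separating fusion from
  conversion; samples with unrelated marker-gene CNVs would confound the
  table (they surface as conflict reports, not wrong calls).
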
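# pseudopanel

Pseudogene-aware amplicon screening for recombinant gene/pseudogene alleles,
built for the tenascin-X situation: the 3′ end of the functional gene *TNXB*
(exons 32–44) is >97% identical to the neighboring pseudogene *TNXA*, and the
~30-kb unit between them (which contains *CYP21A2*) recombines.  Non-allelic
homologous recombination deletes the unit and creates a *TNXB/TNXA* fusion
gene; gene conversion copies pseudogene sequence into the gene while keeping
the unit.  Biallelic loss of tenascin-X causes classical-like Ehlers–Danlos
syndrome, so a diagnostic panel must call variants inside a region where
naive short-read mapping cannot tell gene from pseudogene.

The package is a simulator-backed implementation of the screening strategy a
diagnostic lab uses for this locus, for people who want to study, test or
teach that strategy end to end:

* **Locus model** — a desk-scale synthetic paralog locus (gene B, intervening
  unit with marker gene C, pseudogene A) with the seven diagnostic index
  variants **a**–**g**: the 120-bp exon 35–intron 35 deletion
  (c.11435_11524+30del, **a**), c.12150C>G (**b**), c.12174C>G (**c**),
  c.12204+39dup (**d**), c.12204+43T>G (**e**), c.12628-52A>G (**f**) and the
  marker-gene copy loss (**g**).  Full HGVS-style cDNA coordinate parsing and
  arithmetic (`c.12204+39` → genomic) is included.
* **Masked alignment** — *standard* mode masks the homologous gene region and
  the whole pseudogene with `N` (which is why such variants are invisible to
  conventional panels); *modified* mode masks only the pseudogene except its
  exon-35 homolog, so reads spanning the 120-bp deletion junction align
  there and the deletion becomes visible.
* **Hotspot calling with no-call logic** — paired coverage sentinels in the
  gene's exon 35 and the pseudogene's exon-35 homolog encode the zygosity
  rule: both called → heterozygous deletion; gene no-call + pseudogene
  called → homozygous; gene called only → no deletion.
* **Copy number** — a median-normalized log2-ratio caller over amplicon
  depths, plus MLPA probe-ratio interpretation, distinguishing fusion
  (marker gene lost) from conversion (marker gene kept).
* **Allele classification** — an exhaustive decision table fusing deletion
  zygosity, index genotypes, copy numbers, point variants and optional
  phasing into per-allele calls: `fusion_type1/2`, `conversion_type1/2`,
  `point_variant`, `cnv_deletion`, `normal` — with ambiguity as an explicit,
  phasing-resolvable output state and a biallelic-null verdict.
* **Cohort statistics** — the nine-family cohort tables as editable TSV
  fixtures with N/A-aware feature frequencies, demographics and the
  pseudogene-derived family fraction.

## Worked example

Screen a simulated compound heterozygote carrying a nonsense variant on one
allele and a type 1 fusion gene on the other (the packaged scenario `P4`):

```text
$ pseudopanel screen --scenario P4 --allele1 x --allele2 x
sample P4
  exon-35 deletion zygosity: heterozygous
  index zygosity: {'b': 'het', 'c': 'het', 'd': 'het', 'e': 'het', 'f': 'het'}
  exon-35 copies: 1
  copy calls: exon2=2, exon3=2, marker_c=1
  point variants: c.10274C>G(het)
  call: fusion_type1 / point_variant(c.10274C>G,p.(Ser3425*))
  biallelic null: biallelic null: fusion_type1 / point_variant(c.10274C>G,p.(Ser3425*))
    - heterozygous 120-bp deletion: one type 1 allele
    - het deletion + het index c + one marker-C loss: cis (fusion type 1) and trans (conversion type 1 + fusion type 2) both fit
    - phasing: index_c on the deleted-exon-35 allele
    - phasing: c.10274C>G on the normal-exon-35 allele
```

Reading the output: the modified (long-PCR) run sees the 120-bp deletion
heterozygously and all five substitution/dup indices at ~50% allele
fraction; the copy-number run shows one marker-gene copy lost, so one allele
is a fusion.  That evidence alone is ambiguous — the deletion and index c
could be in cis (one fusion allele) or in trans (a conversion plus a type 2
fusion) — so the tool runs the allele-specific phasing amplification, finds
index c on the deleted-exon-35 allele and the nonsense variant on the normal
one, and resolves the pair as a type 1 fusion gene plus a truncating point
variant: a biallelic null.

Cohort summaries print the fixture's totals, e.g.

```text
$ pseudopanel cohort-stats --feature skin_hyperextensibility
skin_hyperextensibility 7/8     87.5%
female  66.7%   median_age      60
pseudogene_derived_families     7/9     77.8%
```

Other entry points: `simulate-locus`, `simulate-sample`, `simulate-reads`,
`mask-ref`, `align`, `call-hotspots`, `cnv`, `mlpa`, `classify`,
`compare-modes` — each a thin wrapper over the library (see `--help`).

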
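# ctlforge

Design toolkit for building **complex trait loci (CTLs)** in maize with
CRISPR-Cas9 gene targeting.

A CTL is a small, well-characterised chromosomal region carrying multiple
preselected transgene insertion sites. Each site receives a ~3 kb
**site-specific insertion landing pad (SSILP)** by homology-directed repair
(HDR) at a Cas9 cut; trait genes are later swapped into the pad by
FLP/FRT recombinase-mediated cassette exchange, and pads carrying different
traits are combined onto one chromosome by ordinary crossing, then
introgressed as a single locus. `ctlforge` covers the in-silico half of
that programme, for molecular breeders and genome-engineering groups:

| module | what it does |
|---|---|
| `genome_io` | FASTA/GFF3/genetic-map loading; bp ↔ cM interpolation with extrapolation and plateau flags |
| `ctl_scanner` | slides a 10-cM window to nominate 4–5 cM regions that are haplotype-conserved in the SS and NSS germplasm pools, gene-poor, and recombinogenic |
| `cts_selector` | enumerates SpCas9 NGG target sites and filters them: ≥2 kb from genes, genome-unique site and 200–500 bp flanks, ≥2 mismatches in the seed (positions 1–10 5′ of the PAM) versus every other NGG locus, ≥0.1 cM spacing |
| `template_designer` | assembles the SSILP repair template (~400 bp arms + PSA/PSB tags + cassette) and plans junction / overlapping long PCR amplicons |
| `event_screen` | classifies T0 junction-PCR + qPCR assays into HDR event classes and computes per-site modification and 2×HDR frequencies |
| `stacking` | simulates repulsion-phase two-marker BC1 populations and estimates genetic distance from recombinant counts (1% recombinants = 1 cM; Haldane optional) |
| `fixtures` | deterministic synthetic genomes/panels/assay tables with planted ground truth |

## The statistics at the core

For two linked loci at map distance *d* (cM), the recombination fraction is
*r* = *d*/100 (direct rule, used throughout; Haldane
*r* = (1 − e<sup>−2d/100</sup>)/2 available). In a repulsion-phase BC1 each
seed is A-only or B-only with probability (1 − *r*)/2 and carries both
markers or neither with probability *r*/2. The distance estimate from
observed counts is

> d̂ = 100 · (n<sub>both</sub> + n<sub>neither</sub>) / n,

rounded half-up to two decimals, with a Clopper–Pearson interval on the
recombinant proportion. Screening frequencies are the analogous count
ratios: modification frequency = modified/regenerated (integer %), 2×HDR
frequency = both-junction-positive/regenerated (one decimal %).

## Worked example

Simulate one BC1 population of 2,688 seeds for two landing pads 0.55 cM
apart, and estimate their distance back from the genotype counts:

```bash
$ ctlforge stack-sim --distance 0.55 --n 2688 --seed 7
{"n_total": 2688, "n_a_only": 1330, "n_b_only": 1345, "n_both": 10,
 "n_neither": 3, "cm_estimate": 0.48, "ci_low": 0.2578, "ci_high": 0.8256}
```

13 of 2,688 seeds are recombinant (both markers or neither), giving
d̂ = 0.48 cM with a 95% CI of [0.26, 0.83] cM that covers the true 0.55.

Classify an exact-counts screening table (214 T0 plants, 198 with a
modified site, 3 positive at both junctions):

```python
>>> from ctlforge.fixtures import make_screen_table
>>> from ctlforge.event_screen import summarize_site
>>> records, _ = make_screen_table("TS49", 214,
...     class_counts={"hdr2_monoallelic": 3, "nhej_mutant": 195})
>>> summarize_site(records)
SiteSummary(site_id='TS49', n_regenerated=214, n_modified=198,
            mod_freq_pct=93, n_hdr1_5p=0, n_hdr1_3p=0, n_2xhdr=3,
            hdr2_freq_pct=1.4)
```

93% of plants carry a modified site and 1.4% are 2×HDR events — the
frequencies a screening lab would print for this site.

The full design pipeline on a synthetic genome:

```bash
ctlforge make-fixtures --seed 0 --out fx/
ctlforge scan-ctl --genome fx/genome.fasta --gff fx/genes.gff3 \
    --map fx/map.tsv --haplotypes fx/haplotypes.csv --out candidates.tsv
ctlforge select-cts --genome fx/genome.fasta --gff fx/genes.gff3 \
    --map fx/map.tsv --region chr1:150000-195000 --out cts.tsv
ctlforge design-ssilp --genome fx/genome.fasta --cts cts.tsv --row 0 \
    --out template.gb
```

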
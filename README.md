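# splicecase

Consequence analysis and therapeutic-editing feasibility for splice-acceptor
point mutations, built around the minimal workflow for monogenic splicing
disorders: **(1)** identify the pathogenic variant, **(2)** predict its
primary splicing effect, **(3)** derive its secondary consequences, and
**(4)** select a genome-editing strategy.

The motivating case is the *NF1* splice-acceptor mutation c.61-2A>G
(rs1131691100, chr17:31,155,981 on GRCh38), an autosomal-dominant cause of
neurofibromatosis type 1. The package is aimed at rare-disease
bioinformaticians who have a variant call, a gene model and a reference
slice, and need the downstream mRNA- and protein-level mechanics plus an
in-silico editing assessment — without running deep-learning splice
predictors or RNA isoform callers.

## What it computes

**Primary splicing effect.** A variant at intron position −1/−2 destroys the
canonical AG acceptor. Splicing shifts to the nearest downstream exonic AG
(cryptic acceptor), removing the start of the exon from the mature mRNA:

* `deletion_length` — exonic bases removed (the 1-based exonic position of
  the second base of the chosen AG);
* `distance_from_variant` — bases in the closed interval from the variant
  to that AG's second base (both conventions are always reported; for
  *NF1* c.61-2A>G they are 16 and 18).

**Secondary consequences.** If the deletion length *d* satisfies
*d* mod 3 ≠ 0 the reading frame shifts: translation produces novel residues
until a premature termination codon (PTC). The package reports the novel-
residue count, the PTC position, the wild-type codons of the affected exon
lost downstream of the PTC, the truncated peptide and its average mass, a
three-frame stop map, and nonsense-mediated decay (NMD) under the classic
rule — NMD-positive iff the PTC starts ≥ 55 nt upstream of the last
exon–exon junction. It also reports CpG dinucleotides created or destroyed
by the substitution (c.61-2A>G creates a CpG whose cytosine is at
chr17:31,155,980) and aggregates per-read 5mC calls at any site.

**Editing feasibility.** For the correction (alt → ref), every nuclease in
a catalog (shipped defaults: Cas12a CBE with TTTV TAM, SpCas9 ABE/CBE with
NGG PAM) is scanned on both strands within ±20 nt. A placement is viable
when the editor's chemistry (CBE: C→T, ABE: A→G on the protospacer strand)
performs the correction and the target sits in the editing window. Every
other editable base in the window is a bystander edit and is classified
against a pathogenic-variant table; any pathogenic bystander makes the
strategy *hazardous* and demotes it below prime editing, for which
simplified nCas9/NGG pegRNA candidates (nick between protospacer positions
17/18, fixed PBS, RTT covering the edit plus a 3′ homology arm) are
proposed.

**Expression statistics.** Cohort z-score `z = (x − μ)/σ` with two-tailed
normal p and both empirical and normal-theory percentiles; the
low-expression filter (drop genes with TPM ≤ 1 in strictly more than 90% of
samples); 2^−ΔΔCt relative qPCR quantification with replicate-propagated
standard errors; pooled-variance t-test and one-way ANOVA for pedigree
comparisons.

**Synthetic data.** Every input can be generated with planted ground truth
(`splicecase.synthetic_data`): multi-exon genes with canonical GT–AG
introns, a polypyrimidine tract and a 20-nt poly-T run, a planted cryptic
AG at a chosen offset with exact novel/truncated codon counts, editing
contexts with a single planted TAM and known bystanders, Gaussian TPM
cohorts, Ct tables with a planted fold change, and binary methylation
calls. All generators are deterministic functions of (parameters, seed).

## Worked example

The bundled synthetic mirror of the *NF1* case plants the published
geometry at the published coordinates (the sequence itself is synthetic):

```python
from splicecase import synthetic_data as sd
from splicecase.splice_engine import splice_consequence_for_variant

case = sd.nf1_like_case()          # A>G at chr17:31,155,981
res = splice_consequence_for_variant(case.genome, case.gene, case.variant)
```

Formatting the result (see `splicecase consequence --help` for the CLI
equivalent) prints:

```text
classification     : acceptor-2 (intron 1)
cryptic acceptor   : deletion 16 nt, 18 nt from the variant
reading frame      : shift +1, 17 novel aa, PTC at CDS 112
exon truncation    : 26 wild-type aa lost after the PTC
NMD                : True
peptide            : 37 aa, 4.08 kDa
CpG created        : C at 31155980
Cas12a placement   : PAM TAAA at 31155990 (9 nt from target), verdict hazardous
strategy ranking   : prime_editing first
```

Reading: the mutation disables the canonical acceptor; the next AG lies 16
exonic bases in, so exon 2 loses 16 nt, shifting the frame (+1). Seventeen
novel residues are translated before a PTC that truncates 26 further
wild-type exon-2 residues; the PTC sits far upstream of the last junction,
so the transcript is an NMD substrate (haploinsufficiency). The only base-
editor placement (Cas12a, TAM 9 nt downstream) would co-edit the adjacent
guanine at 31,155,982 — itself a pathogenic variant (rs1263745475) — so
prime editing is ranked first.

The same workflow runs from the shell on any FASTA + gene model + variant:

```sh
splicecase consequence --fasta genome.fa --gene-model model.json --hgvs c.61-2A>G
splicecase editscan --fasta genome.fa --variant chr17:31155981A>G \
    --pathogenic-table clinvar_slice.tsv
splicecase report --config case.yaml --out report.json
splicecase simulate splice --seed 7 --out dataset/
```

## Layout

| Module | Role |
| --- | --- |
| `splicecase.genome_io` | FASTA/GFF3/VCF/JSON I/O, HGVS c. → genomic mapping, strand handling |
| `splicecase.splice_engine` | splice-site location, cryptic-acceptor scan, frame/PTC/NMD/peptide analysis |
| `splicecase.epigenetic_delta` | CpG creation/destruction, methylation aggregation, homopolymer runs |
| `splicecase.editing_feasibility` | nuclease catalog, PAM/TAM scan, bystander hazards, prime design, ranking |
| `splicecase.expression_stats` | z-scores, expression filter, 2^−ΔΔCt, t-test/ANOVA |
| `splicecase.synthetic_data` | seeded generators with planted ground truth |
| `splicecase.report` / `splicecase.cli` | consolidated case report and the `splicecase` command |

See `docs/methods.md` for the model conventions, parameter defaults and
known limitations.
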
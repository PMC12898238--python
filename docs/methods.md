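# Methods

This note records the models, conventions and defaults behind `splicecase`,
the reasoning for design choices that were genuinely open, and what the
synthetic-data generators do and do not emulate.

## Coordinates, strands and variants

All external coordinates are 1-based and inclusive (VCF/GFF3 convention);
no half-open representation is visible at any interface. A
`GenomeSequence` carries an `origin` — the genomic coordinate of its first
base — so a 1 kb slice around a locus behaves identically to a whole
chromosome; this is what allows desk-scale analyses and tests at real
GRCh38 coordinates without a reference download.

HGVS `c.` strings carry transcript-strand alleles; `Variant` always stores
genomic plus-strand alleles, so the two round-trip unambiguously through a
reverse complement on minus-strand genes. The HGVS walker maps a CDS
position by accumulating coding lengths across exons in transcript order,
then applies an intronic offset stepwise into the adjacent intron; `c.X+k`
requires X to be the last coding base of its exon and `c.X-k` the first,
matching HGVS semantics, and any walk leaving the intron raises. Only SNVs
are supported: the causal variants and bystander edits in this problem
class are substitutions, and structural variation is out of scope.

## Cryptic-acceptor model

Canonical splice sites are the intron-terminal GT (donor, positions +1/+2)
and AG (acceptor, positions −2/−1); non-GT–AG introns are flagged, not
rejected. When a variant hits the acceptor dinucleotide, the engine scans
the *alt-applied* sequence from the canonical −2 position downstream into
the exon for the nearest AG, excluding the canonical pair itself (even if
the substitution recreates an AG there, its function is destroyed by
hypothesis). An AG whose second base is the exon's first base is a valid
offset-1 call. The scan is nearest-AG by design — no branch-point or
polypyrimidine strength scoring — because the biological question is "where
is the next available AG", and strength models are a non-goal. Scanning is
capped at `max_scan_nt` (default 100) or the exon length, whichever is
smaller; absence of an AG is a valid result, not an error.

Two distance conventions are always reported to prevent off-by-two
confusion:

* `deletion_length` = exonic bases removed = exonic position of the chosen
  AG's second base;
* `distance_from_variant` = bases in the closed interval from the variant
  to that second base.

For an acceptor−2 variant these differ by exactly 2, which is how a single
event can be described as both a "16-nt deletion" and an AG "~18 bases
downstream". An optional flag additionally reports the nearest *upstream
intronic* AG (a partial intron-retention alternative), clearly labelled;
the default pipeline is downstream-exonic only.

## Frame, PTC and truncation accounting

The mutant CDS is rebuilt by trimming the affected exon's 5′ end and
re-splicing. Frame analysis aligns mutant to wild type by the longest
common nucleotide prefix (the deletion point), translates the mutant CDS
and locates the first stop. `novel_aa_count` is the number of codons
between the last aligned wild-type codon and the stop. The PTC is mapped
back to wild-type CDS coordinates by adding the deletion length;
`wildtype_exon_aa_lost_after_ptc` counts whole wild-type codons of the
affected exon lying entirely downstream of the PTC-equivalent triplet.
Counting whole codons of the affected exon (not the junction codon, not
later exons) is a documented choice where published descriptions are
ambiguous; it reproduces the 17/26 split of the motivating case. In-frame
deletions report zero novel residues and no PTC by definition. A
three-frame stop map of the mutant CDS is emitted for figure-style
reporting.

## NMD rule

The classic junction rule with a configurable threshold (default 55 nt, the
literature convention): NMD-positive iff the PTC's first base lies at least
55 nt upstream of the last exon–exon junction of the *mutant* transcript
(junction positions account for the deletion). PTCs in the last exon, and
single-exon transcripts, are NMD-negative. The rule is a binary
prediction, not an efficiency estimate.

## Peptide mass

Average (not monoisotopic) residue masses, pinned in
`splice_engine.AVERAGE_RESIDUE_MASS_DA`, plus one water (18.0153 Da),
reported in kDa. Average masses match how truncated-protein sizes are
quoted in the motivating literature (a 37-residue product is "~4 kDa").

## CpG delta and methylation

An SNV can only alter the two dinucleotides overlapping the mutated base,
so exactly those two are compared before/after substitution; CpG is
strand-symmetric, so plus-strand detection suffices and the C position is
reported. Methylation is consumed as a per-read binary call table (calling
5mC from raw signal is out of scope); aggregation counts distinct reads and
rejects duplicate (read, site) rows rather than guessing which call to
keep. Homopolymer runs are maximal single-base runs ≥ a threshold, used to
describe contexts such as the 20-nt poly-T tract abutting the acceptor.

## Editing feasibility

Editor windows are stored as inclusive protospacer positions counted from
the **PAM-proximal end** of the protospacer, one convention for all
nucleases. For Cas12a (PAM 5′ of the protospacer) this coincides with the
usual literature numbering; note that for SpCas9 (PAM 3′) the shipped
window [4, 8] is therefore counted from the PAM side. The shipped catalog
(Cas12a-CBE: TTTV, spacer 23, window 8–14; SpCas9-ABE/CBE: NGG, spacer 20,
window 4–8) is a versioned config file whose sha256 is recorded in every
report, so results are attributable to a catalog revision. PAMs are
reported in plus-strand orientation (a minus-strand TTTV displays as BAAA),
and `target_distance_to_pam` is the distance from the target base to the
nearest motif base — printed alongside the window position so the two
conventions cannot drift apart.

A base-editing candidate requires both chemistry match (the correction
alt→ref must equal C→T for CBE or A→G for ABE *on the protospacer strand*)
and the target inside the window. Bystanders are every other same-chemistry
base in the window; classification is an exact (contig, pos, ref, alt)
match against a local pathogenic-variant TSV (no live database queries, so
results are deterministic), and one pathogenic match makes the verdict
hazardous.

Prime-editing design is deliberately simplified: all NGG placements on
either strand whose nick (between protospacer positions 17/18, i.e. 3 nt
5′ of the PAM) lies within `max_nick_to_edit` (default 30 nt) of the
target, with fixed PBS length 13 and RTT = gap + edit + 10 nt of 3′
homology. Replicating a full pegRNA scoring tool is a non-goal; the
candidates establish *feasibility*, not an optimized design. Ranking is
rule-based: clean base editors first (they are simpler payloads), then
prime editing, then hazardous base editors, each with a stated reason.

## Expression statistics

`z = (x − μ)/σ` with p = 2Φ(−|z|). When raw controls are given, μ and σ
use the n−1 estimator and an empirical percentile (% of controls ≤ x) is
computed; the normal-theory percentile is always computed. Both are
labelled and reported because small or skewed cohorts make them visibly
different, and published percentiles rarely say which was used.

The low-expression filter removes a gene iff strictly more than
`sample_fraction` (default 0.9) of samples are ≤ `tpm_threshold` (default
1), so a gene low in exactly 90% of samples is retained; the boundary
follows the rule's wording "more than 90%".

2^−ΔΔCt: replicates averaged per (sample, gene); ΔCt = Ct(target) −
Ct(reference); ΔΔCt against a named calibrator sample whose relative
expression is exactly 1. Replicate standard errors propagate as
SE(RE) = RE·ln2·SE(ΔΔCt). Under per-well Gaussian Ct noise σ with
triplicates, SE(ΔΔCt) = σ·√(4/3) ≈ 1.155σ — four independent triplicate
means contribute — so at σ = 0.1 the *median* relative error of the
recovered fold change is ≈ 5.4%; this is a property of the measurement
model, not of the estimator (the replicate means are sufficient
statistics). The t-test (pooled variance) and one-way ANOVA are direct
textbook-formula implementations with p-values from the t and F
distributions, with optional Bonferroni-corrected pairwise post hoc tests;
they exist for small pedigree comparisons, not as a general linear-model
layer.

## Synthetic data: what it emulates and what it does not

The generators produce deterministic, seed-reproducible inputs with planted
truth, which is what makes 100%-recovery round-trip testing meaningful.
Key construction devices:

* **A-free filler.** Every stop codon contains an adenine, so coding filler
  drawn from {C, G, T}³ can never terminate translation in any frame; stop
  placement is therefore exact by construction, not by rejection sampling.
* **Planted acceptor geometry.** Intron 1 ends in a polypyrimidine/poly-T
  tract, one C, and the canonical AG; the affected exon's first AG is
  placed at exactly the requested offset, with the preceding bases drawn
  from {C, T} so no earlier AG can occur. An offset of 1 is represented
  with an acceptor−1 G>A variant, the only geometry in which an AG can end
  at exon position 1 next to a canonical acceptor.
* **Planted editing contexts.** The background contains no adenine and no
  CC dinucleotide, which provably excludes every catalog placement other
  than the planted minus-strand TTTV (plus-strand matches fail the
  chemistry requirement for a G>A correction); one upstream GG guarantees a
  prime-editing alternative exists.
* **`nf1_like_case`.** A 58-exon construct with the planted features at the
  real GRCh38 coordinates of the motivating case (variant at
  chr17:31,155,981, exon-2 start at 31,155,983). It is synthetic sequence
  with planted coordinates, clearly labelled as such — not a reference
  slice.

What the generators do **not** emulate: realistic human background
composition (GC content, repeats beyond the planted poly-T), splice-site
strength variation, multiple competing cryptic sites of graded strength,
sequencing error in methylation calls, or cohort batch effects.
Consequently, passing round-trip tests demonstrates that the pipeline's
arithmetic and scanning logic are exact under the stated model — it does
not validate nearest-AG as a biological predictor against real
transcriptomes, which is an experimental question.

## Problem sizes and numerics

Default test and acceptance runs use desk-scale inputs chosen as the
smallest sizes that exercise every code path: genes of 3–58 exons (a few
kb), 200 seeded splice cases covering every cryptic offset 1–60, 100
seeded editing cases, 1000 random 60-nt windows against the motif-expansion
oracle, 1000 seeded Ct tables, and a 609-control expression cohort matching
the motivating study's cohort size. All statistics use double precision;
the only tolerance-sensitive comparison is the ddCt recovery distribution
discussed above. Ties in candidate ordering are broken deterministically
(by nuclease name, position, then strand) so reports are byte-stable.

## Known limitations

* Donor-side variants are classified but cryptic-*donor* scanning is not
  implemented (acceptor-only v1).
* Nearest-AG is a deliberate simplification; a weak AG may be skipped in
  vivo for a stronger one further downstream.
* The NMD rule is binary and ignores known escape mechanisms (long 3′
  UTRs, start-proximal PTCs).
* Prime-editing candidates are unscored; PBS/RTT lengths are fixed
  defaults, not optimized per locus.
* The shipped nuclease catalog is a small, versioned default; real
  feasibility screens should supply a current catalog and pathogenic table.
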
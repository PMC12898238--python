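"""Splice-site disruption, cryptic-acceptor scanning and reading-frame analysis.

The central scenario: a point mutation destroys a canonical intron-terminal
AG acceptor, splicing shifts to the nearest downstream exonic AG, the 5' end
of the exon is deleted from the mature mRNA, and — when the deletion length
is not a multiple of three — translation runs out of frame until a premature
termination codon (PTC).  Transcripts whose PTC lies well upstream of the
last exon-exon junction are flagged for nonsense-mediated decay (NMD) by the
classic 55-nt rule.

Distance conventions (reported side by side to avoid off-by-two confusion):

* ``deletion_length`` / ``offset_exonic`` — exonic bases removed; equals the
  1-based exonic position of the *second* base of the chosen cryptic AG.
* ``distance_from_variant`` — bases in the closed interval from the variant
  position to that second AG base, in transcript orientation.  For an
  acceptor−2 variant this is ``deletion_length + 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .genome_io import (
    CoordinateError,
    GeneModel,
    GenomeSequence,
    ModelError,
    Variant,
    revcomp,
)

STOP_CODONS = ("TAA", "TAG", "TGA")

#: average residue masses in daltons, pinned for reproducible peptide masses
AVERAGE_RESIDUE_MASS_DA = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS_DA = 18.0153


@dataclass(frozen=True)
class SpliceSite:
    """One donor or acceptor of one intron, in transcript orientation."""

    kind: str                      # 'donor' | 'acceptor'
    intron_index: int              # 1-based
    dinucleotide_pos: tuple[int, int]  # genomic positions, transcript order
    first_exonic_pos: int          # adjacent exon's transcript-first/last base
    contig: str
    strand: str
    canonical: bool                # GT for donors, AG for acceptors


@dataclass(frozen=True)
class CrypticAcceptorCall:
    """Nearest downstream exonic AG after canonical-acceptor loss."""

    found: bool
    intron_index: int
    offset_exonic: int | None = None
    deletion_length: int | None = None
    distance_from_variant: int | None = None
    upstream_intronic_offset: int | None = None  # optional retention report


@dataclass
class SpliceConsequence:
    """Frameshift / PTC / truncation record for one mis-spliced transcript."""

    deletion_length_nt: int
    frame_offset: int
    is_frameshift: bool
    novel_aa_count: int
    ptc_cds_pos: int | None
    wildtype_exon_aa_lost_after_ptc: int
    nmd_predicted: bool | None
    rule_detail: str
    peptide: str
    peptide_mass_kda: float
    stop_map_per_frame: dict[int, list[int]] = field(default_factory=dict)
    has_stop: bool = True
    affected_exon_index: int | None = None


def locate_splice_sites(gene_model: GeneModel, genome: GenomeSequence) -> list[SpliceSite]:
    """One donor and one acceptor per intron, flagged canonical or not."""
    sites: list[SpliceSite] = []
    for i, (lo, hi) in enumerate(gene_model.introns(), start=1):
        if hi - lo + 1 < 4:
            raise ModelError(f"intron {i} shorter than 4 bases")
        if gene_model.strand == "+":
            donor_pos = (lo, lo + 1)
            acceptor_pos = (hi - 1, hi)
            donor_exonic = lo - 1
            acceptor_exonic = hi + 1
            donor_seq = genome.fetch(lo, lo + 1)
            acceptor_seq = genome.fetch(hi - 1, hi)
        else:
            donor_pos = (hi, hi - 1)
            acceptor_pos = (lo + 1, lo)
            donor_exonic = hi + 1
            acceptor_exonic = lo - 1
            donor_seq = revcomp(genome.fetch(hi - 1, hi))
            acceptor_seq = revcomp(genome.fetch(lo, lo + 1))
        sites.append(SpliceSite("donor", i, donor_pos, donor_exonic,
                                gene_model.contig, gene_model.strand,
                                donor_seq == "GT"))
        sites.append(SpliceSite("acceptor", i, acceptor_pos, acceptor_exonic,
                                gene_model.contig, gene_model.strand,
                                acceptor_seq == "AG"))
    return sites


def classify_splice_variant(
    variant: Variant, gene_model: GeneModel, genome: GenomeSequence
) -> tuple[str, int | None]:
    """Classify a variant position against the gene's splice dinucleotides.

    Returns one of ``acceptor-2 / acceptor-1 / donor+1 / donor+2 / exonic /
    deep_intronic`` plus the affected intron index (None for exonic).
    """
    if variant.contig != gene_model.contig:
        raise CoordinateError(
            f"variant contig {variant.contig!r} is not the gene's contig"
        )
    for site in locate_splice_sites(gene_model, genome):
        if variant.pos == site.dinucleotide_pos[0]:
            label = "acceptor-2" if site.kind == "acceptor" else "donor+1"
            return label, site.intron_index
        if variant.pos == site.dinucleotide_pos[1]:
            label = "acceptor-1" if site.kind == "acceptor" else "donor+2"
            return label, site.intron_index
    exon = gene_model.exon_containing(variant.pos)
    if exon is not None:
        return "exonic", None
    lo, hi = gene_model.span()
    if lo <= variant.pos <= hi:
        for i, (ilo, ihi) in enumerate(gene_model.introns(), start=1):
            if ilo <= variant.pos <= ihi:
                return "deep_intronic", i
        return "deep_intronic", None
    raise CoordinateError(
        f"variant {variant.contig}:{variant.pos} lies outside the gene span"
    )


def _acceptor_site(gene_model: GeneModel, intron_index: int,
                   genome: GenomeSequence) -> SpliceSite:
    for site in locate_splice_sites(gene_model, genome):
        if site.kind == "acceptor" and site.intron_index == intron_index:
            return site
    raise ModelError(f"no acceptor for intron {intron_index}")


def scan_cryptic_acceptor(
    genome_with_alt: GenomeSequence,
    splice_site: SpliceSite,
    max_scan_nt: int = 100,
    variant_pos: int | None = None,
    exon_length: int | None = None,
    include_upstream_intronic: bool = False,
) -> CrypticAcceptorCall:
    """Find the nearest AG usable in place of a disrupted canonical acceptor.

    Scans from the canonical acceptor dinucleotide downstream into the exon
    (transcript orientation) on the alt-applied sequence.  The canonical AG
    itself is excluded — even if the alt allele re-creates an AG there, the
    variant destroyed its function by definition.  ``found=False`` when no AG
    occurs within ``max_scan_nt`` exonic bases (capped at the exon length
    when known).  ``variant_pos`` defaults to the acceptor −2 position.
    """
    if splice_site.kind != "acceptor":
        raise ValueError("cryptic scan requires an acceptor splice site")
    a1, a2 = splice_site.dinucleotide_pos
    step = 1 if splice_site.strand == "+" else -1
    scan = max_scan_nt if exon_length is None else min(max_scan_nt, exon_length)
    # transcript-oriented string: index 0 = intron −2, 1 = intron −1, 2 = exon pos 1
    last = splice_site.first_exonic_pos + step * (scan - 1)
    if splice_site.strand == "+":
        last = min(last, genome_with_alt.end)
        s = genome_with_alt.fetch(a1, last)
    else:
        last = max(last, genome_with_alt.origin)
        s = revcomp(genome_with_alt.fetch(last, a1))

    if variant_pos is None:
        variant_pos = a1
    upstream = None
    if include_upstream_intronic:
        upstream = _nearest_upstream_intronic_ag(genome_with_alt, splice_site,
                                                 max_scan_nt)
    for i in range(1, len(s) - 1):
        if s[i] == "A" and s[i + 1] == "G":
            offset_exonic = i  # second base at string index i+1 = exon pos i
            second_base_pos = splice_site.first_exonic_pos + step * (i + 1 - 2)
            distance = abs(second_base_pos - variant_pos) + 1
            return CrypticAcceptorCall(
                found=True,
                intron_index=splice_site.intron_index,
                offset_exonic=offset_exonic,
                deletion_length=offset_exonic,
                distance_from_variant=distance,
                upstream_intronic_offset=upstream,
            )
    return CrypticAcceptorCall(found=False, intron_index=splice_site.intron_index,
                               upstream_intronic_offset=upstream)


def _nearest_upstream_intronic_ag(
    genome: GenomeSequence, site: SpliceSite, max_scan_nt: int
) -> int | None:
    """Offset (bases upstream of intron −2) of the nearest intronic AG.

    Clearly-labelled optional extra describing a partial intron-retention
    alternative; the default pipeline scans downstream-exonic only.
    The returned offset is the transcript-orientation distance from the
    canonical −2 base to the second base of the nearest upstream AG.
    """
    a1, _ = site.dinucleotide_pos
    # transcript-oriented string ending at intron position −3
    if site.strand == "+":
        lo = max(genome.origin, a1 - max_scan_nt)
        if lo > a1 - 1:
            return None
        t = genome.fetch(lo, a1 - 1)
    else:
        hi = min(genome.end, a1 + max_scan_nt)
        if a1 + 1 > hi:
            return None
        t = revcomp(genome.fetch(a1 + 1, hi))
    j = t.rfind("AG")
    if j == -1:
        return None
    return len(t) - (j + 1)  # second AG base is this many bases upstream of −2


def reconstruct_transcript(
    gene_model: GeneModel,
    genome: GenomeSequence,
    cryptic_call: CrypticAcceptorCall | None = None,
) -> tuple[str, str]:
    """Spliced mRNA and CDS strings, wild-type when ``cryptic_call`` is None.

    With a cryptic call, the exon downstream of the named intron is trimmed
    by ``deletion_length`` at its transcript 5' end.
    """
    exons = [list(e) for e in gene_model.exons]
    if cryptic_call is not None and cryptic_call.found:
        idx = cryptic_call.intron_index  # affected exon = intron_index + 1 (1-based)
        s, e = exons[idx]
        d = cryptic_call.deletion_length
        if d >= e - s + 1:
            raise ModelError(
                f"deletion of {d} nt consumes exon {idx + 1} (length {e - s + 1})"
            )
        if gene_model.strand == "+":
            exons[idx][0] = s + d
        else:
            exons[idx][1] = e - d

    def fetch_tx(lo: int, hi: int) -> str:
        seq = genome.fetch(lo, hi)
        return seq if gene_model.strand == "+" else revcomp(seq)

    mrna = "".join(fetch_tx(s, e) for s, e in exons)
    cds_lo = min(gene_model.cds_start, gene_model.cds_end)
    cds_hi = max(gene_model.cds_start, gene_model.cds_end)
    cds_parts = []
    for s, e in exons:
        a, b = max(s, cds_lo), min(e, cds_hi)
        if a <= b:
            cds_parts.append(fetch_tx(a, b))
    return mrna, "".join(cds_parts)


def stop_map(cds: str) -> dict[int, list[int]]:
    """1-based nt start positions of stop codons in each of the 3 frames."""
    out: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for frame in range(3):
        for start in range(frame, len(cds) - 2, 3):
            if cds[start : start + 3] in STOP_CODONS:
                out[frame].append(start + 1)
    return out


def peptide_mass(peptide: str, kda: bool = True) -> float:
    """Average molecular mass of a peptide (one water plus residue masses)."""
    try:
        total = WATER_MASS_DA + sum(AVERAGE_RESIDUE_MASS_DA[a] for a in peptide)
    except KeyError as exc:
        raise ValueError(f"unknown amino-acid letter {exc}") from exc
    return total / 1000.0 if kda else total


def analyze_frame(
    wild_cds: str,
    mutant_cds: str,
    affected_exon_cds_span: tuple[int, int],
) -> SpliceConsequence:
    """Frameshift / PTC / truncation analysis of a mutant CDS.

    ``affected_exon_cds_span`` gives the 1-based wild-type CDS coordinates of
    the affected exon's coding part.  ``wildtype_exon_aa_lost_after_ptc``
    counts whole wild-type codons of that exon lying entirely downstream of
    the region the PTC maps back to.
    """
    if not wild_cds.startswith("ATG") or not mutant_cds.startswith("ATG"):
        raise ValueError("CDS must begin at an ATG start codon")
    if len(mutant_cds) > len(wild_cds):
        raise ValueError("mutant CDS longer than wild type: not a deletion case")
    d = len(wild_cds) - len(mutant_cds)
    frame_offset = d % 3
    is_frameshift = frame_offset != 0

    # longest common nucleotide prefix locates the deletion point
    p = 0
    while p < len(mutant_cds) and mutant_cds[p] == wild_cds[p]:
        p += 1
    aligned_codons = p // 3

    mut_peptide_full = str(Seq(mutant_cds[: len(mutant_cds) - len(mutant_cds) % 3]).translate())
    stop_idx = mut_peptide_full.find("*")
    has_stop = stop_idx != -1
    if has_stop:
        peptide = mut_peptide_full[:stop_idx]
        ptc_cds_pos = 3 * stop_idx + 1
    else:
        peptide = mut_peptide_full
        ptc_cds_pos = None

    novel_aa = 0
    truncated = 0
    if is_frameshift and has_stop:
        novel_aa = max(0, stop_idx - aligned_codons)
        w = ptc_cds_pos + d  # wild coordinate of the PTC's first base
        a, b = affected_exon_cds_span
        first_start = w + 3  # first position past the PTC-equivalent triplet
        rem = (1 - first_start) % 3
        c0 = first_start + rem  # next codon boundary (codon starts are 1 mod 3)
        if c0 >= a:
            truncated = max(0, (b - c0 + 1) // 3)
        else:
            truncated = max(0, (b - a + 1) // 3)

    detail = []
    if is_frameshift:
        detail.append(f"deletion {d} nt shifts frame by {frame_offset}")
    else:
        detail.append(f"in-frame deletion of {d} nt ({d // 3} residues)")
    if not has_stop:
        detail.append("no stop codon in mutant CDS; peptide reported to CDS end")

    return SpliceConsequence(
        deletion_length_nt=d,
        frame_offset=frame_offset,
        is_frameshift=is_frameshift,
        novel_aa_count=novel_aa,
        ptc_cds_pos=ptc_cds_pos,
        wildtype_exon_aa_lost_after_ptc=truncated,
        nmd_predicted=None,
        rule_detail="; ".join(detail),
        peptide=peptide,
        peptide_mass_kda=peptide_mass(peptide),
        stop_map_per_frame=stop_map(mutant_cds),
        has_stop=has_stop,
    )


def predict_nmd(
    consequence: SpliceConsequence,
    gene_model: GeneModel,
    cryptic_call: CrypticAcceptorCall | None = None,
    threshold_nt: int = 55,
) -> tuple[bool, str]:
    """Classic junction rule: NMD-positive iff the PTC starts >= ``threshold_nt``
    upstream of the last exon-exon junction of the mutant transcript."""
    if consequence.ptc_cds_pos is None:
        consequence.nmd_predicted = False
        consequence.rule_detail += "; no PTC: NMD not applicable"
        return False, "no PTC"
    lengths = [e - s + 1 for s, e in gene_model.exons]
    affected = None
    if cryptic_call is not None and cryptic_call.found:
        affected = cryptic_call.intron_index + 1
        lengths[affected - 1] -= cryptic_call.deletion_length
    if len(lengths) < 2:
        consequence.nmd_predicted = False
        consequence.rule_detail += "; no junction"
        return False, "no junction"
    # transcript coordinate of the PTC start: 5' UTR length + CDS position
    utr5 = gene_model._tx_index(gene_model.cds_start)
    if affected is not None:
        # deletion upstream of the CDS start would shorten the 5' UTR
        dstart = sum(lengths[: affected - 1])
        if utr5 > dstart:
            utr5 = max(dstart, utr5 - (cryptic_call.deletion_length or 0))
    ptc_tx = utr5 + consequence.ptc_cds_pos
    last_junction_tx = sum(lengths[:-1])
    dist = last_junction_tx - ptc_tx
    positive = dist >= threshold_nt
    rule = (
        f"PTC {dist} nt upstream of the last exon-exon junction "
        f"({'>=' if positive else '<'} {threshold_nt} nt rule)"
    )
    consequence.nmd_predicted = positive
    consequence.rule_detail += "; " + rule
    return positive, rule


def splice_consequence_for_variant(
    genome: GenomeSequence,
    gene_model: GeneModel,
    variant: Variant,
    max_scan_nt: int = 100,
    nmd_threshold_nt: int = 55,
    include_upstream_intronic: bool = False,
) -> dict:
    """End-to-end consequence analysis of one acceptor-disrupting variant.

    Returns a dict with the classification, the cryptic acceptor call, the
    SpliceConsequence and both reconstructed CDS strings.
    """
    classification, intron_index = classify_splice_variant(variant, gene_model, genome)
    result = {
        "variant": variant,
        "classification": classification,
        "intron_index": intron_index,
        "cryptic": None,
        "consequence": None,
        "wild_cds": None,
        "mutant_cds": None,
    }
    if classification not in ("acceptor-1", "acceptor-2"):
        return result
    mutant_genome = genome.with_variant(variant)
    site = _acceptor_site(gene_model, intron_index, genome)
    affected_exon = intron_index + 1
    call = scan_cryptic_acceptor(
        mutant_genome, site, max_scan_nt,
        variant_pos=variant.pos,
        exon_length=gene_model.exon_length(affected_exon),
        include_upstream_intronic=include_upstream_intronic,
    )
    result["cryptic"] = call
    if not call.found:
        return result
    _, wild_cds = reconstruct_transcript(gene_model, genome)
    _, mutant_cds = reconstruct_transcript(gene_model, mutant_genome, call)
    span = gene_model.cds_span_of_exon(affected_exon)
    if span is None:
        raise ModelError(f"affected exon {affected_exon} is entirely non-coding")
    consequence = analyze_frame(wild_cds, mutant_cds, span)
    consequence.affected_exon_index = affected_exon
    predict_nmd(consequence, gene_model, call, nmd_threshold_nt)
    result["consequence"] = consequence
    result["wild_cds"] = wild_cds
    result["mutant_cds"] = mutant_cds
    return result
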
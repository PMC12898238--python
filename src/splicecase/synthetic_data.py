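"""Seeded generators producing every pipeline input with planted ground truth.

The splice-case generator builds a multi-exon gene with canonical GT-AG
introns, a polypyrimidine tract and a 20-nt poly-T run upstream of intron
1's acceptor, then plants:

* an acceptor-disrupting SNV (A>G at intron position −2; G>A at −1 for the
  special case of a cryptic AG ending at exon position 1, which is the only
  way such an AG can exist next to a canonical acceptor),
* the first exonic AG of the affected exon at exactly the requested offset,
* downstream codons engineered so the shifted reading frame meets its first
  stop after exactly ``novel_aa`` codons with ``truncation_aa`` whole
  wild-type codons of the exon remaining downstream.

Filler regions use an A-free codon alphabet: every stop codon contains an A,
so A-free sequence can never terminate translation in any reading frame,
which makes stop placement exact by construction.

All generators are deterministic functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomeSequence, Variant

#: codons free of stops in every reading frame (no adenine anywhere)
A_FREE_CODONS = tuple("".join(c) for c in product("CGT", repeat=3))


class GenerationError(ValueError):
    """The requested planted geometry cannot be represented."""


@dataclass
class PlantedSpliceCase:
    genome: GenomeSequence
    gene: GeneModel
    variant: Variant
    truth: dict
    pathogenic_table: pd.DataFrame | None = None


@dataclass
class PlantedEditingCase:
    genome: GenomeSequence
    target: Variant
    truth: dict
    pathogenic_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def _ct_filler(rng, n: int) -> str:
    return "".join(rng.choice(("C", "T"), size=n)) if n > 0 else ""


def _a_free(rng, n: int) -> str:
    return "".join(rng.choice(("C", "G", "T"), size=n)) if n > 0 else ""


def _codons(rng, n: int, first_char_not: str | None = None) -> list[str]:
    pool = list(A_FREE_CODONS)
    out = []
    for i in range(n):
        if i == 0 and first_char_not is not None:
            choices = [c for c in pool if c[0] != first_char_not]
        else:
            choices = pool
        out.append(choices[int(rng.integers(len(choices)))])
    return out


def _build_affected_exon_prefix(rng, d: int, in_frame: bool,
                                novel_aa: int) -> str:
    """First ``d`` exonic bases: no AG before the one ending at position d."""
    if d == 1:
        return "G"
    if d == 2:
        return "AG"
    chars = list(_ct_filler(rng, d - 2))
    if in_frame:
        # guard against a wild-frame TAG across the planted AG (d % 3 == 0)
        chars[d - 3] = "C"
    if novel_aa == 0 and not in_frame:
        # first mutant codon is the stop TAA; anchor the frameshift point
        chars[0] = "C"
    return "".join(chars) + "AG"


def make_splice_case(
    n_exons: int = 3,
    exon_lengths: list[int] | None = None,
    cryptic_offset: int = 16,
    novel_aa: int = 17,
    truncation_aa: int = 26,
    seed: int = 0,
    contig: str = "chrS",
    origin: int = 1,
    strand: str = "+",
    exon2_prefix: str | None = None,
    intron_interior_nt: int = 6,
    flank_nt: int = 30,
) -> PlantedSpliceCase:
    """Build a gene with a planted acceptor-disrupting SNV and known truth.

    ``cryptic_offset`` (= planted deletion length) is the exonic position of
    the second base of the first AG of exon 2.  For frameshifting offsets the
    shifted frame hits TAA after exactly ``novel_aa`` codons and leaves
    ``truncation_aa`` whole wild-type exon-2 codons downstream; in-frame
    offsets force both to zero.
    """
    rng = np.random.default_rng(seed)
    d = int(cryptic_offset)
    if d < 1:
        raise GenerationError("cryptic_offset must be >= 1")
    if n_exons < 3:
        raise GenerationError("need at least 3 exons (terminal stop lives in "
                              "the last exon)")
    in_frame = d % 3 == 0
    if in_frame and (novel_aa != 0 or truncation_aa != 0):
        raise GenerationError(
            f"offset {d} is in-frame: novel_aa and truncation_aa must be 0"
        )

    L1 = exon_lengths[0] if exon_lengths else 60
    if L1 % 3 != 0 or L1 < 6:
        raise GenerationError("exon 1 coding length must be a multiple of 3, >= 6")

    if in_frame:
        L2 = exon_lengths[1] if exon_lengths else d + 36
        if L2 < d + 3:
            raise GenerationError(f"exon 2 too short for a {d}-nt deletion")
    else:
        w = L1 + 3 * novel_aa + 1 + d        # wild coordinate of the PTC image
        c0 = (w + 3) + ((1 - (w + 3)) % 3)   # next codon boundary past it
        L2 = c0 + 3 * truncation_aa - 1 - L1
        if exon_lengths and exon_lengths[1] != L2:
            raise GenerationError(
                f"requested exon 2 length {exon_lengths[1]} incompatible with "
                f"geometry (needs {L2})"
            )

    rest_lengths = (list(exon_lengths[2:]) if exon_lengths
                    else [30] * (n_exons - 2))
    if len(rest_lengths) != n_exons - 2 or any(l < 3 for l in rest_lengths):
        raise GenerationError("bad downstream exon lengths")
    if exon_lengths is None:
        rest_lengths[-1] += (-(L1 + L2 + sum(rest_lengths))) % 3
    total = L1 + L2 + sum(rest_lengths)
    if total % 3 != 0:
        raise GenerationError("total CDS length must be a multiple of 3")

    # --- exon contents -------------------------------------------------------
    exon1 = "ATG" + "".join(_codons(rng, L1 // 3 - 1))

    if exon2_prefix is not None:
        prefix = exon2_prefix.upper()
        if len(prefix) != d or (d >= 2 and prefix[d - 2:] != "AG") \
                or "AG" in prefix[: d - 1]:
            raise GenerationError("exon2_prefix must be d bases ending in its "
                                  "first AG")
    else:
        prefix = _build_affected_exon_prefix(rng, d, in_frame, novel_aa)

    wild60 = prefix[0]  # wild CDS base right after exon 1
    if in_frame:
        suffix = _a_free(rng, L2 - d)
        if L2 > d and suffix[0] == wild60:
            suffix = ("C" if wild60 != "C" else "G") + suffix[1:]
    else:
        novel = _codons(rng, novel_aa, first_char_not=wild60 if novel_aa else None)
        tail_len = L2 - d - 3 * novel_aa - 3
        suffix = "".join(novel) + "TAA" + _a_free(rng, tail_len)
        if novel_aa == 0 and suffix[0] == wild60:  # pragma: no cover - guarded upstream
            raise GenerationError("cannot anchor frameshift point")
    exon2 = prefix + suffix

    rest = [_a_free(rng, l) for l in rest_lengths]
    rest[-1] = rest[-1][:-3] + "TAA"  # terminal stop codon

    # --- introns -------------------------------------------------------------
    def intron_generic() -> str:
        return "GT" + _a_free(rng, intron_interior_nt) + _ct_filler(rng, 8) + "AG"

    intron1 = ("GT" + _ct_filler(rng, max(0, intron_interior_nt - 1)) + "C"
               + "T" * 20 + "C" + "AG")
    introns = [intron1] + [intron_generic() for _ in range(n_exons - 2)]

    flank5 = _a_free(rng, flank_nt)
    flank3 = _a_free(rng, flank_nt)

    exon_seqs = [exon1, exon2] + rest
    pieces, exon_coords, cursor = [flank5], [], flank_nt
    for i, ex in enumerate(exon_seqs):
        exon_coords.append((origin + cursor, origin + cursor + len(ex) - 1))
        pieces.append(ex)
        cursor += len(ex)
        if i < len(introns):
            pieces.append(introns[i])
            cursor += len(introns[i])
    pieces.append(flank3)
    seq = "".join(pieces)

    genome = GenomeSequence(contig, seq, origin)
    gene = GeneModel(
        gene_id="SYNGENE", transcript_id="SYNGENE-T1", contig=contig,
        strand="+", exons=tuple(exon_coords),
        cds_start=exon_coords[0][0], cds_end=exon_coords[-1][1],
    )
    exon2_start = exon_coords[1][0]
    if d == 1:
        variant = Variant(contig, exon2_start - 1, "G", "A")
        distance = d + 1
    else:
        variant = Variant(contig, exon2_start - 2, "A", "G")
        distance = d + 2

    # --- independent string-level self-checks -------------------------------
    alt_seq = (seq[: variant.pos - origin] + variant.alt
               + seq[variant.pos - origin + 1:])
    acc_idx = exon2_start - 2 - origin  # index of intron −2 in alt_seq
    scan = alt_seq[acc_idx: acc_idx + 2 + len(exon2)]
    first_ag = next((i for i in range(1, len(scan) - 1)
                     if scan[i: i + 2] == "AG"), None)
    if first_ag != d:
        raise GenerationError(
            f"planted AG check failed: first AG at {first_ag}, wanted {d}"
        )
    if not in_frame:
        mutant_cds = exon1 + exon2[d:] + "".join(rest)
        stop_i = next(i for i in range(0, len(mutant_cds) - 2, 3)
                      if mutant_cds[i: i + 3] in ("TAA", "TAG", "TGA"))
        got_novel = stop_i // 3 - L1 // 3
        if got_novel != novel_aa:
            raise GenerationError(
                f"planted frame check failed: {got_novel} novel codons, "
                f"wanted {novel_aa}"
            )

    # --- truth ---------------------------------------------------------------
    if in_frame:
        nmd = False
    else:
        mut_lengths = [L1, L2 - d] + rest_lengths
        ptc_tx = L1 + 3 * novel_aa + 1
        last_junction = sum(mut_lengths[:-1])
        nmd = (last_junction - ptc_tx) >= 55
    truth = {
        "cryptic_offset": d,
        "deletion_nt": d,
        "distance_nt": distance,
        "novel_aa": 0 if in_frame else novel_aa,
        "truncation_aa": 0 if in_frame else truncation_aa,
        "nmd": nmd,
    }
    case = PlantedSpliceCase(genome, gene, variant, truth)
    return _flip_case(case) if strand == "-" else case


def _flip_case(case: PlantedSpliceCase) -> PlantedSpliceCase:
    """Mirror a plus-strand case onto the minus strand (same truth)."""
    from .genome_io import complement_base, revcomp

    g = case.genome
    L, org = len(g.seq), g.origin

    def m(p: int) -> int:
        return 2 * org + L - 1 - p

    genome = GenomeSequence(g.contig, revcomp(g.seq), org)
    gene = GeneModel(
        gene_id=case.gene.gene_id, transcript_id=case.gene.transcript_id,
        contig=g.contig, strand="-",
        exons=tuple((m(e), m(s)) for s, e in case.gene.exons),
        cds_start=m(case.gene.cds_start), cds_end=m(case.gene.cds_end),
    )
    v = case.variant
    variant = Variant(g.contig, m(v.pos), complement_base(v.ref),
                      complement_base(v.alt), v.id)
    return PlantedSpliceCase(genome, gene, variant, dict(case.truth),
                             case.pathogenic_table)


def make_editing_case(
    pam_offset: int = 9,
    n_bystanders: int = 1,
    hazardous: bool = True,
    seed: int = 0,
    contig: str = "chrE",
    origin: int = 1,
) -> PlantedEditingCase:
    """A target SNV with exactly one Cas12a base-editing placement.

    The patient slice carries the target alt allele G (desired correction
    G>A), one TTTV motif on the minus strand (``TAAA`` on the displayed plus
    strand) whose nearest base sits ``pam_offset`` nt 3' of the target, and
    ``n_bystanders`` additional editable G bases inside the editing window.
    The background contains no adenine and no CC dinucleotide, so no other
    CBE placement in the shipped catalog can match; one upstream GG provides
    an NGG context so a prime-editing alternative always exists.
    """
    rng = np.random.default_rng(seed)
    if not 8 <= pam_offset <= 14:
        raise GenerationError("pam_offset must lie in the Cas12a window 8..14")
    if not 0 <= n_bystanders <= 6:
        raise GenerationError("0..6 bystanders fit in the 7-nt window")

    n, t_idx = 81, 40
    # background over {C, T} with no CC (prevents minus-strand NGG matches)
    chars = []
    for _ in range(n):
        if chars and chars[-1] == "C":
            chars.append("T")
        else:
            chars.append(str(rng.choice(("C", "T"))))
    chars[t_idx] = "G"
    pam_idx = t_idx + pam_offset
    chars[pam_idx: pam_idx + 4] = list("TAAA")
    # a GG upstream of the window guarantees an NGG prime-editing placement
    # (nick within reach of the target) without adding any base-editor match
    chars[24] = chars[25] = "G"
    window_idx = [t_idx + pam_offset - k for k in range(8, 15)]  # window 8..14
    free = [i for i in window_idx if i != t_idx]
    picks = sorted(rng.choice(free, size=n_bystanders, replace=False).tolist()) \
        if n_bystanders else []
    for i in picks:
        chars[i] = "G"
    seq = "".join(chars)
    if "CC" in seq or seq.count("AAA") != 1:  # construction guards
        raise GenerationError("background constraint violated")

    target = Variant(contig, origin + t_idx, "A", "G")
    bystander_pos = [origin + i for i in picks]

    rows = []
    if n_bystanders:
        sig = "Pathogenic" if hazardous else "Benign"
        rows.append({"contig": contig, "pos": bystander_pos[0], "ref": "G",
                     "alt": "A", "id": "rsSYN0001", "significance": sig})
    table = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "id",
                                        "significance"])

    truth = {
        "n_candidates_per_nuclease": {"Cas12a-CBE": 1, "SpCas9-ABE": 0,
                                      "SpCas9-CBE": 0},
        "pam_distance_nt": pam_offset,
        "bystander_positions": bystander_pos,
        "hazardous": bool(hazardous and n_bystanders > 0),
    }
    return PlantedEditingCase(GenomeSequence(contig, seq, origin), target,
                              truth, table)


def nf1_like_case(seed: int = 7) -> PlantedSpliceCase:
    """Synthetic mirror of the NF1 c.61-2A>G case geometry.

    This is a *synthetic* construct, not real GRCh38 sequence: coordinates
    are planted so the acceptor-disrupting A>G falls at chr17:31,155,981 with
    exon 2's first coding base (c.61) at 31,155,983, a 20-nt poly-T run ends
    at 31,155,979, the first exonic AG sits 16 nt into exon 2, the shifted
    frame meets its stop after 17 codons with 26 wild-type exon-2 codons
    downstream, and a single minus-strand TTTV motif (``TAAA`` on the plus
    strand) places the target at editing-window position 9 with one bystander
    G at 31,155,982 (matching the pathogenic record rs1263745475 in the
    bundled table).
    """
    # exon-2 prefix: positions 1-7 filler, 8-11 the PAM image TAAA,
    # 12-14 filler, 15-16 the cryptic AG
    prefix = "CTTCTCT" + "TAAA" + "CTT" + "AG"
    variant_pos = 31_155_981
    # exon 2 starts after flank(30) + exon1(60) + intron1(31) = index 121
    origin = variant_pos + 2 - 121
    case = make_splice_case(
        n_exons=58, cryptic_offset=16, novel_aa=17, truncation_aa=26,
        seed=seed, contig="chr17", origin=origin, exon2_prefix=prefix,
    )
    assert case.variant.pos == variant_pos
    case.pathogenic_table = pd.DataFrame([{
        "contig": "chr17", "pos": 31_155_982, "ref": "G", "alt": "A",
        "id": "rs1263745475", "significance": "Pathogenic",
    }])
    return case


def make_expression_cohort(
    n: int = 609,
    mean: float = 4.43,
    sd: float = 1.97,
    patient_value: float = 2.94,
    seed: int = 0,
    gene: str = "NF1",
) -> pd.DataFrame:
    """Gene x sample TPM matrix: n Gaussian controls plus a 'patient' column."""
    if n < 2 or sd <= 0:
        raise GenerationError("need n >= 2 controls and sd > 0")
    rng = np.random.default_rng(seed)
    vals = rng.normal(mean, sd, size=n)
    while (vals < 0).any():  # TPM is non-negative; redraw the tail
        bad = vals < 0
        vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    cols = [f"control_{i + 1:04d}" for i in range(n)] + ["patient"]
    data = np.concatenate([vals, [patient_value]])
    return pd.DataFrame([data], index=[gene], columns=cols)


def make_ct_table(
    fold_change: float | dict = 0.5,
    sigma: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
    target_gene: str = "NF1",
    reference_gene: str = "GAPDH",
    calibrator: str = "calibrator",
) -> pd.DataFrame:
    """Tidy qPCR Ct table with a planted relative expression per sample.

    ``fold_change`` is either one value (sample named 'case') or a mapping
    sample -> planted 2^-ddCt relative expression.  Gaussian noise with
    standard deviation ``sigma`` is added independently to every replicate.
    """
    if isinstance(fold_change, (int, float)):
        fold_change = {"case": float(fold_change)}
    if any(f <= 0 for f in fold_change.values()):
        raise GenerationError("fold changes must be positive")
    if replicates < 1:
        raise GenerationError("need at least one replicate")
    rng = np.random.default_rng(seed)
    base_ref, base_target = 20.0, 26.0
    rows = []
    plan = {calibrator: 1.0, **fold_change}
    for sample, fold in plan.items():
        for gene, ct0 in ((reference_gene, base_ref),
                          (target_gene, base_target - np.log2(fold))):
            for r in range(1, replicates + 1):
                rows.append({"sample": sample, "gene": gene, "replicate": r,
                             "ct": ct0 + (rng.normal(0, sigma) if sigma else 0.0)})
    return pd.DataFrame(rows)


def make_methylation_calls(
    n_reads: int = 12,
    n_methylated: int = 10,
    seed: int = 0,
    contig: str = "chr17",
    pos: int = 31_155_980,
) -> pd.DataFrame:
    """Per-read binary 5mC calls at one site, order shuffled by seed."""
    if not 0 <= n_methylated <= n_reads or n_reads < 1:
        raise GenerationError("need 0 <= n_methylated <= n_reads, n_reads >= 1")
    rng = np.random.default_rng(seed)
    flags = np.array([1] * n_methylated + [0] * (n_reads - n_methylated))
    rng.shuffle(flags)
    return pd.DataFrame({
        "read_id": [f"read_{i + 1:04d}" for i in range(n_reads)],
        "contig": contig,
        "pos": pos,
        "methylated": flags,
    })
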
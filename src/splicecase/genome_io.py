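"""Sequences, gene models, variants and coordinate mapping.

All external coordinates are 1-based and inclusive (VCF/GFF3 convention).
A :class:`GenomeSequence` carries an ``origin`` so that a short slice of a
chromosome (e.g. 1 kb around a variant of interest) behaves exactly like the
whole chromosome for every downstream operation.

HGVS ``c.`` coordinates carry transcript-strand bases; :class:`Variant`
always stores bases on the genomic plus strand.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file does not conform to the expected format."""


class ModelError(ValueError):
    """A gene model violates its structural invariants."""


class CoordinateError(ValueError):
    """A coordinate walk left the valid range (CDS, intron or slice)."""


_VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the alphabet {A, C, G, T, N}."""
    s = seq.upper()
    if set(s) - _VALID_BASES:
        bad = sorted(set(s) - _VALID_BASES)
        raise FormatError(f"cannot reverse-complement characters {bad}")
    return s.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    if base not in _VALID_BASES:
        raise FormatError(f"not a DNA base: {base!r}")
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class GenomeSequence:
    """A named, possibly offset, uppercase DNA sequence.

    ``origin`` is the 1-based genomic coordinate of the first base of
    ``seq``, so genomic position *p* maps to ``seq[p - origin]``.
    """

    contig: str
    seq: str
    origin: int = 1

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) < 1:
            raise FormatError(f"empty sequence for contig {self.contig!r}")
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"contig {self.contig!r} contains non-IUPAC characters {sorted(bad)}"
            )
        if self.origin < 1:
            raise FormatError("origin must be >= 1")

    @property
    def end(self) -> int:
        """Genomic coordinate of the last base."""
        return self.origin + len(self.seq) - 1

    def contains(self, pos: int) -> bool:
        return self.origin <= pos <= self.end

    def base(self, pos: int) -> str:
        if not self.contains(pos):
            raise CoordinateError(
                f"position {self.contig}:{pos} outside slice "
                f"[{self.origin}, {self.end}]"
            )
        return self.seq[pos - self.origin]

    def fetch(self, start: int, end: int) -> str:
        """Sequence of the closed genomic interval [start, end]."""
        if start > end:
            raise CoordinateError(f"inverted interval [{start}, {end}]")
        if not (self.contains(start) and self.contains(end)):
            raise CoordinateError(
                f"interval {self.contig}:{start}-{end} outside slice "
                f"[{self.origin}, {self.end}]"
            )
        return self.seq[start - self.origin : end - self.origin + 1]

    def with_variant(self, variant: "Variant") -> "GenomeSequence":
        """Return a copy with the variant's alt allele substituted."""
        if variant.contig != self.contig:
            raise CoordinateError(
                f"variant contig {variant.contig!r} != sequence contig {self.contig!r}"
            )
        ref_here = self.base(variant.pos)
        if ref_here != variant.ref:
            raise CoordinateError(
                f"reference mismatch at {self.contig}:{variant.pos}: "
                f"sequence has {ref_here}, variant says {variant.ref}"
            )
        i = variant.pos - self.origin
        return GenomeSequence(
            self.contig, self.seq[:i] + variant.alt + self.seq[i + 1 :], self.origin
        )


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant on the genomic plus strand."""

    contig: str
    pos: int
    ref: str
    alt: str
    id: str | None = None
    annotations: dict[str, str] | None = None

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise FormatError("only SNVs are supported (ref and alt must be one base)")
        if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
            raise FormatError(f"invalid alleles {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise FormatError("ref and alt must differ")

    def reversed(self) -> "Variant":
        """The correction that undoes this variant (alt -> ref)."""
        return Variant(self.contig, self.pos, self.alt, self.ref, self.id)


@dataclass(frozen=True)
class HgvsC:
    """Parsed ``c.`` coordinate of an SNV, e.g. c.61-2A>G."""

    cds_pos: int
    intron_offset: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.cds_pos < 1:
            raise FormatError("cds_pos must be >= 1")

    def __str__(self) -> str:
        off = ""
        if self.intron_offset > 0:
            off = f"+{self.intron_offset}"
        elif self.intron_offset < 0:
            off = str(self.intron_offset)
        return f"c.{self.cds_pos}{off}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware exon/CDS structure of one transcript.

    ``exons`` are 1-based closed genomic intervals in *transcript* order
    (ascending genomic start on '+', descending on '-').  ``cds_start`` and
    ``cds_end`` are the genomic positions of the first and last coding base
    in transcript orientation.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        if self.strand not in "+-":
            raise ModelError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ModelError("gene model needs at least one exon")
        for s, e in self.exons:
            if s > e:
                raise ModelError(f"inverted exon [{s}, {e}]")
        starts = [s for s, _ in self.exons]
        if self.strand == "+":
            if starts != sorted(starts):
                raise ModelError("'+' strand exons must ascend in transcript order")
        else:
            if starts != sorted(starts, reverse=True):
                raise ModelError("'-' strand exons must descend in transcript order")
        prev = None
        for s, e in sorted(self.exons):
            if prev is not None:
                gap = s - prev - 1
                if gap < 0:
                    raise ModelError("exons overlap")
                if gap < 4:
                    raise ModelError(f"intron shorter than 4 bases (length {gap})")
            prev = e
        for name, pos in (("cds_start", self.cds_start), ("cds_end", self.cds_end)):
            if not any(s <= pos <= e for s, e in self.exons):
                raise ModelError(f"{name} {pos} falls outside every exon")
        first, last = self._cds_tx_index(self.cds_start), self._cds_tx_index(self.cds_end)
        if first > last:
            raise ModelError("cds_start lies downstream of cds_end in transcript order")

    # -- transcript geometry ------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_length(self, exon_index: int) -> int:
        s, e = self.exons[exon_index - 1]
        return e - s + 1

    def introns(self) -> list[tuple[int, int]]:
        """Genomic (low, high) intervals, transcript order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return out

    def span(self) -> tuple[int, int]:
        lows = min(s for s, _ in self.exons)
        highs = max(e for _, e in self.exons)
        return lows, highs

    def exon_containing(self, pos: int) -> int | None:
        """1-based exon index containing a genomic position, else None."""
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= pos <= e:
                return i
        return None

    def _tx_index(self, pos: int) -> int:
        """0-based position along the spliced transcript."""
        acc = 0
        for s, e in self.exons:
            if s <= pos <= e:
                if self.strand == "+":
                    return acc + (pos - s)
                return acc + (e - pos)
            acc += e - s + 1
        raise CoordinateError(f"position {pos} is not exonic")

    def _cds_tx_index(self, pos: int) -> int:
        return self._tx_index(pos)

    def cds_length(self) -> int:
        return self._tx_index(self.cds_end) - self._tx_index(self.cds_start) + 1

    def cds_pos_to_genomic(self, cds_pos: int) -> int:
        """Map a 1-based CDS coordinate to a genomic position."""
        if not 1 <= cds_pos <= self.cds_length():
            raise CoordinateError(
                f"c.{cds_pos} beyond CDS length {self.cds_length()}"
            )
        target = self._tx_index(self.cds_start) + cds_pos - 1
        acc = 0
        for s, e in self.exons:
            n = e - s + 1
            if target < acc + n:
                off = target - acc
                return s + off if self.strand == "+" else e - off
            acc += n
        raise CoordinateError("unreachable: CDS position not mapped")  # pragma: no cover

    def cds_span_of_exon(self, exon_index: int) -> tuple[int, int] | None:
        """1-based CDS coordinates covered by one exon, or None if non-coding."""
        s, e = self.exons[exon_index - 1]
        lo, hi = self._tx_index(self.cds_start), self._tx_index(self.cds_end)
        if self.strand == "+":
            ex_lo, ex_hi = self._tx_index(s), self._tx_index(e)
        else:
            ex_lo, ex_hi = self._tx_index(e), self._tx_index(s)
        a, b = max(lo, ex_lo), min(hi, ex_hi)
        if a > b:
            return None
        return a - lo + 1, b - lo + 1

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "transcript_id": self.transcript_id,
            "contig": self.contig,
            "strand": self.strand,
            "exons": [list(e) for e in self.exons],
            "cds_start": self.cds_start,
            "cds_end": self.cds_end,
        }


# -- FASTA ------------------------------------------------------------------


def read_fasta(path: str) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into GenomeSequence slices.

    An ``origin=N`` tag in the header description sets the genomic offset of
    the record, so desk-scale slices round-trip through FASTA.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    # locate offending line numbers before handing to the parser
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">") or not line.strip():
            continue
        bad = set(line.strip().upper()) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: non-IUPAC characters {sorted(bad)} on line {lineno}"
            )
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        origin = 1
        m = re.search(r"origin=(\d+)", rec.description)
        if m:
            origin = int(m.group(1))
        records.append(GenomeSequence(rec.id, str(rec.seq).upper(), origin))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[GenomeSequence], path: str) -> None:
    seqrecs = []
    for g in records:
        desc = f"origin={g.origin}" if g.origin != 1 else ""
        seqrecs.append(SeqRecord(Seq(g.seq), id=g.contig, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


# -- gene models ------------------------------------------------------------


def read_gene_model(path: str, transcript_id: str | None = None) -> GeneModel:
    """Read a gene model from JSON or a GFF3 subset (gene/mRNA/exon/CDS)."""
    with open(path) as fh:
        head = fh.read(1)
    if head == "{":
        with open(path) as fh:
            return gene_model_from_dict(json.load(fh))
    return _gene_model_from_gff3(path, transcript_id)


def gene_model_from_dict(d: dict) -> GeneModel:
    try:
        return GeneModel(
            gene_id=d["gene_id"],
            transcript_id=d["transcript_id"],
            contig=d["contig"],
            strand=d["strand"],
            exons=tuple(tuple(e) for e in d["exons"]),
            cds_start=int(d["cds_start"]),
            cds_end=int(d["cds_end"]),
        )
    except KeyError as exc:
        raise FormatError(f"gene-model JSON missing key {exc}") from exc


def write_gene_model(model: GeneModel, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
        fh.write("\n")


def _gene_model_from_gff3(path: str, transcript_id: str | None) -> GeneModel:
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    mrnas = list(db.features_of_type("mRNA"))
    if not mrnas:
        raise FormatError(f"{path}: no mRNA feature found")
    if transcript_id is not None:
        mrnas = [m for m in mrnas if m.id == transcript_id]
        if not mrnas:
            raise FormatError(f"{path}: transcript {transcript_id!r} not found")
    elif len(mrnas) > 1:
        raise FormatError(
            f"{path}: multiple mRNAs present; pass transcript_id to choose one"
        )
    mrna = mrnas[0]
    exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
    cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
    if not exons or not cds:
        raise FormatError(f"{path}: mRNA {mrna.id} lacks exon or CDS features")
    strand = mrna.strand
    exons.sort(reverse=(strand == "-"))
    if strand == "+":
        cds_start = min(s for s, _ in cds)
        cds_end = max(e for _, e in cds)
    else:
        cds_start = max(e for _, e in cds)
        cds_end = min(s for s, _ in cds)
    parents = list(db.parents(mrna, featuretype="gene"))
    gene_id = parents[0].id if parents else mrna.id
    return GeneModel(gene_id, mrna.id, mrna.seqid, strand, tuple(exons),
                     cds_start, cds_end)


# -- variants ---------------------------------------------------------------

_HGVS_RE = re.compile(r"^c\.(\d+)(?:([+-])(\d+))?([ACGT])>([ACGT])$")


def parse_hgvs_c(text: str, gene_model: GeneModel) -> tuple[HgvsC, Variant]:
    """Map an HGVS ``c.`` SNV string to a genomic plus-strand Variant.

    The CDS is walked across exons in transcript orientation; an intronic
    offset then steps into the adjacent intron.  ``c.X+k`` requires X to be
    the last coding base of its exon, ``c.X-k`` the first, matching HGVS
    semantics.  On '-' strand models the emitted Variant carries
    reverse-complemented alleles on the genomic plus strand.
    """
    m = _HGVS_RE.match(text.strip())
    if not m:
        raise FormatError(
            f"unsupported HGVS string {text!r} (SNV grammar c.<int>[+|-<int>]<ref>><alt>)"
        )
    cds_pos = int(m.group(1))
    offset = 0
    if m.group(2):
        offset = int(m.group(3)) * (1 if m.group(2) == "+" else -1)
    ref_t, alt_t = m.group(4), m.group(5)
    hgvs = HgvsC(cds_pos, offset, ref_t, alt_t)

    g = gene_model.cds_pos_to_genomic(cds_pos)
    if offset != 0:
        exon_idx = gene_model.exon_containing(g)
        s, e = gene_model.exons[exon_idx - 1]
        tx_first, tx_last = (s, e) if gene_model.strand == "+" else (e, s)
        if offset > 0 and g != tx_last:
            raise CoordinateError(
                f"{text}: '+' offset requires the last coding base of an exon"
            )
        if offset < 0 and g != tx_first:
            raise CoordinateError(
                f"{text}: '-' offset requires the first coding base of an exon"
            )
        step = 1 if gene_model.strand == "+" else -1
        gpos = g + step * offset
        # the computed position must fall inside the adjacent intron
        intron_idx = exon_idx if offset > 0 else exon_idx - 1
        introns = gene_model.introns()
        if not 1 <= intron_idx <= len(introns):
            raise CoordinateError(f"{text}: no intron on that side of the exon")
        lo, hi = introns[intron_idx - 1]
        if not lo <= gpos <= hi:
            raise CoordinateError(f"{text}: offset walks past intron bounds")
    else:
        gpos = g

    if gene_model.strand == "+":
        ref, alt = ref_t, alt_t
    else:
        ref, alt = complement_base(ref_t), complement_base(alt_t)
    return hgvs, Variant(gene_model.contig, gpos, ref, alt)


_VARIANT_STR_RE = re.compile(r"^([\w.]+):([\d,]+)\s*([ACGT])>([ACGT])$")


def parse_variant_string(text: str) -> Variant:
    """Parse ``chr17:31155981A>G`` (commas in the position are ignored)."""
    m = _VARIANT_STR_RE.match(text.strip())
    if not m:
        raise FormatError(f"cannot parse variant string {text!r}")
    return Variant(m.group(1), int(m.group(2).replace(",", "")),
                   m.group(3), m.group(4))


def read_vcf(path: str) -> list[Variant]:
    """Read SNVs from a (possibly minimal) VCF v4.2 text file."""
    out = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if len(rec.ref) != 1 or len(alt) != 1:
                    raise FormatError(
                        f"{path}: only SNVs are supported "
                        f"({rec.chrom}:{rec.pos} {rec.ref}>{alt})"
                    )
                vid = rec.id if rec.id not in (None, ".") else None
                out.append(Variant(rec.chrom, rec.pos, rec.ref, alt, vid))
    if not out:
        raise FormatError(f"{path}: no variants found")
    return out


def write_vcf(variants: list[Variant], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        contigs = sorted({v.contig for v in variants})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(
                f"{v.contig}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\n"
            )
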
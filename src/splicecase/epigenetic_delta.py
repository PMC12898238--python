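"""CpG creation/destruction by an SNV, per-read methylation summaries and
homopolymer runs.

CpG dinucleotides are strand-symmetric (a plus-strand 5'-CG-3' is also a
minus-strand 5'-CG-3'), so plus-strand detection suffices.  An SNV can only
change the two dinucleotides overlapping the mutated base, so only those two
are inspected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .genome_io import CoordinateError, GenomeSequence, Variant


@dataclass(frozen=True)
class CpGDelta:
    """Plus-strand CpG sites created or destroyed by one substitution.

    Positions are the genomic coordinates of the C of each CpG.
    """

    created: tuple[int, ...]
    destroyed: tuple[int, ...]
    variant: Variant


@dataclass(frozen=True)
class MethylationSummary:
    site_pos: int
    n_reads: int
    n_methylated: int

    @property
    def fraction(self) -> float:
        return self.n_methylated / self.n_reads


@dataclass(frozen=True)
class HomopolymerRun:
    base: str
    start_pos: int
    length: int


def cpg_delta(genome: GenomeSequence, variant: Variant) -> CpGDelta:
    """CpG dinucleotides gained or lost when ``variant`` is applied."""
    pos = variant.pos
    if not (genome.contains(pos - 1) and genome.contains(pos + 1)):
        raise CoordinateError(
            f"variant at {genome.contig}:{pos} lacks a 1-base flank inside the slice"
        )
    if genome.base(pos) != variant.ref:
        raise CoordinateError(
            f"reference mismatch at {genome.contig}:{pos}: "
            f"sequence has {genome.base(pos)}, variant says {variant.ref}"
        )
    before = {
        pos - 1: genome.base(pos - 1) + variant.ref,
        pos: variant.ref + genome.base(pos + 1),
    }
    after = {
        pos - 1: genome.base(pos - 1) + variant.alt,
        pos: variant.alt + genome.base(pos + 1),
    }
    created = tuple(p for p in sorted(before) if after[p] == "CG" and before[p] != "CG")
    destroyed = tuple(p for p in sorted(before) if before[p] == "CG" and after[p] != "CG")
    return CpGDelta(created, destroyed, variant)


def read_methylation_calls(path: str) -> pd.DataFrame:
    """Read a per-read call table (TSV: read_id, contig, pos, methylated)."""
    df = pd.read_csv(path, sep="\t")
    required = {"read_id", "contig", "pos", "methylated"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: calls table missing columns {sorted(missing)}")
    return df


def methylation_fraction(calls: pd.DataFrame, site_pos: int,
                         contig: str | None = None) -> MethylationSummary:
    """Aggregate binary per-read methylation calls at one genomic site."""
    sub = calls[calls["pos"] == site_pos]
    if contig is not None and "contig" in calls.columns:
        sub = sub[sub["contig"] == contig]
    if len(sub) == 0:
        raise ValueError(f"no methylation calls at position {site_pos}")
    if sub["read_id"].duplicated().any():
        dup = sub.loc[sub["read_id"].duplicated(), "read_id"].iloc[0]
        raise ValueError(f"duplicate call for read {dup!r} at position {site_pos}")
    if not set(sub["methylated"].unique()) <= {0, 1}:
        raise ValueError("methylated column must be binary 0/1")
    return MethylationSummary(
        site_pos=site_pos,
        n_reads=int(len(sub)),
        n_methylated=int(sub["methylated"].sum()),
    )


def homopolymer_runs(genome: GenomeSequence, min_length: int) -> list[HomopolymerRun]:
    """All maximal single-base runs of length >= ``min_length``.

    Runs of N are not reported.  Coordinates are genomic via ``origin``.
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    out = []
    for m in re.finditer(r"(A+|C+|G+|T+)", genome.seq):
        if m.end() - m.start() >= min_length:
            out.append(HomopolymerRun(
                base=m.group()[0],
                start_pos=genome.origin + m.start(),
                length=m.end() - m.start(),
            ))
    return out


def intersect_tf_sites(created_positions: list[int], bed_path: str,
                       contig: str) -> list[dict]:
    """Intersect created-CpG positions with a user-supplied BED of TF sites.

    BED intervals are 0-based half-open; positions are 1-based genomic.
    """
    hits = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            if chrom != contig:
                continue
            for pos in created_positions:
                if start < pos <= end:
                    hits.append({"pos": pos, "tf_site": name,
                                 "interval": [start + 1, end]})
    return hits
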
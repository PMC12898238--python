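"""Base-editing and prime-editing feasibility around a target SNV.

Given a patient genome slice carrying a pathogenic SNV, the desired
therapeutic edit is the *reversal* of that variant (alt back to ref).  Base
editors can only perform it when (a) a PAM/TAM places the target inside the
editor's activity window and (b) the editor's chemistry matches the required
substitution on the protospacer strand (CBE: C->T, ABE: A->G).  Every other
same-chemistry base inside the window is a bystander edit; bystanders that
match a pathogenic-variant table make the strategy hazardous, in which case
prime editing (which installs an exact templated edit) is ranked first.

Window positions are inclusive protospacer positions counted from the
PAM-proximal end of the protospacer.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import re
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .genome_io import GenomeSequence, Variant, complement_base, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: chemistry -> (editable base, product base) on the protospacer strand
CHEMISTRY = {"CBE": ("C", "T"), "ABE": ("A", "G")}


class CatalogError(ValueError):
    """A nuclease catalog entry violates the schema."""


@dataclass(frozen=True)
class NucleaseSpec:
    name: str
    motif: str
    motif_side: str          # '5prime_of_protospacer' | '3prime_of_protospacer'
    spacer_length: int
    window: tuple[int, int]  # inclusive, from the PAM-proximal end
    chemistry: str           # 'CBE' | 'ABE'

    def __post_init__(self):
        object.__setattr__(self, "window", tuple(self.window))
        if any(c not in IUPAC for c in self.motif.upper()) or not self.motif:
            raise CatalogError(f"{self.name}: motif {self.motif!r} is not IUPAC")
        object.__setattr__(self, "motif", self.motif.upper())
        if self.motif_side not in ("5prime_of_protospacer", "3prime_of_protospacer"):
            raise CatalogError(f"{self.name}: bad motif_side {self.motif_side!r}")
        w_start, w_end = self.window
        if not (1 <= w_start <= w_end <= self.spacer_length):
            raise CatalogError(
                f"{self.name}: window {list(self.window)} outside "
                f"1..{self.spacer_length} or inverted"
            )
        if self.chemistry not in CHEMISTRY:
            raise CatalogError(f"{self.name}: chemistry must be CBE or ABE")

    def to_dict(self) -> dict:
        return {
            "name": self.name, "motif": self.motif,
            "motif_side": self.motif_side, "spacer_length": self.spacer_length,
            "window": list(self.window), "chemistry": self.chemistry,
        }


@dataclass(frozen=True)
class BystanderEdit:
    pos: int
    substitution: str        # 'X>Y' on the genomic plus strand
    classification: str = "unannotated"
    matched_id: str | None = None


@dataclass
class EditingCandidate:
    nuclease: str
    strand: str              # protospacer strand
    pam_start: int           # lowest genomic coordinate of the motif match
    pam_plus_strand: str     # motif as it reads on the displayed plus strand
    protospacer_span: tuple[int, int]
    target_in_window: bool
    target_window_position: int | None
    target_distance_to_pam: int
    window_span: tuple[int, int] = (0, 0)
    chemistry: str = ""
    bystanders: list[BystanderEdit] = field(default_factory=list)


@dataclass(frozen=True)
class PrimeEditCandidate:
    spacer: str
    pam_pos: int             # lowest genomic coordinate of the NGG triplet
    strand: str
    nick_to_edit_nt: int     # bases strictly between the nick and the target
    pbs_length: int
    rtt_length: int


# -- catalog ------------------------------------------------------------------


def load_nuclease_catalog(path: str | None = None) -> list[NucleaseSpec]:
    """Load a JSON/YAML nuclease catalog; None loads the shipped defaults."""
    if path is None:
        text = (
            importlib.resources.files("splicecase.data")
            .joinpath("nucleases.json")
            .read_text()
        )
        data = json.loads(text)
    else:
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text)
    entries = data["nucleases"] if isinstance(data, dict) else data
    specs = []
    for e in entries:
        try:
            specs.append(NucleaseSpec(
                name=e["name"], motif=e["motif"], motif_side=e["motif_side"],
                spacer_length=int(e["spacer_length"]),
                window=tuple(e["window"]), chemistry=e["chemistry"],
            ))
        except (KeyError, TypeError) as exc:
            raise CatalogError(f"malformed catalog entry {e!r}: {exc}") from exc
    if not specs:
        raise CatalogError("catalog is empty")
    return specs


def write_nuclease_catalog(specs: list[NucleaseSpec], path: str) -> None:
    payload = {"nucleases": [s.to_dict() for s in specs]}
    with open(path, "w") as fh:
        if path.endswith((".yaml", ".yml")):
            yaml.safe_dump(payload, fh, sort_keys=False)
        else:
            json.dump(payload, fh, indent=1)
            fh.write("\n")


def catalog_hash(specs: list[NucleaseSpec]) -> str:
    """Stable sha256 over the catalog content, recorded in every scan report."""
    blob = json.dumps([s.to_dict() for s in specs], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# -- motif scanning -----------------------------------------------------------


def _motif_regex(motif: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[c]}]" for c in motif))


def iter_motif_matches(seq: str, motif: str):
    """Yield 0-based start indices of IUPAC motif matches (overlapping)."""
    pat = _motif_regex(motif)
    i = 0
    while True:
        m = pat.search(seq, i)
        if m is None:
            return
        yield m.start()
        i = m.start() + 1


def _protospacer_coords(spec: NucleaseSpec, strand: str,
                        motif_lo: int, motif_hi: int) -> list[int]:
    """Genomic plus-strand coordinates of protospacer positions 1..spacer,
    position 1 being the PAM-proximal end."""
    n = spec.spacer_length
    if spec.motif_side == "5prime_of_protospacer":
        # protospacer immediately 3' of the PAM on the protospacer strand
        if strand == "+":
            return [motif_hi + k for k in range(1, n + 1)]
        return [motif_lo - k for k in range(1, n + 1)]
    # PAM 3' of protospacer: protospacer ends just before the PAM;
    # position 1 (PAM-proximal) is the base adjacent to the PAM.
    if strand == "+":
        return [motif_lo - k for k in range(1, n + 1)]
    return [motif_hi + k for k in range(1, n + 1)]


def scan_editor_sites(
    genome: GenomeSequence,
    target_variant: Variant,
    catalog: list[NucleaseSpec],
    flank_nt: int = 20,
) -> list[EditingCandidate]:
    """All base-editor placements that could revert ``target_variant``.

    The genome slice is the patient sequence (it carries the alt allele; if
    it still carries ref, the variant is applied first).  Motifs are matched
    on both strands within +/- ``flank_nt`` of the target; a candidate is
    kept when the required correction (alt -> ref) matches the editor
    chemistry on the protospacer strand and the target sits inside the
    editing window.
    """
    t = target_variant.pos
    if genome.base(t) == target_variant.ref:
        genome = genome.with_variant(target_variant)
    elif genome.base(t) != target_variant.alt:
        raise ValueError(
            f"genome base {genome.base(t)} at {t} matches neither ref nor alt"
        )
    lo = max(genome.origin, t - flank_nt)
    hi = min(genome.end, t + flank_nt)
    region = genome.fetch(lo, hi)

    candidates = []
    for spec in catalog:
        src, _ = CHEMISTRY[spec.chemistry]
        for strand in "+-":
            # required substitution on the protospacer strand
            if strand == "+":
                need_from, need_to = target_variant.alt, target_variant.ref
            else:
                need_from = complement_base(target_variant.alt)
                need_to = complement_base(target_variant.ref)
            if (need_from, need_to) != CHEMISTRY[spec.chemistry]:
                continue
            search_seq = region if strand == "+" else revcomp(region)
            for start in iter_motif_matches(search_seq, spec.motif):
                L = len(spec.motif)
                if strand == "+":
                    motif_lo = lo + start
                else:
                    motif_lo = hi - start - (L - 1)
                motif_hi = motif_lo + L - 1
                coords = _protospacer_coords(spec, strand, motif_lo, motif_hi)
                if min(coords) < genome.origin or max(coords) > genome.end:
                    continue
                w_lo, w_hi = spec.window
                window_coords = coords[w_lo - 1 : w_hi]
                if t not in window_coords:
                    continue
                win_pos = coords.index(t) + 1
                pam_plus = genome.fetch(motif_lo, motif_hi)
                cand = EditingCandidate(
                    nuclease=spec.name,
                    strand=strand,
                    pam_start=motif_lo,
                    pam_plus_strand=pam_plus,
                    protospacer_span=(min(coords), max(coords)),
                    target_in_window=True,
                    target_window_position=win_pos,
                    target_distance_to_pam=min(abs(t - motif_lo), abs(t - motif_hi)),
                    window_span=(min(window_coords), max(window_coords)),
                    chemistry=spec.chemistry,
                )
                cand.bystanders = enumerate_bystanders(cand, genome, target_variant)
                candidates.append(cand)
    candidates.sort(key=lambda c: (c.nuclease, c.pam_start, c.strand))
    return candidates


def enumerate_bystanders(
    candidate: EditingCandidate,
    genome: GenomeSequence,
    target_variant: Variant,
) -> list[BystanderEdit]:
    """Every same-chemistry editable base in the window except the target."""
    if not candidate.target_in_window:
        raise ValueError("bystander enumeration requires the target in-window")
    src, dst = CHEMISTRY[candidate.chemistry]
    out = []
    for pos in range(candidate.window_span[0], candidate.window_span[1] + 1):
        if pos == target_variant.pos:
            continue
        plus_base = genome.base(pos)
        proto_base = plus_base if candidate.strand == "+" else complement_base(plus_base)
        if proto_base == src:
            if candidate.strand == "+":
                sub = f"{plus_base}>{dst}"
            else:
                sub = f"{plus_base}>{complement_base(dst)}"
            out.append(BystanderEdit(pos=pos, substitution=sub))
    return out


# -- pathogenic-variant classification ---------------------------------------


def read_pathogenic_table(path: str) -> pd.DataFrame:
    """TSV with columns contig, pos, ref, alt, id, significance."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "id": str,
                                            "significance": str})
    required = ["contig", "pos", "ref", "alt", "id", "significance"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: pathogenic table missing columns {sorted(missing)}")
    for i, row in df.iterrows():
        if pd.isna(row["pos"]) or str(row["ref"]) not in "ACGT" \
                or str(row["alt"]) not in "ACGT":
            raise ValueError(f"{path}: malformed pathogenic table row {i + 2}")
    return df


def classify_bystanders(
    bystanders: list[BystanderEdit],
    pathogenic_table: pd.DataFrame | None,
    contig: str,
) -> tuple[list[BystanderEdit], str]:
    """Annotate bystanders against the table; hazardous iff any pathogenic."""
    annotated = []
    hazardous = False
    for b in bystanders:
        classification, matched = "unannotated", None
        if pathogenic_table is not None:
            ref, alt = b.substitution.split(">")
            hit = pathogenic_table[
                (pathogenic_table["contig"] == contig)
                & (pathogenic_table["pos"] == b.pos)
                & (pathogenic_table["ref"] == ref)
                & (pathogenic_table["alt"] == alt)
            ]
            if len(hit):
                sig = str(hit.iloc[0]["significance"]).lower()
                matched = str(hit.iloc[0]["id"])
                if "pathogenic" in sig:
                    classification = "pathogenic"
                    hazardous = True
                elif "benign" in sig:
                    classification = "annotated_benign"
        annotated.append(BystanderEdit(b.pos, b.substitution, classification, matched))
    return annotated, ("hazardous" if hazardous else "clean")


# -- prime editing ------------------------------------------------------------


def design_prime_edit(
    genome: GenomeSequence,
    target_variant: Variant,
    max_nick_to_edit: int = 30,
    pbs_length: int = 13,
    rtt_3prime_homology: int = 10,
) -> list[PrimeEditCandidate]:
    """Simplified nCas9 (NGG) pegRNA placements able to revert the target.

    The nick falls between protospacer positions 17 and 18 (three bases 5' of
    the PAM); the target must lie 3' of the nick on the nicked strand within
    ``max_nick_to_edit`` bases.  The RT template covers the nick-to-edit gap,
    the edited base and a fixed 3' homology arm.  Sorted by nick distance.
    """
    t = target_variant.pos
    if genome.base(t) == target_variant.ref:
        genome = genome.with_variant(target_variant)
    out = []
    seq, org = genome.seq, genome.origin
    # plus-strand protospacer: spacer [s, s+19], PAM [s+20, s+22], nick after s+16
    for i in range(len(seq) - 2):
        p = org + i  # candidate PAM start (plus strand): needs GG at p+1, p+2
        if seq[i + 1] == "G" and seq[i + 2] == "G":
            s = p - 20
            if s >= org:
                nick_to_edit = t - (s + 17)
                if 0 <= nick_to_edit <= max_nick_to_edit:
                    out.append(PrimeEditCandidate(
                        spacer=genome.fetch(s, s + 19),
                        pam_pos=p, strand="+",
                        nick_to_edit_nt=nick_to_edit,
                        pbs_length=pbs_length,
                        rtt_length=nick_to_edit + 1 + rtt_3prime_homology,
                    ))
        # minus-strand PAM: CCN on plus at [p, p+2]; protospacer [p+3, p+22]
        if seq[i] == "C" and seq[i + 1] == "C":
            if p + 22 <= genome.end:
                nick_to_edit = (p + 5) - t
                if 0 <= nick_to_edit <= max_nick_to_edit:
                    out.append(PrimeEditCandidate(
                        spacer=revcomp(genome.fetch(p + 3, p + 22)),
                        pam_pos=p, strand="-",
                        nick_to_edit_nt=nick_to_edit,
                        pbs_length=pbs_length,
                        rtt_length=nick_to_edit + 1 + rtt_3prime_homology,
                    ))
    out.sort(key=lambda c: (c.nick_to_edit_nt, c.pam_pos, c.strand))
    return out


# -- strategy ranking ---------------------------------------------------------


def rank_strategies(
    base_candidates: list[tuple[EditingCandidate, str]],
    prime_candidates: list[PrimeEditCandidate],
) -> dict:
    """Order strategies: clean base editing, then prime, then hazardous base.

    ``base_candidates`` pairs each candidate with its bystander verdict.
    """
    strategies = []
    clean = [c for c, v in base_candidates if v == "clean"]
    hazardous = [c for c, v in base_candidates if v == "hazardous"]
    for c in sorted(clean, key=lambda c: c.target_distance_to_pam):
        strategies.append({
            "type": "base_editing", "nuclease": c.nuclease,
            "pam_start": c.pam_start, "strand": c.strand,
            "reason": "no pathogenic bystander edits in the editing window",
        })
    for c in prime_candidates:
        strategies.append({
            "type": "prime_editing", "nuclease": "nCas9-PE",
            "pam_start": c.pam_pos, "strand": c.strand,
            "reason": f"templated exact correction, nick {c.nick_to_edit_nt} nt from edit",
        })
    for c in sorted(hazardous, key=lambda c: c.target_distance_to_pam):
        strategies.append({
            "type": "base_editing", "nuclease": c.nuclease,
            "pam_start": c.pam_start, "strand": c.strand,
            "reason": "demoted: editing window contains a pathogenic bystander edit",
        })
    if not strategies:
        return {"strategies": [], "summary": "no in-silico strategy"}
    return {"strategies": strategies, "summary": strategies[0]["type"] + " first"}
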
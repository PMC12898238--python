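"""Consolidated case report: the four-step workflow in one call.

``run_case`` executes, in order: (1) variant identification/validation,
(2) primary splicing effect (cryptic acceptor), (3) secondary consequences
(frame, PTC, NMD, peptide, CpG, methylation), (4) editing-tool selection
(base-editor scan with bystander hazards, prime-editing candidates,
ranking).  Optional inputs enable optional blocks; a missing optional input
marks its block ``skipped`` with a reason; a stage failure marks its block
``failed`` and downstream independent stages still run.

Re-running with identical inputs yields byte-identical reports: provenance
records content digests, never timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.metadata
import importlib.resources
import json

import yaml

from . import epigenetic_delta, expression_stats
from .editing_feasibility import (
    catalog_hash,
    classify_bystanders,
    design_prime_edit,
    load_nuclease_catalog,
    rank_strategies,
    read_pathogenic_table,
    scan_editor_sites,
)
from .genome_io import (
    parse_hgvs_c,
    parse_variant_string,
    read_fasta,
    read_gene_model,
    read_vcf,
)
from .splice_engine import splice_consequence_for_variant


class ConfigurationError(ValueError):
    """A mandatory input is missing or unreadable."""


class SchemaError(ValueError):
    """The report does not satisfy the shipped JSON schema."""


def _tool_version() -> str:
    try:
        return importlib.metadata.version("splicecase")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return obj


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg


def run_case(config: dict) -> dict:
    """Run the full workflow described by a config mapping.

    Mandatory keys: ``fasta``, ``gene_model`` and one of ``variant`` (string
    or VCF path via ``vcf``) or ``hgvs``.  Optional keys enable blocks:
    ``methylation_calls`` + ``methylation_site``, ``nuclease_catalog``,
    ``pathogenic_table``, ``tpm_matrix`` + ``expression_gene`` +
    ``patient_column``, ``ct_table`` + ``ddct_target`` + ``ddct_reference``
    + ``ddct_calibrator``, ``max_scan_nt``, ``flank_nt``, ``transcript_id``.
    """
    for key in ("fasta", "gene_model"):
        if key not in config:
            raise ConfigurationError(f"missing mandatory config key {key!r}")
    if not any(k in config for k in ("variant", "hgvs", "vcf")):
        raise ConfigurationError("config needs 'variant', 'hgvs' or 'vcf'")

    digests = {}
    for key in ("fasta", "gene_model", "vcf", "methylation_calls",
                "nuclease_catalog", "pathogenic_table", "tpm_matrix",
                "ct_table"):
        if key in config and isinstance(config[key], str):
            digests[key] = _digest(config[key])

    genomes = read_fasta(config["fasta"])
    gene_model = read_gene_model(config["gene_model"],
                                 config.get("transcript_id"))
    genome = next((g for g in genomes if g.contig == gene_model.contig),
                  genomes[0])

    if "hgvs" in config:
        _, variant = parse_hgvs_c(config["hgvs"], gene_model)
    elif "variant" in config:
        variant = parse_variant_string(config["variant"])
    else:
        variant = read_vcf(config["vcf"])[0]

    catalog = load_nuclease_catalog(config.get("nuclease_catalog"))
    report = {
        "tool": "splicecase",
        "variant": {"contig": variant.contig, "pos": variant.pos,
                    "ref": variant.ref, "alt": variant.alt, "id": variant.id},
        "provenance": {
            "tool_version": _tool_version(),
            "catalog_hash": catalog_hash(catalog),
            "input_digests": digests,
            "seeds": config.get("seeds", {}),
        },
    }

    # (2)-(3) primary splicing effect and secondary consequences ------------
    try:
        res = splice_consequence_for_variant(
            genome, gene_model, variant,
            max_scan_nt=int(config.get("max_scan_nt", 100)),
            nmd_threshold_nt=int(config.get("nmd_threshold_nt", 55)),
        )
        block = {"status": "ok", "classification": res["classification"],
                 "intron_index": res["intron_index"]}
        if res["cryptic"] is not None:
            c = res["cryptic"]
            block["cryptic"] = {
                "found": c.found, "deletion_nt": c.deletion_length,
                "distance_nt": c.distance_from_variant,
            }
        if res["consequence"] is not None:
            q = res["consequence"]
            block.update({
                "frameshift": {"novel_aa": q.novel_aa_count,
                               "ptc_cds_pos": q.ptc_cds_pos,
                               "frame_offset": q.frame_offset},
                "truncation_aa": q.wildtype_exon_aa_lost_after_ptc,
                "nmd": {"predicted": q.nmd_predicted, "rule": q.rule_detail},
                "peptide": q.peptide,
                "peptide_mass_kda": round(q.peptide_mass_kda, 2),
                "stop_map_per_frame": {str(k): v for k, v in
                                       q.stop_map_per_frame.items()},
            })
        report["splice_consequence"] = block
    except Exception as exc:  # noqa: BLE001 - stage isolation by design
        report["splice_consequence"] = {"status": "failed", "reason": str(exc)}

    # CpG delta --------------------------------------------------------------
    try:
        delta = epigenetic_delta.cpg_delta(genome, variant)
        report["cpg_delta"] = {
            "status": "ok",
            "created": list(delta.created),
            "destroyed": list(delta.destroyed),
        }
    except Exception as exc:  # noqa: BLE001
        report["cpg_delta"] = {"status": "failed", "reason": str(exc)}

    # methylation (optional) --------------------------------------------------
    if "methylation_calls" in config and "methylation_site" in config:
        try:
            calls = epigenetic_delta.read_methylation_calls(
                config["methylation_calls"])
            summ = epigenetic_delta.methylation_fraction(
                calls, int(config["methylation_site"]), variant.contig)
            report["methylation"] = {
                "status": "ok", "site_pos": summ.site_pos,
                "n_reads": summ.n_reads, "n_methylated": summ.n_methylated,
                "fraction": round(summ.fraction, 4),
            }
        except Exception as exc:  # noqa: BLE001
            report["methylation"] = {"status": "failed", "reason": str(exc)}
    else:
        report["methylation"] = {"status": "skipped",
                                 "reason": "no methylation calls supplied"}

    # (4) editing ------------------------------------------------------------
    try:
        table = None
        if "pathogenic_table" in config:
            table = read_pathogenic_table(config["pathogenic_table"])
        candidates = scan_editor_sites(genome, variant, catalog,
                                       int(config.get("flank_nt", 20)))
        base_block, pairs = [], []
        for cand in candidates:
            annotated, verdict = classify_bystanders(
                cand.bystanders, table, variant.contig)
            cand.bystanders = annotated
            pairs.append((cand, verdict))
            base_block.append({
                "nuclease": cand.nuclease, "strand": cand.strand,
                "pam_start": cand.pam_start,
                "pam_plus_strand": cand.pam_plus_strand,
                "target_window_position": cand.target_window_position,
                "target_distance_to_pam": cand.target_distance_to_pam,
                "bystanders": [_asdict(b) for b in annotated],
                "verdict": verdict,
            })
        primes = design_prime_edit(
            genome, variant,
            max_nick_to_edit=int(config.get("max_nick_to_edit", 30)))
        ranking = rank_strategies(pairs, primes)
        report["editing"] = {
            "status": "ok",
            "base_candidates": base_block,
            "prime_candidates": [_asdict(p) for p in primes],
            "ranking": ranking,
        }
    except Exception as exc:  # noqa: BLE001
        report["editing"] = {"status": "failed", "reason": str(exc)}

    # expression (optional) ---------------------------------------------------
    expr: dict = {}
    if "tpm_matrix" in config:
        try:
            import pandas as pd

            tpm = pd.read_csv(config["tpm_matrix"], sep="\t", index_col=0)
            gene = config.get("expression_gene", tpm.index[0])
            patient_col = config["patient_column"]
            controls = tpm.loc[gene].drop(patient_col)
            stat = expression_stats.expression_zscore(
                float(tpm.loc[gene, patient_col]), controls.to_numpy())
            expr["zscore"] = _asdict(stat)
        except Exception as exc:  # noqa: BLE001
            expr["zscore"] = {"status": "failed", "reason": str(exc)}
    if "ct_table" in config:
        try:
            import pandas as pd

            ct = pd.read_csv(config["ct_table"], sep="\t")
            res = expression_stats.ddct(
                ct, config["ddct_target"], config["ddct_reference"],
                config["ddct_calibrator"])
            expr["ddct"] = {s: _asdict(r) for s, r in res.items()}
        except Exception as exc:  # noqa: BLE001
            expr["ddct"] = {"status": "failed", "reason": str(exc)}
    if expr:
        expr["status"] = "ok"
        report["expression"] = expr
    else:
        report["expression"] = {"status": "skipped",
                                "reason": "no expression tables supplied"}

    validate_report(report)
    return report


def report_json(report: dict) -> str:
    """Canonical serialization (sorted keys) for byte-stable reruns."""
    return json.dumps(report, indent=1, sort_keys=True) + "\n"


# -- minimal structural schema validation -------------------------------------

_JSON_TYPES = {
    "object": dict, "array": list, "string": str, "integer": int,
    "number": (int, float), "boolean": bool,
}


def load_schema() -> dict:
    text = (importlib.resources.files("splicecase.data")
            .joinpath("report.schema.json").read_text())
    return json.loads(text)


def validate_report(report: dict, schema: dict | None = None,
                    path: str = "$") -> None:
    """Check type/required/properties constraints of the shipped schema."""
    if schema is None:
        schema = load_schema()
    expected = schema.get("type")
    if expected and not isinstance(report, _JSON_TYPES[expected]):
        raise SchemaError(f"{path}: expected {expected}")
    if expected == "object":
        for key in schema.get("required", []):
            if key not in report:
                raise SchemaError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{path}.{key}")
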
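"""End-to-end orchestration: configuration, staging, reports.

A pipeline run derives splice sites (from GFF3 gene models or by exact
spliced mapping of CDSs onto genomic sequence, or from a simulated
family), projects them onto a protein alignment, classifies shared /
absent / shifted sites, optionally scores signature windows and catalytic
conservation, and writes TSV reports plus a machine-readable JSON summary.
Reruns with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from splicemark.alignment_projection import (
    ProteinAlignment,
    classify_site_groups,
    project_sites,
    render_site_table,
)
from splicemark.family_simulator import (
    SimulationConfig,
    evaluate_recovery,
    simulate_family,
    write_family,
)
from splicemark.gene_structures import (
    CodingSpliceSite,
    GeneModel,
    derive_coding_splice_sites,
    map_cds_to_genome,
    parse_gff3,
    translate_cds,
)
from splicemark.signature_analysis import (
    catalytic_residue_check,
    parse_prosite_pattern,
    score_signature_window,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for an inconsistent or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


SITE_COLUMNS = ["gene_id", "protein_index", "residue", "frame", "coding_offset", "label"]


def sites_to_frame(sites: dict[str, list[CodingSpliceSite]]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": gene_id,
            "protein_index": s.protein_index,
            "residue": s.residue,
            "frame": s.frame,
            "coding_offset": s.coding_offset,
            "label": s.label,
        }
        for gene_id, site_list in sites.items()
        for s in site_list
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def frame_to_sites(frame: pd.DataFrame) -> dict[str, list[CodingSpliceSite]]:
    sites: dict[str, list[CodingSpliceSite]] = {}
    for row in frame.itertuples(index=False):
        sites.setdefault(row.gene_id, []).append(
            CodingSpliceSite(
                int(row.protein_index),
                int(row.frame),
                int(row.coding_offset),
                str(row.residue),
            )
        )
    return sites


def read_sites_tsv(path: str | Path) -> dict[str, list[CodingSpliceSite]]:
    return frame_to_sites(pd.read_csv(path, sep="\t"))


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (usually loaded from YAML)."""

    out_dir: str = "splicemark_out"
    seed: int = 0
    simulate: dict | None = None  # SimulationConfig keyword arguments
    gff: str | None = None
    genome_fasta: str | None = None
    cds_fasta: str | None = None
    min_intron: int = 20
    alignment: str | None = None  # aligned FASTA; identity alignment if absent
    project: bool = True
    reference_protein: str | None = None
    shift_window: int = 1
    signatures: list[dict] = field(default_factory=list)
    # each: {pattern, accession, anchor_protein, anchor_index}
    catalytic: dict | None = None  # {ref_id, ref_protein_index, expected}
    colocation: list[list[str]] = field(default_factory=list)  # id pairs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        sources = [self.simulate is not None, self.gff is not None,
                   self.cds_fasta is not None]
        if sum(sources) != 1:
            raise ConfigError(
                "exactly one site source required: 'simulate', 'gff', or "
                "'cds_fasta'"
            )
        if self.gff is not None and self.genome_fasta is None:
            raise ConfigError("'gff' input requires 'genome_fasta'")
        if self.cds_fasta is not None and self.genome_fasta is None:
            raise ConfigError("'cds_fasta' input requires 'genome_fasta'")
        for key in ("gff", "genome_fasta", "cds_fasta", "alignment"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{key}: file not found: {value}")
        if self.project and self.simulate is None and self.alignment is None:
            raise ConfigError(
                "projection requires an 'alignment' (simulated runs use the "
                "identity alignment)"
            )
        for sig in self.signatures:
            for want in ("pattern", "anchor_protein", "anchor_index"):
                if want not in sig:
                    raise ConfigError(f"signature entry missing '{want}'")
        if self.catalytic is not None:
            for want in ("ref_id", "ref_protein_index", "expected"):
                if want not in self.catalytic:
                    raise ConfigError(f"catalytic entry missing '{want}'")

    def content_hash(self) -> str:
        # the output directory does not affect the analysis
        payload = json.dumps(
            {
                k: getattr(self, k)
                for k in self.__dataclass_fields__
                if k != "out_dir"
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def colocation_check(
    models: list[GeneModel], id_a: str, id_b: str
) -> dict:
    """Genomic co-location of two gene models.

    Returns ``same_sequence`` (both models on one seq_id) and, when they
    are, the base-pair gap between the nearest interval ends (0 when the
    models overlap); the distance is undefined (None) across sequences.
    """
    by_id = {m.gene_id: m for m in models}
    for gene_id in (id_a, id_b):
        if gene_id not in by_id:
            raise KeyError(f"unknown gene id: {gene_id}")
    a, b = by_id[id_a], by_id[id_b]
    if a.seq_id != b.seq_id:
        return {"same_sequence": False, "distance": None}
    a_start = min(iv.start for iv in a.intervals)
    a_end = max(iv.end for iv in a.intervals)
    b_start = min(iv.start for iv in b.intervals)
    b_end = max(iv.end for iv in b.intervals)
    if a_end < b_start:
        distance = b_start - a_end - 1
    elif b_end < a_start:
        distance = a_start - b_end - 1
    else:
        distance = 0
    return {"same_sequence": True, "distance": distance}


def _stage(name):
    """Decorator tagging exceptions with the failing stage."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(name, exc) from exc

        return inner

    return wrap


@_stage("sites")
def _collect_sites(config: PipelineConfig, outdir: Path):
    """Produce (models, proteins, sites, family) from the configured source."""
    family = None
    if config.simulate is not None:
        sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
        family = simulate_family(sim)
        write_family(family, outdir / "simulated")
        models = family.models
        proteins = dict(family.proteins)
    elif config.gff is not None:
        genomes = read_fasta(config.genome_fasta)
        parsed = parse_gff3(Path(config.gff).read_text())
        models, proteins = {}, {}
        for model in parsed:
            if model.seq_id not in genomes:
                raise KeyError(
                    f"{model.gene_id}: sequence {model.seq_id} not in FASTA"
                )
            model.source_seq = genomes[model.seq_id]
            model.validate()
            models[model.gene_id] = model
            proteins[model.gene_id] = translate_cds(model.coding_sequence())
    else:
        genomes = read_fasta(config.genome_fasta)
        cds_records = read_fasta(config.cds_fasta)
        models, proteins = {}, {}
        for name, cds in cds_records.items():
            genome_id = name if name in genomes else next(iter(genomes))
            models[name] = map_cds_to_genome(
                cds, genomes[genome_id], min_intron=config.min_intron,
                seq_id=genome_id, gene_id=name,
            )
            proteins[name] = translate_cds(cds)
    sites = {
        gene_id: derive_coding_splice_sites(model, proteins[gene_id])
        for gene_id, model in models.items()
    }
    return models, proteins, sites, family


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns a report bundle dictionary.

    The bundle maps report names to paths, plus a ``summary`` dict that is
    also written as JSON (with the configuration hash, per-stage outputs,
    and recovery metrics when the run is simulated).
    """
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("splicemark")
    root.addHandler(handler)
    summary: dict = {"config_hash": config.content_hash(), "seed": config.seed}
    bundle: dict = {"log": log_path}
    try:
        models, proteins, sites, family = _collect_sites(config, outdir)
        sites_frame = sites_to_frame(sites)
        sites_path = outdir / "sites.tsv"
        sites_frame.to_csv(sites_path, sep="\t", index=False)
        bundle["sites"] = sites_path
        summary["n_genes"] = len(models)
        summary["n_sites"] = int(len(sites_frame))

        alignment = None
        if config.project:
            try:
                if config.alignment is not None:
                    alignment = ProteinAlignment.from_fasta(config.alignment)
                else:
                    alignment = ProteinAlignment.identity(proteins)
                calls = project_sites(alignment, sites)
                groups = classify_site_groups(
                    calls,
                    alignment,
                    reference_protein=config.reference_protein,
                    shift_window=config.shift_window,
                )
                table = render_site_table(
                    groups, list(alignment.rows), shared_only=False
                )
                shared_path = outdir / "shared_sites.tsv"
                table.to_csv(shared_path, sep="\t")
                bundle["shared_sites"] = shared_path
                summary["n_groups"] = len(groups)
                summary["n_shared_groups"] = sum(g.shared for g in groups)
                if family is not None:
                    metrics = evaluate_recovery(family, groups)
                    summary["recovery"] = {
                        "precision": metrics.precision,
                        "recall": metrics.recall,
                        "f1": metrics.f1,
                    }
                    logger.info("recovery F1 = %.3f", metrics.f1)
            except StageError:
                raise
            except Exception as exc:
                raise StageError("projection", exc) from exc

        if config.signatures:
            if alignment is None:
                raise StageError(
                    "signatures", ConfigError("signature scoring needs projection")
                )
            try:
                rows = []
                for sig in config.signatures:
                    pattern = parse_prosite_pattern(
                        sig["pattern"], sig.get("accession", "pattern")
                    )
                    scores = score_signature_window(
                        pattern, alignment,
                        (sig["anchor_protein"], int(sig["anchor_index"])),
                    )
                    for score in scores:
                        rows.append(
                            {
                                "accession": pattern.accession,
                                "protein_id": score.protein_id,
                                "window_start_column": score.window_start_column,
                                "matches": score.matches,
                                "out_of": score.out_of,
                                "per_position": "".join(
                                    "1" if f else "0" for f in score.per_position
                                ),
                            }
                        )
                sig_path = outdir / "signatures.tsv"
                pd.DataFrame(rows).to_csv(sig_path, sep="\t", index=False)
                bundle["signatures"] = sig_path
            except StageError:
                raise
            except Exception as exc:
                raise StageError("signatures", exc) from exc

        if config.catalytic is not None:
            if alignment is None:
                raise StageError(
                    "catalytic", ConfigError("catalytic check needs an alignment")
                )
            try:
                results = catalytic_residue_check(
                    alignment,
                    config.catalytic["ref_id"],
                    int(config.catalytic["ref_protein_index"]),
                    config.catalytic["expected"],
                )
                cat_path = outdir / "catalytic.tsv"
                pd.DataFrame(
                    [
                        {
                            "protein_id": r.protein_id,
                            "residue": r.label,
                            "is_expected": r.is_expected,
                            "status": r.status,
                        }
                        for r in results
                    ]
                ).to_csv(cat_path, sep="\t", index=False)
                bundle["catalytic"] = cat_path
                summary["n_expected_catalytic"] = sum(
                    r.is_expected for r in results
                )
            except StageError:
                raise
            except Exception as exc:
                raise StageError("catalytic", exc) from exc

        if config.colocation:
            try:
                model_list = list(models.values())
                summary["colocation"] = [
                    {"pair": [a, b], **colocation_check(model_list, a, b)}
                    for a, b in config.colocation
                ]
            except Exception as exc:
                raise StageError("colocation", exc) from exc

        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        bundle["summary_path"] = summary_path
        bundle["summary"] = summary
        return bundle
    finally:
        root.removeHandler(handler)
        handler.close()
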
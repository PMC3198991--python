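"""End-to-end orchestration: classify -> tree -> monophyly -> HGT screen.

The pipeline mirrors the analysis shape that delineates a rhodopsin class:
call every protein's functional class from anchored residues, build a
bootstrapped distance tree, ask whether the candidate set (by default, all
XENORHODOPSIN calls) forms a clade, and screen the encoding genes of a host
genome for compositional atypicality.  Stages degrade gracefully: a missing
genome simply omits the HGT section.
"""

from __future__ import annotations

import hashlib
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .align import ScoringScheme, reference_anchored_alignment
from .composition import flag_atypical, gene_reports, reports_to_frame
from .fingerprint import (
    FingerprintConfig,
    RhodopsinClass,
    batch_classify,
    default_config,
    load_reference,
)
from .phylo import bootstrap_supports, is_monophyletic
from .seqio import (
    AlignedSet,
    GeneAnnotation,
    GenomeRecord,
    ProteinRecord,
    extract_gene,
    read_aligned_fasta,
    read_bed,
    read_fasta,
)


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    proteins: str | None = None  # FASTA path
    alignment: str | None = None  # aligned FASTA path (optional)
    genome: str | None = None  # nucleotide FASTA path (optional)
    genes_bed: str | None = None  # BED path (required with genome)
    fingerprint_yaml: str | None = None
    tree_model: str = "poisson_corrected"
    bootstrap_reps: int = 100
    seed: int = 42
    hgt_z_cutoff: float = 2.0
    imm_k_max: int = 5
    candidate_clade: list[str] | str = "auto"  # "auto" = all XENORHODOPSIN calls

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "proteins": self.proteins,
            "alignment": self.alignment,
            "genome": self.genome,
            "genes_bed": self.genes_bed,
            "fingerprint_yaml": self.fingerprint_yaml,
            "tree_model": self.tree_model,
            "bootstrap_reps": self.bootstrap_reps,
            "seed": self.seed,
            "hgt_z_cutoff": self.hgt_z_cutoff,
            "imm_k_max": self.imm_k_max,
            "candidate_clade": self.candidate_clade,
        }


@dataclass
class RunReport:
    """Consolidated result of one pipeline run."""

    calls: pd.DataFrame
    tree_newick: str | None
    monophyly: dict[str, Any]
    hgt: pd.DataFrame | None
    provenance: dict[str, Any]
    stages: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        body = {
            "provenance": self.provenance,
            "stages": self.stages,
            "calls": self.calls.to_dict(orient="records"),
            "tree_newick": self.tree_newick,
            "monophyly": self.monophyly,
            "hgt": None if self.hgt is None else self.hgt.to_dict(orient="records"),
        }
        return json.dumps(body, indent=2, default=str)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def analyze(
    records: list[ProteinRecord],
    cfg: PipelineConfig,
    alignment: AlignedSet | None = None,
    genome: GenomeRecord | None = None,
    genes: list[GeneAnnotation] | None = None,
    fingerprint_cfg: FingerprintConfig | None = None,
) -> RunReport:
    """Run the pipeline on in-memory inputs (the core of :func:`run_pipeline`)."""
    if not records:
        raise ValueError("no input proteins")
    fp_cfg = fingerprint_cfg or (
        FingerprintConfig.from_yaml(cfg.fingerprint_yaml)
        if cfg.fingerprint_yaml
        else default_config()
    )
    reference = load_reference()
    scheme = ScoringScheme()
    stages: dict[str, str] = {}

    # 1. classification
    calls = batch_classify(records, fp_cfg, reference, scheme)
    stages["classify"] = f"{len(calls)} proteins, " + ", ".join(
        f"{lab}={n}" for lab, n in calls["label"].value_counts().items()
    )

    # 2. tree
    tree = None
    tree_newick = None
    usable_ids = set(
        calls.loc[~calls.get("low_confidence", False).fillna(True), "id"]
        if "low_confidence" in calls
        else calls["id"]
    )
    tree_records = [r for r in records if r.id in usable_ids]
    if alignment is None and len(tree_records) >= 4:
        alignment = reference_anchored_alignment(
            tree_records, reference, fp_cfg.numbering_offset, scheme
        )
    if alignment is not None and len(alignment.records) >= 4:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = bootstrap_supports(
                alignment,
                n_reps=cfg.bootstrap_reps,
                seed=cfg.seed,
                model=cfg.tree_model,  # type: ignore[arg-type]
            )
        buf = io.StringIO()
        t = tree.copy()
        for node in t.non_tips():
            if getattr(node, "support", None) is not None:
                node.name = format(node.support, "g")
        t.write(buf, format="newick")
        tree_newick = buf.getvalue().strip()
        stages["tree"] = (
            f"NJ/{cfg.tree_model}, {len(alignment.records)} taxa, "
            f"{alignment.n_columns} columns, {cfg.bootstrap_reps} bootstrap reps"
        )
    else:
        stages["tree"] = "skipped (fewer than 4 usable sequences)"

    # 3. monophyly of the candidate clade
    if cfg.candidate_clade == "auto":
        candidate = set(
            calls.loc[calls["label"] == RhodopsinClass.XENORHODOPSIN.value, "id"]
        )
    else:
        candidate = set(cfg.candidate_clade)
    monophyly: dict[str, Any] = {"candidate": sorted(candidate)}
    if tree is None:
        monophyly["verdict"] = "not applicable (no tree)"
    elif not candidate:
        monophyly["verdict"] = "not applicable (candidate clade empty)"
    else:
        tips = {t.name for t in tree.tips()}
        present = candidate & tips
        if not present or not present < tips:
            monophyly["verdict"] = "not applicable (candidate not a proper subset)"
        else:
            mono, support = is_monophyletic(tree, present)
            monophyly["verdict"] = "monophyletic" if mono else "not monophyletic"
            monophyly["support"] = support
    stages["monophyly"] = monophyly["verdict"]

    # 4. HGT screen
    hgt = None
    if genome is not None and genes:
        cds = {g.gene_id: extract_gene(genome, g) for g in genes}
        cds = {gid: s for gid, s in cds.items() if len(s) % 3 == 0}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports = gene_reports(genome, cds, k_max=cfg.imm_k_max)
            reports = flag_atypical(reports, z_cutoff=cfg.hgt_z_cutoff)
        hgt = reports_to_frame(reports)
        stages["hgt"] = (
            f"{len(hgt)} genes screened, {int(hgt['atypical'].sum())} atypical"
        )
    else:
        stages["hgt"] = "skipped (no genome/annotations)"

    provenance = {
        "xenoscan_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
    }
    return RunReport(
        calls=calls,
        tree_newick=tree_newick,
        monophyly=monophyly,
        hgt=hgt,
        provenance=provenance,
        stages=stages,
    )


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> RunReport:
    """Load the configured inputs, run every stage, optionally write outputs.

    Outputs under ``out_dir``: calls.tsv, tree.nwk, monophyly.txt,
    hgt_report.tsv, report.json.
    """
    if not cfg.proteins:
        raise ValueError("config must name a protein FASTA")
    records = read_fasta(cfg.proteins, "protein")
    alignment = read_aligned_fasta(cfg.alignment) if cfg.alignment else None
    genome = genes = None
    if cfg.genome:
        genome = read_fasta(cfg.genome, "nucleotide")[0]
        if not cfg.genes_bed:
            raise ValueError("a genome requires a genes BED file")
        genes = read_bed(cfg.genes_bed, genome)
    report = analyze(records, cfg, alignment=alignment, genome=genome, genes=genes)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.calls.to_csv(out / "calls.tsv", sep="\t", index=False)
        if report.tree_newick:
            (out / "tree.nwk").write_text(report.tree_newick + "\n")
        (out / "monophyly.txt").write_text(
            "\n".join(f"{k}: {v}" for k, v in report.monophyly.items()) + "\n"
        )
        if report.hgt is not None:
            report.hgt.to_csv(out / "hgt_report.tsv", sep="\t", index=False)
        (out / "report.json").write_text(report.to_json())
    return report
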
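"""End-to-end orchestration: VCFs in, burden tables and manifest out.

``run_pipeline`` reads the two cohort VCFs once, then for each variant
class builds qualifying genotype stores, runs the per-gene burden test
and (when panels are supplied) the gene-set test, and writes TSV
reports plus a JSON run manifest recording the config snapshot, input
digests and the count of variants surviving each filter stage.  Given
identical inputs and config the TSVs are byte identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .collapse import CohortGenotypes
from .config import PipelineConfig
from .geneset import read_panels_dir, run_geneset_burden
from .stats import burden_frame, run_gene_burden
from .variants import CohortVariants, build_cohort_genotypes, classify_consequence, is_rare, read_cohort

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Audit record for one pipeline run."""

    version: str
    timestamp: str
    config: dict
    inputs: dict = field(default_factory=dict)        # path -> sha256
    stage_counts: dict = field(default_factory=dict)  # cohort -> {stage: count}
    outputs: list = field(default_factory=list)
    failed_stage: str | None = None

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_counts(cohort: CohortVariants, cfg: PipelineConfig) -> dict:
    rare = [v for v in cohort.variants if is_rare(v, cfg.filters)]
    by_class: dict[str, int] = {}
    for v in rare:
        by_class[classify_consequence(v, cfg.filters)] = by_class.get(classify_consequence(v, cfg.filters), 0) + 1
    return {
        "records_read": len(cohort.variants),
        "rare": len(rare),
        "qualifying_missense": by_class.get("missense", 0),
        "qualifying_lof": by_class.get("lof", 0),
    }


def run_pipeline(
    case_vcf: str | Path,
    control_vcf: str | Path,
    out_dir: str | Path,
    panels_dir: str | Path | None = None,
    cfg: PipelineConfig | None = None,
) -> RunManifest:
    """Run filtering, collapsing, burden and gene-set tests end to end.

    Writes ``burden_<class>.tsv`` per variant class, ``geneset_<class>.tsv``
    when panels are present, and ``manifest.json``.
    """
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        config=cfg.to_dict(),
    )
    try:
        manifest.failed_stage = "ingest"
        case_path, control_path = Path(case_vcf), Path(control_vcf)
        manifest.inputs = {str(case_path): _sha256(case_path), str(control_path): _sha256(control_path)}
        case_cohort = read_cohort(case_path, cfg.annotations)
        control_cohort = read_cohort(control_path, cfg.annotations)
        manifest.stage_counts = {
            "case": _stage_counts(case_cohort, cfg),
            "control": _stage_counts(control_cohort, cfg),
        }

        panels = []
        if panels_dir is not None:
            panels = read_panels_dir(panels_dir)
            if not panels:
                log.warning("no panels found in %s; gene-level results only", panels_dir)

        for vclass in cfg.variant_classes:
            manifest.failed_stage = f"burden:{vclass}"
            cases: CohortGenotypes = build_cohort_genotypes(case_cohort, cfg.filters, vclass, "case")
            controls = build_cohort_genotypes(control_cohort, cfg.filters, vclass, "control")
            rows = run_gene_burden(
                cases, controls, vclass, min_variants=cfg.min_variants, alternative=cfg.alternative
            )
            df = burden_frame(rows)
            gene_path = out / f"burden_{vclass}.tsv"
            df.to_csv(gene_path, sep="\t", index=False)
            manifest.outputs.append(str(gene_path))
            manifest.stage_counts[f"genes_tested_{vclass}"] = int(df["tested"].sum())
            manifest.stage_counts[f"genes_reported_{vclass}"] = int(len(df))

            if panels:
                manifest.failed_stage = f"geneset:{vclass}"
                gs = run_geneset_burden(
                    cases,
                    controls,
                    panels,
                    model=cfg.geneset_model,
                    alternative=cfg.alternative,
                    adjust=cfg.geneset_adjust,
                )
                gs_path = out / f"geneset_{vclass}.tsv"
                gs.to_csv(gs_path, sep="\t", index=False)
                manifest.outputs.append(str(gs_path))

        manifest.failed_stage = None
    finally:
        manifest.write(out / "manifest.json")
    return manifest
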
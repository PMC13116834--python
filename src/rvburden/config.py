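"""Single-file YAML configuration for the whole pipeline.

All analysis thresholds live here with the study defaults: population
AF cutoff 0.05, site quality > 20, genotype depth > 10, at least 3
qualifying variant sites per cohort for a gene to be tested.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .variants import AnnotationSpec, FilterConfig


@dataclass
class PipelineConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    annotations: AnnotationSpec = field(default_factory=AnnotationSpec)
    min_variants: int = 3
    #: Fisher alternative for all burden tests: 'greater' (case
    #: enrichment, the collapsing-framework convention) or 'two-sided'.
    alternative: str = "greater"
    variant_classes: tuple[str, ...] = ("missense", "lof")
    geneset_model: str = "dominant"
    geneset_adjust: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filters"]["missense_terms"] = sorted(self.filters.missense_terms)
        d["filters"]["lof_terms"] = sorted(self.filters.lof_terms)
        d["variant_classes"] = list(self.variant_classes)
        return d


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a pipeline config from YAML; ``None`` gives the defaults.

    Recognised keys: ``max_pop_af``, ``min_site_quality``, ``min_depth``,
    ``missense_terms``, ``lof_terms``, ``gene_key``, ``consequence_key``,
    ``af_key``, ``min_variants``, ``alternative``, ``variant_classes``,
    ``geneset_model``, ``geneset_adjust``.
    """
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    fc_kwargs = {}
    for k in ("max_pop_af", "min_site_quality", "min_depth"):
        if k in raw:
            fc_kwargs[k] = raw.pop(k)
    for k in ("missense_terms", "lof_terms"):
        if k in raw:
            fc_kwargs[k] = frozenset(raw.pop(k))
    spec_kwargs = {k: raw.pop(k) for k in ("gene_key", "consequence_key", "af_key") if k in raw}
    pc_kwargs = {}
    for k in ("min_variants", "alternative", "geneset_model", "geneset_adjust"):
        if k in raw:
            pc_kwargs[k] = raw.pop(k)
    if "variant_classes" in raw:
        pc_kwargs["variant_classes"] = tuple(raw.pop("variant_classes"))
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return PipelineConfig(
        filters=FilterConfig(**fc_kwargs),
        annotations=AnnotationSpec(**spec_kwargs),
        **pc_kwargs,
    )
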
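"""Reading annotated cohort VCFs and selecting qualifying variants.

A *qualifying variant* is a variant that survives three filters:

* rarity — population allele frequency below a cutoff (default 5%);
* per-genotype quality control — site quality above 20 and genotype
  depth above 10, with uncalled genotypes never qualifying;
* consequence class — missense, or loss-of-function (frameshift,
  stop-gain, canonical splice donor/acceptor).

Filtering is applied per genotype: a variant can qualify in one sample
and fail depth in another.  A failing genotype contributes dosage 0 to
downstream collapsing; the site itself is not discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .collapse import CohortGenotypes, GeneMatrix

log = logging.getLogger(__name__)

MISSENSE = "missense"
LOF = "lof"
OTHER = "other"

#: Sequence Ontology terms counted as loss-of-function by default:
#: frameshift, stop-gain and canonical splice donor/acceptor variants.
DEFAULT_LOF_TERMS = frozenset(
    {
        "frameshift_variant",
        "stop_gained",
        "splice_donor_variant",
        "splice_acceptor_variant",
    }
)

DEFAULT_MISSENSE_TERMS = frozenset({"missense_variant"})


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds defining qualifying variants.

    Comparisons are strict: a variant qualifies when ``pop_af <
    max_pop_af``, ``site_quality > min_site_quality`` and ``depth >
    min_depth``.  A variant absent from the population reference
    database (``pop_af`` missing) counts as rare.
    """

    max_pop_af: float = 0.05
    min_site_quality: float = 20.0
    min_depth: int = 10
    missense_terms: frozenset[str] = DEFAULT_MISSENSE_TERMS
    lof_terms: frozenset[str] = DEFAULT_LOF_TERMS

    def __post_init__(self) -> None:
        if not (0.0 < self.max_pop_af <= 1.0):
            raise ValueError(f"max_pop_af must be in (0, 1], got {self.max_pop_af}")
        if self.min_site_quality < 0 or self.min_depth < 0:
            raise ValueError("quality/depth thresholds must be non-negative")


@dataclass(frozen=True)
class AnnotationSpec:
    """Names of the INFO keys carrying the per-variant annotations."""

    gene_key: str = "GENE"
    consequence_key: str = "CSQ"
    af_key: str = "POP_AF"


@dataclass
class AnnotatedVariant:
    """One biallelic variant site with its annotations and genotypes.

    ``dosages`` holds the alt-allele count per sample (0/1/2, -1 for an
    uncalled genotype) aligned with the cohort's sample order; ``depths``
    the per-sample read depth.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    pop_af: float | None
    site_quality: float
    dosages: np.ndarray
    depths: np.ndarray

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class CohortVariants:
    """All annotated variants read from one cohort VCF."""

    sample_ids: list[str]
    variants: list[AnnotatedVariant] = field(default_factory=list)


def read_cohort(vcf_path: str | Path, spec: AnnotationSpec | None = None) -> CohortVariants:
    """Read an annotated cohort VCF into :class:`AnnotatedVariant` records.

    Multi-allelic records are split into one record per alt allele, with
    per-allele annotations (``Number=A`` INFO fields) carried to the
    matching split record.  Sample order is preserved.

    Raises
    ------
    FileNotFoundError
        If ``vcf_path`` does not exist.
    KeyError
        If a required annotation key is absent, naming the key and the
        first offending record.
    """
    from cyvcf2 import VCF

    spec = spec or AnnotationSpec()
    path = Path(vcf_path)
    if not path.exists():
        raise FileNotFoundError(f"cohort VCF not found: {path}")

    vcf = VCF(str(path))
    cohort = CohortVariants(sample_ids=list(vcf.samples))
    n_samples = len(cohort.sample_ids)

    for rec in vcf:
        alts = rec.ALT
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        try:
            dp = rec.format("DP")
            depths = np.asarray(dp[:, 0], dtype=np.int64) if dp is not None else np.zeros(n_samples, dtype=np.int64)
        except KeyError:
            depths = np.zeros(n_samples, dtype=np.int64)
        depths = np.where(depths < 0, 0, depths)

        for alt_idx, alt in enumerate(alts):
            allele = alt_idx + 1
            dosages = np.empty(n_samples, dtype=np.int8)
            for i, gt in enumerate(gts):
                a = gt[:-1]  # drop phase flag
                if any(x < 0 for x in a):
                    dosages[i] = -1
                else:
                    dosages[i] = sum(1 for x in a if x == allele)

            gene = _info_value(rec, spec.gene_key, alt_idx, required=True)
            csq = _info_value(rec, spec.consequence_key, alt_idx, required=True)
            af = _info_value(rec, spec.af_key, alt_idx, required=False)
            cohort.variants.append(
                AnnotatedVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=str(gene),
                    consequence=str(csq),
                    pop_af=None if af is None else float(af),
                    site_quality=float(rec.QUAL) if rec.QUAL is not None else 0.0,
                    dosages=dosages,
                    depths=depths.copy(),
                )
            )
    return cohort


def _info_value(rec, key: str, alt_idx: int, required: bool):
    val = rec.INFO.get(key)
    if val is None:
        if required:
            raise KeyError(
                f"annotation key {key!r} missing at record {rec.CHROM}:{rec.POS}"
            )
        return None
    if isinstance(val, (tuple, list)):
        return val[alt_idx]
    if isinstance(val, str) and "," in val:
        parts = val.split(",")
        if len(parts) > alt_idx:
            return parts[alt_idx]
    return val


def passes_qc(v: AnnotatedVariant, sample_id: str, sample_ids: list[str], cfg: FilterConfig) -> bool:
    """Whether the genotype of ``sample_id`` at ``v`` passes quality control.

    True iff site quality > ``min_site_quality``, genotype depth >
    ``min_depth`` (both strict) and the genotype is called.
    """
    try:
        i = sample_ids.index(sample_id)
    except ValueError:
        raise KeyError(f"unknown sample id {sample_id!r}") from None
    return bool(
        v.site_quality > cfg.min_site_quality
        and v.depths[i] > cfg.min_depth
        and v.dosages[i] >= 0
    )


def is_rare(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """True iff the population AF is strictly below the cutoff.

    A missing AF (the variant is absent from the reference database)
    counts as rare.
    """
    return v.pop_af is None or v.pop_af < cfg.max_pop_af


_warned_terms: set[str] = set()


def classify_consequence(v: AnnotatedVariant, cfg: FilterConfig) -> str:
    """Classify a variant as ``missense``, ``lof`` or ``other``.

    The consequence annotation may hold several ``&``-joined Sequence
    Ontology terms (VEP style); LoF takes precedence over missense.
    Variants classed ``other`` never qualify.
    """
    terms = set(v.consequence.split("&"))
    if terms & cfg.lof_terms:
        return LOF
    if terms & cfg.missense_terms:
        return MISSENSE
    for t in terms - cfg.lof_terms - cfg.missense_terms:
        if t not in _warned_terms:
            _warned_terms.add(t)
            log.debug("consequence term %r not in missense/LoF vocabulary; classed 'other'", t)
    return OTHER


def qualifying_dosages(v: AnnotatedVariant, cfg: FilterConfig) -> np.ndarray:
    """Per-sample qualifying dosage vector for one variant.

    Genotypes failing QC (low depth, low site quality, or uncalled) are
    set to dosage 0 — the site is kept but the genotype does not count.
    """
    ok = (v.depths > cfg.min_depth) & (v.dosages >= 0)
    if v.site_quality <= cfg.min_site_quality:
        ok[:] = False
    return np.where(ok, np.maximum(v.dosages, 0), 0).astype(np.int8)


def build_cohort_genotypes(
    cohort: CohortVariants,
    cfg: FilterConfig,
    variant_class: str,
    label: str,
) -> CohortGenotypes:
    """Assemble the per-gene qualifying dosage matrices for one cohort.

    Only rare variants of ``variant_class`` (``missense`` or ``lof``)
    enter the matrices; QC-failing genotypes are zeroed.
    """
    if variant_class not in (MISSENSE, LOF):
        raise ValueError(f"variant_class must be 'missense' or 'lof', got {variant_class!r}")
    per_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in cohort.variants:
        if not is_rare(v, cfg):
            continue
        if classify_consequence(v, cfg) != variant_class:
            continue
        per_gene.setdefault(v.gene, []).append(v)

    genes: dict[str, GeneMatrix] = {}
    n = len(cohort.sample_ids)
    for gene, vs in per_gene.items():
        mat = np.zeros((n, len(vs)), dtype=np.int8)
        for j, v in enumerate(vs):
            mat[:, j] = qualifying_dosages(v, cfg)
        genes[gene] = GeneMatrix(variant_keys=[v.key for v in vs], dosages=mat)
    return CohortGenotypes(label=label, sample_ids=list(cohort.sample_ids), genes=genes)
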
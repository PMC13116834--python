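"""Synthetic case/control cohort generator.

Generates annotated cohorts with the statistical structure the burden
analysis assumes: per-gene rare variant sites with control allele
frequencies drawn from a configurable law, genotypes in Hardy–Weinberg
proportions (dosage ~ Binomial(2, AF)), and an optional per-gene
multiplicative enrichment of the case allele frequency.  Sites are
independent (no linkage disequilibrium) — sufficient for validating
collapsing and test calibration, not for emulating haplotype structure.

Each gene draws from its own random substream keyed by (seed, gene
index), so adding genes to a configuration never perturbs the genotypes
of existing ones.  With a fixed seed the emitted VCFs are byte
identical across runs.

``make_table1_fixture`` constructs cohorts that collapse exactly to
requested HET/CH/HOM carrier counts, for end-to-end regression tests
against published carrier-count tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .collapse import CohortGenotypes, GeneMatrix
from .variants import LOF, MISSENSE, OTHER, FilterConfig

#: Sequence Ontology term emitted per consequence class.
CLASS_TERMS = {MISSENSE: "missense_variant", LOF: "stop_gained", OTHER: "synonymous_variant"}


@dataclass
class SimulationConfig:
    """Study conditions for a simulated case-control cohort.

    Defaults mirror the target study design: 247 cases vs 1622
    controls, 50 genes with 5 rare sites each, control allele
    frequencies uniform on (0.0005, 0.01), and a variant-class mix
    dominated by missense over loss-of-function (roughly the 9:1 ratio
    typical of rare coding variation).  ``enrichment`` multiplies the
    case allele frequency (capped at 1); 1.0 everywhere is the null.
    """

    n_cases: int = 247
    n_controls: int = 1622
    n_genes: int = 50
    gene_symbols: list[str] | None = None
    sites_per_gene: int = 5
    af_low: float = 0.0005
    af_high: float = 0.01
    enrichment: float | Mapping[str, float] = 1.0
    class_mix: tuple[float, float, float] = (0.85, 0.10, 0.05)  # missense, lof, other
    qc_failure_rate: float = 0.0
    site_quality: float = 60.0
    depth_pass: int = 50
    depth_fail: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort sizes must be >= 1")
        if not (0.0 <= self.af_low <= self.af_high < 1.0):
            raise ValueError("need 0 <= af_low <= af_high < 1")
        if isinstance(self.enrichment, (int, float)) and self.enrichment < 0:
            raise ValueError("enrichment must be non-negative")
        if any(e < 0 for e in self._enrichment_map().values()):
            raise ValueError("enrichment must be non-negative")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or any(w < 0 for w in self.class_mix):
            raise ValueError("class_mix must be non-negative and sum to 1")
        if not (0.0 <= self.qc_failure_rate < 1.0):
            raise ValueError("qc_failure_rate must be in [0, 1)")
        if self.gene_symbols is not None and len(self.gene_symbols) != self.n_genes:
            raise ValueError("gene_symbols length must equal n_genes")

    @property
    def genes(self) -> list[str]:
        if self.gene_symbols is not None:
            return list(self.gene_symbols)
        return [f"GENE{i + 1:04d}" for i in range(self.n_genes)]

    def _enrichment_map(self) -> dict[str, float]:
        if isinstance(self.enrichment, Mapping):
            return dict(self.enrichment)
        return {}

    def gene_enrichment(self, gene: str) -> float:
        if isinstance(self.enrichment, Mapping):
            return float(self.enrichment.get(gene, 1.0))
        return float(self.enrichment)


@dataclass
class Site:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    term: str
    af_control: float
    af_case: float
    quality: float


@dataclass
class SimulatedCohorts:
    """In-memory simulated cohorts: site metadata plus dosage/depth arrays."""

    config: SimulationConfig
    sites: list[Site]
    case_sample_ids: list[str]
    control_sample_ids: list[str]
    case_dosages: np.ndarray      # (n_cases, n_sites)
    control_dosages: np.ndarray   # (n_controls, n_sites)
    case_depths: np.ndarray
    control_depths: np.ndarray
    truth: "object" = field(default=None)  # pandas DataFrame


def simulate(cfg: SimulationConfig) -> SimulatedCohorts:
    """Draw a full synthetic cohort pair under ``cfg``."""
    import pandas as pd

    genes = cfg.genes
    sites: list[Site] = []
    case_blocks, control_blocks = [], []
    case_fail, control_fail = [], []
    truth_rows = []
    class_labels = [MISSENSE, LOF, OTHER]

    for gidx, gene in enumerate(genes):
        rng = np.random.default_rng([cfg.seed, gidx])
        S = cfg.sites_per_gene
        afs = rng.uniform(cfg.af_low, cfg.af_high, S)
        classes = rng.choice(3, size=S, p=list(cfg.class_mix))
        enr = cfg.gene_enrichment(gene)
        afs_case = np.minimum(afs * enr, 1.0)

        case_blocks.append(rng.binomial(2, afs_case, size=(cfg.n_cases, S)).astype(np.int8))
        control_blocks.append(rng.binomial(2, afs, size=(cfg.n_controls, S)).astype(np.int8))
        # qc-failure mask is always drawn so the genotype stream is
        # unchanged when only qc_failure_rate differs between runs
        case_fail.append(rng.random((cfg.n_cases, S)) < cfg.qc_failure_rate)
        control_fail.append(rng.random((cfg.n_controls, S)) < cfg.qc_failure_rate)

        for s in range(S):
            sites.append(
                Site(
                    gene=gene,
                    chrom="1",
                    pos=(gidx + 1) * 100_000 + s * 10 + 1,
                    ref="A",
                    alt="G",
                    term=CLASS_TERMS[class_labels[classes[s]]],
                    af_control=float(afs[s]),
                    af_case=float(afs_case[s]),
                    quality=cfg.site_quality,
                )
            )
        p_dom_control = 1.0 - np.prod((1.0 - afs) ** 2)
        p_dom_case = 1.0 - np.prod((1.0 - afs_case) ** 2)
        truth_rows.append(
            {
                "gene": gene,
                "enrichment": enr,
                "mean_af_control": float(afs.mean()),
                "p_dom_carrier_control": float(p_dom_control),
                "p_dom_carrier_case": float(p_dom_case),
            }
        )

    case_dos = np.hstack(case_blocks)
    control_dos = np.hstack(control_blocks)
    case_depths = np.where(np.hstack(case_fail), cfg.depth_fail, cfg.depth_pass)
    control_depths = np.where(np.hstack(control_fail), cfg.depth_fail, cfg.depth_pass)

    return SimulatedCohorts(
        config=cfg,
        sites=sites,
        case_sample_ids=[f"CASE{i + 1:05d}" for i in range(cfg.n_cases)],
        control_sample_ids=[f"CTRL{i + 1:05d}" for i in range(cfg.n_controls)],
        case_dosages=case_dos,
        control_dosages=control_dos,
        case_depths=case_depths,
        control_depths=control_depths,
        truth=pd.DataFrame(truth_rows),
    )


def to_genotypes(
    sim: SimulatedCohorts,
    variant_class: str = MISSENSE,
    cfg: FilterConfig | None = None,
) -> tuple[CohortGenotypes, CohortGenotypes]:
    """Collapse-ready qualifying genotype stores straight from a simulation.

    Applies the same per-genotype QC and class/rarity selection the
    ingest module applies after a VCF round trip, without file I/O.
    """
    cfg = cfg or FilterConfig()
    term_class = {CLASS_TERMS[MISSENSE]: MISSENSE, CLASS_TERMS[LOF]: LOF, CLASS_TERMS[OTHER]: OTHER}

    def build(dosages, depths, sample_ids, label):
        genes: dict[str, GeneMatrix] = {}
        for gene in sim.config.genes:
            cols = [
                j
                for j, s in enumerate(sim.sites)
                if s.gene == gene
                and term_class[s.term] == variant_class
                and s.af_control < cfg.max_pop_af
                and s.quality > cfg.min_site_quality
            ]
            if not cols:
                continue
            d = dosages[:, cols].copy()
            d[depths[:, cols] <= cfg.min_depth] = 0
            keys = [f"{sim.sites[j].chrom}:{sim.sites[j].pos}:A>G" for j in cols]
            genes[gene] = GeneMatrix(variant_keys=keys, dosages=d)
        return CohortGenotypes(label=label, sample_ids=list(sample_ids), genes=genes)

    cases = build(sim.case_dosages, sim.case_depths, sim.case_sample_ids, "case")
    controls = build(sim.control_dosages, sim.control_depths, sim.control_sample_ids, "control")
    return cases, controls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=rvburden-synthetic
##contig=<ID=1>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence term (Sequence Ontology)">
##INFO=<ID=POP_AF,Number=1,Type=Float,Description="Population allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(
    path: str | Path,
    sample_ids: list[str],
    sites: list[Site],
    dosages: np.ndarray,
    depths: np.ndarray,
) -> Path:
    """Write a deterministic single-alt VCF with GENE/CSQ/POP_AF annotations."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for j, s in enumerate(sites):
            info = f"GENE={s.gene};CSQ={s.term};POP_AF={s.af_control:.6g}"
            cells = [f"{_GT[int(dosages[i, j])]}:{int(depths[i, j])}" for i in range(len(sample_ids))]
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t{s.quality:g}\tPASS\t{info}\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )
    return path


def simulate_cohorts(cfg: SimulationConfig, out_dir: str | Path) -> tuple[Path, Path, "object"]:
    """Simulate and write case/control VCFs plus the truth table.

    Returns ``(case_vcf, control_vcf, truth)``; the truth table (also
    written as ``truth.tsv``) records each gene's true enrichment and
    expected dominant-carrier probabilities for recovery tests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate(cfg)
    case_vcf = write_vcf(out / "cases.vcf", sim.case_sample_ids, sim.sites, sim.case_dosages, sim.case_depths)
    control_vcf = write_vcf(
        out / "controls.vcf", sim.control_sample_ids, sim.sites, sim.control_dosages, sim.control_depths
    )
    sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return case_vcf, control_vcf, sim.truth


@dataclass(frozen=True)
class CarrierSpec:
    """Requested collapsed counts for one gene in a regression fixture."""

    gene: str
    case_het: int = 0
    case_ch: int = 0
    case_hom: int = 0
    control_het: int = 0
    control_ch: int = 0
    control_hom: int = 0

    def cohort_total(self, cohort: str) -> int:
        if cohort == "case":
            return self.case_het + self.case_ch + self.case_hom
        return self.control_het + self.control_ch + self.control_hom


def make_table1_fixture(
    specs: list[CarrierSpec],
    out_dir: str | Path,
    n_cases: int = 247,
    n_controls: int = 1622,
    n_sites: int = 3,
) -> tuple[Path, Path]:
    """Build cohorts that collapse exactly to the requested carrier counts.

    Each gene gets ``n_sites`` rare missense sites (≥3 so the gene
    passes the inclusion rule whenever every site is observed in both
    cohorts); carrier alleles are spread round-robin across sites.
    Raises ``ValueError`` for requests infeasible at the cohort sizes.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites per gene for compound heterozygotes")
    for spec in specs:
        if spec.cohort_total("case") > n_cases or spec.cohort_total("control") > n_controls:
            raise ValueError(f"carrier counts for {spec.gene} exceed cohort size")
        if min(
            spec.case_het, spec.case_ch, spec.case_hom,
            spec.control_het, spec.control_ch, spec.control_hom,
        ) < 0:
            raise ValueError(f"negative carrier counts for {spec.gene}")

    sites: list[Site] = []
    case_cols, control_cols = [], []
    for gidx, spec in enumerate(specs):
        for s in range(n_sites):
            sites.append(
                Site(
                    gene=spec.gene,
                    chrom="1",
                    pos=(gidx + 1) * 100_000 + s * 10 + 1,
                    ref="A",
                    alt="G",
                    term=CLASS_TERMS[MISSENSE],
                    af_control=0.001,
                    af_case=0.001,
                    quality=99.0,
                )
            )
        case_cols.append(_fill_gene(n_cases, n_sites, spec.case_hom, spec.case_ch, spec.case_het))
        control_cols.append(_fill_gene(n_controls, n_sites, spec.control_hom, spec.control_ch, spec.control_het))

    case_dos = np.hstack(case_cols) if case_cols else np.zeros((n_cases, 0), dtype=np.int8)
    control_dos = np.hstack(control_cols) if control_cols else np.zeros((n_controls, 0), dtype=np.int8)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    case_ids = [f"CASE{i + 1:05d}" for i in range(n_cases)]
    control_ids = [f"CTRL{i + 1:05d}" for i in range(n_controls)]
    depth = np.full_like(case_dos, 50, dtype=np.int64)
    case_vcf = write_vcf(out / "cases.vcf", case_ids, sites, case_dos, depth)
    control_vcf = write_vcf(
        out / "controls.vcf", control_ids, sites, control_dos, np.full_like(control_dos, 50, dtype=np.int64)
    )
    return case_vcf, control_vcf


def _fill_gene(n: int, n_sites: int, n_hom: int, n_ch: int, n_het: int) -> np.ndarray:
    """Dosage matrix whose collapse yields exactly the given category counts."""
    d = np.zeros((n, n_sites), dtype=np.int8)
    i = 0
    cursor = 0
    for _ in range(n_hom):
        d[i, cursor % n_sites] = 2
        i += 1
        cursor += 1
    for _ in range(n_ch):
        d[i, cursor % n_sites] = 1
        d[i, (cursor + 1) % n_sites] = 1
        i += 1
        cursor += 1
    for _ in range(n_het):
        d[i, cursor % n_sites] = 1
        i += 1
        cursor += 1
    return d
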
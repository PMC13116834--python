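"""Per-gene collapsing of qualifying genotypes into carrier categories.

Each individual is assigned to exactly one category per gene, with
precedence HOM > CH > HET:

* HOM — homozygous for a qualifying variant (any dosage-2 site);
* CH  — putative compound heterozygote: two or more distinct qualifying
  variant sites, each heterozygous (phase unknown in exome data);
* HET — exactly one qualifying heterozygous variant.

The dominant model counts any individual with at least one qualifying
allele (HET + CH + HOM); the recessive model counts putative biallelic
individuals (CH + HOM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GeneMatrix:
    """Qualifying variants of one gene: keys plus samples × sites dosages."""

    variant_keys: list[str]
    dosages: np.ndarray  # shape (n_samples, n_sites), entries in {0, 1, 2}

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.variant_keys):
            raise ValueError("dosage matrix shape does not match variant list")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must be in {0, 1, 2}")


@dataclass
class CohortGenotypes:
    """Qualifying-genotype store for one cohort, keyed by gene symbol."""

    label: str
    sample_ids: list[str]
    genes: dict[str, GeneMatrix] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def n_qualifying_sites(self, gene: str) -> int:
        """Distinct qualifying variant sites observed (≥1 allele) in this cohort."""
        gm = self.genes.get(gene)
        if gm is None or gm.dosages.size == 0:
            return 0
        return int(((gm.dosages > 0).any(axis=0)).sum())


@dataclass(frozen=True)
class GeneCarrierCounts:
    """Collapsed carrier counts for one gene in one cohort (one table row)."""

    gene: str
    n_het: int
    n_ch: int
    n_hom: int
    total_ac: int
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_het + self.n_ch + self.n_hom > self.n_samples:
            raise ValueError("carrier categories exceed cohort size")
        if self.total_ac < self.n_het + self.n_ch + self.n_hom:
            raise ValueError("total allele count below carrier count")


def carrier_categories(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean HOM/CH/HET masks per individual for one gene's dosage matrix."""
    d = np.asarray(dosages)
    if d.size == 0:
        n = d.shape[0]
        empty = np.zeros(n, dtype=bool)
        return empty, empty.copy(), empty.copy()
    hom = (d == 2).any(axis=1)
    n_het_sites = (d == 1).sum(axis=1)
    ch = ~hom & (n_het_sites >= 2)
    het = ~hom & ~ch & (n_het_sites == 1)
    return hom, ch, het


def collapse_gene(genotypes: CohortGenotypes, gene: str) -> GeneCarrierCounts:
    """Collapse one gene's qualifying genotypes into carrier counts.

    Raises ``KeyError`` for a gene absent from the store.
    """
    if gene not in genotypes.genes:
        raise KeyError(f"gene {gene!r} not present in cohort {genotypes.label!r}")
    gm = genotypes.genes[gene]
    hom, ch, het = carrier_categories(gm.dosages)
    return GeneCarrierCounts(
        gene=gene,
        n_het=int(het.sum()),
        n_ch=int(ch.sum()),
        n_hom=int(hom.sum()),
        total_ac=int(gm.dosages.sum()),
        n_samples=genotypes.n_samples,
    )


def empty_counts(gene: str, n_samples: int) -> GeneCarrierCounts:
    return GeneCarrierCounts(gene=gene, n_het=0, n_ch=0, n_hom=0, total_ac=0, n_samples=n_samples)


def dominant_carriers(c: GeneCarrierCounts) -> int:
    """Individuals with at least one qualifying allele in the gene."""
    return c.n_het + c.n_ch + c.n_hom


def recessive_carriers(c: GeneCarrierCounts) -> int:
    """Individuals with a putative biallelic genotype (HOM or unphased CH)."""
    return c.n_ch + c.n_hom
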
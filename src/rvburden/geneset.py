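"""Panel-level (gene-set) burden testing.

Carrier status is collapsed at the individual level across all member
genes of a panel: under the dominant model an individual is a set
carrier if they hold at least one qualifying allele in any member gene;
under the recessive model if they are a recessive-model carrier in at
least one member gene.  Each individual counts at most once per set.
The same exact test used at the gene level is then applied to the set's
2×2 carrier table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .collapse import CohortGenotypes, carrier_categories
from .stats import bh_adjust, fisher_exact_p

log = logging.getLogger(__name__)

UNION_SET_NAME = "ALL_PANEL_GENES"


@dataclass(frozen=True)
class GeneSet:
    """A named panel: a non-empty list of unique gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")


def read_panel(path: str | Path) -> GeneSet:
    """Read a panel file: one gene symbol per line, ``#`` comments allowed.

    Duplicate symbols are collapsed (first occurrence kept).
    """
    path = Path(path)
    genes: list[str] = []
    seen = set()
    for line in path.read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym and sym not in seen:
            seen.add(sym)
            genes.append(sym)
    return GeneSet(name=path.stem, genes=tuple(genes))


def read_panels_dir(panels_dir: str | Path) -> list[GeneSet]:
    """All ``*.txt`` panels in a directory, sorted by file name."""
    d = Path(panels_dir)
    sets = []
    for p in sorted(d.glob("*.txt")):
        try:
            sets.append(read_panel(p))
        except ValueError as e:
            log.warning("skipping panel %s: %s", p.name, e)
    return sets


def union_set(sets: list[GeneSet], name: str = UNION_SET_NAME) -> GeneSet:
    """The union of several panels as one GeneSet."""
    genes: list[str] = []
    seen = set()
    for s in sets:
        for g in s.genes:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    return GeneSet(name=name, genes=tuple(genes))


def set_carrier_mask(genotypes: CohortGenotypes, gene_set: GeneSet, model: str) -> np.ndarray:
    """Per-individual boolean carrier mask for a gene set.

    Member genes absent from the genotype store contribute nothing
    (zero-variant genes).
    """
    if model not in ("dominant", "recessive"):
        raise ValueError(f"model must be 'dominant' or 'recessive', got {model!r}")
    mask = np.zeros(genotypes.n_samples, dtype=bool)
    for gene in gene_set.genes:
        gm = genotypes.genes.get(gene)
        if gm is None or gm.dosages.size == 0:
            continue
        if model == "dominant":
            mask |= (gm.dosages > 0).any(axis=1)
        else:
            hom, ch, _ = carrier_categories(gm.dosages)
            mask |= hom | ch
    return mask


def set_carriers(genotypes: CohortGenotypes, gene_set: GeneSet, model: str = "dominant") -> int:
    """Number of individuals who are set-level carriers (counted once each)."""
    return int(set_carrier_mask(genotypes, gene_set, model).sum())


def run_geneset_burden(
    cases: CohortGenotypes,
    controls: CohortGenotypes,
    sets: list[GeneSet],
    model: str = "dominant",
    alternative: str = "greater",
    adjust: bool = False,
    include_union: bool = True,
):
    """Burden test per gene set, plus the union of all panels.

    Returns a DataFrame with one row per set: member-gene count, carrier
    counts in both cohorts and the exact p-value.  No cross-panel
    multiple-testing correction is applied unless ``adjust`` is set, in
    which case a BH-adjusted column is added.
    """
    import pandas as pd

    if not sets:
        raise ValueError("no gene sets supplied")
    all_sets = list(sets)
    if include_union and len(sets) > 1:
        all_sets.append(union_set(sets))

    n_ca, n_co = cases.n_samples, controls.n_samples
    recs = []
    for s in all_sets:
        ca = set_carriers(cases, s, model)
        co = set_carriers(controls, s, model)
        p = fisher_exact_p(ca, n_ca - ca, co, n_co - co, alternative)
        recs.append(
            {
                "set": s.name,
                "n_genes": len(s.genes),
                "case_carriers": ca,
                "case_n": n_ca,
                "control_carriers": co,
                "control_n": n_co,
                "model": model,
                "p": float(f"{p:.4f}"),
                "p_full": p,
            }
        )
    df = pd.DataFrame.from_records(recs)
    if adjust:
        df["q_full"] = bh_adjust(df["p_full"].to_numpy())
        df["q"] = df["q_full"].round(4)
    return df
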
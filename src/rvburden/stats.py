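"""Exact burden tests on 2×2 carrier tables and FDR adjustment.

The burden test compares collapsed carrier frequencies between cases
and controls with Fisher's exact test on the table

    [[carriers_cases,    non_carriers_cases],
     [carriers_controls, non_carriers_controls]]

computed from first principles via the hypergeometric distribution of
the top-left cell given fixed margins.  Point probabilities are
evaluated in log space so cohort totals around N ≈ 1900 cannot
overflow.  Two conventions are provided:

* ``greater`` — one-sided, enrichment of carriers in the first row
  (cases); this is the convention of collapsing-analysis tools such as
  TRAPD and the package's pipeline default;
* ``two-sided`` — the minimum-likelihood rule: sum the probabilities of
  all tables whose point probability does not exceed the observed
  table's (relative tie tolerance 1e-7).

Multiple testing is controlled per (variant class × inheritance model)
family with the Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .collapse import (
    CohortGenotypes,
    GeneCarrierCounts,
    collapse_gene,
    dominant_carriers,
    empty_counts,
    recessive_carriers,
)

log = logging.getLogger(__name__)

#: Relative tolerance for point-probability ties in the two-sided sum.
TIE_RTOL = 1e-7


def _log_hypergeom_pmf(k: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeom(N=r1+r2, K=c1, n=r1)."""
    n = r1 + r2

    def lchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return lchoose(r1, k) + lchoose(r2, c1 - k) - lchoose(n, c1)


def _validate_table(a: int, b: int, c: int, d: int) -> None:
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError(f"table counts must be non-negative integers, got ({a}, {b}, {c}, {d})")


def _support(a: int, b: int, c: int, d: int):
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return r1, r2, c1, np.arange(lo, hi + 1)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p-value for the table [[a, b], [c, d]].

    With margins fixed, sums the hypergeometric point probabilities of
    every table at most as probable as the observed one (within relative
    tolerance ``TIE_RTOL``).  Degenerate margins (an empty row or
    column) give 1.0.
    """
    _validate_table(a, b, c, d)
    r1, r2, c1, ks = _support(a, b, c, d)
    if len(ks) <= 1:
        return 1.0
    logp = _log_hypergeom_pmf(ks, r1, r2, c1)
    log_obs = logp[a - ks[0]]
    p = float(np.exp(logp[logp <= log_obs + np.log1p(TIE_RTOL)]).sum())
    return min(p, 1.0)


def fisher_one_sided_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p-value: enrichment of the top-left cell.

    P(X ≥ a) under the hypergeometric null — the probability that cases
    carry at least as many carriers as observed.
    """
    _validate_table(a, b, c, d)
    r1, r2, c1, ks = _support(a, b, c, d)
    if len(ks) <= 1:
        return 1.0
    logp = _log_hypergeom_pmf(ks, r1, r2, c1)
    p = float(np.exp(logp[ks >= a]).sum())
    return min(p, 1.0)


def fisher_exact_p(a: int, b: int, c: int, d: int, alternative: str = "greater") -> float:
    """Exact Fisher p-value under the chosen alternative."""
    if alternative == "greater":
        return fisher_one_sided_greater(a, b, c, d)
    if alternative == "two-sided":
        return fisher_two_sided(a, b, c, d)
    raise ValueError(f"alternative must be 'greater' or 'two-sided', got {alternative!r}")


def gene_inclusion(case_variant_count: int, control_variant_count: int, min_variants: int = 3) -> bool:
    """Gene inclusion rule: both cohorts need ≥ ``min_variants`` distinct
    qualifying variant sites, so that no association rests on a single
    variant."""
    if case_variant_count < 0 or control_variant_count < 0:
        raise ValueError("variant counts must be non-negative")
    return case_variant_count >= min_variants and control_variant_count >= min_variants


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``q_(i) = min_{j ≥ i} p_(j) · m / j`` over the sorted p-values,
    capped at 1, with the input order restored.  ``m`` defaults to the
    number of p-values but may be larger when the list is a subset of a
    bigger test family.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size if m is None else int(m)
    if m < p.size:
        raise ValueError("family size m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    q_sorted = p[order] * m / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclass
class GeneBurdenRow:
    """One gene's burden-test record (the per-gene report row)."""

    gene: str
    case: GeneCarrierCounts
    control: GeneCarrierCounts
    case_sites: int
    control_sites: int
    tested: bool
    p_dom: float | None = None
    p_rec: float | None = None
    q_dom: float | None = None
    q_rec: float | None = None


def run_gene_burden(
    cases: CohortGenotypes,
    controls: CohortGenotypes,
    variant_class: str = "missense",
    min_variants: int = 3,
    alternative: str = "greater",
) -> list[GeneBurdenRow]:
    """Per-gene collapsing burden test for one variant class.

    Genes failing the inclusion rule are reported with ``tested=False``
    and no p-values, never silently dropped.  Raw p-values come from the
    exact test on the dominant and recessive carrier tables; adjusted
    values from BH with the family size equal to the number of genes
    tested in this class.  Rows are sorted by dominant p-value
    ascending, untested genes last alphabetically.
    """
    genes = sorted(set(cases.genes) | set(controls.genes))
    n_ca, n_co = cases.n_samples, controls.n_samples
    rows: list[GeneBurdenRow] = []
    for gene in genes:
        cc = collapse_gene(cases, gene) if gene in cases.genes else empty_counts(gene, n_ca)
        kc = collapse_gene(controls, gene) if gene in controls.genes else empty_counts(gene, n_co)
        s_ca = cases.n_qualifying_sites(gene)
        s_co = controls.n_qualifying_sites(gene)
        tested = gene_inclusion(s_ca, s_co, min_variants)
        row = GeneBurdenRow(gene, cc, kc, s_ca, s_co, tested)
        if tested:
            dom_ca, dom_co = dominant_carriers(cc), dominant_carriers(kc)
            rec_ca, rec_co = recessive_carriers(cc), recessive_carriers(kc)
            row.p_dom = fisher_exact_p(dom_ca, n_ca - dom_ca, dom_co, n_co - dom_co, alternative)
            row.p_rec = fisher_exact_p(rec_ca, n_ca - rec_ca, rec_co, n_co - rec_co, alternative)
        rows.append(row)

    tested_rows = [r for r in rows if r.tested]
    if not tested_rows:
        log.warning("no genes passed the inclusion rule (%s class)", variant_class)
    else:
        q_dom = bh_adjust([r.p_dom for r in tested_rows])
        q_rec = bh_adjust([r.p_rec for r in tested_rows])
        for r, qd, qr in zip(tested_rows, q_dom, q_rec):
            r.q_dom, r.q_rec = float(qd), float(qr)

    rows.sort(key=lambda r: (not r.tested, r.p_dom if r.tested else 0.0, r.gene))
    return rows


def burden_frame(rows: list[GeneBurdenRow]):
    """Burden results as a DataFrame in the carrier-count table schema.

    Reported p/q columns are rounded to 4 decimals (the reporting
    precision); ``*_full`` columns retain machine precision.
    """
    import pandas as pd

    columns = [
        "gene",
        "case_het", "case_ch", "case_hom", "case_total_ac",
        "control_het", "control_ch", "control_hom", "control_total_ac",
        "case_sites", "control_sites", "tested",
        "p_dom", "p_rec", "q_dom", "q_rec",
        "p_dom_full", "p_rec_full", "q_dom_full", "q_rec_full",
    ]

    def fmt(x):
        return float(f"{x:.4f}") if x is not None else np.nan

    recs = []
    for r in rows:
        recs.append(
            {
                "gene": r.gene,
                "case_het": r.case.n_het,
                "case_ch": r.case.n_ch,
                "case_hom": r.case.n_hom,
                "case_total_ac": r.case.total_ac,
                "control_het": r.control.n_het,
                "control_ch": r.control.n_ch,
                "control_hom": r.control.n_hom,
                "control_total_ac": r.control.total_ac,
                "case_sites": r.case_sites,
                "control_sites": r.control_sites,
                "tested": r.tested,
                "p_dom": fmt(r.p_dom),
                "p_rec": fmt(r.p_rec),
                "q_dom": fmt(r.q_dom),
                "q_rec": fmt(r.q_rec),
                "p_dom_full": np.nan if r.p_dom is None else r.p_dom,
                "p_rec_full": np.nan if r.p_rec is None else r.p_rec,
                "q_dom_full": np.nan if r.q_dom is None else r.q_dom,
                "q_rec_full": np.nan if r.q_rec is None else r.q_rec,
            }
        )
    return pd.DataFrame.from_records(recs, columns=columns)
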
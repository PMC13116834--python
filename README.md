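# rvburden

Case-control rare-variant **collapsing burden analysis** for annotated
cohort VCFs: qualifying-variant filtering, per-gene dominant/recessive
carrier collapsing, exact Fisher burden tests with Benjamini–Hochberg
FDR control, panel-level gene-set tests, and a synthetic cohort
generator so the whole pipeline can be exercised and validated without
patient data.

It is aimed at statistical-genetics analysts running gene-level and
pathway-level enrichment of rare germline variants in a case cohort
against in-house controls — the typical setting of a rare-disease or
complex-trait exome study where per-gene variant counts are too sparse
for single-variant association.

## Method

A variant is **qualifying** when it is rare (population allele
frequency < 5% by default, absent-from-database counting as rare),
passes per-genotype QC (site quality > 20, genotype depth > 10, strict
inequalities), and belongs to the analysed consequence class — missense,
or loss-of-function (frameshift, stop-gain, canonical splice
donor/acceptor).

Per gene *g*, qualifying genotypes are collapsed per individual with
precedence HOM > CH > HET:

* **HOM** — homozygous for a qualifying variant;
* **CH** — putative compound heterozygote: ≥ 2 distinct qualifying
  heterozygous sites (phase-naive, as exome data are unphased);
* **HET** — exactly one qualifying heterozygous site.

The **dominant** carrier count is HET + CH + HOM; the **recessive**
count is CH + HOM. For each gene with ≥ 3 qualifying variant sites in
*both* cohorts, the carrier counts feed a 2×2 table

|          | carriers | non-carriers |
|----------|----------|--------------|
| cases    | a        | N₁ − a       |
| controls | c        | N₂ − c       |

tested with Fisher's exact test computed from the hypergeometric
distribution of *a* given fixed margins (log-space, overflow-safe at
N ≈ 1900). The default alternative is one-sided case enrichment,
P(X ≥ a) — the convention of collapsing-analysis tools; the two-sided
minimum-likelihood rule is available via configuration. Benjamini–
Hochberg adjusted values q₍ᵢ₎ = minⱼ≥ᵢ p₍ⱼ₎·m/j are computed per
(variant class × model) family with m = genes tested in that family.

Gene-set (panel) testing collapses carrier status across all member
genes at the individual level — each individual counted at most once
per set — and applies the same exact test.

The simulator draws per-site control allele frequencies from a
configurable law and genotypes in Hardy–Weinberg proportions,
dosage ~ Binomial(2, AF), with an optional multiplicative case
enrichment of AF; defaults emulate a 247-case / 1622-control design.

## Worked example

Build a fixture cohort pair whose collapsed counts equal two published
carrier configurations (247 cases vs 1622 controls), run the pipeline,
and read the gene report:

```python
import rvburden as rb, pandas as pd

specs = [rb.CarrierSpec("PNPT1", case_het=8, control_het=12),
         rb.CarrierSpec("FBXL4", case_het=21, case_hom=3, control_het=83)]
case_vcf, control_vcf = rb.make_table1_fixture(specs, "fixture")
rb.run_pipeline(case_vcf, control_vcf, "out")
df = pd.read_csv("out/burden_missense.tsv", sep="\t")
print(df[["gene", "case_het", "case_ch", "case_hom", "control_het",
          "tested", "p_dom", "q_dom"]].to_string(index=False))
```

prints

```
 gene  case_het  case_ch  case_hom  control_het  tested  p_dom  q_dom
PNPT1         8        0         0           12    True 0.0025 0.0048
FBXL4        21        0         3           83    True 0.0048 0.0048
```

PNPT1's 8/247 case carriers vs 12/1622 control carriers give an exact
dominant p-value of 0.0025; FBXL4's 24 (21 HET + 3 HOM) vs 83 give
0.0048. The q column is the BH adjustment over the two genes tested
here. The full report also carries recessive-model p-values, allele
counts, per-cohort qualifying-site counts and full-precision columns;
`manifest.json` records input digests and per-stage filter counts.

The same stages are available from a shell:

```sh
burden simulate --seed 7 --out sim/
burden run --cases sim/cases.vcf --controls sim/controls.vcf --out results/
```

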
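# Methods

## Model and procedure

The package implements a collapsing burden framework for rare germline
variants in a case cohort versus controls. The unit of inference is the
gene (or gene set), not the variant: qualifying variants are collapsed
into a per-individual carrier status, and carrier frequencies are
compared between cohorts with an exact test. This is the appropriate
regime when individual variants are too rare for single-marker tests
and effects are assumed to aggregate within a gene.

Assumptions worth stating explicitly:

* cohorts are unrelated and drawn from comparable populations — no
  covariate or population-structure adjustment is performed (a
  structure-confounded cohort will inflate the test);
* genotypes are unphased, so compound heterozygosity is *putative*:
  any two qualifying heterozygous sites in a gene count as CH whether
  or not they are in trans;
* carrier categories are disjoint with precedence HOM > CH > HET, so
  an individual appears in exactly one column of the report. An
  individual with a homozygous site plus extra heterozygous sites is
  counted once, as HOM.

## Qualifying-variant filters

| parameter | default | meaning |
|---|---|---|
| `max_pop_af` | 0.05 | population AF cutoff; comparison is strict (`<`), and a variant missing from the reference database counts as rare — absence is itself evidence of rarity. Configurable. |
| `min_site_quality` | 20 | site QUAL; strict (`>`). |
| `min_depth` | 10 | per-genotype read depth; strict (`>`). |
| `lof_terms` | frameshift, stop-gain, splice donor/acceptor | Sequence Ontology terms counted as loss-of-function; the vocabulary is configuration, not code. |
| `min_variants` | 3 | distinct qualifying sites required in *each* cohort for a gene to be tested, so no association rests on a single variant. Counts sites, not alleles. |

QC is per genotype: depth is a property of one sample's genotype, and a
failing genotype is treated as dosage 0 rather than discarding the
whole site. Uncalled genotypes never qualify. `&`-joined consequence
strings are resolved with LoF taking precedence over missense; unknown
terms fall through to `other` and never qualify.

## The exact test and its sidedness

Fisher's exact test is computed directly from the hypergeometric
distribution of the top-left cell with margins fixed; point
probabilities are evaluated in log space (via `gammaln`) so cohort
totals of a few thousand cannot overflow, and the support is summed in
one pass per table.

Two conventions are exposed through `alternative`:

* `greater` (default): P(X ≥ a), a one-sided test of carrier
  *enrichment in cases*. This is the convention of the established
  collapsing tools and the one under which the package's regression
  fixtures reproduce published carrier-table p-values. A burden screen
  is directional by design — depletion of rare qualifying variants in
  cases is not the alternative of interest.
* `two-sided`: the minimum-likelihood rule — sum all tables whose
  point probability does not exceed the observed table's, with a
  relative tie tolerance of 1e-7 so floating-point near-ties on the
  opposite tail are included, matching mainstream statistics libraries.

Degenerate margins (an empty row or column, or a single-table support)
return p = 1.0.

BH adjustment is the standard step-up q₍ᵢ₎ = minⱼ≥ᵢ p₍ⱼ₎·m/j capped at
1, applied separately per (variant class × inheritance model) family
with m equal to the number of genes tested in that family; `m` may be
passed explicitly when the p-value list is a subset of a larger family.

Reported p/q values are rounded to 4 decimals in the TSV (the
reporting precision); `*_full` columns retain machine precision.

## Gene-set testing

The set statistic collapses carrier status at the individual level
across member genes (dominant by default) and applies the same exact
test. The alternative aggregation — summing allele counts — weights
multi-carrier individuals more heavily and is more sensitive to a few
deeply burdened samples; it is noted as an option but not implemented
as the default because carrier collapsing keeps the gene-level and
set-level statistics on the same footing. Member genes absent from the
data contribute nothing, so padding a panel with untouched genes never
changes its p-value. No cross-panel correction is applied unless
requested (`geneset_adjust`), since panel screens are usually reported
nominally.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
independent rare sites per gene, control allele frequencies from a
uniform law on a configurable interval, genotypes in Hardy–Weinberg
proportions (dosage ~ Binomial(2, AF)), and case enrichment acting
multiplicatively on AF (capped at 1). Under the rare-variant regime a
multiplicative AF effect is nearly identical to a carrier
relative-risk effect, and it keeps the closed form for the expected
dominant carrier count, n·(1 − Π (1−AF)²), exact.

Defaults are the study design the package targets: 247 cases vs 1622
controls, 50 genes × 5 sites, AF ~ U(0.0005, 0.01), class mix
0.85/0.10/0.05 missense/LoF/other (roughly the 9:1 missense:LoF ratio
typical of rare coding variation, plus a small non-qualifying
fraction). Calibration experiments use a pure-missense mix so "sites
per gene" means qualifying sites.

Each gene draws from a substream keyed by (seed, gene index), so
extending a configuration with more genes never perturbs existing
genotypes; with a fixed seed the emitted VCFs are byte identical.
`qc_failure_rate` assigns failing depth to a random subset of
genotypes; the failure mask is drawn even at rate 0 so two runs
differing only in the rate share the same genotype stream.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: linkage disequilibrium
between sites, realistic site-frequency spectra, population structure
or relatedness, genotyping error correlated with genotype, X-chromosome
hemizygosity, and annotation error. The simulator validates the
collapsing arithmetic and the test's calibration, not robustness to
those phenomena.

`make_table1_fixture` is the deterministic counterpart: it constructs
cohorts whose collapsed counts equal requested HET/CH/HOM values,
spreading carrier alleles round-robin over ≥ 3 sites per gene so the
inclusion rule is met, for end-to-end regression against published
carrier-count tables.

## Numerical and degenerate-input choices

* Table validation rejects negative counts; empty cohorts of tested
  genes yield an empty (but fully-columned) report with a warning, not
  an error.
* Report rows are sorted by dominant p ascending; untested genes are
  appended alphabetically, flagged `tested=False`, never dropped.
* Ties in the two-sided sum use a 1e-7 *relative* comparison of point
  probabilities.
* The total allele count column is the sum of qualifying dosages; it
  is reported for audit but no test statistic depends on it, because
  published AC columns are not always reconcilable with carrier counts
  under a single definition.

## Known limitations

No phasing or pedigree validation of compound heterozygotes; no
covariate-adjusted regression (SKAT-style or GLM burden tests are out
of scope); no X-chromosome hemizygote handling; recessive-model
results depend on the phase-naive CH definition and should be read as
an upper bound on biallelic carriers. Simulation sizes in the test
suite (200 null replicates, 100 recovery replicates, full exact-test
sweep to N = 60) were chosen as the package's own validation budget;
the closed-form and oracle checks are exact, the Monte-Carlo checks
are bounded by the stated MCSE terms.
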
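# Methods

This note documents the statistical model, the synthetic-data design, the
numerical choices, and the limitations of the `exoburden` package.

## Collapsing burden model

The analysis tests, gene by gene and separately for three variant classes
(loss-of-function, damaging missense, synonymous), whether *carriers* of
rare qualifying variants are enriched among cases. Collapsing to a binary
carrier indicator (dominant model) is what gives the test power when a gene
is hit by many distinct, individually near-private variants: the per-gene
statistic depends only on carrier counts, not on which variant each carrier
has. The test is the two-sided Fisher exact test with the point-probability
two-sided rule: conditional on the table margins, sum the hypergeometric
probabilities of every table whose probability does not exceed the observed
one. A relative tolerance of 1 + 10⁻⁷ guards the "does not exceed"
comparison against floating-point representation of exact ties; the
implementation is validated against exact integer-arithmetic enumeration
for every table with total ≤ 60 and against an independent library
implementation on random tables.

The synonymous class is carried through the identical machinery as a
negative control: synonymous variants are assumed functionally neutral, so
any systematic case-control imbalance there indicates residual stratification
or differential quality, not biology.

### Multiple testing

The gene universe G is *derived* — the set of genes retaining at least one
qualifying variant of any tested class — and the exome-wide threshold is
α/G with α = 0.05. Significance is strict (`p < α/G`); a tie at the
threshold is not significant. At the realistic exome scale G ≈ 19,199 this
threshold is 2.6 × 10⁻⁶.

## Qualifying variants

Site-quality filters, with bounds following their textual statement
exactly (">" exclusive, "≥" inclusive):

| criterion | rule | default |
|---|---|---|
| mean read depth | DP > 10 | exclusive |
| carrier alternate-read fraction | ≥ 0.25 | inclusive |
| mean quality-by-depth | QD > 10 | exclusive |
| site Phred quality | QUAL > 30 | exclusive |
| mean genotype quality | GQ > 20 | exclusive |
| allele frequency | < 0.001 everywhere | exclusive |

DP, QD and QUAL are site-level means taken as provided by the annotation
input; alternate-read fraction and GQ are averaged over carrier genotypes.
The rarity filter requires AF < 0.1% separately in the internal case and
control cohorts and in every external database with an entry; a variant
absent from an external source counts as frequency 0 there (absence of
evidence is the standard treatment in rarity filtering). Attrition is
attributed to the *first* failing criterion in the fixed order
DP → alt_fraction → QD → QUAL → GQ → MAF → class, so per-filter counts sum
to the input count.

## LoF curation (NMD / PVS1 rule)

Truncating consequences (nonsense, frameshift, canonical splice) are LoF
candidates. When the induced premature termination codon (PTC) position is
known in CDS coordinates and a transcript model is available, the candidate
is retained only if

1. the PTC is predicted to trigger nonsense-mediated decay: strictly 5′ of
   the boundary B = (CDS 3′ end of the penultimate coding exon) − 50 nt.
   A PTC at exactly B, in the escape zone, or in the last exon escapes;
   single-coding-exon transcripts always escape. "Before the 3′-most 50 bp"
   is read as strictly upstream, matching the canonical 50–55-nt rule's
   usual statement; and
2. the truncation removes ≥ 10% of the protein:
   loss = (L − ⌊(ptc − 1)/3⌋)/L for protein length L; the CDS length
   includes the stop codon, so L = CDS/3 − 1.

Splice and frameshift variants without a resolvable PTC are retained as LoF
by consequence alone, with `nmd_evaluated = False` recorded — the
functional validation that would resolve them (minigene assays) is outside
the package's scope. Damaging missense requires a unanimous deleterious
call from all three in-silico predictors ("and", not majority). In-frame
changes and non-consensus missense fall into an untested `other` bin.

## Sample QC

* **Coverage:** samples with mean coding depth strictly below ×30 are
  excluded.
* **Relatedness:** for every pair with KING kinship ≥ 0.0884 (KING's
  published 2nd-degree lower bound — this subsumes duplicates/MZ twins and
  1st degree), the lower-coverage member is excluded; depth ties break by
  excluding the lexicographically later sample id. The rule is applied to
  every flagged pair, so the result is order-independent and a single pass
  leaves no related pair among retained samples.
* **Ancestry:** markers of a common-variant genotype matrix are
  standardized by the sample allele frequency (center 2p̂, scale
  √(2p̂(1−p̂)); monomorphic and zero-variance markers dropped), PCs come
  from the SVD, and the mean/SD of PC1 and PC2 are computed over study
  samples only — reference-panel samples (e.g. a 1000 Genomes-style panel)
  serve as ancestry anchors and are never excluded. A study sample is
  excluded if it deviates more than 4 SD from the study mean on PC1 *or*
  PC2 (marginal filters, not an ellipse — the literal reading of "±4 SD
  across PC1 and PC2"). SD uses the n−1 denominator. Exclusion decisions
  are invariant to PC sign and marker permutation.

## Permutation calibration and λ

The expected null distribution of P values comes from K = 1,000 (default)
case/control relabelings preserving group sizes. Genotypes, QC and
classification are label-independent, so a permutation scan reduces to
re-counting how many of each gene's carriers land in the shuffled case
group and looking the resulting table up in a per-margin cache of Fisher P
values — exactly identical to re-running the full scan, which is tested.
The expected P at rank i is the across-permutation mean of the i-th
smallest P (a median variant is switchable; the mean is smoother at
K = 1,000).

λ is the least-squares slope through the origin of observed vs expected
−log10 P, after dropping rank pairs whose observed P is exactly 1 (an
uninformative atom of the discrete test) or beyond the Bonferroni threshold
(true signal must not inflate λ). The −log10 scale is the QQ-plot scale; a
free intercept would make λ = 1 ill-defined at the origin, though an OLS
variant is available. λ ≈ 1 indicates a well-calibrated scan; it is
reported, never applied as a correction.

### Discreteness-adjusted uniformity

An exact test's P value is stochastically larger than uniform under the
null, so "P values look uniform" cannot be tested directly. The mid-P
adjustment (subtract half the observed table's point probability) restores
uniformity *in mean* but keeps atoms at the support midpoints; with
thousands of genes sharing the same cohort margins those atoms align across
genes, and a KS test rejects even a perfectly calibrated scan — this was
verified empirically, and is why the package's distribution-level check
uses the randomized probability-integral transform instead
(P − V·Pr(point), V ~ Uniform(0,1), seeded), which is exactly Uniform(0,1)
under the null. `discreteness_adjusted_p` computes either variant; the
mid-P (V = ½) remains the default for summary purposes.

## Prevalence estimation

Carrier frequencies are binomial proportions k/n with Clopper–Pearson
exact intervals (beta-quantile form, validated against tail-inversion by
bisection at 10⁻⁹); at prevalences near 10⁻⁴ the exact interval is the
defensible default, with the Wilson score interval available by option.
The pooled ("accumulated") prevalence over several population databases is
Σk/Σn with the exact CI of the pooled counts — invariant to source order
and splitting. Case-vs-population enrichment is the frequency ratio plus a
two-sided Fisher exact P on the combined 2×2. The carrier sex ratio is a
two-sided exact binomial test of the female share against p₀ = 0.5 (no
adjustment for database sex composition; p₀ is a parameter).

The population-database table shipped with the package
(`synthetic_database_counts`) is **synthetic**: six sources whose carrier
counts and order-of-magnitude denominators reproduce published per-source
carrier frequencies (0%, 0%, 0.0094%, 0.0014%, 0.0093%, 0.014%) at their
printed rounding, with a 63/50 female/male split in the largest source. It
is a stand-in for per-database tallies that are not redistributable, not a
copy of any release data.

## Synthetic cohort generator

The generator produces exactly the structure the analysis consumes, nothing
more. Defaults are the discovery-scale study conditions: 1,027 cases,
2,733 controls, and a scaled-down universe of G = 2,000 genes (the
full-exome universe of ~19,000 genes adds nothing statistically to the
per-gene test and would triple runtimes; the Bonferroni threshold always
uses the derived G of the run).

* **Carriers first.** For each gene × class, each individual carries with
  probability `null_carrier_rate` (default 0.005 — about 19 expected
  carriers per gene among 3,760 samples, a realistic aggregate for rare
  qualifying variants), or with planted case/control rates for planted
  genes. Carriers are then attributed, in shuffled order, to concrete
  variants with at most 2 carriers each (near-private regime; the cap also
  guarantees in-cohort AF < 0.1% at default cohort sizes — cohorts smaller
  than ~500 per arm cannot satisfy that bound with any carrier, and need a
  relaxed rarity threshold for study).
* **QC noise.** Extra variants are generated per gene × class (Poisson,
  mean 2.0): with probability 0.05 a variant fails *exactly one* QC
  criterion (drawn uniformly; value placed strictly in the failing range),
  with probability 0.05 it is common (external AF ≥ 0.1%). Passing
  variants draw all metrics uniformly above thresholds. This makes filter
  attribution exactly predictable, and the manifest records the truth.
* **NMD structure.** Toy transcripts have 3–8 fully coding exons of
  120–657 nt. Truncating variants receive a CDS PTC position in NMD
  territory (also guaranteeing ≥ 10% C-terminal loss); a 10% fraction of
  non-planted truncating variants is placed in the escape zone instead and
  is expected to be demoted by classification (their carriers are removed
  from the bookkept truth). Planted-gene variants are always NMD-positive
  so planted carrier rates are realized exactly.
* **Fixtures.** Kinship: the requested number of 2nd-degree-or-closer case
  pairs (kinship U(0.177, 0.354)) plus an equal number of sub-threshold
  background pairs. Ancestry: a 500-marker genotype matrix with one study
  population, a slightly diverged reference panel, and injected outliers
  drawn from mirrored allele frequencies (guaranteeing > 4 SD separation).

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, genotype missingness, batch/capture-kit artifacts,
per-variant effect-size variation, or population substructure within the
study sample. Passing tests therefore demonstrate correctness of the
statistical machinery under the model's own assumptions — not robustness
to the real-data pathologies that sample QC exists to catch; those stages
are tested on targeted fixtures instead.

## Numerical and reproducibility choices

* P-value tie tolerance 1 + 10⁻⁷ (relative); per-margin P tables cached
  and shared between the observed scan and permutations.
* Results sort ascending P within class, ties broken lexicographically by
  gene symbol; all writers iterate in deterministic order, so identical
  seeds give byte-identical artifacts.
* Reals are serialized at 12 significant digits; round-trips are exact at
  that precision.
* One global seed fans out to stage seeds by fixed offsets (permutations:
  +101), so stages are independently reproducible.
* Degenerate inputs fail loudly with the offending sample/variant named:
  missing depth, unknown samples in kinship pairs or genotypes, PTC outside
  the CDS, CDS length not divisible by 3, empty gene universe, fewer than
  2 rank pairs surviving the λ exclusions.

## Known limitations

* Per-gene sample sizes are the full post-QC cohort sizes; missing
  genotypes are treated as non-carrier rather than reducing the per-gene
  denominator.
* Internal AF is checked per cohort (cases and controls separately); a
  pooled-cohort reading of the rarity rule is possible and switchable, but
  not the default.
* The NMD rule needs a CDS-resolved PTC; splice/frameshift variants
  without one are retained as LoF by consequence, flagged unevaluated.
* Covariate-adjusted tests (Firth regression, SKAT) are out of scope; the
  design relies on ancestry matching plus the PCA filter, with the
  synonymous class as the empirical null check.
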
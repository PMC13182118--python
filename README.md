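# milkvar

Identification of bovine milk-protein variants from multi-sample DNA
sequence data.

The six major milk proteins — the caseins α_S1_-CN (*CSN1S1*), β-CN
(*CSN2*), α_S2_-CN (*CSN1S2*) and κ-CN (*CSN3*), and the whey proteins α-LA
(*LALBA*) and β-LG (*PAEP*) — are polymorphic, and their named protein
variants (β-CN A1 vs A2, κ-CN A vs B, …) matter for milk processing,
nutrition and breeding. `milkvar` takes a multi-sample VCF restricted to
the six gene regions (±2,000 bp), a gene-model table, a sample→breed panel
and a catalog of known variants, and produces:

- quality-filtered, region-annotated SNVs (upstream / 5′UTR / intron /
  synonymous / missense / 3′UTR / downstream),
- per-gene coding-haplotype frequencies estimated by EM from unphased
  genotypes (cohort-wide and within each breed),
- mature-protein substitution sets per haplotype, matched against the
  catalog; unmatched combinations are named with a hierarchical dotted
  nomenclature (`A1.1`, `A1.1.2`, …) recording successive substitution
  layers on a base variant,
- per-breed variant frequency tables and functional summaries (β-CN
  A2-family = Pro at mature position 67; κ-CN A/B; β-LG B),
- variant networks whose edges connect protein variants differing at
  exactly one mature-protein position (GraphML/DOT/TSV).

A synthetic-data module simulates multi-breed diploid cohorts with known
ground truth (per-breed haplotype pools, genotype errors, missingness,
negative-binomial read depth), so the whole pipeline is testable without
any sequence download.

## The statistical core

Phasing of multi-heterozygous genotypes is ambiguous: an individual
heterozygous at *k* coding sites is compatible with 2^(k−1) unordered
haplotype pairs. Haplotype frequencies *f_h* are estimated by
expectation–maximization under Hardy–Weinberg proportions. For individual
*i* with compatible pair set P_i, the E-step weighs pair (h₁, h₂) by

    w(h1,h2) ∝ 2·f_h1·f_h2   (f_h² if h1 = h2),

normalized within the individual, and the M-step sets each *f_h* to its
expected chromosome count divided by 2N. The log-likelihood
Σ_i log Σ_{(h1,h2)∈P_i} w is non-decreasing across iterations (asserted at
run time). Each individual is then assigned its maximum-posterior pair
(ties broken lexicographically), and occurrence counts of protein variants
are haplotype-copy counts under that assignment.

## Worked example

Simulate a clean three-breed cohort over the bundled toy *CSN2*/*CSN3*
models (real coordinates, synthetic coding sequences) and run the full
pipeline:

```bash
milkvar simulate --seed 3 --out-dir sim
milkvar run-all --vcf sim/cohort.vcf --panel sim/panel.tsv \
    --gene-models sim/gene_models.tsv --catalog sim/catalog.tsv --out-dir out
```

`out/protein_variants.tsv` then contains (seed 3, nested demo pools):

```
gene   name  substitutions    status  occurrences
CSN2   B     -                known   72
CSN2   A2    67:H>P           known   60
CSN2   A2.1  67:H>P;139:W>S   novel   48
CSN3   B     -                known   75
CSN3   A     56:L>Q           known   53
CSN3   A.1   56:L>Q;112:N>T   novel   52
```

The reference haplotype is the catalogued reference variant (β-CN B for
*CSN2*); the Pro67 haplotype matches the catalogued A2 entry; and the
haplotype carrying one further substitution on top of A2 is novel, so it is
named `A2.1` — the first child of its base. Occurrences are chromosome-copy
counts (2 × 90 animals per gene in total). Per-breed EM frequencies land in
`variant_frequencies.tsv`, the A2-family/κ-CN/β-LG summary in
`functional_report.tsv`, and the substitution networks in
`network_<gene>.graphml`.

The two-individual EM worked example is instructive on its own: one
hom-ref individual plus one double heterozygote yields frequencies
{00: 0.75, 11: 0.25} — the EM concentrates the double-het's mass on the
phase sharing the common haplotype:

```python
>>> from milkvar import em_estimate
>>> # genotypes over two sites: I1 hom-ref, I2 het at both
>>> est = em_estimate(matrix([[0, 0], [1, 1]]))  # see tests for `matrix`
>>> est.frequencies["00"], est.frequencies["11"]
(0.7499999..., 0.2500000...)
```

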
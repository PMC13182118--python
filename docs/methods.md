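# Methods

## Scope and data model

`milkvar` analyses single-nucleotide variants in the six bovine
milk-protein genes and their ±2,000 bp flanks. Coordinates are 1-based
inclusive throughout (the VCF and genome-annotation convention); gene size
is `end − start + 1`. Only SNVs are supported: indel and MNV records are
skipped with a counter at VCF reading, and the classifier raises a typed
error for non-SNV alleles. The bundled six-gene fixture uses the real
ARS-UCD1.2 coordinates, strands and exon counts of *CSN1S1*, *CSN2*,
*CSN1S2*, *CSN3*, *LALBA* and *PAEP*, but synthetic exon boundaries and
coding sequences sized like the real proteins; real CDS content and the
per-gene signal-peptide lengths are user-supplied configuration in
production use (the fixture carries the literature values 15/15/15/21/19/16
residues). One printed annotation size (*PAEP*, 5,049 bp) disagrees with
the arithmetic convention by one bp; validation reports the discrepancy
rather than special-casing the gene.

Region classification is strand-aware: on reverse-strand genes the
higher-coordinate flank is upstream and the UTR classes follow the
transcription direction. Coding SNVs are resolved through the standard
genetic code (no mitochondrial table); stop gain/loss is reported as
`coding_other`. Splice-site consequences are not called; splice-region
SNVs fall into `intron`.

## Filtering

A variant is retained when (i) the cohort total of alt-supporting reads is
at least 3, (ii) site quality ≥ 20 (phred), (iii) mapping quality ≥ 20,
and (iv) at least 2 distinct individuals carry the alternate allele.
"At least three reads" is interpreted cohort-wide because per-sample AD is
not always available and the cohort reading is the weaker, safer
criterion; a per-sample mode is available by flag. Missing AD passes the
read criterion and is counted; missing genotypes never count as carriers.
Genotypes with depth strictly below 6 are flagged low-confidence rather
than removed, and per-site mean depths are reported. All thresholds are
configurable; the defaults above are the package's standard operating
point.

## Haplotype-frequency EM

Within each gene, haplotypes are built over missense coding sites by
default (a flag adds synonymous sites); individuals missing a genotype at
any selected site are excluded for that gene and counted. The estimator is
the classical EM for unphased multilocus genotypes under Hardy–Weinberg
proportions: E-step weights each compatible unordered pair (h₁,h₂) by
2·f₁·f₂ (f² when homozygous), M-step divides expected haplotype counts by
2N. Numerical choices:

- deterministic uniform initialization over the union of pair-compatible
  haplotypes (no random restarts);
- convergence when max |Δf| < 1e-8 (default), capped at 1,000 iterations;
  non-convergence is flagged, not raised;
- identical genotype rows are grouped, so cost scales with distinct
  genotype classes rather than individuals;
- pair enumeration is capped at 20 heterozygous sites (2^19 pairs) with a
  typed error beyond — far above anything the six genes produce;
- the log-likelihood trace is checked non-decreasing (1e-9 slack for
  floating-point noise) and frequencies must sum to 1 within 1e-9;
- haplotypes estimated below 1/(4N) — less than half a chromosome copy —
  are treated as numerical dust unless hard-assigned to some individual.

Breed-level runs are seeded from cohort frequencies blended with 1% of a
uniform distribution, which stabilizes small breeds without pinning any
haplotype at exactly zero. Maximum-posterior pair assignment breaks ties
lexicographically on the sorted pair, making downstream occurrence counts
deterministic. Occurrences default to hard-assignment copy counts, with
posterior-weighted expected counts available by flag.

## Protein variants and nomenclature

A haplotype's substitutions are obtained by editing the reference CDS and
re-translating affected codons jointly (two SNVs in one codon give a
single joint substitution). Substitutions within the signal peptide and
synonymous alleles contribute nothing to the mature protein; mature
positions are precursor positions minus the signal-peptide length.

Catalog matching is exact substitution-set equality. Novel sets are named
`base.k`: the base is the catalogued variant whose substitution set is a
subset of the novel set with maximal overlap (dotted names are eligible,
so layers nest); ties prefer the base with more observed copies in the
current dataset, then the lexicographically smaller name — the tie rule is
a package decision, since nesting order is genuinely underdetermined when
a novel set extends two unrelated bases. Novel variants are processed in
descending occurrence order (ties by the sorted substitution listing), and
each assigned name is appended to the working catalog before the next
assignment, so naming is deterministic and reproducible. Novel sets
observed below 2 chromosome copies and 2 carriers are still named but
flagged `unconfirmed`.

For κ-casein, mature positions map to functional regions: 1–95
para-κ-casein (micelle-retained), 105/106 the chymosin cleavage site
(Phe105–Met106), 113–169 the C-terminal part of the caseinomacropeptide.

## Reporting

The composition table covers within-gene variants (5′UTR, missense,
synonymous, intron, 3′UTR, coding-other), with upstream/downstream counted
separately; percentages are rounded half-up to two decimals, so they may
sum to slightly off 100. Breed frequency tables aggregate breed-level EM
haplotype frequencies by variant name. β-CN A2-family membership is
computed from substitution sets (Pro at mature position 67 relative to
the reference residue), so novel Pro67 variants are included
automatically; functional summaries default to breeds with ≥ 20 animals.
Variant networks connect variants whose substitution sets differ at
exactly one mature-protein position (added, removed, or changed residue);
catalogued-but-undetected variants appear as their own node class.

## Synthetic cohorts: what they emulate and what they do not

The generator draws, per breed and gene, two haplotypes per individual
independently from a breed-specific pool (Hardy–Weinberg within breed),
over nine sites per gene spanning every region category, including a
signal-peptide missense site whose substitution must vanish at the protein
level. Genotype errors (allele flips), missingness, negative-binomial
depth (mean 10, dispersion 8 — a comfortably covered short-read regime),
and Gaussian site quality (mean 60) are applied after the truth ledger is
recorded. Two pool styles exist: `spread` (crossing allele patterns, so
double heterozygotes are genuinely phase-ambiguous) and `nested`
(haplotypes ordered by inclusion, making every genotype phase-resolvable —
the regime used for exact truth-recovery checks). Defaults are three
breeds of 30 animals over two genes.

Deliberately not simulated: read-level data, linkage between genes (the
casein cluster's inter-gene LD), population relatedness within breeds,
reference bases outside the simulated sites, and allele-specific depth
biases. Passing the end-to-end tests therefore demonstrates correctness of
the pipeline's logic under its own model assumptions — it does not certify
behavior on real cohorts with phasing errors, relatedness, or calling
artifacts. The toy CDS for *CSN2* pins mature position 67 to His and 122
to Arg so the reference encodes a B-like protein and the A2-defining
Pro67 is reachable by a single transition, mirroring the real gene's
layout; all other toy codons are arbitrary.

## Problem sizes in tests and the acceptance script

The suite runs EM oracle comparisons on random instances of ≤ 4 sites and
≤ 20 individuals (exhaustive pair enumeration is tractable there),
parameter recovery on 200 replicates of 400 chromosomes drawn from four
haplotypes at 0.4/0.3/0.2/0.1, and end-to-end recovery on 90-animal
three-breed cohorts — sizes at which every check completes in seconds
while keeping binomial sampling error small relative to the tolerances
tested.

## Known limitations

- Multiallelic sites are decomposed into biallelic views; a genotype
  carrying a different alternate allele is treated as reference in each
  view, which slightly undercounts carriers at genuinely triallelic sites.
- Individuals with any missing genotype at a gene's selected sites are
  dropped for that gene rather than marginalized.
- The EM likelihood can have non-identifiable ridges in tiny cohorts (a
  single double heterozygote); the deterministic initialization makes the
  returned point reproducible but it is then one of several maxima.
- Known-variant novelty labeling is purely lookup-based against a
  user-supplied key list; no external database is contacted.
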
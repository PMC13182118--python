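"""Synthetic multi-breed cohorts with known ground truth.

The simulator emulates the structure of a multi-breed whole-genome-sequencing
panel restricted to the milk-protein gene regions: each breed has its own
pool of gene haplotypes spanning missense, synonymous, signal-peptide,
intronic, UTR and flanking sites; each individual draws two haplotypes per
gene independently from its breed pool (Hardy-Weinberg within breed).
Genotype errors, missing genotypes and per-genotype read depths (negative
binomial, mean 10 by default) are applied after the truth ledger is recorded,
so every downstream stage can be checked against known answers. Output is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .gene_models import GeneModel, bovine_milk_gene_models, write_gene_models
from .protein_variants import Catalog, haplotype_to_substitutions
from .haplotype_em import SiteInfo
from .variant_filtering import MISSING, SamplePanel, write_vcf


@dataclass(frozen=True)
class SimSite:
    """One simulated polymorphic site with its true region category."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    category: str
    cds_offset: Optional[int] = None

    def to_site_info(self) -> SiteInfo:
        return SiteInfo(self.chrom, self.pos, self.ref, self.alt, self.cds_offset)


@dataclass
class BreedSpec:
    """Breed name, cohort size and per-gene haplotype pools with frequencies."""

    name: str
    n_individuals: int
    pools: dict[str, dict[str, float]]

    def validate(self, sites: dict[str, list[SimSite]]) -> None:
        if self.n_individuals < 2:
            raise ConfigError(f"breed {self.name}: need >= 2 individuals")
        for gene, pool in self.pools.items():
            if abs(sum(pool.values()) - 1.0) > 1e-9:
                raise ConfigError(f"breed {self.name}/{gene}: pool frequencies must sum to 1")
            for hap in pool:
                if len(hap) != len(sites[gene]):
                    raise ConfigError(
                        f"breed {self.name}/{gene}: haplotype length {len(hap)} != "
                        f"{len(sites[gene])} sites"
                    )


@dataclass
class SyntheticConfig:
    """Full description of a simulated cohort."""

    models: dict[str, GeneModel]
    sites: dict[str, list[SimSite]]
    breeds: list[BreedSpec]
    error_rate: float = 0.0
    missing_rate: float = 0.0
    depth_mean: float = 10.0
    depth_dispersion: float = 8.0
    qual_mean: float = 60.0
    qual_sd: float = 5.0
    mq: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for rate in (self.error_rate, self.missing_rate):
            if not 0.0 <= rate < 1.0:
                raise ConfigError("rates must lie in [0, 1)")
        for b in self.breeds:
            b.validate(self.sites)


@dataclass
class SimulationResult:
    """In-memory truth ledger plus the paths of any files written."""

    panel: SamplePanel
    sites: pd.DataFrame
    individuals: pd.DataFrame
    breed_freqs: pd.DataFrame
    vcf_path: Optional[str] = None
    panel_path: Optional[str] = None
    truth_paths: dict[str, str] = field(default_factory=dict)


def simulate_population(cfg: SyntheticConfig, out_dir=None) -> SimulationResult:
    """Simulate the cohort; optionally write VCF + panel + truth TSVs to ``out_dir``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = list(cfg.sites)
    samples, breeds_of = [], {}
    pairs: list[dict] = []
    for b in cfg.breeds:
        for i in range(b.n_individuals):
            sid = f"{b.name}_{i + 1:03d}"
            samples.append(sid)
            breeds_of[sid] = b.name
    panel = SamplePanel(samples, breeds_of)

    # true haplotype pairs per individual per gene
    hap_of: dict[tuple[str, str], tuple[str, str]] = {}
    for b in cfg.breeds:
        for gene in genes:
            pool = b.pools.get(gene)
            if pool is None:
                raise ConfigError(f"breed {b.name}: no pool for gene {gene}")
            haps = sorted(pool)
            p = np.array([pool[h] for h in haps])
            for i in range(b.n_individuals):
                sid = f"{b.name}_{i + 1:03d}"
                h1, h2 = rng.choice(len(haps), size=2, p=p)
                pair = (haps[h1], haps[h2])
                hap_of[(sid, gene)] = pair
                pairs.append(
                    {"sample": sid, "breed": b.name, "gene": gene, "hap1": pair[0], "hap2": pair[1]}
                )

    # genotypes per site, then noise
    records = []
    site_rows = []
    for gene in genes:
        sites = cfg.sites[gene]
        for j, site in enumerate(sites):
            genotypes = []
            for sid in samples:
                a = int(hap_of[(sid, gene)][0][j])
                bb = int(hap_of[(sid, gene)][1][j])
                genotypes.append((a, bb))
            # error/missingness applied after truth is recorded
            noisy = []
            for a, bb in genotypes:
                if cfg.error_rate > 0:
                    if rng.random() < cfg.error_rate:
                        a = 1 - a
                    if rng.random() < cfg.error_rate:
                        bb = 1 - bb
                if cfg.missing_rate > 0 and rng.random() < cfg.missing_rate:
                    noisy.append((MISSING, MISSING))
                else:
                    noisy.append(tuple(sorted((a, bb))))
            n = len(samples)
            r = cfg.depth_dispersion
            depths = rng.negative_binomial(r, r / (r + cfg.depth_mean), size=n)
            alt_frac = np.array([0.0 if g == (MISSING, MISSING) else (g[0] + g[1]) / 2 for g in noisy])
            alt_depths = rng.binomial(depths, alt_frac)
            qual = max(0.0, float(rng.normal(cfg.qual_mean, cfg.qual_sd)))
            records.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "id": None,
                    "ref": site.ref,
                    "alt": site.alt,
                    "qual": round(qual, 1),
                    "mq": cfg.mq,
                    "genotypes": noisy,
                    "alt_depths": alt_depths,
                    "depths": depths,
                }
            )
            site_rows.append(
                {
                    "gene": gene,
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "ref": site.ref,
                    "alt": site.alt,
                    "category": site.category,
                    "cds_offset": site.cds_offset,
                }
            )
    records.sort(key=lambda r: (r["chrom"], r["pos"]))
    sites_df = pd.DataFrame(site_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    individuals_df = pd.DataFrame(pairs)
    freq_rows = [
        {"breed": b.name, "gene": gene, "haplotype": hap, "frequency": f}
        for b in cfg.breeds
        for gene in genes
        for hap, f in sorted(b.pools[gene].items())
    ]
    breed_freqs_df = pd.DataFrame(freq_rows)

    result = SimulationResult(panel, sites_df, individuals_df, breed_freqs_df)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        contigs = sorted({r["chrom"] for r in records})
        vcf_path = os.path.join(out_dir, "cohort.vcf")
        write_vcf(vcf_path, samples, records, contigs)
        panel_path = os.path.join(out_dir, "panel.tsv")
        panel.to_tsv(panel_path)
        truth_paths = {}
        for key, df in (
            ("sites", sites_df),
            ("individuals", individuals_df),
            ("breed_freqs", breed_freqs_df),
        ):
            p = os.path.join(out_dir, f"truth_{key}.tsv")
            df.to_csv(p, sep="\t", index=False)
            truth_paths[key] = p
        result.vcf_path = vcf_path
        result.panel_path = panel_path
        result.truth_paths = truth_paths
    return result


# ---------------------------------------------------------------------------
# Recipe: site selection and demo configurations
# ---------------------------------------------------------------------------

def _find_coding_site(
    model: GeneModel, kind: str, mature_pos: Optional[int] = None
) -> SimSite:
    """Locate a coding SNV of the requested kind on a gene model.

    kind: "missense" (at ``mature_pos``), "synonymous", or "signal_peptide"
    (a missense change within the signal peptide).
    """
    if kind == "missense":
        codons = [model.signal_peptide_len + mature_pos]
    elif kind == "signal_peptide":
        codons = list(range(2, model.signal_peptide_len + 1))
    else:
        codons = list(range(model.signal_peptide_len + 1, len(model.cds_sequence) // 3 + 1))
    for codon_no in codons:
        for within in (2, 1, 0) if kind == "synonymous" else (1, 0, 2):
            off = (codon_no - 1) * 3 + within + 1
            ref_t = model.cds_sequence[off - 1]
            for alt_t in "ACGT":
                if alt_t == ref_t:
                    continue
                eff = model.codon_effect(off, alt_t)
                if "*" in (eff.ref_aa, eff.alt_aa):
                    continue
                syn = eff.synonymous
                if (kind == "synonymous") != syn:
                    continue
                pos = model.cds_to_genomic(off)
                if model.strand == "+":
                    ref, alt = ref_t, alt_t
                else:
                    comp = str.maketrans("ACGT", "TGCA")
                    ref, alt = ref_t.translate(comp), alt_t.translate(comp)
                category = "synonymous" if syn else "missense"
                return SimSite(model.name, model.chrom, pos, ref, alt, category, off)
    raise ConfigError(f"{model.name}: no {kind} site found")


def _noncoding_site(model: GeneModel, category: str) -> SimSite:
    """A flanking/UTR/intronic SNV on the model (ref/alt arbitrary bases)."""
    if category == "upstream":
        pos = (model.start - 500) if model.strand == "+" else (model.end + 500)
    elif category == "downstream":
        pos = (model.end + 500) if model.strand == "+" else (model.start - 500)
    elif category == "five_prime_utr":
        # UTR bp sit between the transcription-first exon edge and the CDS
        pos = model.exons[0][0] + 2 if model.strand == "+" else model.exons[-1][1] - 2
    elif category == "three_prime_utr":
        pos = model.exons[-1][1] - 2 if model.strand == "+" else model.exons[0][0] + 2
    elif category == "intron":
        pos = model.exons[0][1] + 5  # just past the first exon
    else:
        raise ConfigError(f"unknown category {category}")
    got = model.classify_region(pos, "A", "G").value
    if got != category:
        raise ConfigError(f"{model.name}: expected {category} at {pos}, got {got}")
    return SimSite(model.name, model.chrom, pos, "A", "G", category, None)


def demo_sites(model: GeneModel) -> list[SimSite]:
    """The standard per-gene site layout: every region category is exercised.

    Order: upstream, 5'UTR, signal-peptide missense, two mature missense
    sites, synonymous, intron, 3'UTR, downstream. For CSN2 the first mature
    missense site is His67->Pro (the A2-family defining change).
    """
    mature_len = len(model.mature_protein)
    if model.name == "CSN2":
        m1 = 67  # His67 -> Pro67 by construction of the toy CDS
    else:
        m1 = max(1, mature_len // 3)
    m2 = max(m1 + 1, (2 * mature_len) // 3)
    return [
        _noncoding_site(model, "upstream"),
        _noncoding_site(model, "five_prime_utr"),
        _find_coding_site(model, "signal_peptide"),
        _find_coding_site(model, "missense", m1),
        _find_coding_site(model, "missense", m2),
        _find_coding_site(model, "synonymous"),
        _noncoding_site(model, "intron"),
        _noncoding_site(model, "three_prime_utr"),
        _noncoding_site(model, "downstream"),
    ]


#: index of each demo site within a haplotype string
DEMO_SITE_INDEX = {
    "upstream": 0,
    "five_prime_utr": 1,
    "signal_peptide": 2,
    "missense_1": 3,
    "missense_2": 4,
    "synonymous": 5,
    "intron": 6,
    "three_prime_utr": 7,
    "downstream": 8,
}


def _hap(*alt_idx: int) -> str:
    h = ["0"] * 9
    for i in alt_idx:
        h[i] = "1"
    return "".join(h)


def _demo_pool(style: str = "spread") -> list[str]:
    """Haplotypes over the nine demo sites; every site is polymorphic.

    ``spread`` (default): four haplotypes with crossing allele patterns, so
    double heterozygotes are genuinely phase-ambiguous and the EM has real
    work to do. ``nested``: three haplotypes ordered by inclusion
    (ref < A < B), which makes every genotype phase-resolvable — the regime
    for exact truth-recovery checks.
    """
    if style == "spread":
        return [
            _hap(),  # reference haplotype
            _hap(3, 6, 0),  # missense_1 + intron + upstream
            _hap(4, 5, 8),  # missense_2 + synonymous + downstream
            _hap(3, 4, 2, 1, 7),  # both missense + signal peptide + UTRs
        ]
    if style == "nested":
        return [
            _hap(),
            _hap(3, 6, 0),  # A: missense_1 + intron + upstream
            _hap(3, 6, 0, 4, 5, 2, 1, 7, 8),  # B: A plus every remaining site
        ]
    raise ConfigError(f"unknown pool style {style!r}")


#: default per-breed frequency vectors over the demo haplotypes
DEMO_BREED_FREQS = {
    "spread": {
        "Alpina": (0.4, 0.3, 0.2, 0.1),
        "Boreas": (0.1, 0.2, 0.3, 0.4),
        "Caldera": (0.55, 0.05, 0.25, 0.15),
    },
    "nested": {
        "Alpina": (0.5, 0.3, 0.2),
        "Boreas": (0.2, 0.3, 0.5),
        "Caldera": (0.6, 0.25, 0.15),
    },
}


def demo_config(
    seed: int,
    gene_names: Sequence[str] = ("CSN2", "CSN3"),
    n_per_breed: int = 30,
    breed_freqs: Optional[dict[str, Sequence[float]]] = None,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    pool_style: str = "spread",
    **kwargs,
) -> SyntheticConfig:
    """A ready-to-run cohort over the bundled toy genes.

    Three breeds by default, each with breed-specific frequencies over a
    shared haplotype pool (see :func:`_demo_pool` for the two pool styles).
    All rates default to the clean (error-free) regime.
    """
    models = bovine_milk_gene_models()
    models = {g: models[g] for g in gene_names}
    sites = {g: demo_sites(m) for g, m in models.items()}
    freqs = breed_freqs or DEMO_BREED_FREQS[pool_style]
    base_haps = _demo_pool(pool_style)
    breeds = []
    for name, fs in freqs.items():
        if len(fs) != len(base_haps) or abs(sum(fs) - 1.0) > 1e-9:
            raise ConfigError(f"breed {name}: need {len(base_haps)} frequencies summing to 1")
        pools = {g: dict(zip(base_haps, fs)) for g in gene_names}
        breeds.append(BreedSpec(name, n_per_breed, pools))
    return SyntheticConfig(
        models=models,
        sites=sites,
        breeds=breeds,
        error_rate=error_rate,
        missing_rate=missing_rate,
        seed=seed,
        **kwargs,
    )


def demo_catalog(config: SyntheticConfig) -> Catalog:
    """A catalog fixture covering part of the simulated haplotype space.

    Per gene: the reference variant (empty set) plus one named entry for the
    first missense haplotype, so pipelines see both known and novel calls.
    The CSN2 Pro67 entry is called A2 and the CSN3 entry A, echoing the
    field's variant names; substitution content is synthetic (it follows the
    toy CDS, not the real proteins).
    """
    cat = Catalog()
    known_name = {"CSN2": "A2", "CSN3": "A", "CSN1S1": "C", "CSN1S2": "B", "LALBA": "A", "PAEP": "A"}
    for gene, model in config.models.items():
        cat.add_gene(gene, model.reference_variant_name)
        site_infos = [s.to_site_info() for s in config.sites[gene]]
        hap = ["0"] * len(site_infos)
        hap[DEMO_SITE_INDEX["missense_1"]] = "1"
        subs = haplotype_to_substitutions(model, "".join(hap), site_infos)
        cat.add(gene, known_name.get(gene, "A"), subs)
    cat.validate()
    return cat


# ---------------------------------------------------------------------------
# YAML config and canonical fixtures
# ---------------------------------------------------------------------------

def config_from_yaml(path) -> SyntheticConfig:
    """Load a demo-recipe configuration from YAML.

    Keys: ``seed`` (required), ``genes`` (list of toy gene names), ``breeds``
    (mapping name -> {n, freqs}), ``error_rate``, ``missing_rate``,
    ``depth_mean``, ``depth_dispersion``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "seed" not in doc:
        raise ConfigError("YAML config must set a seed")
    breeds = doc.get("breeds")
    breed_freqs = (
        {name: tuple(spec["freqs"]) for name, spec in breeds.items()} if breeds else None
    )
    n_per_breed = (
        next(iter(breeds.values()))["n"] if breeds else 30
    )
    return demo_config(
        seed=int(doc["seed"]),
        gene_names=tuple(doc.get("genes", ("CSN2", "CSN3"))),
        n_per_breed=int(n_per_breed),
        breed_freqs=breed_freqs,
        error_rate=float(doc.get("error_rate", 0.0)),
        missing_rate=float(doc.get("missing_rate", 0.0)),
        depth_mean=float(doc.get("depth_mean", 10.0)),
        depth_dispersion=float(doc.get("depth_dispersion", 8.0)),
    )


def filter_fixture_records(models: dict[str, GeneModel]) -> tuple[list[str], list[dict], list[str]]:
    """The five-variant filter fixture: samples, records, expected kept keys.

    Hand-constructed inside the CSN3 window for four samples so that exactly
    three records survive the (3 alt reads / QUAL 20 / MQ 20 / >=2 carriers)
    filter: one fails QUAL at 19.9 and one is carried by a single individual.
    """
    m = models["CSN3"]
    samples = ["S1", "S2", "S3", "S4"]
    base = m.start + 1000

    def rec(pos, ref, alt, qual, mq, gts, ads):
        depths = np.array([10] * 4)
        return {
            "chrom": m.chrom,
            "pos": pos,
            "id": None,
            "ref": ref,
            "alt": alt,
            "qual": qual,
            "mq": mq,
            "genotypes": gts,
            "alt_depths": np.array(ads),
            "depths": depths,
        }

    records = [
        # passes everything: 2 carriers, 8 alt reads
        rec(base, "A", "G", 50.0, 60.0, [(0, 1), (0, 1), (0, 0), (0, 0)], [4, 4, 0, 0]),
        # fails QUAL at the 19.9 boundary
        rec(base + 10, "C", "T", 19.9, 60.0, [(0, 1), (0, 1), (0, 0), (0, 0)], [4, 4, 0, 0]),
        # passes: 3 carriers including one homozygote
        rec(base + 20, "G", "A", 45.0, 60.0, [(1, 1), (0, 1), (0, 1), (0, 0)], [9, 5, 5, 0]),
        # fails carriers: alt seen in one individual only
        rec(base + 30, "T", "C", 50.0, 60.0, [(1, 1), (0, 0), (0, 0), (0, 0)], [10, 0, 0, 0]),
        # passes at the exact thresholds: QUAL 20, MQ 20, 3 alt reads, 2 carriers
        rec(base + 40, "A", "C", 20.0, 20.0, [(0, 1), (0, 1), (0, 0), (0, 0)], [2, 1, 0, 0]),
    ]
    kept_keys = [f"{m.chrom}:{base}:A:G", f"{m.chrom}:{base + 20}:G:A", f"{m.chrom}:{base + 40}:A:C"]
    return samples, records, kept_keys


def make_fixture_suite(out_dir) -> dict[str, str]:
    """Write the canonical small fixtures used across the test suite.

    Contents: the toy six-gene model TSV, the five-variant filter VCF with its
    expected kept set, the two-individual double-heterozygote EM cohort (true
    answer: frequencies 0.75/0.25), and the naming catalog fixture. Every
    fixture is regenerated deterministically.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    models = bovine_milk_gene_models()

    p = os.path.join(out_dir, "gene_models.tsv")
    write_gene_models(models, p)
    paths["gene_models"] = p

    samples, records, kept = filter_fixture_records(models)
    p = os.path.join(out_dir, "filter_fixture.vcf")
    write_vcf(p, samples, records, [models["CSN3"].chrom])
    paths["filter_vcf"] = p
    with open(os.path.join(out_dir, "filter_fixture.README"), "w") as fh:
        fh.write(
            "Five SNVs in the CSN3 window; under thresholds 3 alt reads / QUAL 20 /\n"
            "MQ 20 / >=2 carriers exactly these pass:\n" + "\n".join(kept) + "\n"
        )

    # EM worked example: one hom-ref individual + one double heterozygote
    m = models["CSN3"]
    em_samples = ["I1", "I2"]
    em_records = [
        {
            "chrom": m.chrom,
            "pos": m.start + 3000 + k * 10,
            "id": None,
            "ref": "A",
            "alt": "G",
            "qual": 60.0,
            "mq": 60.0,
            "genotypes": [(0, 0), (0, 1)],
            "alt_depths": np.array([0, 5]),
            "depths": np.array([10, 10]),
        }
        for k in range(2)
    ]
    p = os.path.join(out_dir, "em_double_het.vcf")
    write_vcf(p, em_samples, em_records, [m.chrom])
    paths["em_vcf"] = p
    with open(os.path.join(out_dir, "em_double_het.README"), "w") as fh:
        fh.write(
            "Two biallelic sites; individual I1 hom-ref, I2 het at both.\n"
            "EM haplotype frequencies converge to {00: 0.75, 11: 0.25}.\n"
        )

    cfg = demo_config(seed=1)
    cat = demo_catalog(cfg)
    p = os.path.join(out_dir, "catalog.tsv")
    cat.to_tsv(p)
    paths["catalog"] = p
    with open(os.path.join(out_dir, "catalog.README"), "w") as fh:
        fh.write(
            "Synthetic naming catalog over the toy gene models: per gene the\n"
            "reference variant plus one known substitution set (CSN2 A2 = Pro67).\n"
            "Substitution content follows the toy CDS sequences, not the real proteins.\n"
        )
    return paths
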
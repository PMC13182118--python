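"""Reporting surfaces: variant-type composition, per-breed variant frequencies
and functional-variant summaries.

The composition table mirrors the usual annotation breakdown of milk-protein
gene surveys (5'UTR / missense / synonymous / intron / 3'UTR within the gene;
upstream and downstream flank counts reported separately), with percentages
rounded half-up to two decimals. Breed-level variant frequencies come from
breed-level EM haplotype estimates, not gene counting, so phase-ambiguous
individuals contribute properly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigError
from .gene_models import GeneModel, RegionCategory, WITHIN_GENE_CATEGORIES
from .haplotype_em import HaplotypeFrequencyEstimate
from .protein_variants import Catalog, ProteinVariant, Substitution


def _pct(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(Decimal("0.01"), ROUND_HALF_UP)
    )


@dataclass
class CompositionReport:
    """Counts and percentages of within-gene variant types, plus flank counts."""

    counts: dict[RegionCategory, int]
    percentages: dict[RegionCategory, float]
    total_within_gene: int
    upstream: int
    downstream: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": [c.value for c in self.counts],
                "count": list(self.counts.values()),
                "percent": [self.percentages[c] for c in self.counts],
            }
        )


def variant_type_table(
    categories: Iterable[RegionCategory],
) -> CompositionReport:
    """Tabulate region categories of annotated variants.

    Percentages are over within-gene variants only; upstream/downstream flank
    variants are counted separately. An empty input yields an empty report.
    """
    cats = list(categories)
    upstream = sum(1 for c in cats if c == RegionCategory.UPSTREAM)
    downstream = sum(1 for c in cats if c == RegionCategory.DOWNSTREAM)
    within = [c for c in cats if c in WITHIN_GENE_CATEGORIES]
    counts = {c: 0 for c in WITHIN_GENE_CATEGORIES}
    for c in within:
        counts[c] += 1
    counts = {c: n for c, n in counts.items() if n > 0}
    total = len(within)
    percentages = {c: _pct(n, total) for c, n in counts.items()}
    return CompositionReport(counts, percentages, total, upstream, downstream)


def polymorphic_site_percent(n_within_gene: int, models: Mapping[str, GeneModel]) -> float:
    """Within-gene polymorphic sites as a percentage of summed gene sizes (2 dp)."""
    total_bp = sum(m.length for m in models.values())
    if total_bp == 0:
        raise ConfigError("no gene models supplied")
    return float(
        (Decimal(n_within_gene) * 100 / Decimal(total_bp)).quantize(
            Decimal("0.01"), ROUND_HALF_UP
        )
    )


@dataclass
class FrequencyTable:
    """Named-variant frequencies for one gene in one scope (cohort or breed)."""

    scope: str
    gene: str
    frequencies: dict[str, float]
    n_chromosomes: int

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if self.frequencies and abs(total - 1.0) > 1e-6:
            raise ConfigError(
                f"{self.gene}/{self.scope}: variant frequencies sum to {total}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            {
                "scope": self.scope,
                "gene": self.gene,
                "variant": [n for n, _ in rows],
                "frequency": [f for _, f in rows],
                "n_chromosomes": self.n_chromosomes,
            }
        )


def variant_frequency_table(
    gene: str,
    scope: str,
    est: HaplotypeFrequencyEstimate,
    hap_to_name: Mapping[str, str],
) -> FrequencyTable:
    """Aggregate haplotype frequencies into named-variant frequencies.

    Haplotypes mapping to the same protein variant (e.g. differing only at
    synonymous or signal-peptide sites) have their frequencies summed.
    """
    freqs: dict[str, float] = {}
    for hap, f in est.frequencies.items():
        name = hap_to_name.get(hap)
        if name is None:
            continue
        freqs[name] = freqs.get(name, 0.0) + f
    # renormalize over named haplotypes (unnamed = unassigned mass, usually 0)
    total = sum(freqs.values())
    if total > 0:
        freqs = {n: f / total for n, f in freqs.items()}
    return FrequencyTable(scope, gene, freqs, est.n_chromosomes)


def breed_frequencies(
    gene: str,
    breed_estimates: Mapping[str, HaplotypeFrequencyEstimate],
    hap_to_name: Mapping[str, str],
) -> list[FrequencyTable]:
    """Per-breed named-variant frequency tables from breed-level EM estimates."""
    return [
        variant_frequency_table(gene, breed, est, hap_to_name)
        for breed, est in breed_estimates.items()
    ]


def frequency_tables_to_frame(tables: Iterable[FrequencyTable]) -> pd.DataFrame:
    frames = [t.to_frame() for t in tables]
    if not frames:
        return pd.DataFrame(columns=["scope", "gene", "variant", "frequency", "n_chromosomes"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Functional variants
# ---------------------------------------------------------------------------

#: mature beta-casein position whose proline defines the A2 family
A2_FAMILY_POSITION = 67


def carries_residue(
    variant_subs: frozenset[Substitution],
    model: GeneModel,
    mature_pos: int,
    residue: str,
) -> bool:
    """Does a variant (substitution set vs the reference) carry ``residue`` at a position?"""
    for s in variant_subs:
        if s.mature_pos == mature_pos:
            return s.alt_aa == residue
    return model.mature_residue(mature_pos) == residue


def a2_family_frequency(
    table: FrequencyTable, catalog: Catalog, model: GeneModel
) -> float:
    """Summed frequency of beta-casein variants carrying Pro at mature position 67.

    Membership is computed from substitution sets (not a name list), so novel
    Pro67 variants count automatically.
    """
    named = catalog.entries.get(table.gene, {})
    total = 0.0
    for name, f in table.frequencies.items():
        if name not in named:
            raise ConfigError(f"variant {name} missing from catalog for {table.gene}")
        if carries_residue(named[name], model, A2_FAMILY_POSITION, "P"):
            total += f
    return total


def functional_report(
    tables_by_gene: Mapping[str, Sequence[FrequencyTable]],
    catalog: Catalog,
    models: Mapping[str, GeneModel],
    panel_counts: Mapping[str, int],
    min_animals: int = 20,
) -> pd.DataFrame:
    """Per-breed frequencies of the key functional variants.

    Columns: beta-casein A2-family (Pro67) frequency, kappa-casein A and B,
    beta-lactoglobulin B. Only breeds with at least ``min_animals`` animals
    are reported (configurable).
    """
    by_breed: dict[str, dict[str, float]] = {}

    def put(breed: str, col: str, value: float) -> None:
        by_breed.setdefault(breed, {})[col] = value

    for gene, tables in tables_by_gene.items():
        for t in tables:
            if t.scope == "cohort" or panel_counts.get(t.scope, 0) < min_animals:
                continue
            if gene == "CSN2" and gene in models:
                put(t.scope, "beta_cn_A2_family", a2_family_frequency(t, catalog, models[gene]))
            elif gene == "CSN3":
                put(t.scope, "kappa_cn_A", t.frequencies.get("A", 0.0))
                put(t.scope, "kappa_cn_B", t.frequencies.get("B", 0.0))
            elif gene == "PAEP":
                put(t.scope, "beta_lg_B", t.frequencies.get("B", 0.0))
    rows = [{"breed": b, "n_animals": panel_counts.get(b, 0), **cols} for b, cols in sorted(by_breed.items())]
    return pd.DataFrame(rows)
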
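"""Translate coding haplotypes to mature-protein substitution sets and name them.

A milk-protein variant is a combination of amino-acid substitutions in the
mature protein (after signal-peptide cleavage), so a coding haplotype maps to
a set of (position, ref, alt) substitutions: signal-peptide changes and
synonymous alleles drop out, and multiple SNVs inside one codon are
re-translated jointly from the edited codon.

Known variants are matched by exact substitution-set equality against a
user-supplied catalog. Unmatched sets are novel and receive a hierarchical
dotted name: a novel variant derived from base variant X becomes X.1, X.2, ...
and further layers nest (X.1.1), recording successive layers of substitutions
on the base. The base is the catalogued variant whose substitution set is a
subset of the novel set with maximal overlap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigError, FormatError, IntegrityError, RangeError
from .gene_models import GeneModel
from .haplotype_em import SiteInfo


@dataclass(frozen=True, order=True)
class Substitution:
    """One amino-acid substitution at a 1-based mature-protein position."""

    mature_pos: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.mature_pos < 1:
            raise ConfigError("mature position must be >= 1")
        if self.ref_aa == self.alt_aa:
            raise ConfigError("ref and alt residues must differ")

    def __str__(self) -> str:
        return f"{self.mature_pos}:{self.ref_aa}>{self.alt_aa}"

    @classmethod
    def parse(cls, text: str) -> "Substitution":
        m = re.fullmatch(r"(\d+):([A-Z*])>([A-Z*])", text.strip())
        if not m:
            raise FormatError(f"cannot parse substitution {text!r}")
        return cls(int(m.group(1)), m.group(2), m.group(3))


def format_substitutions(subs: Iterable[Substitution]) -> str:
    return ";".join(str(s) for s in sorted(subs)) or "-"


def parse_substitutions(text: str) -> frozenset[Substitution]:
    text = text.strip()
    if text in ("", "-", "."):
        return frozenset()
    return frozenset(Substitution.parse(t) for t in text.split(";"))


@dataclass
class ProteinVariant:
    """A named mature-protein substitution set with occurrence bookkeeping."""

    gene: str
    name: str
    substitutions: frozenset[Substitution]
    status: str  # "known" | "novel"
    occurrences: int = 0
    low_confidence: bool = False
    unconfirmed: bool = False
    breed_occurrences: dict[str, int] = field(default_factory=dict)
    haplotype: Optional[str] = None

    def __post_init__(self) -> None:
        positions = [s.mature_pos for s in self.substitutions]
        if len(positions) != len(set(positions)):
            raise IntegrityError(f"{self.gene} {self.name}: duplicate substitution positions")


# ---------------------------------------------------------------------------
# Haplotype -> substitutions
# ---------------------------------------------------------------------------

def haplotype_to_substitutions(
    model: GeneModel,
    haplotype: str,
    sites: Sequence[SiteInfo],
) -> frozenset[Substitution]:
    """Substitution set of a coding haplotype relative to the reference protein.

    ``haplotype`` is a '0'/'1' allele string over ``sites`` (ordered by CDS
    offset; each site needs ``cds_offset`` set, alt base stored in genomic
    orientation). Codons carrying several alternate alleles are re-translated
    jointly. Changes within the signal peptide and synonymous changes yield no
    substitution; a stop gain/loss is reported with '*' as the residue.
    """
    if len(haplotype) != len(sites):
        raise IntegrityError("haplotype length does not match site count")
    edits: dict[int, dict[int, str]] = {}  # codon index -> {within-codon pos: alt base}
    for allele, site in zip(haplotype, sites):
        if allele == "0":
            continue
        if allele != "1":
            raise IntegrityError(f"invalid haplotype allele {allele!r}")
        off = site.cds_offset
        if off is None:
            raise IntegrityError(f"site {site.chrom}:{site.pos} has no CDS offset")
        alt_t = site.alt if model.strand == "+" else str(Seq(site.alt).complement())
        ref_t = site.ref if model.strand == "+" else str(Seq(site.ref).complement())
        if model.cds_sequence[off - 1] != ref_t:
            raise IntegrityError(
                f"site {site.chrom}:{site.pos}: ref allele inconsistent with CDS"
            )
        codon_idx = (off - 1) // 3
        edits.setdefault(codon_idx, {})[(off - 1) % 3] = alt_t
    subs = []
    for codon_idx, bases in edits.items():
        codon = list(model.cds_sequence[codon_idx * 3 : codon_idx * 3 + 3])
        for within, alt in bases.items():
            codon[within] = alt
        ref_aa = str(Seq(model.cds_sequence[codon_idx * 3 : codon_idx * 3 + 3]).translate())
        alt_aa = str(Seq("".join(codon)).translate())
        precursor_pos = codon_idx + 1
        if precursor_pos <= model.signal_peptide_len or ref_aa == alt_aa:
            continue
        subs.append(Substitution(precursor_pos - model.signal_peptide_len, ref_aa, alt_aa))
    return frozenset(subs)


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

_DOTTED = re.compile(r"^(?P<base>.+)\.(?P<idx>\d+)$")


@dataclass
class Catalog:
    """Per-gene registry of named protein variants and their substitution sets."""

    entries: dict[str, dict[str, frozenset[Substitution]]] = field(default_factory=dict)
    reference_names: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for gene, named in self.entries.items():
            ref = self.reference_names.get(gene)
            if ref is None or ref not in named:
                raise ConfigError(f"{gene}: catalog lacks its reference variant")
            if named[ref]:
                raise ConfigError(f"{gene}: reference variant {ref} must have empty set")
            for name in named:
                m = _DOTTED.match(name)
                if m and m.group("base") not in named:
                    raise ConfigError(f"{gene}: dotted name {name} lacks base {m.group('base')}")

    def add_gene(self, gene: str, reference_name: str) -> None:
        self.entries.setdefault(gene, {})[reference_name] = frozenset()
        self.reference_names[gene] = reference_name

    def add(self, gene: str, name: str, subs: frozenset[Substitution]) -> None:
        named = self.entries.setdefault(gene, {})
        if name in named:
            raise ConfigError(f"{gene}: duplicate variant name {name}")
        named[name] = frozenset(subs)

    def match(self, gene: str, subs: frozenset[Substitution]) -> Optional[str]:
        for name, cat_subs in self.entries.get(gene, {}).items():
            if cat_subs == subs:
                return name
        return None

    def names(self, gene: str) -> list[str]:
        return list(self.entries.get(gene, {}))

    def copy(self) -> "Catalog":
        return Catalog(
            {g: dict(named) for g, named in self.entries.items()},
            dict(self.reference_names),
        )

    # -- TSV round trip -----------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "Catalog":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"gene", "name", "substitutions", "is_reference"}
        if not required <= set(df.columns):
            raise FormatError(f"catalog TSV needs columns {sorted(required)}")
        cat = cls()
        for row in df.itertuples(index=False):
            cat.add(row.gene, row.name, parse_substitutions(row.substitutions))
            if str(row.is_reference) in ("1", "True", "true"):
                cat.reference_names[row.gene] = row.name
        cat.validate()
        return cat

    def to_tsv(self, path) -> None:
        rows = []
        for gene in sorted(self.entries):
            for name in sorted(self.entries[gene]):
                rows.append(
                    {
                        "gene": gene,
                        "name": name,
                        "substitutions": format_substitutions(self.entries[gene][name]),
                        "is_reference": int(self.reference_names.get(gene) == name),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def match_catalog(
    subs: frozenset[Substitution], catalog: Catalog, gene: str
) -> tuple[Optional[str], str]:
    """Exact-match a substitution set: (name, "known") or (None, "novel")."""
    name = catalog.match(gene, subs)
    if name is not None:
        return name, "known"
    return None, "novel"


def assign_name(
    novel_subs: frozenset[Substitution],
    catalog: Catalog,
    gene: str,
    occurrences: Optional[dict[str, int]] = None,
) -> str:
    """Name a novel substitution set by its deepest catalogued base, and register it.

    The base is the catalogued variant whose substitution set is a subset of
    the novel set with maximal overlap (dotted names are eligible, so layers
    nest). Ties prefer the base with more occurrences in the current dataset,
    then the lexicographically smaller name. The child index is one past the
    base's highest existing child, and the new name is appended to the catalog
    so later assignments see it.
    """
    named = catalog.entries.get(gene)
    if not named:
        raise ConfigError(f"no catalog entries for gene {gene}")
    subsets = [(name, s) for name, s in named.items() if s <= novel_subs]
    if not subsets:
        raise IntegrityError(f"{gene}: no subset base found (reference missing?)")
    best_overlap = max(len(s) for _, s in subsets)
    occ = occurrences or {}
    base = min(
        (name for name, s in subsets if len(s) == best_overlap),
        key=lambda name: (-occ.get(name, 0), name),
    )
    child_re = re.compile(re.escape(base) + r"\.(\d+)$")
    existing = [int(m.group(1)) for n in named if (m := child_re.match(n))]
    name = f"{base}.{max(existing, default=0) + 1}"
    catalog.add(gene, name, novel_subs)
    return name


def name_variants(
    gene: str,
    hap_subs: dict[str, frozenset[Substitution]],
    occurrences: dict[str, int],
    catalog: Catalog,
    carriers: Optional[dict[str, int]] = None,
    min_copies: int = 2,
    min_carriers: int = 2,
) -> list[ProteinVariant]:
    """Match or name every observed haplotype's substitution set.

    ``hap_subs`` maps haplotype strings to substitution sets; haplotypes with
    identical sets collapse into one protein variant whose occurrence count is
    the summed haplotype copies. Novel variants are processed in descending
    occurrence order (ties by the lexicographic substitution listing) so
    naming is deterministic; novel sets observed below ``min_copies`` copies
    and ``min_carriers`` carriers are flagged ``unconfirmed`` but still named,
    after all confirmed variants.

    Names assigned here are appended to ``catalog`` (pass a copy to keep the
    input catalog pristine).
    """
    by_subs: dict[frozenset[Substitution], dict] = {}
    for hap, subs in hap_subs.items():
        rec = by_subs.setdefault(subs, {"occ": 0, "carriers": 0, "haps": []})
        rec["occ"] += occurrences.get(hap, 0)
        rec["carriers"] += (carriers or {}).get(hap, occurrences.get(hap, 0))
        rec["haps"].append(hap)
    name_occ: dict[str, int] = {}
    results: list[ProteinVariant] = []
    novel: list[tuple[frozenset[Substitution], dict]] = []
    for subs, rec in by_subs.items():
        name, status = match_catalog(subs, catalog, gene)
        if status == "known":
            name_occ[name] = rec["occ"]
            results.append(
                ProteinVariant(gene, name, subs, "known", rec["occ"], haplotype=min(rec["haps"]))
            )
        else:
            novel.append((subs, rec))

    def sort_key(item):
        subs, rec = item
        return (-rec["occ"], format_substitutions(subs))

    confirmed = [x for x in novel if x[1]["occ"] >= min_copies or x[1]["carriers"] >= min_carriers]
    unconfirmed = [x for x in novel if x not in confirmed]
    for subs, rec in sorted(confirmed, key=sort_key) + sorted(unconfirmed, key=sort_key):
        name = assign_name(subs, catalog, gene, name_occ)
        name_occ[name] = rec["occ"]
        results.append(
            ProteinVariant(
                gene,
                name,
                subs,
                "novel",
                rec["occ"],
                unconfirmed=(subs, rec) in unconfirmed,
                haplotype=min(rec["haps"]),
            )
        )
    return results


# ---------------------------------------------------------------------------
# kappa-casein functional regions
# ---------------------------------------------------------------------------

#: mature kappa-casein length in residues
KAPPA_CN_LENGTH = 169


def kappa_region(sub: Substitution | int) -> str:
    """Functional region of a mature kappa-casein position.

    Residues 1-95 form para-kappa-casein (micelle-retained after chymosin
    cleavage), 105/106 the chymosin cleavage site (Phe105-Met106), and
    113-169 the C-terminal part of the soluble caseinomacropeptide (CMP).
    """
    pos = sub.mature_pos if isinstance(sub, Substitution) else int(sub)
    if not 1 <= pos <= KAPPA_CN_LENGTH:
        raise RangeError(f"kappa-casein mature position {pos} out of 1..{KAPPA_CN_LENGTH}")
    if pos <= 95:
        return "para_kappa"
    if pos in (105, 106):
        return "chymosin_site"
    if 113 <= pos <= 169:
        return "cmp"
    return "other"
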
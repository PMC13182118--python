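"""Gene structures and coordinate conversions for the six bovine milk-protein genes.

All coordinates are 1-based inclusive, matching VCF and the usual genome-browser
convention. A :class:`GeneModel` carries the genomic layout (exons, CDS bounds,
strand) together with the reference coding sequence in transcription
orientation, so that a genomic position can be mapped to a CDS offset, a codon,
a precursor-protein position and finally a mature-protein position (after
removal of the N-terminal signal peptide).

The module also classifies single-nucleotide variants into the region
categories used for variant-type composition tables: upstream/downstream
flanks, UTRs, introns, and synonymous/missense coding changes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigError, FormatError, RangeError, UnsupportedVariantError

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Flanking distance analysed around each gene, in bp.
DEFAULT_FLANK = 2000


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class RegionCategory(str, Enum):
    """Region/consequence classes for single-nucleotide variants.

    ``coding_other`` covers coding changes that are neither simple synonymous
    nor simple missense events (stop gain/loss).
    """

    UPSTREAM = "upstream"
    FIVE_PRIME_UTR = "five_prime_utr"
    INTRON = "intron"
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    THREE_PRIME_UTR = "three_prime_utr"
    DOWNSTREAM = "downstream"
    CODING_OTHER = "coding_other"


#: Categories that count as "within gene" for composition tables.
WITHIN_GENE_CATEGORIES = (
    RegionCategory.FIVE_PRIME_UTR,
    RegionCategory.MISSENSE,
    RegionCategory.SYNONYMOUS,
    RegionCategory.INTRON,
    RegionCategory.THREE_PRIME_UTR,
    RegionCategory.CODING_OTHER,
)


@dataclass(frozen=True)
class CodonEffect:
    """Consequence of substituting one base within the coding sequence."""

    precursor_pos: int
    ref_aa: str
    alt_aa: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa


@dataclass
class GeneModel:
    """One milk-protein gene: layout, coding sequence and protein metadata.

    Parameters
    ----------
    name : str
        Gene symbol (e.g. ``CSN3``).
    chrom : str
        Chromosome label.
    start, end : int
        1-based inclusive genomic bounds of the gene.
    strand : str
        ``"+"`` (forward) or ``"-"`` (reverse).
    exons : list of (int, int)
        Non-overlapping exon intervals, sorted by genomic position.
    cds_start, cds_end : int
        Genomic bounds of the coding sequence.
    signal_peptide_len : int
        Number of N-terminal residues cleaved to yield the mature protein.
    cds_sequence : str
        Reference coding sequence in transcription orientation (for
        reverse-strand genes this is the reverse complement of the genomic
        reference over the CDS exons). Length must be a multiple of 3.
    flank : int
        Flanking distance in bp considered part of the analysed region.
    reference_variant_name : str
        Name of the protein variant encoded by the reference sequence.
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    signal_peptide_len: int
    cds_sequence: str
    flank: int = DEFAULT_FLANK
    reference_variant_name: str = "REF"
    _cds_intervals: list[tuple[int, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigError(f"{self.name}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ConfigError(f"{self.name}: start > end")
        last = 0
        for s, e in self.exons:
            if s > e or s <= last:
                raise ConfigError(f"{self.name}: exons must be sorted and non-overlapping")
            last = e
        if not (self.start <= self.exons[0][0] and self.exons[-1][1] <= self.end):
            raise ConfigError(f"{self.name}: exons outside gene bounds")
        self.cds_sequence = self.cds_sequence.upper()
        if len(self.cds_sequence) % 3 != 0:
            raise ConfigError(f"{self.name}: CDS length not a multiple of 3")
        self._cds_intervals = [
            (max(s, self.cds_start), min(e, self.cds_end))
            for s, e in self.exons
            if e >= self.cds_start and s <= self.cds_end
        ]
        span = sum(e - s + 1 for s, e in self._cds_intervals)
        if span != len(self.cds_sequence):
            raise ConfigError(
                f"{self.name}: CDS sequence length {len(self.cds_sequence)} != "
                f"exonic CDS span {span}"
            )
        n_codons = len(self.cds_sequence) // 3
        if not (0 <= self.signal_peptide_len < n_codons - 1):
            raise ConfigError(f"{self.name}: signal peptide length out of range")

    # -- basic geometry -----------------------------------------------------

    @property
    def length(self) -> int:
        """Gene size in bp, ``end - start + 1``."""
        return self.end - self.start + 1

    @property
    def region_start(self) -> int:
        return self.start - self.flank

    @property
    def region_end(self) -> int:
        return self.end + self.flank

    def contains(self, chrom: str, pos: int) -> bool:
        """True if ``pos`` lies within the gene ± flank on the right chromosome."""
        return chrom == self.chrom and self.region_start <= pos <= self.region_end

    # -- protein views ------------------------------------------------------

    @property
    def precursor_protein(self) -> str:
        """Translation of the reference CDS (single-letter amino acids)."""
        return str(Seq(self.cds_sequence).translate())

    @property
    def mature_protein(self) -> str:
        """Precursor protein minus the signal peptide, minus any trailing stop."""
        prot = self.precursor_protein.rstrip("*")
        return prot[self.signal_peptide_len:]

    def mature_residue(self, mature_pos: int) -> str:
        """Reference residue at a 1-based mature-protein position."""
        prot = self.mature_protein
        if not 1 <= mature_pos <= len(prot):
            raise RangeError(f"{self.name}: mature position {mature_pos} out of range")
        return prot[mature_pos - 1]

    # -- coordinate conversions --------------------------------------------

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """Map a genomic position to a 1-based CDS offset, or None if non-coding.

        The offset runs along ``cds_sequence`` in transcription orientation:
        reverse-strand genes count from ``cds_end`` downward.
        """
        if not self.region_start <= pos <= self.region_end:
            raise RangeError(f"{self.name}: position {pos} outside gene ± {self.flank} bp")
        offset = 0
        if self.strand == "+":
            for s, e in self._cds_intervals:
                if s <= pos <= e:
                    return offset + (pos - s) + 1
                offset += e - s + 1
        else:
            for s, e in reversed(self._cds_intervals):
                if s <= pos <= e:
                    return offset + (e - pos) + 1
                offset += e - s + 1
        return None

    def cds_to_genomic(self, cds_offset: int) -> int:
        """Inverse of :meth:`genomic_to_cds` for coding offsets."""
        if not 1 <= cds_offset <= len(self.cds_sequence):
            raise RangeError(f"{self.name}: CDS offset {cds_offset} out of range")
        remaining = cds_offset
        if self.strand == "+":
            for s, e in self._cds_intervals:
                n = e - s + 1
                if remaining <= n:
                    return s + remaining - 1
                remaining -= n
        else:
            for s, e in reversed(self._cds_intervals):
                n = e - s + 1
                if remaining <= n:
                    return e - remaining + 1
                remaining -= n
        raise AssertionError("unreachable")

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    # -- consequences -------------------------------------------------------

    def codon_effect(self, cds_offset: int, alt_base: str) -> CodonEffect:
        """Effect of substituting ``alt_base`` (transcription orientation) at a CDS offset."""
        if not 1 <= cds_offset <= len(self.cds_sequence):
            raise RangeError(f"{self.name}: CDS offset {cds_offset} out of range")
        alt_base = alt_base.upper()
        if alt_base not in "ACGT":
            raise UnsupportedVariantError(f"invalid base {alt_base!r}")
        codon_idx = (cds_offset - 1) // 3
        within = (cds_offset - 1) % 3
        codon = self.cds_sequence[codon_idx * 3 : codon_idx * 3 + 3]
        alt_codon = codon[:within] + alt_base + codon[within + 1 :]
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        return CodonEffect(codon_idx + 1, ref_aa, alt_aa)

    def classify_region(self, pos: int, ref: str, alt: str) -> RegionCategory:
        """Classify a SNV at ``pos`` into a :class:`RegionCategory`.

        ``ref``/``alt`` are single bases in genomic (plus-strand) orientation.
        Upstream/downstream are relative to the transcription direction, so on
        reverse-strand genes the higher-coordinate flank is upstream.
        """
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            raise UnsupportedVariantError(f"only SNVs supported, got {ref}>{alt}")
        if not self.region_start <= pos <= self.region_end:
            raise RangeError(f"{self.name}: position {pos} outside gene ± {self.flank} bp")
        if pos < self.start:
            return RegionCategory.UPSTREAM if self.strand == "+" else RegionCategory.DOWNSTREAM
        if pos > self.end:
            return RegionCategory.DOWNSTREAM if self.strand == "+" else RegionCategory.UPSTREAM
        cds_off = self.genomic_to_cds(pos)
        if cds_off is not None:
            alt_t = alt if self.strand == "+" else alt.translate(_COMPLEMENT)
            eff = self.codon_effect(cds_off, alt_t)
            if "*" in (eff.ref_aa, eff.alt_aa) and eff.ref_aa != eff.alt_aa:
                return RegionCategory.CODING_OTHER
            return RegionCategory.SYNONYMOUS if eff.synonymous else RegionCategory.MISSENSE
        if self.in_exon(pos):
            before_cds = pos < self.cds_start
            if self.strand == "+":
                return RegionCategory.FIVE_PRIME_UTR if before_cds else RegionCategory.THREE_PRIME_UTR
            return RegionCategory.THREE_PRIME_UTR if before_cds else RegionCategory.FIVE_PRIME_UTR
        return RegionCategory.INTRON


def gene_length(model: GeneModel) -> int:
    """Gene size in bp (``end − start + 1``)."""
    return model.length


# ---------------------------------------------------------------------------
# Bundled six-gene fixture (Table-3-style coordinates with synthetic CDS)
# ---------------------------------------------------------------------------

# (chrom, start, end, strand, n_exons, printed_size, signal_peptide_len,
#  mature protein length used for the synthetic CDS, reference variant name)
_MILK_GENES = {
    "CSN1S1": ("6", 85_411_118, 85_429_268, "+", 19, 18_151, 15, 199, "B"),
    "CSN2": ("6", 85_449_164, 85_457_744, "-", 9, 8_581, 15, 209, "B"),
    "CSN1S2": ("6", 85_529_905, 85_548_556, "+", 18, 18_652, 15, 207, "A"),
    "CSN3": ("6", 85_645_854, 85_658_926, "+", 5, 13_073, 21, 169, "B"),
    "LALBA": ("5", 31_183_432, 31_186_209, "+", 4, 2_778, 19, 123, "B"),
    "PAEP": ("11", 103_255_824, 103_260_873, "+", 7, 5_049, 16, 162, "B"),
}

#: Gene sizes as printed in the reference annotation table (used by
#: :func:`validate_gene_sizes`; PAEP is printed one bp short of the
#: arithmetic size).
PRINTED_GENE_SIZES = {g: row[5] for g, row in _MILK_GENES.items()}

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if str(Seq(a + b + c).translate()) != "*"
]


def _synthetic_cds(name: str, n_codons: int, pinned: dict[int, str] | None = None) -> str:
    """Deterministic synthetic CDS: ATG start, no internal stops.

    ``pinned`` maps 1-based codon numbers to fixed codons (used to give the
    toy CSN2 its His67/Arg122 mature-protein landmarks).
    """
    rng = np.random.default_rng(zlib.crc32(name.encode()))
    codons = ["ATG"] + [
        _NON_STOP_CODONS[i] for i in rng.integers(0, len(_NON_STOP_CODONS), n_codons - 1)
    ]
    for codon_no, codon in (pinned or {}).items():
        codons[codon_no - 1] = codon
    return "".join(codons)


def _toy_layout(
    start: int, end: int, n_exons: int, cds_len: int, utr: int = 60
) -> tuple[list[tuple[int, int]], int, int]:
    """Spread ``n_exons`` exons across [start, end] holding ``cds_len`` coding bp.

    Both terminal exons carry ``utr`` non-coding bp at their outer edge, so the
    layout is symmetric and valid for either strand.
    """
    chunk = cds_len // n_exons
    lens = [chunk] * n_exons
    lens[-1] += cds_len - chunk * n_exons
    lens[0] += utr
    lens[-1] += utr
    span = end - start + 1
    total = sum(lens)
    if total > span:
        raise ConfigError("gene span too small for requested layout")
    exons = []
    if n_exons == 1:
        exons = [(start, start + lens[0] - 1)]
    else:
        gap = (span - total) // (n_exons - 1)
        pos = start
        for ln in lens[:-1]:
            exons.append((pos, pos + ln - 1))
            pos += ln + gap
        exons.append((end - lens[-1] + 1, end))
    cds_start = exons[0][0] + utr
    cds_end = exons[-1][1] - utr
    return exons, cds_start, cds_end


def bovine_milk_gene_models(flank: int = DEFAULT_FLANK) -> dict[str, GeneModel]:
    """The six milk-protein genes with real genomic coordinates and synthetic CDS.

    Coordinates, strand and exon counts follow the ARS-UCD1.2 annotation of
    CSN1S1, CSN2, CSN1S2, CSN3, LALBA and PAEP; exon boundaries and coding
    sequences are synthetic stand-ins sized like the real proteins, intended
    for testing and simulation (real CDS sequences are user-provided input).
    """
    models = {}
    for name, (chrom, start, end, strand, n_exons, _size, spl, mature_len, ref_var) in _MILK_GENES.items():
        n_codons = spl + mature_len
        pinned = None
        if name == "CSN2":
            # mature 67 = His, mature 122 = Arg: the reference encodes the
            # B-like protein; Pro67 (A2 family) is reachable by one SNV (CAT->CCT)
            pinned = {spl + 67: "CAT", spl + 122: "CGT"}
        cds = _synthetic_cds(name, n_codons, pinned)
        exons, cds_start, cds_end = _toy_layout(start, end, n_exons, len(cds))
        models[name] = GeneModel(
            name=name,
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
            signal_peptide_len=spl,
            cds_sequence=cds,
            flank=flank,
            reference_variant_name=ref_var,
        )
    return models


def validate_gene_sizes(
    models: dict[str, GeneModel], printed_sizes: dict[str, int] | None = None
) -> list[str]:
    """Compare arithmetic gene sizes against printed annotation sizes.

    Returns human-readable messages for any discrepancy instead of raising:
    printed tables occasionally disagree with ``end − start + 1`` by one bp
    (PAEP in the bundled set), and the arithmetic convention is kept.
    """
    printed = printed_sizes if printed_sizes is not None else PRINTED_GENE_SIZES
    messages = []
    for name, model in models.items():
        if name in printed and model.length != printed[name]:
            messages.append(
                f"{name}: printed size {printed[name]} != end-start+1 = {model.length}"
            )
    return messages


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = [
    "gene",
    "chrom",
    "start",
    "end",
    "strand",
    "exons",
    "cds_start",
    "cds_end",
    "signal_peptide_len",
    "cds_sequence",
    "reference_variant_name",
]


def read_gene_models(path, flank: int = DEFAULT_FLANK) -> dict[str, GeneModel]:
    """Read gene models from a TSV file.

    The ``exons`` column is a comma-separated list of ``start-end`` intervals.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene model table missing columns: {missing}")
    models = {}
    for row in df.itertuples(index=False):
        exons = [
            (int(a), int(b))
            for a, b in (iv.split("-") for iv in str(row.exons).split(","))
        ]
        models[row.gene] = GeneModel(
            name=row.gene,
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            exons=exons,
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            signal_peptide_len=int(row.signal_peptide_len),
            cds_sequence=row.cds_sequence,
            flank=flank,
            reference_variant_name=row.reference_variant_name,
        )
    return models


def write_gene_models(models: dict[str, GeneModel], path) -> None:
    """Write gene models to the TSV layout read by :func:`read_gene_models`."""
    rows = []
    for m in models.values():
        rows.append(
            {
                "gene": m.name,
                "chrom": m.chrom,
                "start": m.start,
                "end": m.end,
                "strand": m.strand,
                "exons": ",".join(f"{s}-{e}" for s, e in m.exons),
                "cds_start": m.cds_start,
                "cds_end": m.cds_end,
                "signal_peptide_len": m.signal_peptide_len,
                "cds_sequence": m.cds_sequence,
                "reference_variant_name": m.reference_variant_name,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
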
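"""Read multi-sample VCF records for the gene regions and apply quality filters.

Filtering follows the whole-genome-sequencing practice for milk-protein gene
surveys: an SNV is retained only when the cohort shows at least three reads
supporting the alternate allele, site quality (phred) >= 20, mapping quality
>= 20, and the alternate allele is carried by at least two distinct
individuals. Genotypes supported by read depth below 6 are flagged
low-confidence downstream rather than removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import FormatError, PanelError
from .gene_models import GeneModel

MISSING = -1


@dataclass
class SamplePanel:
    """Ordered sample list with a sample -> breed assignment."""

    samples: list[str]
    breed_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.samples if s not in self.breed_of]
        if missing:
            raise PanelError(f"samples without breed assignment: {missing[:5]}")

    @property
    def breeds(self) -> list[str]:
        seen = dict.fromkeys(self.breed_of[s] for s in self.samples)
        return list(seen)

    def breed_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.samples:
            counts[self.breed_of[s]] = counts.get(self.breed_of[s], 0) + 1
        return counts

    def small_breeds(self, min_samples: int = 2) -> list[str]:
        """Breeds represented by fewer than ``min_samples`` animals."""
        return [b for b, n in self.breed_counts().items() if n < min_samples]

    @classmethod
    def from_tsv(cls, path) -> "SamplePanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample_id", "breed"} <= set(df.columns):
            raise FormatError("panel TSV needs columns: sample_id, breed")
        return cls(list(df["sample_id"]), dict(zip(df["sample_id"], df["breed"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample_id": self.samples, "breed": [self.breed_of[s] for s in self.samples]}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class SequenceVariant:
    """A biallelic SNV site with per-sample genotypes and depths.

    ``genotypes`` holds one ``(a1, a2)`` pair per panel sample, alleles coded
    0 (ref), 1 (alt) or -1 (missing). ``alt_depths``/``depths`` are per-sample
    read counts, or None when the VCF lacks AD/DP.
    """

    chrom: str
    pos: int
    id: Optional[str]
    ref: str
    alt: str
    qual: Optional[float]
    mq: Optional[float]
    genotypes: list[tuple[int, int]]
    alt_depths: Optional[np.ndarray] = None
    depths: Optional[np.ndarray] = None
    gene: Optional[str] = None

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def carriers(self) -> int:
        """Number of individuals carrying >= 1 called alt allele."""
        return sum(1 for a, b in self.genotypes if a == 1 or b == 1)

    def total_alt_reads(self) -> Optional[int]:
        if self.alt_depths is None:
            return None
        return int(np.sum(self.alt_depths))

    def alt_allele_count(self) -> int:
        return sum((a == 1) + (b == 1) for a, b in self.genotypes)

    def called_chromosomes(self) -> int:
        return sum((a != MISSING) + (b != MISSING) for a, b in self.genotypes)


@dataclass
class ReadStats:
    """Bookkeeping from :func:`read_vcf`."""

    n_records: int = 0
    n_kept: int = 0
    n_outside: int = 0
    n_skipped_indel: int = 0
    n_skipped_non_snv_alt: int = 0


def _assign_gene(chrom: str, pos: int, models: Sequence[GeneModel]) -> Optional[str]:
    for m in models:
        if m.contains(chrom, pos):
            return m.name
    return None


def read_vcf(
    path, panel: SamplePanel, models: Sequence[GeneModel]
) -> tuple[list[SequenceVariant], ReadStats]:
    """Read SNVs within any gene ± flank window, decomposing multiallelic sites.

    Samples are reordered to panel order; a sample set mismatch raises
    :class:`PanelError`. Indel/MNV alternate alleles are skipped and counted.
    In decomposed records, genotype alleles equal to a different alternate are
    treated as reference for the biallelic view.
    """
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if set(vcf_samples) != set(panel.samples):
        raise PanelError(
            f"VCF samples do not match panel ({len(vcf_samples)} vs {len(panel.samples)})"
        )
    order = [vcf_samples.index(s) for s in panel.samples]
    stats = ReadStats()
    out: list[SequenceVariant] = []
    for rec in vcf:
        stats.n_records += 1
        gene = _assign_gene(rec.CHROM, rec.POS, models)
        if gene is None:
            stats.n_outside += 1
            continue
        if len(rec.REF) != 1:
            stats.n_skipped_indel += 1
            continue
        raw_gt = rec.genotypes
        if raw_gt is None:
            raise FormatError(f"record {rec.CHROM}:{rec.POS} has no GT field")
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        mq = rec.INFO.get("MQ")
        any_snv = False
        for alt_idx, alt in enumerate(rec.ALT):
            if len(alt) != 1 or alt not in "ACGT":
                continue
            any_snv = True
            allele_code = alt_idx + 1
            genotypes = []
            for i in order:
                g = raw_gt[i]
                alleles = g[:-1]  # last element is phasing flag
                pair = tuple(
                    MISSING if a is None or a < 0 else (1 if a == allele_code else 0)
                    for a in alleles
                )
                if len(pair) == 1:  # haploid record; duplicate for diploid view
                    pair = (pair[0], pair[0])
                genotypes.append(pair)
            alt_depths = None
            depths = None
            if ad is not None and ad.shape[1] > allele_code:
                alt_depths = np.maximum(ad[order, allele_code], 0).astype(int)
                depths = np.maximum(ad[order], 0).clip(min=0).sum(axis=1).astype(int)
            if dp is not None:
                depths = np.maximum(np.asarray(dp).reshape(-1)[order], 0).astype(int)
            out.append(
                SequenceVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    id=rec.ID,
                    ref=rec.REF,
                    alt=alt,
                    qual=rec.QUAL,
                    mq=float(mq) if mq is not None else None,
                    genotypes=genotypes,
                    alt_depths=alt_depths,
                    depths=depths,
                    gene=gene,
                )
            )
            stats.n_kept += 1
        if not any_snv:
            stats.n_skipped_indel += 1
    return out, stats


@dataclass
class FilterResult:
    kept: list[SequenceVariant]
    removed: list[tuple[SequenceVariant, tuple[str, ...]]]
    n_missing_ad: int = 0

    def removal_ledger(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.key, ";".join(reasons)) for v, reasons in self.removed],
            columns=["variant", "reasons"],
        )


def apply_filters(
    variants: Iterable[SequenceVariant],
    min_alt_reads: int = 3,
    min_qual: float = 20.0,
    min_mq: float = 20.0,
    min_carriers: int = 2,
    per_sample_reads: bool = False,
) -> FilterResult:
    """Apply the SNV quality filters; every variant lands in kept or removed.

    A variant passes when: cohort alt-supporting reads >= ``min_alt_reads``
    (or, with ``per_sample_reads``, some single sample reaches the threshold),
    QUAL >= ``min_qual``, MQ >= ``min_mq``, and >= ``min_carriers`` distinct
    individuals carry the alt allele. Missing AD passes the read criterion
    (counted in ``n_missing_ad``); missing QUAL/MQ pass their criteria.
    """
    kept, removed = [], []
    n_missing_ad = 0
    for v in variants:
        reasons = []
        if v.alt_depths is None:
            n_missing_ad += 1
        else:
            if per_sample_reads:
                ok = bool(np.any(v.alt_depths >= min_alt_reads))
            else:
                ok = v.total_alt_reads() >= min_alt_reads
            if not ok:
                reasons.append("alt_reads")
        if v.qual is not None and not math.isnan(v.qual) and v.qual < min_qual:
            reasons.append("qual")
        if v.mq is not None and not math.isnan(v.mq) and v.mq < min_mq:
            reasons.append("mq")
        if v.carriers() < min_carriers:
            reasons.append("carriers")
        if reasons:
            removed.append((v, tuple(reasons)))
        else:
            kept.append(v)
    return FilterResult(kept, removed, n_missing_ad)


@dataclass
class DepthSummary:
    """Per-sample low-depth flags and site mean depth for one variant."""

    variant_key: str
    low_confidence: np.ndarray  # bool per panel sample
    mean_depth: float

    @property
    def n_flagged(self) -> int:
        return int(np.sum(self.low_confidence))


def flag_low_depth(
    variants: Iterable[SequenceVariant], genotype_depth_threshold: int = 6
) -> list[DepthSummary]:
    """Flag genotypes with DP strictly below the threshold; report site mean depth.

    Sites without DP get no flags and a NaN mean (the violin-plot-style
    summary omits them).
    """
    out = []
    for v in variants:
        if v.depths is None:
            n = len(v.genotypes)
            out.append(DepthSummary(v.key, np.zeros(n, dtype=bool), float("nan")))
            continue
        depths = np.asarray(v.depths)
        out.append(
            DepthSummary(
                v.key,
                depths < genotype_depth_threshold,
                float(np.mean(depths)),
            )
        )
    return out


def read_known_ids(path) -> set[str]:
    """Read a known-variant key list (one rsID or chrom:pos:ref:alt per line)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def label_novelty(
    variants: Iterable[SequenceVariant], known_ids: set[str]
) -> list[str]:
    """Label each variant ``known`` if its ID or positional key is catalogued, else ``novel``."""
    labels = []
    for v in variants:
        known = (v.id is not None and v.id in known_ids) or v.key in known_ids
        labels.append("known" if known else "novel")
    return labels


def write_vcf(
    path,
    samples: Sequence[str],
    records: Sequence[dict],
    contigs: Sequence[str] = (),
) -> None:
    """Write a minimal VCFv4.2 text file with GT:AD:DP per sample.

    Each record dict needs chrom, pos, id, ref, alt, qual, mq, genotypes
    (list of (a1, a2), -1 = missing) and optional alt_depths/depths arrays.
    """
    lines = ["##fileformat=VCFv4.2"]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines += [
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" + "\t".join(["FORMAT"] + list(samples)),
    ]
    for r in records:
        info = f"MQ={r['mq']:g}" if r.get("mq") is not None else "."
        qual = f"{r['qual']:g}" if r.get("qual") is not None else "."
        fields = [
            str(r["chrom"]),
            str(r["pos"]),
            r.get("id") or ".",
            r["ref"],
            r["alt"],
            qual,
            "PASS",
            info,
            "GT:AD:DP",
        ]
        ad = r.get("alt_depths")
        dp = r.get("depths")
        for i, (a, b) in enumerate(r["genotypes"]):
            gt = "/".join("." if x == MISSING else str(x) for x in (a, b))
            if dp is not None:
                d = int(dp[i])
                alt_d = int(ad[i]) if ad is not None else 0
                fields.append(f"{gt}:{d - alt_d},{alt_d}:{d}")
            else:
                fields.append(f"{gt}:.:.")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def variants_to_records(variants: Iterable[SequenceVariant]) -> list[dict]:
    """Convert SequenceVariants to the record dicts accepted by :func:`write_vcf`."""
    return [
        {
            "chrom": v.chrom,
            "pos": v.pos,
            "id": v.id,
            "ref": v.ref,
            "alt": v.alt,
            "qual": v.qual,
            "mq": v.mq,
            "genotypes": v.genotypes,
            "alt_depths": v.alt_depths,
            "depths": v.depths,
        }
        for v in variants
    ]
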
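"""Haplotype-frequency estimation from unphased diploid genotypes by EM.

Phasing of multi-heterozygous individuals is ambiguous: an individual
heterozygous at k sites is compatible with 2^(k-1) unordered haplotype pairs.
The expectation-maximization algorithm (Excoffier-Slatkin style) treats the
pair as the latent variable. Under Hardy-Weinberg proportions the probability
of an unordered pair (h1, h2) is 2*f_h1*f_h2 (f_h1^2 when h1 == h2); the
E-step distributes each individual across its compatible pairs in proportion
to these terms, and the M-step sets each haplotype frequency to its expected
chromosome count divided by 2N. The log-likelihood is non-decreasing across
iterations, which the implementation asserts on its own trace.

Haplotypes are represented as strings of '0'/'1' over the selected sites
ordered by CDS offset, so lexicographic order is well defined for
deterministic tie-breaking.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CombinatorialLimitError, IntegrityError, MilkvarError
from .variant_filtering import MISSING, SamplePanel, SequenceVariant

#: maximum heterozygous sites before pair enumeration is refused
DEFAULT_HET_CAP = 20


@dataclass
class SiteInfo:
    """Metadata for one site entering haplotype construction."""

    chrom: str
    pos: int
    ref: str
    alt: str
    cds_offset: Optional[int] = None


@dataclass
class GenotypeMatrix:
    """Per-individual diploid genotypes over a gene's selected coding sites.

    ``genotypes`` is an (n_individuals, n_sites) array of alt-allele counts
    (0/1/2). Individuals with a missing genotype at any selected site are
    excluded at construction and counted in ``n_dropped``.
    """

    genotypes: np.ndarray
    sites: list[SiteInfo]
    samples: list[str]
    breeds: list[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != len(self.sites):
            raise IntegrityError("genotype matrix shape does not match site metadata")
        if len(self.samples) != self.genotypes.shape[0] or len(self.breeds) != len(self.samples):
            raise IntegrityError("sample/breed labels do not match matrix rows")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def subset_breed(self, breed: str) -> "GenotypeMatrix":
        idx = [i for i, b in enumerate(self.breeds) if b == breed]
        return GenotypeMatrix(
            self.genotypes[idx],
            self.sites,
            [self.samples[i] for i in idx],
            [breed] * len(idx),
        )

    @classmethod
    def from_variants(
        cls,
        variants: Sequence[SequenceVariant],
        panel: SamplePanel,
        cds_offsets: Optional[Sequence[int]] = None,
    ) -> "GenotypeMatrix":
        """Build the matrix from per-site SequenceVariants (sites in given order).

        ``cds_offsets`` optionally attaches CDS offsets to the site metadata;
        sites are sorted by offset when provided.
        """
        sites = [
            SiteInfo(v.chrom, v.pos, v.ref, v.alt, None if cds_offsets is None else cds_offsets[i])
            for i, v in enumerate(variants)
        ]
        order = range(len(sites))
        if cds_offsets is not None:
            order = sorted(order, key=lambda i: sites[i].cds_offset)
        sites = [sites[i] for i in order]
        variants = [variants[i] for i in order]
        n = len(panel.samples)
        g = np.zeros((n, len(sites)), dtype=np.int8)
        ok = np.ones(n, dtype=bool)
        for j, v in enumerate(variants):
            for i, (a, b) in enumerate(v.genotypes):
                if a == MISSING or b == MISSING:
                    ok[i] = False
                else:
                    g[i, j] = a + b
        kept = np.where(ok)[0]
        return cls(
            g[kept],
            sites,
            [panel.samples[i] for i in kept],
            [panel.breed_of[panel.samples[i]] for i in kept],
            n_dropped=int(n - len(kept)),
        )


def enumerate_compatible_pairs(
    genotype: Sequence[int], het_cap: int = DEFAULT_HET_CAP
) -> list[tuple[str, str]]:
    """All unordered haplotype pairs explaining a diploid genotype vector.

    A genotype with k heterozygous sites yields max(1, 2^(k-1)) pairs. Each
    pair is returned sorted so (h1, h2) with h1 <= h2.
    """
    g = np.asarray(genotype)
    het = np.where(g == 1)[0]
    if len(het) > het_cap:
        raise CombinatorialLimitError(
            f"{len(het)} heterozygous sites exceeds cap {het_cap}"
        )
    base = np.where(g == 2, 1, 0)
    if len(het) == 0:
        h = "".join(map(str, base))
        return [(h, h)]
    pairs = []
    seen = set()
    # fix the first het site's assignment to avoid double counting swaps
    for bits in itertools.product((0, 1), repeat=len(het) - 1):
        h1 = base.copy()
        h2 = base.copy()
        assignment = (0,) + bits
        for site, bit in zip(het, assignment):
            h1[site] = bit
            h2[site] = 1 - bit
        pair = tuple(sorted(("".join(map(str, h1)), "".join(map(str, h2)))))
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    return pairs


@dataclass
class HaplotypeFrequencyEstimate:
    """EM result: haplotype -> frequency with convergence diagnostics."""

    frequencies: dict[str, float]
    loglik_trace: list[float]
    iterations: int
    converged: bool
    n_chromosomes: int
    sites: list[SiteInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise IntegrityError(f"haplotype frequencies sum to {total}, not 1")
        for prev, cur in zip(self.loglik_trace, self.loglik_trace[1:]):
            if cur < prev - 1e-9:
                raise IntegrityError("log-likelihood decreased during EM")

    def sub_singleton(self) -> set[str]:
        """Haplotypes estimated below 1/(4N): effectively less than half a copy."""
        if self.n_chromosomes == 0:
            return set()
        cut = 1.0 / (2 * self.n_chromosomes)
        return {h for h, f in self.frequencies.items() if 0 < f < cut}

    def to_frame(self, scope: str = "cohort") -> pd.DataFrame:
        rows = sorted(self.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            {
                "scope": scope,
                "haplotype": [h for h, _ in rows],
                "frequency": [f for _, f in rows],
                "n_chromosomes": self.n_chromosomes,
                "converged": self.converged,
                "iterations": self.iterations,
            }
        )


def em_estimate(
    gm: GenotypeMatrix,
    tol: float = 1e-8,
    max_iter: int = 1000,
    init_freqs: Optional[dict[str, float]] = None,
    het_cap: int = DEFAULT_HET_CAP,
) -> HaplotypeFrequencyEstimate:
    """Estimate haplotype frequencies by EM under Hardy-Weinberg proportions.

    Initialization is uniform over the union of pair-compatible haplotypes
    (deterministic); ``init_freqs`` overrides it, e.g. to seed small-breed
    runs from cohort-level estimates. Convergence when max |delta f| < tol.
    Non-convergence returns ``converged=False`` with the result so far.
    """
    if gm.n_individuals == 0:
        raise MilkvarError("empty genotype matrix")
    # group identical genotype rows to save E-step work
    uniq, counts = np.unique(gm.genotypes, axis=0, return_counts=True)
    class_pairs = [enumerate_compatible_pairs(row, het_cap) for row in uniq]
    hap_index: dict[str, int] = {}
    for pairs in class_pairs:
        for h1, h2 in pairs:
            for h in (h1, h2):
                hap_index.setdefault(h, len(hap_index))
    haps = list(hap_index)
    H = len(haps)
    pair_idx = [
        np.array([(hap_index[a], hap_index[b]) for a, b in pairs]) for pairs in class_pairs
    ]
    pair_mult = [
        np.array([1.0 if a == b else 2.0 for a, b in pairs]) for pairs in class_pairs
    ]
    f = np.full(H, 1.0 / H)
    if init_freqs is not None:
        f = np.array([init_freqs.get(h, 0.0) for h in haps])
        if f.sum() <= 0:
            f = np.full(H, 1.0 / H)
        # small uniform admixture keeps haplotypes absent from the seed alive
        f = 0.99 * f / f.sum() + 0.01 / H
    n = 2 * gm.n_individuals
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts_new = np.zeros(H)
        loglik = 0.0
        for c, idx, mult in zip(counts, pair_idx, pair_mult):
            probs = mult * f[idx[:, 0]] * f[idx[:, 1]]
            z = probs.sum()
            if z <= 0:
                # individual incompatible with current frequencies (can only
                # happen with a degenerate seed); fall back to uniform weights
                probs = np.ones_like(probs)
                z = probs.sum()
            else:
                loglik += c * math.log(z)
            w = c * probs / z
            np.add.at(counts_new, idx[:, 0], w)
            np.add.at(counts_new, idx[:, 1], w)
        f_new = counts_new / n
        trace.append(loglik)
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            converged = True
            break
        f = f_new
    frequencies = {h: float(f[i]) for h, i in hap_index.items()}
    return HaplotypeFrequencyEstimate(
        frequencies=frequencies,
        loglik_trace=trace,
        iterations=it,
        converged=converged,
        n_chromosomes=n,
        sites=gm.sites,
    )


@dataclass
class PairAssignment:
    sample: str
    breed: str
    pair: tuple[str, str]
    posterior: float


def assign_best_pairs(
    gm: GenotypeMatrix, est: HaplotypeFrequencyEstimate, het_cap: int = DEFAULT_HET_CAP
) -> list[PairAssignment]:
    """Most-probable haplotype pair per individual under the EM frequencies.

    The posterior over an individual's compatible pairs is proportional to
    2*f1*f2 (f^2 for homozygous pairs); ties break lexicographically by the
    sorted pair.
    """
    f = est.frequencies
    out = []
    for i in range(gm.n_individuals):
        pairs = enumerate_compatible_pairs(gm.genotypes[i], het_cap)
        probs = np.array(
            [(1.0 if a == b else 2.0) * f.get(a, 0.0) * f.get(b, 0.0) for a, b in pairs]
        )
        z = probs.sum()
        if z <= 0:
            post = np.full(len(pairs), 1.0 / len(pairs))
        else:
            post = probs / z
        best_p = post.max()
        candidates = [j for j in range(len(pairs)) if post[j] == best_p]
        best = min(candidates, key=lambda j: pairs[j])
        out.append(PairAssignment(gm.samples[i], gm.breeds[i], pairs[best], float(post[best])))
    return out


def em_by_breed(
    gm: GenotypeMatrix,
    cohort: Optional[HaplotypeFrequencyEstimate] = None,
    min_samples: int = 2,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> dict[str, HaplotypeFrequencyEstimate]:
    """Run EM within each breed, seeded from cohort-level frequencies.

    Breeds with fewer than ``min_samples`` individuals are skipped.
    """
    results = {}
    init = cohort.frequencies if cohort is not None else None
    for breed in dict.fromkeys(gm.breeds):
        sub = gm.subset_breed(breed)
        if sub.n_individuals < min_samples:
            continue
        results[breed] = em_estimate(sub, tol=tol, max_iter=max_iter, init_freqs=init)
    return results


def hard_occurrences(assignments: Sequence[PairAssignment]) -> dict[str, int]:
    """Chromosome-copy counts per haplotype from hard pair assignments."""
    counts: dict[str, int] = {}
    for a in assignments:
        for h in a.pair:
            counts[h] = counts.get(h, 0) + 1
    return counts


def expected_occurrences(
    gm: GenotypeMatrix, est: HaplotypeFrequencyEstimate, het_cap: int = DEFAULT_HET_CAP
) -> dict[str, float]:
    """Posterior-weighted haplotype copy counts (soft alternative to hard counts)."""
    f = est.frequencies
    counts: dict[str, float] = {}
    for i in range(gm.n_individuals):
        pairs = enumerate_compatible_pairs(gm.genotypes[i], het_cap)
        probs = np.array(
            [(1.0 if a == b else 2.0) * f.get(a, 0.0) * f.get(b, 0.0) for a, b in pairs]
        )
        z = probs.sum()
        post = probs / z if z > 0 else np.full(len(pairs), 1.0 / len(pairs))
        for (a, b), w in zip(pairs, post):
            counts[a] = counts.get(a, 0.0) + w
            counts[b] = counts.get(b, 0.0) + w
    return counts
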
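"""Brute-force EM oracle: direct enumeration, independent of milkvar internals.

Enumerates all 2^m haplotypes and, per individual, all ordered haplotype
pairs whose allele sums match the genotype. Initialization is uniform over
haplotypes appearing in at least one compatible pair, mirroring the
deterministic initialization convention, so trajectories are comparable.
"""

from itertools import product


def compatible_ordered_pairs(genotype, haps):
    out = []
    for h1 in haps:
        for h2 in haps:
            if all(int(a) + int(b) == g for a, b, g in zip(h1, h2, genotype)):
                out.append((h1, h2))
    return out


def brute_force_em(genotypes, tol=1e-10, max_iter=5000):
    """Haplotype frequencies by plain EM over explicit pair enumerations."""
    m = len(genotypes[0])
    all_haps = ["".join(bits) for bits in product("01", repeat=m)]
    pair_lists = [compatible_ordered_pairs(g, all_haps) for g in genotypes]
    observed = sorted({h for pairs in pair_lists for hp in pairs for h in hp})
    f = {h: 0.0 for h in all_haps}
    for h in observed:
        f[h] = 1.0 / len(observed)
    n_chrom = 2 * len(genotypes)
    for _ in range(max_iter):
        counts = {h: 0.0 for h in all_haps}
        for pairs in pair_lists:
            weights = [f[a] * f[b] for a, b in pairs]
            z = sum(weights)
            if z == 0:
                weights = [1.0] * len(pairs)
                z = float(len(pairs))
            for (a, b), w in zip(pairs, weights):
                counts[a] += w / z
                counts[b] += w / z
        new = {h: counts[h] / n_chrom for h in all_haps}
        delta = max(abs(new[h] - f[h]) for h in all_haps)
        f = new
        if delta < tol:
            break
    return {h: v for h, v in f.items() if v > 0 or h in observed}
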
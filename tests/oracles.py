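"""Independent brute-force oracles used to check the vectorized statistics.

Everything here is written by direct enumeration over individuals, pairs,
and the four allele pairings of two diploid genotypes — deliberately slow
and independent of the implementations under test.
"""

import itertools

import numpy as np

MISSING = -1


def genotype_mismatch(g1, g2):
    """Expected mismatch of two diploid genotypes by enumerating the 4 pairings."""
    total = 0.0
    for a in g1:
        for b in g2:
            total += a != b
    return total / 4.0


def pair_distance_brute(calls_i, calls_j):
    mismatch, joint = 0.0, 0
    for g1, g2 in zip(calls_i, calls_j):
        if MISSING in g1 or MISSING in g2:
            continue
        mismatch += genotype_mismatch(g1, g2)
        joint += 1
    return mismatch, joint


def _filter_sites(calls, groups, mins):
    keep = []
    for s in range(calls.shape[0]):
        ok = True
        for idx, mn in zip(groups, mins):
            n = sum(1 for i in idx if MISSING not in calls[s, i])
            if n < mn:
                ok = False
        keep.append(ok)
    return calls[np.asarray(keep, dtype=bool)]


def pi_brute(calls, idx, min_genotyped):
    """Mean over distinct-individual pairs of mismatch/joint ratios."""
    sub = _filter_sites(calls, [idx], [min_genotyped])
    ratios = []
    for i, j in itertools.combinations(range(len(idx)), 2):
        m, joint = pair_distance_brute(sub[:, idx[i]], sub[:, idx[j]])
        if joint > 0:
            ratios.append(m / joint)
    return float(np.mean(ratios)) if ratios else np.nan


def dxy_brute(calls, idx_a, idx_b, min_a, min_b):
    sub = _filter_sites(calls, [idx_a, idx_b], [min_a, min_b])
    ratios = []
    for i in idx_a:
        for j in idx_b:
            m, joint = pair_distance_brute(sub[:, i], sub[:, j])
            if joint > 0:
                ratios.append(m / joint)
    return float(np.mean(ratios)) if ratios else np.nan


def fst_brute(calls, idx_a, idx_b, min_a, min_b):
    """K_ST-family F_ST by direct pair enumeration (pair-count K_S weights)."""
    sub = _filter_sites(calls, [idx_a, idx_b], [min_a, min_b])

    def within(idx):
        ratios = []
        for i, j in itertools.combinations(idx, 2):
            m, joint = pair_distance_brute(sub[:, i], sub[:, j])
            if joint > 0:
                ratios.append(m / joint)
        return ratios

    wa, wb = within(idx_a), within(idx_b)
    if not wa or not wb:
        return np.nan
    ks = (sum(wa) + sum(wb)) / (len(wa) + len(wb))
    pooled = list(idx_a) + list(idx_b)
    ratios = []
    for i, j in itertools.combinations(pooled, 2):
        m, joint = pair_distance_brute(sub[:, i], sub[:, j])
        if joint > 0:
            ratios.append(m / joint)
    if not ratios:
        return np.nan
    kt = float(np.mean(ratios))
    if kt == 0:
        return np.nan
    return 1.0 - ks / kt


def random_matrix(rng, n_sites=None, n_per_taxon=None, missing=0.3):
    """Random small two-taxon genotype matrix with missing data."""
    n_sites = n_sites or int(rng.integers(1, 7))
    n_a = n_per_taxon or int(rng.integers(2, 6))
    n_b = n_per_taxon or int(rng.integers(2, 6))
    n = n_a + n_b
    calls = rng.integers(0, 2, size=(n_sites, n, 2)).astype(np.int8)
    mask = rng.random((n_sites, n)) < missing
    calls[mask] = MISSING
    return calls, np.arange(n_a), np.arange(n_a, n)
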
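"""Window-based pi, d_xy, F_ST and d_a with missing-data-aware denominators.

All statistics are built from one primitive: the expected allele mismatch
between two diploid genotypes, averaged per pair of individuals over the
sites jointly genotyped in that pair.  With alternate-allele dosages
x, y in {0, 1/2, 1} the per-site expected mismatch of one random allele
drawn from each individual is ``x + y - 2xy`` (A/A vs A/A -> 0, A/A vs
A/T -> 0.5, A/A vs T/T -> 1, A/T vs A/T -> 0.5).

pi and d_xy are means over pairs of (mismatch sum / jointly genotyped
sites), pairs within one taxon or one individual from each of two taxa
respectively.  F_ST follows the K_ST family: ``1 - K_S / K_T`` where K_S
is the pair-count-weighted mean within-taxon distance and K_T the mean
distance over all pairs of distinct individuals in the pooled sample.
Invariant sites enter every denominator, so values are per genotyped site.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from mimland.genomic_io import GenotypeMatrix, WindowSpec

__all__ = [
    "pair_distance",
    "pairwise_mismatch",
    "pi_window",
    "dxy_window",
    "fst_window",
    "da_pair",
    "z_transform",
    "compute_window_stats",
    "pair_label",
]


def _dosage_from_calls(calls: np.ndarray) -> np.ndarray:
    calls = np.asarray(calls)
    d = (calls[:, 0] + calls[:, 1]) / 2.0
    d = d.astype(float)
    d[np.any(calls < 0, axis=1)] = np.nan
    return d


def pair_distance(calls_i: np.ndarray, calls_j: np.ndarray) -> tuple[float, int]:
    """Mismatch sum and joint genotyped-site count for two call vectors.

    ``calls_i`` / ``calls_j`` are (n_sites, 2) diploid allele-index arrays
    with negative entries meaning missing.  Sites missing in either
    individual are excluded.  Returns ``(mismatch_sum, joint_sites)``;
    ``(0.0, 0)`` when no site is jointly genotyped.
    """
    x = _dosage_from_calls(calls_i)
    y = _dosage_from_calls(calls_j)
    valid = ~np.isnan(x) & ~np.isnan(y)
    xv, yv = x[valid], y[valid]
    return float(np.sum(xv + yv - 2 * xv * yv)), int(valid.sum())


def pairwise_mismatch(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs mismatch sums and joint-site counts from a dosage block.

    ``dos`` is (n_sites, n_individuals) with NaN for missing.  Returns the
    symmetric matrices ``(M, J)`` where ``M[i, j]`` is the summed expected
    mismatch between individuals i and j over their jointly genotyped
    sites and ``J[i, j]`` that site count.
    """
    valid = np.isfinite(dos)
    x0 = np.where(valid, dos, 0.0)
    v = valid.astype(float)
    a = x0.T @ v  # a[i, j] = sum of x_i over sites valid in both
    m = a + a.T - 2.0 * (x0.T @ x0)
    j = v.T @ v
    return m, j


def _pair_ratios(m: np.ndarray, j: np.ndarray, rows, cols, extra: float):
    """Per-pair distance ratios for the index pairs (rows x cols)."""
    jj = j[np.ix_(rows, cols)] + extra
    mm = m[np.ix_(rows, cols)]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(jj > 0, mm / jj, np.nan)
    return r


def _filter_sites(dos: np.ndarray, groups: list[np.ndarray], mins: list[int]):
    """Rows genotyped in at least ``mins[g]`` individuals of every group."""
    keep = np.ones(dos.shape[0], dtype=bool)
    for idx, mn in zip(groups, mins):
        keep &= np.isfinite(dos[:, idx]).sum(axis=1) >= mn
    return keep


def pi_window(
    matrix: GenotypeMatrix,
    taxon: str,
    window: WindowSpec,
    min_genotyped: int = 3,
    extra_invariant: int = 0,
) -> tuple[float, int]:
    """Nucleotide diversity of ``taxon`` in one window.

    Sites are restricted to those genotyped in at least ``min_genotyped``
    individuals of the taxon; the value is the mean over unordered pairs
    of distinct individuals of (mismatch sum / joint sites), pairs sharing
    no site excluded.  ``extra_invariant`` adds jointly genotyped invariant
    sites that are not materialized in the matrix (used by the simulator).
    Returns ``(pi, n_sites_used)``; pi is NaN when fewer than two
    individuals carry data.
    """
    idx = matrix.taxon_indices(taxon)
    sl = matrix.site_slice(window.chrom, window.start, window.end)
    dos = matrix.dosage()[sl][:, idx]
    keep = _filter_sites(dos, [np.arange(len(idx))], [min_genotyped])
    dos = dos[keep]
    m, j = pairwise_mismatch(dos)
    n = len(idx)
    iu = np.triu_indices(n, k=1)
    jj = j[iu] + extra_invariant
    ratios = np.where(jj > 0, m[iu] / np.maximum(jj, 1), np.nan)
    if np.isfinite(ratios).sum() < 1 or n < 2:
        return np.nan, int(keep.sum())
    return float(np.nanmean(ratios)), int(keep.sum()) + extra_invariant


def dxy_window(
    matrix: GenotypeMatrix,
    taxon_a: str,
    taxon_b: str,
    window: WindowSpec,
    min_genotyped: int | tuple[int, int] = 3,
    extra_invariant: int = 0,
) -> tuple[float, int]:
    """Mean between-taxon pairwise distance (d_xy) in one window.

    Pairs draw one individual from each taxon; sites must be genotyped in
    at least ``min_genotyped`` individuals of *each* taxon (pass a tuple
    for asymmetric thresholds, e.g. a smaller outgroup panel).
    """
    mn_a, mn_b = (
        min_genotyped if isinstance(min_genotyped, tuple) else (min_genotyped,) * 2
    )
    ia = matrix.taxon_indices(taxon_a)
    ib = matrix.taxon_indices(taxon_b)
    sl = matrix.site_slice(window.chrom, window.start, window.end)
    dos = matrix.dosage()[sl][:, np.concatenate([ia, ib])]
    ga = np.arange(len(ia))
    gb = np.arange(len(ia), len(ia) + len(ib))
    keep = _filter_sites(dos, [ga, gb], [mn_a, mn_b])
    dos = dos[keep]
    m, j = pairwise_mismatch(dos)
    ratios = _pair_ratios(m, j, ga, gb, extra_invariant)
    if np.isfinite(ratios).sum() < 1:
        return np.nan, int(keep.sum())
    return float(np.nanmean(ratios)), int(keep.sum()) + extra_invariant


def fst_window(
    matrix: GenotypeMatrix,
    taxon_a: str,
    taxon_b: str,
    window: WindowSpec,
    min_genotyped: int | tuple[int, int] = 3,
    extra_invariant: int = 0,
    ks_weighting: str = "pairs",
) -> tuple[float, int]:
    """K_ST-family F_ST between two taxa in one window.

    ``F_ST = 1 - K_S / K_T`` with K_S the weighted mean within-taxon
    pairwise distance (weights proportional to the number of within-taxon
    pairs, or to sample size with ``ks_weighting="size"``) and K_T the
    mean pairwise distance over all pairs of distinct individuals in the
    pooled sample, all with per-pair missing-data denominators.  NaN when
    the pooled sample shows no variation (K_T = 0).
    """
    if ks_weighting not in ("pairs", "size"):
        raise ValueError("ks_weighting must be 'pairs' or 'size'")
    mn_a, mn_b = (
        min_genotyped if isinstance(min_genotyped, tuple) else (min_genotyped,) * 2
    )
    ia = matrix.taxon_indices(taxon_a)
    ib = matrix.taxon_indices(taxon_b)
    sl = matrix.site_slice(window.chrom, window.start, window.end)
    dos = matrix.dosage()[sl][:, np.concatenate([ia, ib])]
    ga = np.arange(len(ia))
    gb = np.arange(len(ia), len(ia) + len(ib))
    keep = _filter_sites(dos, [ga, gb], [mn_a, mn_b])
    dos = dos[keep]
    return (
        _fst_from_mismatch(*pairwise_mismatch(dos), ga, gb, extra_invariant, ks_weighting),
        int(keep.sum()) + extra_invariant,
    )


def _fst_from_mismatch(m, j, ga, gb, extra, ks_weighting="pairs"):
    parts = []  # (mean within distance, n pairs, n individuals) per taxon
    for g in (ga, gb):
        iu = np.triu_indices(len(g), k=1)
        ratios = _pair_ratios(m, j, g, g, extra)[iu]
        ok = np.isfinite(ratios)
        if ok.sum() == 0:
            return np.nan
        parts.append((float(ratios[ok].mean()), int(ok.sum()), len(g)))
    if ks_weighting == "pairs":
        weights = np.array([p[1] for p in parts], dtype=float)
    else:
        weights = np.array([p[2] for p in parts], dtype=float)
    ks = float(np.average([p[0] for p in parts], weights=weights))

    pooled = np.concatenate([ga, gb])
    iu = np.triu_indices(len(pooled), k=1)
    ratios = _pair_ratios(m, j, pooled, pooled, extra)[iu]
    ok = np.isfinite(ratios)
    if ok.sum() == 0:
        return np.nan
    kt = float(ratios[ok].mean())
    if kt == 0.0:
        return np.nan
    return 1.0 - ks / kt


def da_pair(dxy_mean: float, pi_mean_a: float, pi_mean_b: float) -> float:
    """Net divergence ``d_a = d_xy - (pi_a + pi_b) / 2`` from genome means."""
    return dxy_mean - (pi_mean_a + pi_mean_b) / 2.0


def z_transform(series, ddof: int = 0, name: str | None = None) -> np.ndarray:
    """Z-transform a landscape: ``(x - mean) / SD`` over non-missing windows.

    Missing values propagate.  Population SD (``ddof=0``) by default; a
    constant landscape raises naming the offending series.
    """
    x = np.asarray(series, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise ValueError(f"landscape {name or '<unnamed>'}: fewer than 2 values")
    sd = x[ok].std(ddof=ddof)
    if sd == 0:
        raise ValueError(f"landscape {name or '<unnamed>'} has zero variance")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - x[ok].mean()) / sd
    return out


def pair_label(a: str, b: str) -> str:
    return "|".join(sorted((a, b)))


def compute_window_stats(
    matrix: GenotypeMatrix,
    windows: list[WindowSpec],
    min_genotyped: int = 3,
    outgroup: str | None = None,
    outgroup_min: int = 2,
) -> dict[str, pd.DataFrame]:
    """pi, d_xy and F_ST landscapes for every taxon / taxon pair.

    Site filtering is applied independently for each comparison; any
    comparison involving ``outgroup`` uses ``outgroup_min`` for that taxon.
    Returns ``{"pi", "dxy", "fst", "n_sites"}`` DataFrames with window
    coordinate columns followed by one column per taxon or pair.
    """
    taxa = matrix.taxa
    coords = pd.DataFrame(
        [(w.chrom, w.start, w.end) for w in windows],
        columns=["chrom", "start", "end"],
    )

    def mn(taxon):
        return outgroup_min if taxon == outgroup else min_genotyped

    # shared per-window work: slice the dosage matrix once, precompute
    # per-taxon genotyped counts, and reuse one pairwise-mismatch matrix
    # per taxon pair for both d_xy and F_ST
    idx = {t: matrix.taxon_indices(t) for t in taxa}
    dos_all = matrix.dosage()
    geno_counts = {t: np.isfinite(dos_all[:, idx[t]]).sum(axis=1) for t in taxa}
    pairs = list(itertools.combinations(taxa, 2))
    pi_cols = {t: [] for t in taxa}
    ns_cols = {t: [] for t in taxa}
    dxy_cols = {pair_label(a, b): [] for a, b in pairs}
    fst_cols = {pair_label(a, b): [] for a, b in pairs}
    for w in windows:
        sl = matrix.site_slice(w.chrom, w.start, w.end)
        dosw = dos_all[sl]
        cw = {t: geno_counts[t][sl] for t in taxa}
        for t in taxa:
            sub = dosw[np.ix_(cw[t] >= mn(t), idx[t])]
            m, j = pairwise_mismatch(sub)
            iu = np.triu_indices(len(idx[t]), k=1)
            ratios = np.where(j[iu] > 0, m[iu] / np.maximum(j[iu], 1), np.nan)
            ok = np.isfinite(ratios)
            pi_cols[t].append(float(ratios[ok].mean()) if ok.any() else np.nan)
            ns_cols[t].append(int((cw[t] >= mn(t)).sum()))
        for a, b in pairs:
            lab = pair_label(a, b)
            keep = (cw[a] >= mn(a)) & (cw[b] >= mn(b))
            cols = np.concatenate([idx[a], idx[b]])
            sub = dosw[np.ix_(keep, cols)]
            ga = np.arange(len(idx[a]))
            gb = np.arange(len(idx[a]), len(cols))
            m, j = pairwise_mismatch(sub)
            ratios = _pair_ratios(m, j, ga, gb, 0)
            ok = np.isfinite(ratios)
            dxy_cols[lab].append(float(ratios[ok].mean()) if ok.any() else np.nan)
            fst_cols[lab].append(_fst_from_mismatch(m, j, ga, gb, 0))
    return {
        "pi": pd.concat([coords, pd.DataFrame(pi_cols)], axis=1),
        "dxy": pd.concat([coords, pd.DataFrame(dxy_cols)], axis=1),
        "fst": pd.concat([coords, pd.DataFrame(fst_cols)], axis=1),
        "n_sites": pd.concat([coords, pd.DataFrame(ns_cols)], axis=1),
    }
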
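"""ABBA-BABA introgression statistics: Patterson's D, f, and window f_d.

Sites are polarized against the outgroup: only biallelic sites at which
the outgroup sample is fixed are retained, and the derived allele is the
one not carried by the outgroup.  Pattern proportions are computed from
derived-allele frequencies: with derived frequencies p1, p2, p3 and an
ancestral outgroup,

    ABBA_i = (1 - p1) * p2 * p3        BABA_i = p1 * (1 - p2) * p3
    D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA)

Significance uses a weighted delete-one block jackknife over contiguous
genomic blocks (robust to linkage); the genome-wide admixture proportion f
compares the observed ABBA excess to the excess expected between two
halves of P3; window f_d uses a dynamic donor (the higher-derived-frequency
of P2/P3 at each site) so it stays in [0, 1] for admixed windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from mimland.genomic_io import GenotypeMatrix, WindowSpec

__all__ = [
    "PolarizedFreqs",
    "FourTaxonResult",
    "polarize_sites",
    "site_patterns",
    "patterson_d",
    "block_jackknife",
    "admixture_fraction_f",
    "fd_windows",
    "fd_summary",
    "four_taxon_test",
]


@dataclass
class PolarizedFreqs:
    """Derived-allele frequencies for one (((P1,P2),P3),O) quartet."""

    labels: tuple[str, str, str, str]
    chroms: np.ndarray
    positions: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p3_dosage: np.ndarray = field(repr=False)  # sites x P3 individuals, NaN missing

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def _nanmean_rows(block: np.ndarray) -> np.ndarray:
    """Row means ignoring NaN, without empty-slice warnings."""
    counts = np.isfinite(block).sum(axis=1)
    sums = np.nansum(block, axis=1)
    return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def _derived_freq(dos_block: np.ndarray, derived_is_alt: np.ndarray) -> np.ndarray:
    """Mean derived dosage per site, NaN where nothing is genotyped."""
    freq = _nanmean_rows(dos_block)
    return np.where(derived_is_alt, freq, 1.0 - freq)


def polarize_sites(
    matrix: GenotypeMatrix,
    quartet: tuple[str, str, str, str],
    min_genotyped: int = 2,
) -> PolarizedFreqs:
    """Polarize biallelic sites against the outgroup of a quartet.

    Retains sites where the outgroup has >= ``min_genotyped`` genotyped
    individuals all carrying the same allele, and each ingroup taxon has
    >= ``min_genotyped`` genotyped individuals.  The derived allele is the
    non-outgroup allele.
    """
    for label in quartet:
        if label not in matrix.taxa:
            raise KeyError(f"quartet taxon {label!r} absent from taxon map")
    t1, t2, t3, og = quartet
    dos = matrix.dosage()
    variant = matrix.is_variant

    idx = {t: matrix.taxon_indices(t) for t in quartet}
    og_dos = dos[:, idx[og]]
    og_n = np.isfinite(og_dos).sum(axis=1)
    og_freq = _nanmean_rows(og_dos)
    og_fixed = (og_n >= min_genotyped) & ((og_freq == 0.0) | (og_freq == 1.0))

    keep = variant & og_fixed
    for t in (t1, t2, t3):
        keep &= np.isfinite(dos[:, idx[t]]).sum(axis=1) >= min_genotyped
    derived_is_alt = og_freq == 0.0  # outgroup fixed for REF -> ALT is derived

    sel = np.flatnonzero(keep)
    d_alt = derived_is_alt[sel]
    p3_dos = dos[np.ix_(sel, idx[t3])]
    p3_derived = np.where(d_alt[:, None], p3_dos, 1.0 - p3_dos)
    return PolarizedFreqs(
        labels=quartet,
        chroms=matrix.chroms[sel],
        positions=matrix.positions[sel],
        p1=_derived_freq(dos[np.ix_(sel, idx[t1])], d_alt),
        p2=_derived_freq(dos[np.ix_(sel, idx[t2])], d_alt),
        p3=_derived_freq(dos[np.ix_(sel, idx[t3])], d_alt),
        p3_dosage=p3_derived,
    )


def site_patterns(p1, p2, p3) -> tuple[np.ndarray, np.ndarray]:
    """Per-site ABBA and BABA terms from derived-allele frequencies."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    return (1 - p1) * p2 * p3, p1 * (1 - p2) * p3


def patterson_d(freqs: PolarizedFreqs | tuple) -> tuple[float, np.ndarray, np.ndarray]:
    """Patterson's D with the per-site terms retained for jackknife/f_d.

    Returns ``(D, abba, baba)``; D is NaN when no site is informative
    (sum ABBA + sum BABA = 0).
    """
    if isinstance(freqs, PolarizedFreqs):
        p1, p2, p3 = freqs.p1, freqs.p2, freqs.p3
    else:
        p1, p2, p3 = freqs
    abba, baba = site_patterns(p1, p2, p3)
    denom = abba.sum() + baba.sum()
    d = (abba.sum() - baba.sum()) / denom if denom > 0 else np.nan
    return d, abba, baba


def block_jackknife(
    abba: np.ndarray,
    baba: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray | None = None,
    block_bp: int = 500_000,
    weights: str = "none",
) -> tuple[float, float, float]:
    """Delete-one block-jackknife SE, Z, and p for D.

    Blocks are contiguous ``block_bp`` stretches (per contig); each
    delete-one estimate recomputes D from the remaining blocks' summed
    pattern terms.  Requires >= 10 non-empty blocks.  Returns
    ``(SE, Z, p)``; p is two-sided normal and NaN (with SE = 0) when all
    blocks agree exactly.

    ``weights="none"`` (default) uses the classic delete-one variance.
    ``weights="site_sum"`` uses the Busing et al. unequal-block formula
    with block weights proportional to the informative-site sums; in
    coalescent data those weights covary with the block genealogy and the
    resulting SE is anticonservative, so it is not the default.
    """
    if weights not in ("none", "site_sum"):
        raise ValueError("weights must be 'none' or 'site_sum'")
    positions = np.asarray(positions)
    if chroms is None:
        chroms = np.zeros(len(positions), dtype=int)
    keys = pd.MultiIndex.from_arrays([np.asarray(chroms), positions // block_bp])
    codes, _ = pd.factorize(keys)
    g = codes.max() + 1 if len(codes) else 0

    tot = abba + baba
    abba_b = np.bincount(codes, weights=abba, minlength=g)
    baba_b = np.bincount(codes, weights=baba, minlength=g)
    m_j = np.bincount(codes, weights=tot, minlength=g)
    nonempty = m_j > 0
    abba_b, baba_b, m_j = abba_b[nonempty], baba_b[nonempty], m_j[nonempty]
    g = len(m_j)
    if g < 10:
        raise ValueError(f"only {g} non-empty blocks; need >= 10")

    n = m_j.sum()
    theta = (abba_b.sum() - baba_b.sum()) / n
    num_del = (abba_b.sum() - baba_b.sum()) - (abba_b - baba_b)
    theta_del = num_del / (n - m_j)
    if weights == "site_sum":
        h_j = n / m_j
        theta_j = g * theta - np.sum((1 - m_j / n) * theta_del)
        var = (
            np.sum((h_j * theta - (h_j - 1) * theta_del - theta_j) ** 2 / (h_j - 1)) / g
        )
    else:
        var = (g - 1) / g * np.sum((theta_del - theta_del.mean()) ** 2)
    se = float(np.sqrt(var))
    if se == 0:
        return 0.0, np.nan, np.nan
    z = theta / se
    p = 2 * sps.norm.sf(abs(z))
    return se, float(z), float(p)


def _s_excess(p1, pb, pc) -> float:
    """sum ABBA - sum BABA with pb in the P2 role and pc in the P3 role."""
    abba, baba = site_patterns(p1, pb, pc)
    return float(abba.sum() - baba.sum())


def admixture_fraction_f(freqs: PolarizedFreqs, seed: int | None = None) -> float:
    """Genome-wide admixture proportion f.

    The observed ABBA excess S(P1, P2, P3) is divided by the excess
    expected under complete admixture, S(P1, P3a, P3b), where P3a/P3b is a
    random (seeded) half-split of the P3 individuals made once per test.
    NaN when the denominator is not positive.
    """
    n_p3 = freqs.p3_dosage.shape[1]
    if n_p3 < 2:
        raise ValueError("need >= 2 P3 individuals to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_p3)
    half_a, half_b = perm[: n_p3 // 2], perm[n_p3 // 2 :]
    p3a = _nanmean_rows(freqs.p3_dosage[:, half_a])
    p3b = _nanmean_rows(freqs.p3_dosage[:, half_b])
    ok = np.isfinite(p3a) & np.isfinite(p3b)
    denom = _s_excess(freqs.p1[ok], p3a[ok], p3b[ok])
    if denom <= 0:
        return np.nan
    return _s_excess(freqs.p1[ok], freqs.p2[ok], freqs.p3[ok]) / denom


def fd_windows(
    freqs: PolarizedFreqs,
    windows: list[WindowSpec],
    genome_d: float,
) -> tuple[pd.DataFrame, bool]:
    """Window-based admixture proportion f_d.

    When the genome-wide D is negative, P1 and P2 are exchanged first so
    the statistic targets the taxon showing the derived-allele excess
    (flagged in the return).  Per window, the denominator replaces both
    donor roles with PD, the population (of P2, P3) with the higher
    derived frequency at each site.  Windows with a negative numerator or
    non-positive denominator are reported missing, as are windows without
    informative sites.
    """
    p1, p2 = freqs.p1, freqs.p2
    swapped = False
    if np.isfinite(genome_d) and genome_d < 0:
        p1, p2 = p2, p1
        swapped = True
    pd_donor = np.maximum(p2, freqs.p3)
    num_abba, num_baba = site_patterns(p1, p2, freqs.p3)
    den_abba, den_baba = site_patterns(p1, pd_donor, pd_donor)

    rows = []
    for w in windows:
        in_w = (freqs.chroms == w.chrom) & (freqs.positions >= w.start) & (freqs.positions < w.end)
        if not in_w.any():
            rows.append((w.chrom, w.start, w.end, np.nan, 0))
            continue
        num = num_abba[in_w].sum() - num_baba[in_w].sum()
        den = den_abba[in_w].sum() - den_baba[in_w].sum()
        fd = num / den if (num >= 0 and den > 0) else np.nan
        rows.append((w.chrom, w.start, w.end, fd, int(in_w.sum())))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "fd", "n_sites"])
    return table, swapped


def fd_summary(tracks: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-window mean and max f_d over many four-taxon tests.

    Missing tests are skipped per window; a window missing in every test
    stays missing.  All tracks must share one window grid.
    """
    coords = tracks[0][["chrom", "start", "end"]]
    for t in tracks[1:]:
        if not t[["chrom", "start", "end"]].equals(coords):
            raise ValueError("f_d tracks are not on a common window grid")
    values = np.column_stack([t["fd"].to_numpy(dtype=float) for t in tracks])
    finite = np.isfinite(values)
    n_obs = finite.sum(axis=1)
    any_data = n_obs > 0
    mean_fd = np.where(any_data, np.nansum(values, axis=1) / np.maximum(n_obs, 1), np.nan)
    max_fd = np.where(any_data, np.max(np.where(finite, values, -np.inf), axis=1), np.nan)
    out = coords.copy()
    out["mean_fd"] = mean_fd
    out["max_fd"] = max_fd
    out["n_tests"] = np.isfinite(values).sum(axis=1)
    return out


@dataclass
class FourTaxonResult:
    labels: tuple[str, str, str, str]
    D: float
    se: float
    z: float
    p: float
    f: float
    fd_track: pd.DataFrame | None
    swapped: bool
    n_sites: int


def four_taxon_test(
    matrix: GenotypeMatrix,
    quartet: tuple[str, str, str, str],
    windows: list[WindowSpec] | None = None,
    block_bp: int = 500_000,
    min_genotyped: int = 2,
    seed: int | None = None,
) -> FourTaxonResult:
    """Full introgression test for one quartet: D, jackknife, f, f_d track."""
    freqs = polarize_sites(matrix, quartet, min_genotyped)
    d, abba, baba = patterson_d(freqs)
    se, z, p = block_jackknife(abba, baba, freqs.positions, freqs.chroms, block_bp)
    f = admixture_fraction_f(freqs, seed=seed)
    fd_track, swapped = (None, False)
    if windows is not None:
        fd_track, swapped = fd_windows(freqs, windows, d)
    return FourTaxonResult(
        labels=quartet,
        D=d,
        se=se,
        z=z,
        p=p,
        f=f,
        fd_track=fd_track,
        swapped=swapped,
        n_sites=freqs.n_sites,
    )
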
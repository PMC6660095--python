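"""Divergence-time trajectories of landscape correlations across taxon pairs.

Pairwise comparisons among n taxa are phylogenetically non-independent: the
same deep branches enter many pairs.  The correction used here reduces the
C(n, 2) pair values to one value per internal node of the species tree (the
mean over all pairs whose MRCA is that node), giving n - 1 statistically
independent points for regression against net divergence d_a.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from mimland.window_stats import pair_label

__all__ = [
    "taxon_pairs",
    "pair_correlations",
    "ContrastSet",
    "independent_contrasts",
    "DivergenceTimeResult",
    "divergence_time",
]


def taxon_pairs(taxa: list[str]) -> list[tuple[str, str]]:
    """All unordered pairs of distinct taxa (36 for 9 taxa)."""
    return list(itertools.combinations(taxa, 2))


def _corr(x: np.ndarray, y: np.ndarray, min_windows: int = 10) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_windows:
        warnings.warn(f"fewer than {min_windows} complete windows for a correlation")
        return np.nan
    if x[ok].std() == 0 or y[ok].std() == 0:
        return np.nan
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def pair_correlations(
    stats: dict[str, pd.DataFrame],
    covariates: pd.DataFrame,
    min_windows: int = 10,
) -> pd.DataFrame:
    """Landscape/covariate correlations and d_a for every taxon pair.

    ``stats`` is the output of `compute_window_stats` (pi per taxon, dxy
    and F_ST per pair on a common window grid); ``covariates`` supplies
    ``gene_count`` and ``recomb_rate`` on the same grid.  For each pair,
    per-window mean pi is the average of the two taxa and d_a is computed
    from genome-wide means over the grid.  Pearson r is reported per
    statistic couple over complete-case windows.
    """
    pi, dxy, fst = stats["pi"], stats["dxy"], stats["fst"]
    coord_cols = ["chrom", "start", "end"]
    if not (pi[coord_cols].equals(dxy[coord_cols]) and pi[coord_cols].equals(fst[coord_cols])):
        raise ValueError("statistic tables are not on a common window grid")
    genes = covariates["gene_count"].to_numpy(dtype=float)
    recomb = covariates["recomb_rate"].to_numpy(dtype=float)
    taxa = [c for c in pi.columns if c not in coord_cols]

    rows = []
    for a, b in taxon_pairs(taxa):
        lab = pair_label(a, b)
        mean_pi = (pi[a].to_numpy() + pi[b].to_numpy()) / 2.0
        d = dxy[lab].to_numpy()
        f = fst[lab].to_numpy()
        d_a = np.nanmean(d) - (np.nanmean(pi[a]) + np.nanmean(pi[b])) / 2.0
        rows.append(
            {
                "pair": lab,
                "d_a": d_a,
                "r_pi_genes": _corr(mean_pi, genes, min_windows),
                "r_pi_recomb": _corr(mean_pi, recomb, min_windows),
                "r_fst_genes": _corr(f, genes, min_windows),
                "r_fst_recomb": _corr(f, recomb, min_windows),
                "r_dxy_pi": _corr(d, mean_pi, min_windows),
                "r_fst_pi": _corr(f, mean_pi, min_windows),
                "n_windows": int(np.isfinite(mean_pi * d * f).sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ContrastSet:
    """One averaged value per internal node of the species tree."""

    clades: list[frozenset]
    values: np.ndarray
    n_pairs: np.ndarray

    def __len__(self) -> int:
        return len(self.clades)


def independent_contrasts(pair_values: dict, topology: dendropy.Tree) -> ContrastSet:
    """Reduce pair values to node means on a fully resolved rooted tree.

    ``pair_values`` maps unordered taxon pairs (``"a|b"`` labels or
    2-tuples) to values.  Each pair contributes to exactly one internal
    node (its MRCA); a resolved rooted tree over n taxa yields n - 1
    contrasts.  Polytomies are an error.
    """
    tree = dendropy.Tree(topology)  # work on a copy; MRCA needs rooted state
    tree.is_rooted = True
    tree.encode_bipartitions()
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    for node in tree.preorder_internal_node_iter():
        if len(node.child_nodes()) != 2:
            labels = sorted(lf.taxon.label for lf in node.leaf_iter())
            raise ValueError(f"unresolved polytomy at node covering {labels}")

    values = {}
    for key, v in pair_values.items():
        pair = tuple(sorted(key.split("|"))) if isinstance(key, str) else tuple(sorted(key))
        values[pair] = v
    expected = set(taxon_pairs(sorted(tips)))
    if set(values) != expected:
        missing = expected - set(values)
        raise ValueError(f"pair values incomplete; missing e.g. {sorted(missing)[:3]}")

    buckets: dict[int, list] = {}
    clades: dict[int, frozenset] = {}
    for pair, v in values.items():
        taxa = [t for t in tree.taxon_namespace if t.label in pair]
        mrca = tree.mrca(taxa=taxa)
        if mrca.is_leaf():
            raise ValueError(f"pair {pair} maps to a tip")
        buckets.setdefault(id(mrca), []).append(v)
        clades[id(mrca)] = frozenset(lf.taxon.label for lf in mrca.leaf_iter())
    keys = sorted(buckets, key=lambda k: (len(clades[k]), sorted(clades[k])))
    return ContrastSet(
        clades=[clades[k] for k in keys],
        values=np.array([np.mean(buckets[k]) for k in keys]),
        n_pairs=np.array([len(buckets[k]) for k in keys]),
    )


@dataclass
class DivergenceTimeResult:
    T_generations: float
    T_years: float
    mu: float
    generation_time: float


def divergence_time(
    d_a: float, mu: float = 1.5e-8, generation_time_years: float = 2.0
) -> DivergenceTimeResult:
    """Convert net divergence to a split time: ``T = d_a / (2 mu)``.

    ``mu`` is the per-bp per-generation mutation rate; years follow by
    multiplying by the generation time.  A (small-sample) negative d_a is
    clamped to zero with a warning.
    """
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if d_a < 0:
        warnings.warn("negative d_a clamped to 0")
        d_a = 0.0
    t_gen = d_a / (2.0 * mu)
    return DivergenceTimeResult(
        T_generations=t_gen,
        T_years=t_gen * generation_time_years,
        mu=mu,
        generation_time=generation_time_years,
    )
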
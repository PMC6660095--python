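"""Forward Wright-Fisher simulation of two-population landscape evolution.

The model: an ancestral diploid population of constant size N evolves for
10N non-overlapping generations and splits into two daughter populations of
size N that diverge for a further 10N generations.  Individuals carry one
chromosome of L bp; the middle third is always neutral, while mutations in
the two distal thirds can affect fitness depending on the scenario:

    neutral           no fitness effects anywhere
    bgs               tail mutations deleterious w.p. prop_neg (s = -Ns_neg/N)
    bdmi              ancestor as bgs; after the split each new selected
                      tail mutation is deleterious in one population and
                      neutral in the other (random), with migration
    positive          tail mutations beneficial w.p. prop_pos (s = +Ns_pos/N)
    bgs_positive      both classes active
    local_adaptation  tail mutations beneficial in one population only,
                      with migration; at the split, standing neutral tail
                      variants are recruited w.p. prop_pos

Fitness is multiplicative across sites with codominance (h = 0.5).
Population rescaling by Q (N/Q individuals; mu, r, s, m times Q; time / Q)
keeps theta = 4Nmu, rho = 4Nr, Ns, and Nm invariant and brings runs to
desk scale.  Per-timepoint window statistics are computed from sampled
individuals through :mod:`mimland.window_stats`.

Implementation notes: each population stores haplotypes as rows of a
uint8 matrix whose columns are segregating mutations.  Columns are kept
position-sorted in a "core" block so crossovers become contiguous slice
copies; mutations from the last few generations live in an unsorted
pending tail that is merged into the core (and lost/fixed columns
retired) at periodic compactions.  Sites fixed within a population are
archived to a per-window record and re-materialized only when sampling,
which keeps the per-generation cost proportional to segregating variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numba
import numpy as np
import pandas as pd

from mimland.genomic_io import GenotypeMatrix, WindowSpec
from mimland.window_stats import dxy_window, fst_window, pi_window

__all__ = [
    "SimScenario",
    "SimOutput",
    "rescale",
    "shrink_genome",
    "desk_scenario",
    "run_scenario",
    "run_replicates",
    "sim_correlation_course",
]

SCENARIOS = ("neutral", "bgs", "bdmi", "positive", "bgs_positive", "local_adaptation")
H_DOM = 0.5  # codominance


@dataclass(frozen=True)
class SimScenario:
    """Parameter set for one divergence scenario (unscaled full-size defaults)."""

    scenario: str = "neutral"
    N: int = 10_000
    L: int = 21_000_000
    mu: float = 1e-8
    r: float = 1.5e-8
    Ns_neg: float = 100.0
    prop_neg: float = 0.1
    Ns_pos: float = 100.0
    prop_pos: float = 0.001
    Nm: float = 0.0
    T_burn: int | None = None  # default 10N
    T_div: int | None = None  # default 10N
    window_bp: int = 500_000
    Q: float = 1.0  # rescaling already applied (bookkeeping)
    n_sample: int = 20
    n_timepoints: int = 10
    ancestral_selection: bool = True  # bdmi: keep BGS in the ancestor
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.prop_neg + self.prop_pos > 1:
            raise ValueError("prop_neg + prop_pos must not exceed 1")
        if self.Nm > 0 and self.scenario not in ("bdmi", "local_adaptation"):
            raise ValueError("migration only applies to bdmi / local_adaptation")
        if self.L % self.window_bp:
            raise ValueError("L must be divisible by window_bp")

    @property
    def t_burn(self) -> int:
        return 10 * self.N if self.T_burn is None else self.T_burn

    @property
    def t_div(self) -> int:
        return 10 * self.N if self.T_div is None else self.T_div

    @property
    def s_neg(self) -> float:
        return -self.Ns_neg / self.N

    @property
    def s_pos(self) -> float:
        return self.Ns_pos / self.N

    @property
    def m(self) -> float:
        return self.Nm / self.N

    @property
    def tail_bounds(self) -> tuple[int, int]:
        """Neutral middle third [L/3, 2L/3); selection outside it."""
        return self.L // 3, 2 * (self.L // 3)


def rescale(config: SimScenario, Q: float) -> SimScenario:
    """Population-rescale a scenario: N/Q, T/Q, mu*Q, r*Q (s, m follow Ns, Nm).

    theta and rho per window are invariant.  Refuses Q < 1, N/Q < 100, or a
    rescaled selection coefficient beyond the weak-ish-selection regime
    (s*Q > 0.5); warns above 0.1.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    n_new = int(round(config.N / Q))
    if n_new < 100:
        raise ValueError("N/Q must be >= 100")
    s_max = max(config.Ns_neg, config.Ns_pos) / config.N * Q
    if config.scenario != "neutral":
        if s_max > 0.5:
            raise ValueError(
                f"rescaled |s| = {s_max:.3g} > 0.5: strong-selection regime broken"
            )
        if s_max > 0.1:
            warnings.warn(f"rescaled |s| = {s_max:.3g} > 0.1")
    return replace(
        config,
        N=n_new,
        mu=config.mu * Q,
        r=config.r * Q,
        T_burn=None if config.T_burn is None else int(round(config.T_burn / Q)),
        T_div=None if config.T_div is None else int(round(config.T_div / Q)),
        Q=config.Q * Q,
    )


def shrink_genome(config: SimScenario, factor: int) -> SimScenario:
    """Shrink L and the window size by ``factor``, keeping the window count."""
    if config.L % factor or config.window_bp % factor:
        raise ValueError("factor must divide L and window_bp")
    return replace(config, L=config.L // factor, window_bp=config.window_bp // factor)


def desk_scenario(
    scenario: str, seed: int = 0, Q: float = 20.0, l_shrink: int = 10, **kw
) -> SimScenario:
    """Desk-scale profile: Q-rescaled with a proportionally shrunk genome.

    Defaults give N = 500, L = 2.1 Mbp, 50-kb windows (42 windows, the
    same window count as the full-scale 21 Mbp / 500 kb layout), with
    mu' = Q mu and r' = Q r.
    """
    base = SimScenario(scenario=scenario, seed=seed, **kw)
    return shrink_genome(rescale(base, Q), l_shrink)


@numba.njit(cache=False)
def _reproduce(H, c_core, c_old, tail_pos, parents, phases, bp_flat, bp_lo, bp_hi, bcol, out):  # pragma: no cover - jitted
    """Build one generation of gametes.

    Columns [0, c_core) are position-sorted, so crossovers are contiguous
    segment copies; columns [c_core, c_old) are the unsorted pending tail,
    resolved per column from the gamete's (few) breakpoints; columns
    beyond c_old are zeroed for this generation's new mutations.
    """
    n_g, width = out.shape
    for g in range(n_g):
        p2 = 2 * parents[g]
        lo, hi = bp_lo[g], bp_hi[g]
        dst = out[g]
        if hi == lo:
            src = H[p2 + phases[g]]
            for k in range(c_old):  # explicit loops vectorize; slice
                dst[k] = src[k]  # assignment does not in this numba
        else:
            cur = phases[g]
            a = 0
            for j in range(lo, hi):
                c = bcol[j]
                src = H[p2 + cur]
                for k in range(a, c):
                    dst[k] = src[k]
                cur ^= 1
                a = c
            src = H[p2 + cur]
            for k in range(a, c_core):
                dst[k] = src[k]
            h0 = H[p2]
            h1 = H[p2 + 1]
            for k in range(c_core, c_old):
                pc = tail_pos[k - c_core]
                cnt = phases[g]
                for j in range(lo, hi):
                    if bp_flat[j] <= pc:
                        cnt += 1
                dst[k] = h0[k] if cnt & 1 == 0 else h1[k]
        for k in range(c_old, width):
            dst[k] = 0


@numba.njit(cache=False)
def _gather_cols(H, src, out):  # pragma: no cover - jitted
    for i in range(H.shape[0]):
        hi = H[i]
        oi = out[i]
        for k in range(src.shape[0]):
            oi[k] = hi[src[k]]


def _in_sorted(values: np.ndarray, sorted_arr: np.ndarray) -> np.ndarray:
    if len(sorted_arr) == 0:
        return np.zeros(len(values), dtype=bool)
    idx = np.searchsorted(sorted_arr, values)
    idx = np.minimum(idx, len(sorted_arr) - 1)
    return sorted_arr[idx] == values


class _Pop:
    """One population: haplotype rows x mutation columns (core + pending tail)."""

    def __init__(self, n: int):
        self.n = n
        self.H = np.empty((2 * n, 0), dtype=np.uint8)
        self.pos = np.empty(0, dtype=np.int64)  # [:n_core] sorted, rest pending
        self.s = np.empty(0, dtype=np.float64)  # selection coeff in this pop
        self.n_core = 0
        self.fixed = np.empty(0, dtype=np.int64)  # sorted derived-fixed positions

    def copy(self) -> "_Pop":
        new = _Pop(self.n)
        new.H = self.H.copy()
        new.pos = self.pos.copy()
        new.s = self.s.copy()
        new.n_core = self.n_core
        new.fixed = self.fixed.copy()
        return new

    def compact(self):
        """Retire lost/fixed columns and merge the pending tail into the core."""
        if self.H.shape[1] == 0:
            return
        counts = self.H.sum(axis=0, dtype=np.int16)  # 2n <= 32767 always holds here
        fixed = counts == 2 * self.n
        keep = (counts > 0) & ~fixed
        if fixed.any():
            self.fixed = np.sort(np.concatenate([self.fixed, self.pos[fixed]]))
        src = np.flatnonzero(keep)
        src = src[np.argsort(self.pos[src], kind="stable")]
        out = np.empty((self.H.shape[0], len(src)), dtype=np.uint8)
        _gather_cols(self.H, src, out)
        self.H = out
        self.pos = self.pos[src]
        self.s = self.s[src]
        self.n_core = len(src)


class _Engine:
    def __init__(self, cfg: SimScenario):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.effects: dict[int, tuple[float, float]] = {}
        self.pops: list[_Pop] = [_Pop(cfg.N)]
        self.phase = "ancestor"  # or "divergence"
        self.migrant_counts: list[tuple[int, int]] = []
        self._current_pop_idx = 0

    # -- mutation-class assignment --------------------------------------

    def _assign_effects(self, positions: np.ndarray) -> np.ndarray:
        """Per-new-mutation selection coefficients for the current phase.

        Returns the coefficient *in the population of origin*; asymmetric
        effects (bdmi / local adaptation) are registered in ``effects`` as
        (s in pop 0, s in pop 1).
        """
        cfg = self.cfg
        lo, hi = cfg.tail_bounds
        in_tail = (positions < lo) | (positions >= hi)
        s_here = np.zeros(len(positions))
        if cfg.scenario == "neutral" or not in_tail.any():
            return s_here
        u = self.rng.random(len(positions))
        anc = self.phase == "ancestor"

        def register_sym(mask, s_val):
            s_here[mask] = s_val
            for p in positions[mask]:
                self.effects[int(p)] = (s_val, s_val)

        def register_one_pop(mask, s_val):
            idxs = np.flatnonzero(mask)
            which = self.rng.integers(0, 2, len(idxs))
            for i, w in zip(idxs, which):
                eff = (s_val, 0.0) if w == 0 else (0.0, s_val)
                self.effects[int(positions[i])] = eff
                s_here[i] = eff[self._current_pop_idx]

        if cfg.scenario == "bgs":
            register_sym(in_tail & (u < cfg.prop_neg), cfg.s_neg)
        elif cfg.scenario == "positive":
            register_sym(in_tail & (u < cfg.prop_pos), cfg.s_pos)
        elif cfg.scenario == "bgs_positive":
            register_sym(in_tail & (u < cfg.prop_neg), cfg.s_neg)
            pos_mask = in_tail & (u >= cfg.prop_neg) & (u < cfg.prop_neg + cfg.prop_pos)
            register_sym(pos_mask, cfg.s_pos)
        elif cfg.scenario == "bdmi":
            mask = in_tail & (u < cfg.prop_neg)
            if anc:
                if cfg.ancestral_selection:
                    register_sym(mask, cfg.s_neg)
            else:
                register_one_pop(mask, cfg.s_neg)
        elif cfg.scenario == "local_adaptation":
            if not anc:
                register_one_pop(in_tail & (u < cfg.prop_pos), cfg.s_pos)
        return s_here

    # -- one generation of one population --------------------------------

    def _parent_weights(self, pop: _Pop) -> np.ndarray | None:
        sel_cols = np.flatnonzero(pop.s != 0.0)
        if not sel_cols.size:
            return None
        hs = pop.H[:, sel_cols]
        dosage = hs[0::2].astype(np.float64) + hs[1::2]
        # floor at s slightly above -1 so fully recessive-lethal genotypes get
        # a finite (astronomically negative) log fitness instead of -inf
        s_sel = np.maximum(pop.s[sel_cols], -1.0 + 1e-9)
        logw = (dosage == 1) @ np.log1p(H_DOM * s_sel) + (dosage == 2) @ np.log1p(s_sel)
        logw -= logw.max()
        w = np.exp(logw)
        tot = w.sum()
        if not np.isfinite(tot) or tot <= 0:
            raise RuntimeError(
                f"mean fitness collapsed in scenario {self.cfg.scenario} "
                f"({sel_cols.size} selected sites segregating)"
            )
        return w

    def _step_pop(self, pop: _Pop, pop_idx: int) -> _Pop:
        cfg = self.cfg
        rng = self.rng
        self._current_pop_idx = pop_idx
        n = pop.n
        n_gametes = 2 * n

        w = self._parent_weights(pop)
        if w is None:
            parents = rng.integers(0, n, n_gametes)
        else:
            cum = np.cumsum(w)
            parents = np.searchsorted(cum, rng.random(n_gametes) * cum[-1])
            parents = np.minimum(parents, n - 1).astype(np.int64)
        phases = rng.integers(0, 2, n_gametes).astype(np.int64)

        # crossovers, sorted within each gamete
        n_x = rng.poisson(cfg.r * cfg.L, n_gametes)
        bp_hi = np.cumsum(n_x)
        bp_lo = bp_hi - n_x
        bp_flat = rng.integers(0, cfg.L, int(bp_hi[-1]))
        order = np.lexsort((bp_flat, np.repeat(np.arange(n_gametes), n_x)))
        bp_flat = bp_flat[order]

        # new mutations (infinite sites on integer coordinates; collisions
        # with segregating or fixed positions are dropped)
        new_pos = np.unique(rng.integers(0, cfg.L, rng.poisson(n_gametes * cfg.mu * cfg.L)))
        ok = (
            ~_in_sorted(new_pos, pop.pos[: pop.n_core])
            & ~np.isin(new_pos, pop.pos[pop.n_core :])
            & ~_in_sorted(new_pos, pop.fixed)
        )
        new_pos = new_pos[ok]
        new_owner = rng.integers(0, n_gametes, len(new_pos))
        new_s = self._assign_effects(new_pos)

        c_old = len(pop.pos)
        c_core = pop.n_core
        m_new = len(new_pos)
        final = np.empty((n_gametes, c_old + m_new), dtype=np.uint8)
        bcol = np.searchsorted(pop.pos[:c_core], bp_flat)
        _reproduce(
            pop.H, c_core, c_old, pop.pos[c_core:c_old], parents, phases,
            bp_flat, bp_lo, bp_hi, bcol, final,
        )
        if m_new:
            final[new_owner, c_old + np.arange(m_new)] = 1

        child = _Pop(n)
        child.H = final
        child.pos = np.concatenate([pop.pos, new_pos])
        child.s = np.concatenate([pop.s, new_s])
        child.n_core = c_core
        child.fixed = pop.fixed
        return child

    # -- migration --------------------------------------------------------

    def _migrant_derived(self, source: _Pop) -> np.ndarray:
        """Derived-position set of one gamete sampled from ``source``."""
        rng = self.rng
        p = int(rng.integers(0, source.n))
        phase = int(rng.integers(0, 2))
        bp = np.sort(rng.integers(0, self.cfg.L, rng.poisson(self.cfg.r * self.cfg.L)))
        n_passed = np.searchsorted(bp, source.pos, side="right")
        cur = (phase + n_passed) % 2
        hap = np.where(cur == 0, source.H[2 * p], source.H[2 * p + 1])
        active = source.pos[hap == 1]
        return np.sort(np.concatenate([active, source.fixed]))

    def _insert_columns(self, pop: _Pop, positions: np.ndarray, fill: int, pop_idx: int):
        """Materialize new columns (constant ``fill``) at sorted positions."""
        if len(positions) == 0:
            return
        at = np.searchsorted(pop.pos, positions)
        pop.H = np.insert(pop.H, at, fill, axis=1)
        pop.pos = np.insert(pop.pos, at, positions)
        s_vals = np.array(
            [self.effects.get(int(p), (0.0, 0.0))[pop_idx] for p in positions]
        )
        pop.s = np.insert(pop.s, at, s_vals)
        pop.n_core = len(pop.pos)

    def _apply_migration(self, children: list[_Pop]):
        """Whole-individual migration: offspring with both parents from the
        other population, at rate m per offspring (mean Nm migrants/gen)."""
        cfg = self.cfg
        counts = []
        for tgt_idx in (0, 1):
            src_idx = 1 - tgt_idx
            k = int(self.rng.binomial(cfg.N, cfg.m))
            counts.append(k)
            tgt = children[tgt_idx]
            src = self.pops[src_idx]
            for _ in range(k):
                ind = int(self.rng.integers(0, cfg.N))
                for g in range(2):
                    derived = self._migrant_derived(src)
                    # columns the target lacks but the migrant carries
                    novel = derived[
                        ~_in_sorted(derived, tgt.pos) & ~_in_sorted(derived, tgt.fixed)
                    ]
                    self._insert_columns(tgt, novel, 0, tgt_idx)
                    # target-fixed positions the migrant does not carry
                    refix = tgt.fixed[~_in_sorted(tgt.fixed, derived)]
                    self._insert_columns(tgt, refix, 1, tgt_idx)
                    if len(refix):
                        tgt.fixed = tgt.fixed[_in_sorted(tgt.fixed, derived)]
                    row = np.zeros(len(tgt.pos), dtype=np.uint8)
                    row[_in_sorted(tgt.pos, derived)] = 1
                    tgt.H[2 * ind + g] = row
        self.migrant_counts.append(tuple(counts))

    # -- driver -----------------------------------------------------------

    def run(self, snapshot_times: list[int]) -> dict[int, pd.DataFrame]:
        """Burn in, split, diverge; return {t_gen_post_split: window stats}."""
        cfg = self.cfg
        compact_every = 4
        for t in range(cfg.t_burn):
            self.pops[0] = self._step_pop(self.pops[0], 0)
            if t % compact_every == 0:
                self.pops[0].compact()
        self.pops[0].compact()

        # split
        self.phase = "divergence"
        self.pops = [self.pops[0], self.pops[0].copy()]
        if cfg.scenario == "local_adaptation" and cfg.prop_pos > 0:
            self._recruit_standing_variation()

        results = {}
        snapshots = sorted(set(snapshot_times))
        if 0 in snapshots:
            results[0] = self._snapshot()
        for t in range(1, cfg.t_div + 1):
            children = [self._step_pop(p, i) for i, p in enumerate(self.pops)]
            if cfg.m > 0:
                for p in children:
                    p.compact()  # migration bookkeeping needs sorted columns
                self._apply_migration(children)
            self.pops = children
            if t % compact_every == 0 or t in snapshots:
                for p in self.pops:
                    p.compact()
            if t in snapshots:
                results[t] = self._snapshot()
        return results

    def _recruit_standing_variation(self):
        """Local adaptation from standing variation: at the split, each
        segregating neutral tail mutation becomes beneficial in one random
        population with probability prop_pos."""
        cfg = self.cfg
        lo, hi = cfg.tail_bounds
        pop = self.pops[0]  # identical to pops[1] right after the split
        candidates = np.flatnonzero((pop.s == 0.0) & ((pop.pos < lo) | (pop.pos >= hi)))
        recruit = candidates[self.rng.random(len(candidates)) < cfg.prop_pos]
        which = self.rng.integers(0, 2, len(recruit))
        for c, w in zip(recruit, which):
            eff = (cfg.s_pos, 0.0) if w == 0 else (0.0, cfg.s_pos)
            self.effects[int(pop.pos[c])] = eff
            self.pops[0].s[c] = eff[0]
            self.pops[1].s[c] = eff[1]

    # -- sampling ---------------------------------------------------------

    def _snapshot(self) -> pd.DataFrame:
        cfg = self.cfg
        a = self.pops[0]
        b = self.pops[1] if len(self.pops) > 1 else self.pops[0]
        ids_a = self.rng.choice(cfg.N, size=min(cfg.n_sample, cfg.N), replace=False)
        ids_b = self.rng.choice(cfg.N, size=min(cfg.n_sample, cfg.N), replace=False)
        matrix = _sample_matrix(a, b, ids_a, ids_b)
        windows = [
            WindowSpec("sim", w0, w0 + cfg.window_bp, cfg.window_bp, cfg.window_bp)
            for w0 in range(0, cfg.L, cfg.window_bp)
        ]
        rows = []
        for w in windows:
            sl = matrix.site_slice(w.chrom, w.start, w.end)
            extra = cfg.window_bp - (sl.stop - sl.start)
            pi_a, _ = pi_window(matrix, "a", w, 2, extra_invariant=extra)
            pi_b, _ = pi_window(matrix, "b", w, 2, extra_invariant=extra)
            dxy, _ = dxy_window(matrix, "a", "b", w, 2, extra_invariant=extra)
            fst, _ = fst_window(matrix, "a", "b", w, 2, extra_invariant=extra)
            rows.append((w.start, w.end, pi_a, pi_b, dxy, fst))
        return pd.DataFrame(rows, columns=["start", "end", "pi_a", "pi_b", "dxy", "fst"])


def _sample_matrix(a: _Pop, b: _Pop, ids_a, ids_b) -> GenotypeMatrix:
    """Genotype matrix of sampled individuals over the union site set.

    Sites fixed within a population (archived out of its matrix) are
    re-materialized as all-derived for that population's samples, so d_xy
    and F_ST see every fixed difference.  Sites fixed in both populations
    carry no information and are dropped.
    """
    signal = np.unique(
        np.concatenate(
            [a.pos, b.pos, np.setdiff1d(a.fixed, b.fixed), np.setdiff1d(b.fixed, a.fixed)]
        )
    )
    both_fixed = np.intersect1d(a.fixed, b.fixed)
    signal = signal[~_in_sorted(signal, both_fixed)]

    def pop_calls(pop: _Pop, ids):
        rows = np.empty((2 * len(ids),), dtype=np.int64)
        rows[0::2] = 2 * np.asarray(ids)
        rows[1::2] = 2 * np.asarray(ids) + 1
        col_idx = np.searchsorted(pop.pos, signal)
        col_idx_c = np.minimum(col_idx, max(len(pop.pos) - 1, 0))
        present = np.zeros(len(signal), dtype=bool)
        if len(pop.pos):
            present = pop.pos[col_idx_c] == signal
        calls = np.zeros((len(signal), len(ids), 2), dtype=np.int8)
        if present.any():
            block = pop.H[np.ix_(rows, col_idx_c[present])]  # (2k, S_present)
            calls[present, :, 0] = block[0::2].T
            calls[present, :, 1] = block[1::2].T
        is_fixed = _in_sorted(signal, pop.fixed)
        calls[is_fixed] = 1
        return calls

    calls = np.concatenate([pop_calls(a, ids_a), pop_calls(b, ids_b)], axis=1)
    individuals = [f"a_{i}" for i in range(len(ids_a))] + [
        f"b_{i}" for i in range(len(ids_b))
    ]
    taxon_map = {name: name.split("_")[0] for name in individuals}
    n_sites = len(signal)
    return GenotypeMatrix(
        chroms=np.full(n_sites, "sim", dtype=object),
        positions=signal,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        calls=calls,
        individuals=individuals,
        taxon_map=taxon_map,
    )


@dataclass
class SimOutput:
    """Per-timepoint window landscapes of one simulation run.

    ``windows`` has one row per (timepoint, window) with pi_a, pi_b, d_xy,
    F_ST; ``timepoint`` is in units of T_div / n_timepoints generations
    since the split (N generations under the defaults).
    """

    config: SimScenario
    windows: pd.DataFrame
    correlations: pd.DataFrame = field(default=None)
    migrants_per_generation: np.ndarray = field(default=None)
    replicate: int = 0

    def at_time(self, timepoint: float) -> pd.DataFrame:
        return self.windows[self.windows["timepoint"] == timepoint]


def run_scenario(config: SimScenario) -> SimOutput:
    """Run one forward simulation and return its window-statistic course.

    Snapshots are taken at the split (timepoint 0) and at ``n_timepoints``
    evenly spaced times through the divergence phase (10 by default, i.e.
    every N generations up to 10N).
    """
    s_abs = max(abs(config.s_neg), abs(config.s_pos))
    if config.scenario != "neutral" and s_abs > 0.1:
        warnings.warn(f"|s| = {s_abs:.3g}: rescaled selection is strong")
    engine = _Engine(config)
    step = config.t_div / config.n_timepoints
    times = [0] + [round(step * (k + 1)) for k in range(config.n_timepoints)]
    frames = engine.run(times)
    out = []
    for t, df in sorted(frames.items()):
        df = df.copy()
        df.insert(0, "timepoint", t / step if step else 0.0)
        df.insert(1, "t_gen", t)
        out.append(df)
    result = SimOutput(
        config=config,
        windows=pd.concat(out, ignore_index=True),
        migrants_per_generation=np.asarray(engine.migrant_counts),
    )
    result.correlations = sim_correlation_course(result)
    return result


def run_replicates(config: SimScenario, n_reps: int) -> list[SimOutput]:
    """Independent replicates with seeds spawned from the config seed."""
    seeds = np.random.SeedSequence(config.seed).generate_state(n_reps) % (2**31)
    outputs = []
    for i in range(n_reps):
        rep = run_scenario(replace(config, seed=int(seeds[i])))
        rep.replicate = i
        outputs.append(rep)
    return outputs


def sim_correlation_course(output: SimOutput) -> pd.DataFrame:
    """Per-timepoint Pearson r(d_xy, pi) and r(F_ST, pi) across windows.

    pi is the mean of the two populations; a zero-variance landscape at a
    timepoint yields a missing correlation.
    """
    rows = []
    for t, df in output.windows.groupby("timepoint"):
        if len(df) < 3:
            raise ValueError("need at least 3 windows for correlations")
        pi = (df["pi_a"].to_numpy() + df["pi_b"].to_numpy()) / 2.0

        def corr(x, y):
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                return np.nan
            return float(np.corrcoef(x[ok], y[ok])[0, 1])

        rows.append(
            {
                "timepoint": t,
                "r_dxy_pi": corr(df["dxy"].to_numpy(), pi),
                "r_fst_pi": corr(df["fst"].to_numpy(), pi),
            }
        )
    return pd.DataFrame(rows)
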
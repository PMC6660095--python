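"""Coalescent generator of a synthetic 9-taxon radiation with ground truth.

Windows are simulated as independent coalescent loci under a dated species
tree.  Heterogeneous landscapes are injected phenomenologically: every
population size in a window is scaled by a local-Ne multiplier

    lambda_w = 1 / (1 + alpha * g_w / (rho_w + eps))

driven by spatially autocorrelated gene-density (g_w) and recombination
(rho_w) tracks, which mimics the diversity-suppressing signature of linked
selection (more functional targets, less recombination -> lower diversity)
without simulating selection itself.  Admixture is injected as
lineage-reassignment pulses restricted to configurable window sets, and
the generator exports the full ground truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import msprime
import numpy as np
import pandas as pd

from mimland.genomic_io import MISSING, GenotypeMatrix, WindowSpec

__all__ = [
    "AdmixtureEvent",
    "SyntheticConfig",
    "RadiationData",
    "generate_landscape_tracks",
    "generate_radiation",
    "write_dataset",
    "DEFAULT_TOPOLOGY",
]

# Tip names follow the taxa of a bush-monkeyflower-like radiation: a very
# recent ecotype pair (red/yellow), nested ingroup splits, and a distant
# outgroup.  Branch lengths are in generations.
DEFAULT_TOPOLOGY = (
    "(((((((red:4000,yellow:4000):8000,aurantiacus:12000):8000,"
    "(longiflorus:8000,calycinus:8000):12000):10000,parviflorus:30000):10000,"
    "aridus:40000):10000,grandiflorus:50000):50000,clevelandii:100000);"
)


@dataclass
class AdmixtureEvent:
    """A pulse moving ``fraction`` of the recipient's ancestry from donor.

    ``windows`` selects affected window indices (None = genome-wide).
    """

    donor: str
    recipient: str
    time: float
    fraction: float
    windows: list[int] | None = None


@dataclass
class SyntheticConfig:
    topology: str = DEFAULT_TOPOLOGY
    outgroup: str = "clevelandii"
    ne_base: float = 10_000.0
    n_per_taxon: int = 4
    n_outgroup: int = 3
    n_chrom: int = 10
    n_windows: int = 400
    window_bp: int = 2_000
    mu: float = 2.5e-7
    recomb_rate: float = 3e-6
    alpha: float = 1.0
    eps: float = 0.5
    smoothness: int = 6
    cross_corr: bool = True
    admixture_events: list[AdmixtureEvent] = field(default_factory=list)
    missing_rate: float = 0.05
    seed: int = 0


@dataclass
class RadiationData:
    matrix: GenotypeMatrix
    windows: list[WindowSpec]
    gene_count: pd.DataFrame
    recomb_rate: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticConfig


def generate_landscape_tracks(
    n_windows: int,
    smoothness: int,
    seed: int | None = None,
    cross_corr: bool = True,
    mean_genes: float = 5.0,
    mean_recomb: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Spatially autocorrelated gene-count and recombination tracks.

    Both tracks are moving averages (width ``smoothness``) of i.i.d. gamma
    draws, so ``smoothness=1`` gives an i.i.d. track and larger values give
    lag-1 autocorrelation approaching 1.  With ``cross_corr`` the
    recombination track is damped where gene density is high, mirroring
    the negative gene-density/recombination correlation of real genomes.
    """
    if n_windows < 10:
        raise ValueError("need at least 10 windows")
    if smoothness < 1:
        raise ValueError("smoothness must be >= 1")
    rng = np.random.default_rng(seed)

    def smooth(x):
        kernel = np.ones(smoothness) / smoothness
        return np.convolve(x, kernel, mode="valid")

    raw_g = rng.gamma(2.0, 1.0, n_windows + smoothness - 1)
    g = smooth(raw_g)
    g = g * (mean_genes / g.mean())
    gene_count = np.round(g).astype(int)

    raw_r = rng.gamma(3.0, 1.0, n_windows + smoothness - 1)
    r = smooth(raw_r)
    if cross_corr:
        r = r / (1.0 + 0.4 * g)
    r = r * (mean_recomb / r.mean())
    return gene_count, r


def simulate_quartet_freqs(
    seed: int,
    n_samples: tuple[int, int, int, int] = (4, 4, 4, 3),
    ne: float = 10_000.0,
    split_times: tuple[float, float, float] = (4_000.0, 8_000.0, 20_000.0),
    sequence_length: float = 2e6,
    mu: float = 2e-8,
    recomb: float = 1e-8,
    p2_p3_pulse: tuple[float, float] | None = None,
):
    """Coalescent (((P1,P2),P3),O) quartet, polarized against the outgroup.

    Simulates one chromosome, keeps biallelic sites at which the outgroup
    sample is fixed, and returns ``(p1, p2, p3, positions)`` derived-allele
    frequency arrays — the inputs of the ABBA-BABA statistics.  With
    ``p2_p3_pulse = (time, fraction)`` a backwards pulse moves that
    fraction of P2's ancestry into P3 (i.e. forward-time introgression
    from P3 into P2); otherwise the history is migration-free, which is
    the null for D-statistic calibration.
    """
    t12, t123, t_o = split_times
    demog = msprime.Demography()
    for name in ("P1", "P2", "P3", "O", "anc12", "anc123", "root"):
        demog.add_population(name=name, initial_size=ne)
    if p2_p3_pulse is not None:
        t_pulse, frac = p2_p3_pulse
        if not 0 < t_pulse < t12:
            raise ValueError("pulse must postdate the P1/P2 split")
        demog.add_mass_migration(time=t_pulse, source="P2", dest="P3", proportion=frac)
    demog.add_population_split(time=t12, derived=["P1", "P2"], ancestral="anc12")
    demog.add_population_split(time=t123, derived=["anc12", "P3"], ancestral="anc123")
    demog.add_population_split(time=t_o, derived=["anc123", "O"], ancestral="root")
    demog.sort_events()
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31) + 1
    ts = msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(n, population=p, ploidy=2)
            for n, p in zip(n_samples, ("P1", "P2", "P3", "O"))
        ],
        demography=demog,
        sequence_length=sequence_length,
        recombination_rate=recomb,
        random_seed=int(seeds[0]),
    )
    ts = msprime.sim_mutations(
        ts, rate=mu, model=msprime.BinaryMutationModel(), random_seed=int(seeds[1])
    )
    gm = ts.genotype_matrix()
    bounds = np.cumsum([0] + [2 * n for n in n_samples])  # haplotype columns
    counts = [gm[:, bounds[i] : bounds[i + 1]].sum(axis=1) for i in range(4)]
    n_allele = [2 * n for n in n_samples]
    og = counts[3]
    keep = (og == 0) | (og == n_allele[3])
    derived_is_alt = og[keep] == 0
    freqs = []
    for i in range(3):
        f = counts[i][keep] / n_allele[i]
        freqs.append(np.where(derived_is_alt, f, 1.0 - f))
    return (*freqs, ts.sites_position[keep].astype(np.int64))


def simulate_quartet_loci(
    seed: int,
    n_loci: int = 50,
    locus_bp: float = 1e5,
    locus_spacing: int = 500_000,
    n_samples: tuple[int, int, int, int] = (4, 4, 4, 3),
    ne: float = 10_000.0,
    split_times: tuple[float, float, float] = (4_000.0, 8_000.0, 20_000.0),
    mu: float = 1e-8,
    recomb: float = 1e-8,
    p2_p3_pulse: tuple[float, float] | None = None,
):
    """Like `simulate_quartet_freqs` but as independent loci.

    Each locus is an unlinked coalescent simulation whose positions are
    offset by ``locus_spacing`` so that a block jackknife with that block
    size treats loci as blocks — free recombination between blocks, as in
    a genome much longer than the linkage scale.
    """
    t12, t123, t_o = split_times
    demog = msprime.Demography()
    for name in ("P1", "P2", "P3", "O", "anc12", "anc123", "root"):
        demog.add_population(name=name, initial_size=ne)
    if p2_p3_pulse is not None:
        t_pulse, frac = p2_p3_pulse
        if not 0 < t_pulse < t12:
            raise ValueError("pulse must postdate the P1/P2 split")
        demog.add_mass_migration(time=t_pulse, source="P2", dest="P3", proportion=frac)
    demog.add_population_split(time=t12, derived=["P1", "P2"], ancestral="anc12")
    demog.add_population_split(time=t123, derived=["anc12", "P3"], ancestral="anc123")
    demog.add_population_split(time=t_o, derived=["anc123", "O"], ancestral="root")
    demog.sort_events()
    samples = [
        msprime.SampleSet(n, population=p, ploidy=2)
        for n, p in zip(n_samples, ("P1", "P2", "P3", "O"))
    ]
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_loci) % (2**31) + 1
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=demog,
        sequence_length=locus_bp,
        recombination_rate=recomb,
        random_seed=int(seeds[0]),
        num_replicates=n_loci,
    )
    bounds = np.cumsum([0] + [2 * n for n in n_samples])
    n_allele = [2 * n for n in n_samples]
    p_parts: list[list[np.ndarray]] = [[], [], []]
    pos_parts = []
    for k, ts in enumerate(reps):
        ts = msprime.sim_mutations(
            ts, rate=mu, model=msprime.BinaryMutationModel(), random_seed=int(seeds[n_loci + k])
        )
        gm = ts.genotype_matrix()
        counts = [gm[:, bounds[i] : bounds[i + 1]].sum(axis=1) for i in range(4)]
        og = counts[3]
        keep = (og == 0) | (og == n_allele[3])
        derived_is_alt = og[keep] == 0
        for i in range(3):
            f = counts[i][keep] / n_allele[i]
            p_parts[i].append(np.where(derived_is_alt, f, 1.0 - f))
        pos_parts.append(ts.sites_position[keep].astype(np.int64) + k * locus_spacing)
    return (
        np.concatenate(p_parts[0]),
        np.concatenate(p_parts[1]),
        np.concatenate(p_parts[2]),
        np.concatenate(pos_parts),
    )


def _node_ages(tree: dendropy.Tree) -> dict:
    ages = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            child = node.child_nodes()[0]
            ages[node] = ages[child] + child.edge.length
    return ages


def _parse_topology(topology: str):
    tree = dendropy.Tree.get(data=topology, schema="newick")
    ages = _node_ages(tree)
    names = {}
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            names[node] = node.taxon.label
        else:
            names[node] = f"anc{k}"
            k += 1
    tip_parent_age = {
        lf.taxon.label: ages[lf.parent_node] for lf in tree.leaf_node_iter()
    }
    splits = [
        (ages[n], names[n], [names[c] for c in n.child_nodes()])
        for n in tree.preorder_internal_node_iter()
    ]
    return tree, names, splits, tip_parent_age


def _build_demography(
    splits, tip_names, internal_names, ne, events: list[AdmixtureEvent]
):
    demog = msprime.Demography()
    for name in tip_names:
        demog.add_population(name=name, initial_size=ne)
    for name in internal_names:
        demog.add_population(name=name, initial_size=ne)
    for ev in events:
        demog.add_mass_migration(
            time=ev.time, source=ev.recipient, dest=ev.donor, proportion=ev.fraction
        )
    for age, anc, derived in sorted(splits):
        demog.add_population_split(time=age, derived=derived, ancestral=anc)
    demog.sort_events()
    return demog


def generate_radiation(config: SyntheticConfig) -> RadiationData:
    """Simulate genotypes, covariate tracks, and ground truth per window.

    Each window is an independent coalescent locus under the species tree
    with all population sizes scaled by lambda_w; genotypes are emitted
    diploid with explicit invariant sites and i.i.d. missingness.
    """
    cfg = config
    tree, names, splits, tip_parent_age = _parse_topology(cfg.topology)
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if cfg.outgroup not in tips:
        raise ValueError(f"outgroup {cfg.outgroup!r} not a tip of the topology")
    internal = [n for n in names.values() if n.startswith("anc")]

    for ev in cfg.admixture_events:
        limit = min(tip_parent_age[ev.donor], tip_parent_age[ev.recipient])
        if ev.time >= limit:
            raise ValueError(
                f"admixture at t={ev.time} predates the divergence of "
                f"{ev.donor}/{ev.recipient} (limit {limit})"
            )

    rng = np.random.default_rng(cfg.seed)
    gene_count, recomb = generate_landscape_tracks(
        cfg.n_windows, cfg.smoothness, seed=rng.integers(2**31), cross_corr=cfg.cross_corr
    )
    lam = 1.0 / (1.0 + cfg.alpha * gene_count / (recomb + cfg.eps))

    per_chrom = cfg.n_windows // cfg.n_chrom
    if per_chrom * cfg.n_chrom != cfg.n_windows:
        raise ValueError("n_windows must be divisible by n_chrom")
    windows = [
        WindowSpec(
            chrom=f"LG{c + 1}",
            start=i * cfg.window_bp,
            end=(i + 1) * cfg.window_bp,
            size=cfg.window_bp,
            step=cfg.window_bp,
        )
        for c in range(cfg.n_chrom)
        for i in range(per_chrom)
    ]

    taxa_n = {t: (cfg.n_outgroup if t == cfg.outgroup else cfg.n_per_taxon) for t in tips}
    individuals = [f"{t}_{i}" for t in tips for i in range(taxa_n[t])]
    taxon_map = {f"{t}_{i}": t for t in tips for i in range(taxa_n[t])}
    n_ind = len(individuals)
    sample_sets = [msprime.SampleSet(taxa_n[t], population=t, ploidy=2) for t in tips]

    admix_frac = np.zeros(cfg.n_windows)
    events_by_window: list[list[AdmixtureEvent]] = [[] for _ in range(cfg.n_windows)]
    for ev in cfg.admixture_events:
        targets = range(cfg.n_windows) if ev.windows is None else ev.windows
        for w in targets:
            events_by_window[w].append(ev)
            admix_frac[w] += ev.fraction

    seeds = rng.integers(1, 2**31, size=(cfg.n_windows, 2))
    chrom_col, pos_col, ref_col, alt_col, call_blocks = [], [], [], [], []
    mid_trees = []
    for w_idx, w in enumerate(windows):
        demog = _build_demography(
            splits, tips, internal, cfg.ne_base, events_by_window[w_idx]
        )
        for pop in demog.populations:
            pop.initial_size = pop.initial_size * lam[w_idx]
        ts = msprime.sim_ancestry(
            samples=sample_sets,
            demography=demog,
            sequence_length=cfg.window_bp,
            recombination_rate=cfg.recomb_rate,
            random_seed=int(seeds[w_idx, 0]),
        )
        ts = msprime.sim_mutations(
            ts,
            rate=cfg.mu,
            model=msprime.BinaryMutationModel(),
            random_seed=int(seeds[w_idx, 1]),
        )
        mid_trees.append(ts.at(cfg.window_bp / 2).newick())
        gm = ts.genotype_matrix()  # variant sites x haplotypes
        var_pos = ts.sites_position.astype(np.int64)

        calls = np.zeros((cfg.window_bp, n_ind, 2), dtype=np.int8)
        if len(var_pos):
            calls[var_pos, :, 0] = gm[:, 0::2]
            calls[var_pos, :, 1] = gm[:, 1::2]
        variant_mask = np.zeros(cfg.window_bp, dtype=bool)
        variant_mask[var_pos] = True

        chrom_col.append(np.full(cfg.window_bp, w.chrom, dtype=object))
        pos_col.append(np.arange(w.start, w.end, dtype=np.int64))
        ref_col.append(np.full(cfg.window_bp, "A", dtype=object))
        alt = np.full(cfg.window_bp, ".", dtype=object)
        alt[variant_mask] = "T"
        alt_col.append(alt)
        call_blocks.append(calls)

    calls = np.concatenate(call_blocks)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape[:2]) < cfg.missing_rate
        calls[mask] = MISSING

    matrix = GenotypeMatrix(
        chroms=np.concatenate(chrom_col),
        positions=np.concatenate(pos_col),
        ref=np.concatenate(ref_col),
        alt=np.concatenate(alt_col),
        calls=calls,
        individuals=individuals,
        taxon_map=taxon_map,
    )
    coords = pd.DataFrame(
        [(w.chrom, w.start, w.end) for w in windows], columns=["chrom", "start", "end"]
    )
    truth = coords.copy()
    truth["lambda"] = lam
    truth["gene_count"] = gene_count
    truth["recomb_rate"] = recomb
    truth["admix_fraction"] = admix_frac
    truth["admixed"] = admix_frac > 0
    truth["expected_pi"] = 4.0 * cfg.ne_base * lam * cfg.mu
    truth["midpoint_tree"] = mid_trees
    return RadiationData(
        matrix=matrix,
        windows=windows,
        gene_count=coords.assign(gene_count=gene_count),
        recomb_rate=coords.assign(recomb_rate=recomb),
        truth=truth,
        config=cfg,
    )


def write_dataset(data: RadiationData, outdir) -> dict[str, str]:
    """Export VCF, taxon map, gene BED, genetic-map TSV, and truth table.

    The gene BED places ``gene_count`` short intervals inside each window;
    the genetic map places 4 markers per window so the per-window mean
    recombination rate is recoverable (3 interior interval estimates per
    window at the generated cM/Mbp rate).
    """
    import pathlib

    from mimland.genomic_io import write_vcf

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "radiation.vcf",
        "taxon_map": outdir / "taxon_map.tsv",
        "genes": outdir / "genes.bed",
        "genetic_map": outdir / "genetic_map.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_vcf(data.matrix, paths["vcf"])
    with open(paths["taxon_map"], "w") as fh:
        for ind in data.matrix.individuals:
            fh.write(f"{ind}\t{data.matrix.taxon_map[ind]}\n")

    rng = np.random.default_rng(data.config.seed + 12345)
    with open(paths["genes"], "w") as fh:
        for w, g in zip(data.windows, data.gene_count["gene_count"]):
            length = max(10, data.config.window_bp // 20)
            for k in range(int(g)):
                start = int(rng.integers(w.start, max(w.start + 1, w.end - length)))
                fh.write(f"{w.chrom}\t{start}\t{min(start + length, w.end)}\tgene\n")

    rows = []
    cm_acc: dict[str, float] = {}
    marker_id = 0
    for w, rate in zip(data.windows, data.recomb_rate["recomb_rate"]):
        cm = cm_acc.get(w.chrom, 0.0)
        length = w.end - w.start
        # markers at 0, 1/3, 2/3, and the last bp of the window, each with
        # cM consistent with the window's rate, so every interval (incl.
        # the 1-bp join to the next window) carries the local rate
        for k in range(4):
            offset = round(k * (length - 1) / 3)
            bp = w.start + offset + 1
            rows.append((f"m{marker_id}", w.chrom, bp, cm + rate * offset / 1e6))
            marker_id += 1
        cm_acc[w.chrom] = cm + rate * length / 1e6
    pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM"]).to_csv(
        paths["genetic_map"], sep="\t", index=False
    )
    data.truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
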
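"""Genotype, annotation, genetic-map, and window-grid input handling.

Internal coordinates are 0-based half-open throughout; report coordinates
(as printed in output tables) are 1-based inclusive.  VCF positions are
1-based and converted on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class WindowSpec:
    """A genomic window, 0-based half-open."""

    chrom: str
    start: int
    end: int
    size: int
    step: int

    @property
    def label(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def report_coords(self) -> tuple[str, int, int]:
        """1-based inclusive coordinates for output tables."""
        return (self.chrom, self.start + 1, self.end)


@dataclass
class GenotypeMatrix:
    """Sites x individuals diploid genotypes with missing values.

    Attributes
    ----------
    chroms : per-site contig identifier (object array).
    positions : per-site 0-based coordinate, strictly increasing per contig.
    ref, alt : per-site allele symbols; ``alt`` is ``"."`` at invariant sites.
    calls : int8 array of shape (n_sites, n_individuals, 2) holding allele
        indices (0 = ref, 1 = alt) or ``MISSING`` (-1).  Half-called
        genotypes are stored fully missing.
    individuals : ordered sample identifiers.
    taxon_map : individual -> taxon label, covering every individual.
    """

    chroms: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    individuals: list[str]
    taxon_map: dict[str, str]
    _dosage: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n_sites = len(self.positions)
        if self.calls.shape != (n_sites, len(self.individuals), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n_sites} sites x {len(self.individuals)} individuals"
            )
        missing = set(self.individuals) - set(self.taxon_map)
        if missing:
            raise ValueError(f"individuals absent from taxon map: {sorted(missing)}")
        for chrom in dict.fromkeys(self.chroms):
            pos = self.positions[self.chroms == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def taxa(self) -> list[str]:
        seen = dict.fromkeys(self.taxon_map[i] for i in self.individuals)
        return list(seen)

    def taxon_indices(self, taxon: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.individuals) if self.taxon_map[s] == taxon]
        if not idx:
            raise KeyError(f"taxon {taxon!r} not present in taxon map")
        return np.asarray(idx, dtype=np.intp)

    @property
    def is_variant(self) -> np.ndarray:
        return np.asarray(self.alt) != "."

    def dosage(self) -> np.ndarray:
        """Per-site, per-individual alternate-allele dosage / 2.

        Values are 0, 0.5, or 1; missing genotypes are NaN.  Cached, since
        every window statistic is computed from this representation.
        """
        if self._dosage is None:
            calls = self.calls
            d = (calls[:, :, 0] + calls[:, :, 1]) / 2.0
            d[np.any(calls == MISSING, axis=2)] = np.nan
            self._dosage = d
        return self._dosage

    def site_slice(self, chrom: str, start: int, end: int) -> slice:
        """Index slice of sites falling in [start, end) on ``chrom``."""
        mask = self.chroms == chrom
        offsets = np.flatnonzero(mask)
        if offsets.size == 0:
            return slice(0, 0)
        pos = self.positions[mask]
        lo, hi = np.searchsorted(pos, [start, end])
        return slice(int(offsets[0] + lo), int(offsets[0] + hi))


def read_taxon_map(path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>taxon`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "taxon"], dtype=str)
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate samples in taxon map: {dupes}")
    return dict(zip(df["sample"], df["taxon"]))


def load_genotypes(vcf_source, taxon_map: dict[str, str]) -> GenotypeMatrix:
    """Read a VCF (variant + invariant records) into a `GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped; invariant records (no ALT)
    are retained with ``alt="."``.  Half-called diploid genotypes are stored
    as fully missing.  Samples absent from ``taxon_map`` are a hard error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_source), gts012=False)
    samples = list(vcf.samples)
    absent = set(samples) - set(taxon_map)
    if absent:
        raise ValueError(f"VCF samples absent from taxon map: {sorted(absent)}")

    chroms, positions, refs, alts, call_rows = [], [], [], [], []
    for v in vcf:
        alt_alleles = [a for a in v.ALT if a not in (".", "<NON_REF>")]
        if len(alt_alleles) > 1:
            continue  # multiallelic
        if len(v.REF) != 1 or any(len(a) != 1 for a in alt_alleles):
            continue  # indels / complex
        gts = np.asarray(v.genotype.array())[:, :2].astype(np.int8)
        gts[np.any(gts < 0, axis=1)] = MISSING  # half-called -> fully missing
        chroms.append(v.CHROM)
        positions.append(v.POS - 1)
        refs.append(v.REF)
        alts.append(alt_alleles[0] if alt_alleles else ".")
        call_rows.append(gts)
    vcf.close()

    calls = (
        np.stack(call_rows) if call_rows else np.empty((0, len(samples), 2), np.int8)
    )
    return GenotypeMatrix(
        chroms=np.asarray(chroms, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        calls=calls,
        individuals=samples,
        taxon_map=dict(taxon_map),
    )


def make_windows(
    contig_lengths: dict[str, int], size: int, step: int | None = None
) -> list[WindowSpec]:
    """Enumerate a (sliding) window grid over each contig.

    Full windows start at every multiple of ``step`` with ``start + size <=
    length``.  A contig shorter than one window yields a single truncated
    window covering the whole contig; for nonoverlapping grids
    (``step == size``) a trailing truncated window covers any remainder.
    """
    step = size if step is None else step
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    if step > size:
        raise ValueError("step must not exceed size")
    windows: list[WindowSpec] = []
    for chrom, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {chrom} has non-positive length")
        if length < size:
            windows.append(WindowSpec(chrom, 0, int(length), size, step))
            continue
        starts = range(0, length - size + 1, step)
        for s in starts:
            windows.append(WindowSpec(chrom, s, s + size, size, step))
        if step == size and windows[-1].end < length:
            windows.append(WindowSpec(chrom, windows[-1].end, int(length), size, step))
    return windows


def window_recombination(
    genetic_map: pd.DataFrame,
    windows: list[WindowSpec],
    top_fraction: float = 0.05,
    min_intervals: int = 3,
) -> pd.DataFrame:
    """Per-window mean recombination rate (cM/Mbp) from a marker map.

    Per-interval rates are delta-cM / delta-Mbp between adjacent markers on
    each contig.  The top ``top_fraction`` of rates genome-wide are
    discarded as artifacts before averaging; a window value is reported
    only when at least ``min_intervals`` surviving intervals overlap it.

    ``genetic_map`` needs columns ``marker, chrom, bp, cM`` with ``bp``
    1-based.
    """
    rows = []
    for chrom, grp in genetic_map.groupby("chrom", sort=False):
        grp = grp.sort_values("bp")
        bp = grp["bp"].to_numpy(dtype=np.int64)
        cm = grp["cM"].to_numpy(dtype=float)
        if len(bp) < 2:
            warnings.warn(f"contig {chrom}: fewer than 2 markers, skipped")
            continue
        for i in range(len(bp) - 1):
            dbp = bp[i + 1] - bp[i]
            if dbp == 0:
                warnings.warn(
                    f"contig {chrom}: zero physical distance at bp {bp[i]}, "
                    "interval skipped"
                )
                continue
            rate = (cm[i + 1] - cm[i]) / (dbp / 1e6)
            rows.append((chrom, bp[i] - 1, bp[i + 1] - 1, rate))
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "rate"])

    if len(intervals):
        k = int(np.floor(len(intervals) * top_fraction))
        if k > 0:
            cutoff_order = np.argsort(intervals["rate"].to_numpy())[::-1][:k]
            intervals = intervals.drop(intervals.index[cutoff_order])

    out = []
    for w in windows:
        sub = intervals[intervals["chrom"] == w.chrom]
        hit = sub[(sub["start"] < w.end) & (sub["end"] > w.start)]
        value = hit["rate"].mean() if len(hit) >= min_intervals else np.nan
        out.append((w.chrom, w.start, w.end, value))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "recomb_rate"])


def window_gene_count(
    features: pd.DataFrame,
    windows: list[WindowSpec],
    dialect: str = "bed",
) -> pd.DataFrame:
    """Count genes overlapping each window by >= 1 bp.

    A gene spanning several windows is counted in every one of them.
    ``features`` needs columns ``chrom, start, end``; ``dialect`` declares
    the coordinate convention: ``"bed"`` (0-based half-open) or ``"gff3"``
    (1-based inclusive).
    """
    if dialect not in ("bed", "gff3"):
        raise ValueError("dialect must be 'bed' or 'gff3'")
    feats = features[["chrom", "start", "end"]].copy()
    if dialect == "gff3":
        feats["start"] = feats["start"] - 1  # end stays: inclusive -> half-open

    known = {w.chrom for w in windows}
    unknown = set(feats["chrom"]) - known
    if unknown:
        warnings.warn(f"features on unknown contigs skipped: {sorted(unknown)}")
        feats = feats[feats["chrom"].isin(known)]

    by_chrom = {
        chrom: (
            np.sort(grp["start"].to_numpy(np.int64)),
            np.sort(grp["end"].to_numpy(np.int64)),
        )
        for chrom, grp in feats.groupby("chrom", sort=False)
    }
    out = []
    for w in windows:
        starts, ends = by_chrom.get(w.chrom, (np.empty(0, np.int64),) * 2)
        # overlap iff gene.start < w.end and gene.end > w.start
        n = np.searchsorted(starts, w.end, side="left") - np.searchsorted(
            ends, w.start, side="right"
        )
        out.append((w.chrom, w.start, w.end, int(n)))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "gene_count"])


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a `GenotypeMatrix` as an uncompressed VCF 4.2 text file.

    Invariant sites are emitted with ``ALT=.``; missing genotypes as
    ``./.``.  Streams formatted blocks rather than using a record API so
    that multi-hundred-thousand-site synthetic exports stay fast.
    """
    allele_sym = np.array(["0", "1"], dtype="U1")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(matrix.chroms):
            length = int(matrix.positions[matrix.chroms == chrom].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individuals)
            + "\n"
        )
        calls = matrix.calls
        n_sites = matrix.n_sites
        block = 20000
        for lo in range(0, n_sites, block):
            hi = min(lo + block, n_sites)
            sub = calls[lo:hi]
            a = np.where(sub[:, :, 0] >= 0, allele_sym[np.clip(sub[:, :, 0], 0, 1)], ".")
            b = np.where(sub[:, :, 1] >= 0, allele_sym[np.clip(sub[:, :, 1], 0, 1)], ".")
            gt = np.char.add(np.char.add(a.astype("U1"), "/"), b.astype("U1"))
            lines = []
            for i in range(hi - lo):
                j = lo + i
                lines.append(
                    f"{matrix.chroms[j]}\t{matrix.positions[j] + 1}\t.\t"
                    f"{matrix.ref[j]}\t{matrix.alt[j]}\t.\tPASS\t.\tGT\t"
                    + "\t".join(gt[i])
                )
            fh.write("\n".join(lines) + "\n")
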
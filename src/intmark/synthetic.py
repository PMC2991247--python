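"""Synthetic genomes, restriction maps, peak sets and integration sets.

The generator emulates the structure of real integration-site studies on a toy
genome, so every statistic in the package can be exercised with known ground
truth and no downloads:

* a genome of a few chromosomes (default 2 x 5 Mb — large enough for thousands
  of peaks and controls, small enough for seconds-scale tests);
* restriction recognition sites as a Poisson process (default rate 1/256 bp,
  the density of a 4-cutter motif);
* marker peak sets with log-normal widths on the ChIP-seq scale (~10^2-10^3
  bp), summits uniform or clustered;
* integration sites with a *planted* association fraction q: ceil(q V) sites
  fall at a random target summit plus a Normal(0, s^2) offset, the rest are
  uniform background, and the planted/background label of every site is kept
  so tests can compute the achievable within-window fraction exactly;
* the uniform-in-gene scenario: sites uniform inside gene bodies, with a
  virtual one-summit-per-TSS marker, for window-sweep plateau studies.

Every generator is a pure function of its arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ChromLayout, InputError, PeakSet, SiteSet
from .controls import RestrictionIndex

__all__ = [
    "SimConfig", "GeneModel",
    "simulate_genome", "simulate_peakset", "simulate_integrations",
    "simulate_gene_scenario", "random_fasta", "expected_wi",
]

_GENOME_RETRIES = 5


@dataclass
class SimConfig:
    """Bundle of generator defaults describing one synthetic study."""

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    restriction_rate: float = 1.0 / 256.0   # recognition sites per bp
    n_peaks: int = 1000
    peak_mean_width: float = 400.0          # bp, log-normal
    peak_width_sigma: float = 0.4           # log-scale sd
    clustered: bool = False
    n_sites: int = 500                      # V
    q: float = 0.7                          # planted association fraction
    offset_scale: float = 500.0             # s, bp
    control_ratio: int = 10                 # rho

    def __post_init__(self):
        if not (0.0 <= self.q <= 1.0):
            raise InputError("q must lie in [0, 1]")
        if self.offset_scale <= 0:
            raise InputError("offset scale must be positive")
        if min(self.n_chrom, self.chrom_length, self.n_peaks, self.n_sites) <= 0:
            raise InputError("counts and lengths must be positive")


def simulate_genome(n_chrom: int = 2, chrom_length: int = 5_000_000,
                    restriction_rate: float = 1.0 / 256.0,
                    seed: int = 0) -> tuple[ChromLayout, RestrictionIndex]:
    """Toy genome plus a Poisson-process restriction map, one process per chromosome."""
    layout = ChromLayout(tuple(f"chr{i + 1}" for i in range(n_chrom)),
                         np.full(n_chrom, chrom_length, dtype=np.int64))
    rng = np.random.default_rng([seed, 1])
    for attempt in range(_GENOME_RETRIES):
        by_chrom = {}
        ok = True
        for cid in range(n_chrom):
            n = rng.poisson(restriction_rate * chrom_length)
            if n == 0:
                ok = False
                break
            by_chrom[cid] = np.sort(rng.integers(0, chrom_length, size=n))
        if ok:
            return layout, RestrictionIndex("sim-resites", layout, by_chrom)
    raise InputError("restriction rate too low: a chromosome kept drawing zero sites")


def simulate_peakset(layout: ChromLayout, n_peaks: int = 1000,
                     mean_width: float = 400.0, width_sigma: float = 0.4,
                     clustered: bool = False, seed: int = 0,
                     label: str = "sim-marker") -> PeakSet:
    """Marker peaks: summits uniform (or clustered), widths log-normal.

    ``mean_width`` is the arithmetic mean of the log-normal, so the empirical
    mean width converges to it.  Peaks extending past a chromosome end are
    clipped (summit preserved inside the interval).
    """
    rng = np.random.default_rng([seed, 2])
    total = layout.total
    if clustered:
        n_clusters = max(n_peaks // 20, 1)
        centers = rng.uniform(0, total, size=n_clusters)
        g = centers[rng.integers(0, n_clusters, size=n_peaks)] + \
            rng.normal(0, 50_000, size=n_peaks)
        g = np.clip(g, 0, total - 1)
    else:
        g = rng.uniform(0, total, size=n_peaks)
    g = np.sort(g).astype(np.int64)
    offsets = layout.offsets
    cids = np.searchsorted(offsets, g, side="right") - 1
    summit = g - offsets[cids]

    mu = np.log(mean_width) - width_sigma ** 2 / 2.0
    widths = np.maximum(rng.lognormal(mu, width_sigma, size=n_peaks), 2.0).astype(np.int64)
    start = summit - widths // 2
    end = start + widths
    lengths = layout.lengths[cids]
    clipped = (start < 0) | (end > lengths)
    start = np.maximum(start, 0)
    end = np.minimum(end, lengths)
    summit = np.clip(summit, start, end - 1)
    amp = rng.uniform(1.0, 100.0, size=n_peaks)
    return PeakSet(label, layout, cids, start, end, summit, amp,
                   n_rejected=int(clipped.sum()))


def simulate_integrations(layout: ChromLayout, target: PeakSet, n_sites: int = 500,
                          q: float = 0.7, offset_scale: float = 500.0,
                          seed: int = 0, label: str = "sim-sites"
                          ) -> tuple[SiteSet, np.ndarray]:
    """Integration sites with a planted fraction q around target summits.

    ceil(q * n) sites sit at (random summit + Normal(0, s^2)); the rest are
    uniform over the genome.  Returns (sites, planted mask).  Out-of-bounds
    planted placements are resampled.
    """
    if not (0.0 <= q <= 1.0):
        raise InputError("q must lie in [0, 1]")
    if target.n == 0:
        raise InputError("target marker is empty")
    rng = np.random.default_rng([seed, 3])
    n_planted = int(np.ceil(q * n_sites))
    cids, pos = [], []
    for _ in range(n_planted):
        while True:
            j = int(rng.integers(0, target.n))
            p = int(target.summit[j] + round(rng.normal(0, offset_scale)))
            cid = int(target.chrom_ids[j])
            if 0 <= p < layout.lengths[cid]:
                cids.append(cid)
                pos.append(p)
                break
    n_bg = n_sites - n_planted
    g = rng.uniform(0, layout.total, size=n_bg).astype(np.int64)
    bg_cids = np.searchsorted(layout.offsets, g, side="right") - 1
    bg_pos = g - layout.offsets[bg_cids]
    all_cids = np.concatenate([np.array(cids, dtype=np.int64), bg_cids])
    all_pos = np.concatenate([np.array(pos, dtype=np.int64), bg_pos])
    planted = np.zeros(n_sites, dtype=bool)
    planted[:n_planted] = True
    # shuffle so planted/background order carries no information
    order = rng.permutation(n_sites)
    sites = SiteSet(label, layout, all_cids[order], all_pos[order])
    return sites, planted[order]


def expected_wi(q: float, offset_scale: float, window: float,
                target: PeakSet, layout: ChromLayout) -> float:
    """Analytic expectation of the within-window fraction for planted data.

    Planted sites land within w of *some* summit with probability at least
    P(|N(0, s^2)| <= w); background sites with probability equal to the
    fraction of the genome within w of a summit (computed exactly from the
    merged +/-w intervals).
    """
    from scipy.stats import norm
    p_planted = float(norm.cdf(window / offset_scale) - norm.cdf(-window / offset_scale))
    covered = 0
    for cid, summits in target.summits_by_chrom().items():
        lo = np.maximum(summits - window, 0)
        hi = np.minimum(summits + window, layout.lengths[cid] - 1) + 1
        # merge
        cur_lo, cur_hi = lo[0], hi[0]
        for i in range(1, summits.size):
            if lo[i] <= cur_hi:
                cur_hi = max(cur_hi, hi[i])
            else:
                covered += cur_hi - cur_lo
                cur_lo, cur_hi = lo[i], hi[i]
        covered += cur_hi - cur_lo
    p_bg = covered / layout.total
    return q * p_planted + (1 - q) * p_bg


@dataclass
class GeneModel:
    """Transcribed genes as (TSS, length, strand) triples on a layout."""

    layout: ChromLayout
    chrom_ids: np.ndarray
    tss: np.ndarray
    length: np.ndarray
    strand: np.ndarray | None = None

    def __post_init__(self):
        self.chrom_ids = np.asarray(self.chrom_ids, dtype=np.int64)
        self.tss = np.asarray(self.tss, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=np.int64)
        if self.strand is None:
            self.strand = np.full(self.tss.size, "+")
        if np.any(self.length <= 0):
            raise InputError("gene lengths must be positive")
        ends = self.tss + self.length
        if np.any((self.tss < 0) | (ends > self.layout.lengths[self.chrom_ids])):
            raise InputError("genes outside chromosome bounds")

    @property
    def n(self) -> int:
        return int(self.tss.size)

    @property
    def median_length(self) -> float:
        return float(np.median(self.length))

    @classmethod
    def uniform(cls, layout: ChromLayout, n_genes: int, gene_length: int = 20_000,
                seed: int = 0) -> "GeneModel":
        """Non-overlapping equal-length genes placed uniformly at random."""
        rng = np.random.default_rng([seed, 4])
        cids, tss = [], []
        per_chrom = {cid: [] for cid in range(layout.n_chrom)}
        attempts = 0
        while sum(len(v) for v in per_chrom.values()) < n_genes and attempts < 50 * n_genes:
            attempts += 1
            g = int(rng.uniform(0, layout.total))
            cid = int(np.searchsorted(layout.offsets, g, side="right") - 1)
            t = g - int(layout.offsets[cid])
            if t + gene_length > layout.lengths[cid]:
                continue
            if any(abs(t - u) < gene_length for u in per_chrom[cid]):
                continue
            per_chrom[cid].append(t)
        for cid, ts in per_chrom.items():
            cids.extend([cid] * len(ts))
            tss.extend(ts)
        if not tss:
            raise InputError("could not place any gene")
        n = len(tss)
        return cls(layout, np.array(cids), np.array(tss), np.full(n, gene_length))


def simulate_gene_scenario(genes: GeneModel, n_sites: int = 500, seed: int = 0
                           ) -> tuple[SiteSet, PeakSet]:
    """Sites uniform within gene bodies + a virtual one-summit-per-TSS marker.

    Emulates a virus that integrates uniformly along transcribed genes being
    scored against a promoter marker: the window sweep of this fixture rises
    until the window spans the TSS plus about half the gene length, then
    plateaus near the median gene length.
    """
    if genes.n == 0:
        raise InputError("empty gene model")
    rng = np.random.default_rng([seed, 5])
    gi = rng.integers(0, genes.n, size=n_sites)
    offs = (rng.uniform(0, 1, size=n_sites) * genes.length[gi]).astype(np.int64)
    sites = SiteSet("gene-sites", genes.layout, genes.chrom_ids[gi], genes.tss[gi] + offs)
    start = genes.tss
    marker = PeakSet("virtual-TSS", genes.layout, genes.chrom_ids, start, start + 1,
                     start, np.ones(genes.n))
    return sites, marker


def random_fasta(layout: ChromLayout, path, seed: int = 0, gc: float = 0.5) -> None:
    """Write an i.i.d. random genome FASTA matching the layout (testing aid)."""
    rng = np.random.default_rng([seed, 6])
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for name, length in zip(layout.names, layout.lengths):
            fh.write(f">{name}\n")
            seq = "".join(alphabet[rng.choice(4, size=int(length), p=p)])
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
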
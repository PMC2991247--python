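"""Matched in-silico control sites reproducing restriction-enzyme cloning bias.

Integration sites are recovered from genomic DNA by restriction digestion, so
every experimental site sits at some characteristic distance from a recognition
site of the enzyme used.  A matched control preserves that distance: for each
experimental site we measure its distance to the nearest recognition site, then
place each of its controls at exactly that distance (random sign) from a
recognition site chosen uniformly at random — genome-wide by default, since the
bias being modeled is a property of the digest, not of local chromosome
structure.  Controls falling off a chromosome end are resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ChromLayout, InputError, SiteSet, scan_restriction_sites

__all__ = [
    "RestrictionIndex",
    "ControlSet",
    "nearest_restriction_distance",
    "generate_matched_controls",
]

_MAX_RETRIES = 1000


@dataclass
class RestrictionIndex:
    """Sorted recognition-site positions per chromosome for one enzyme motif."""

    label: str
    layout: ChromLayout
    by_chrom: dict[int, np.ndarray]  # chrom index -> sorted positions

    def __post_init__(self):
        for cid, p in self.by_chrom.items():
            p = np.sort(np.asarray(p, dtype=np.int64))
            if p.size == 0:
                raise InputError(f"restriction index empty on {self.layout.names[cid]}")
            self.by_chrom[cid] = p

    @classmethod
    def from_sites(cls, sites: SiteSet) -> "RestrictionIndex":
        if sites.n == 0:
            raise InputError("cannot build a restriction index from zero sites")
        return cls(sites.label, sites.layout, dict(sites.positions_by_chrom()))

    @classmethod
    def from_fasta(cls, fasta_path, motif: str, layout: ChromLayout) -> "RestrictionIndex":
        return cls.from_sites(scan_restriction_sites(fasta_path, motif, layout))

    @property
    def n(self) -> int:
        return sum(p.size for p in self.by_chrom.values())

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """All recognition sites as parallel (chrom_ids, positions) arrays."""
        cids = np.concatenate([np.full(p.size, cid, dtype=np.int64)
                               for cid, p in sorted(self.by_chrom.items())])
        pos = np.concatenate([p for _, p in sorted(self.by_chrom.items())])
        return cids, pos


def _nearest(sorted_arr: np.ndarray, x: int) -> int:
    i = np.searchsorted(sorted_arr, x)
    best = np.inf
    if i < sorted_arr.size:
        best = min(best, abs(int(sorted_arr[i]) - x))
    if i > 0:
        best = min(best, abs(x - int(sorted_arr[i - 1])))
    return int(best)


def nearest_restriction_distance(chrom_id: int, pos: int, index: RestrictionIndex) -> int:
    """Minimum absolute distance from a site to any recognition site on its chromosome."""
    arr = index.by_chrom.get(int(chrom_id))
    if arr is None or arr.size == 0:
        raise InputError(
            f"no recognition site on chromosome {index.layout.names[int(chrom_id)]}")
    return _nearest(arr, int(pos))


@dataclass
class ControlSet:
    """Matched control sites plus full provenance of how each was placed."""

    sites: SiteSet
    source_index: np.ndarray      # index of the experimental site each control matches
    r_chrom: np.ndarray           # chromosome of the chosen recognition site
    r_pos: np.ndarray             # position of the chosen recognition site
    offset: np.ndarray            # signed bp offset applied (|offset| = matched distance)
    ratio: int
    seed: int

    @property
    def n(self) -> int:
        return self.sites.n

    def subset_for_sources(self, source_ids) -> "ControlSet":
        """Controls whose source experimental site is in ``source_ids``.

        Keeps fold independence in cross-validation: a control travels with
        the experimental site it was matched to.
        """
        mask = np.isin(self.source_index, np.asarray(source_ids))
        return ControlSet(self.sites.subset(mask), self.source_index[mask],
                          self.r_chrom[mask], self.r_pos[mask], self.offset[mask],
                          self.ratio, self.seed)

    def provenance_frame(self):
        import pandas as pd
        layout = self.sites.layout
        return pd.DataFrame({
            "control_chrom": [layout.names[c] for c in self.sites.chrom_ids],
            "control_pos": self.sites.pos,
            "source_site_index": self.source_index,
            "resite_chrom": [layout.names[c] for c in self.r_chrom],
            "resite_pos": self.r_pos,
            "offset": self.offset,
        })


def generate_matched_controls(sites: SiteSet, index: RestrictionIndex,
                              ratio: int = 10, seed: int = 0,
                              per_chromosome: bool = False) -> ControlSet:
    """Generate ``ratio`` matched controls per experimental site.

    Each control lies at exactly its source site's nearest-recognition-site
    distance from a uniformly chosen recognition site (genome-wide, or from the
    source site's chromosome when ``per_chromosome``), with a random sign.
    Fully deterministic given ``seed``.
    """
    if ratio < 1:
        raise InputError("control ratio must be >= 1")
    if sites.n == 0:
        raise InputError("cannot match controls to an empty site set")
    if index.n == 0:
        raise InputError("empty restriction index")

    layout = sites.layout
    rng = np.random.default_rng(seed)
    dists = np.array([nearest_restriction_distance(c, p, index)
                      for c, p in zip(sites.chrom_ids, sites.pos)], dtype=np.int64)

    flat_cids, flat_pos = index.flat()
    out_cid, out_pos = [], []
    out_src, out_rc, out_rp, out_off = [], [], [], []
    for i in range(sites.n):
        d = int(dists[i])
        if per_chromosome:
            arr = index.by_chrom[int(sites.chrom_ids[i])]
            pool_cids = np.full(arr.size, int(sites.chrom_ids[i]), dtype=np.int64)
            pool_pos = arr
        else:
            pool_cids, pool_pos = flat_cids, flat_pos
        for _ in range(ratio):
            for attempt in range(_MAX_RETRIES):
                j = int(rng.integers(0, pool_pos.size))
                sign = 1 if rng.integers(0, 2) else -1
                c = int(pool_pos[j]) + sign * d
                cid = int(pool_cids[j])
                if 0 <= c < layout.lengths[cid]:
                    out_cid.append(cid)
                    out_pos.append(c)
                    out_src.append(i)
                    out_rc.append(cid)
                    out_rp.append(int(pool_pos[j]))
                    out_off.append(sign * d)
                    break
            else:
                raise InputError(
                    f"could not place a control at distance {d} after "
                    f"{_MAX_RETRIES} retries; genome too small for the matched distance")

    ctrl_sites = SiteSet(f"{sites.label}-controls", layout,
                         np.array(out_cid, dtype=np.int64), np.array(out_pos, dtype=np.int64))
    return ControlSet(ctrl_sites, np.array(out_src, dtype=np.int64),
                      np.array(out_rc, dtype=np.int64), np.array(out_rp, dtype=np.int64),
                      np.array(out_off, dtype=np.int64), ratio, seed)
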
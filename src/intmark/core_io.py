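"""Genomic coordinate model and readers/writers for the formats the tool touches.

Conventions
-----------
Coordinates are 0-based, half-open internally (BED convention); human-readable
reports convert to 1-based closed form once, at print time.  Integration sites
and control sites are *points*: a BED interval given as a site collapses to its
midpoint.  ChIP-seq peaks are scored intervals with a summit; when the input
carries no summit column the interval midpoint is used.  Strand is read but
ignored by every distance computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("intmark")

__all__ = [
    "InputError",
    "ChromLayout",
    "SiteSet",
    "PeakSet",
    "Region",
    "read_chrom_sizes",
    "read_sites",
    "read_peaks",
    "write_sites",
    "write_peaks",
    "merge_peak_sets",
    "scan_restriction_sites",
    "reverse_complement",
]


class InputError(ValueError):
    """Malformed or inconsistent user input (bad file, bad coordinates)."""


# ---------------------------------------------------------------------------
# chromosome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromLayout:
    """Ordered chromosomes with lengths and cumulative offsets.

    The concatenation order defines a single linear (and, for mandala plots,
    circular) coordinate: global position = offset[chrom] + position.
    """

    names: tuple[str, ...]
    lengths: np.ndarray  # int64, bp

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=np.int64)
        if len(self.names) != len(lengths):
            raise InputError("names and lengths differ in length")
        if len(self.names) == 0:
            raise InputError("empty chromosome layout")
        if len(set(self.names)) != len(self.names):
            raise InputError("duplicate chromosome names in layout")
        if np.any(lengths <= 0):
            raise InputError("chromosome lengths must be positive")
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    @property
    def offsets(self) -> np.ndarray:
        """Cumulative start offset of each chromosome on the concatenated genome."""
        return np.concatenate([[0], np.cumsum(self.lengths)[:-1]])

    @property
    def total(self) -> int:
        return int(self.lengths.sum())

    @property
    def n_chrom(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise InputError(f"unknown chromosome {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def to_dict(self) -> dict:
        return {n: int(l) for n, l in zip(self.names, self.lengths)}

    @classmethod
    def from_dict(cls, d: dict) -> "ChromLayout":
        return cls(tuple(d.keys()), np.array(list(d.values()), dtype=np.int64))


def read_chrom_sizes(path) -> ChromLayout:
    """Read a UCSC chrom.sizes file (two whitespace-separated columns)."""
    names: list[str] = []
    lengths: list[int] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected two columns, got {line!r}")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from None
            if length <= 0:
                raise InputError(f"{path}:{lineno}: non-positive length for {name}")
            if name in seen:
                raise InputError(f"{path}:{lineno}: duplicate chromosome {name}")
            seen.add(name)
            names.append(name)
            lengths.append(length)
    if not names:
        raise InputError(f"{path}: no chromosomes found")
    return ChromLayout(tuple(names), np.array(lengths, dtype=np.int64))


# ---------------------------------------------------------------------------
# site and peak containers
# ---------------------------------------------------------------------------

def _as_int_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.int64)


@dataclass
class SiteSet:
    """Point genomic positions (proviruses, controls, restriction sites)."""

    label: str
    layout: ChromLayout
    chrom_ids: np.ndarray  # int index into layout
    pos: np.ndarray        # bp, 0-based
    strand: np.ndarray | None = None  # '+', '-', '.' per site; distance-irrelevant
    n_rejected: int = 0    # records dropped at read time

    def __post_init__(self):
        self.chrom_ids = _as_int_array(self.chrom_ids)
        self.pos = _as_int_array(self.pos)
        if self.chrom_ids.shape != self.pos.shape:
            raise InputError("chrom_ids and pos differ in shape")
        if self.n > 0:
            if self.chrom_ids.min() < 0 or self.chrom_ids.max() >= self.layout.n_chrom:
                raise InputError(f"{self.label}: chromosome index out of range")
            bad = (self.pos < 0) | (self.pos >= self.layout.lengths[self.chrom_ids])
            if np.any(bad):
                raise InputError(f"{self.label}: {int(bad.sum())} positions outside chromosome bounds")
        self._by_chrom_cache: dict[int, np.ndarray] | None = None

    @property
    def n(self) -> int:
        return int(self.pos.size)

    def __len__(self) -> int:
        return self.n

    def sorted(self) -> "SiteSet":
        order = np.lexsort((self.pos, self.chrom_ids))
        strand = self.strand[order] if self.strand is not None else None
        return SiteSet(self.label, self.layout, self.chrom_ids[order], self.pos[order], strand)

    def positions_by_chrom(self) -> dict[int, np.ndarray]:
        """Sorted positions per chromosome index (cached)."""
        if self._by_chrom_cache is None:
            out = {}
            for cid in np.unique(self.chrom_ids):
                out[int(cid)] = np.sort(self.pos[self.chrom_ids == cid])
            self._by_chrom_cache = out
        return self._by_chrom_cache

    @property
    def global_pos(self) -> np.ndarray:
        """Positions on the concatenated genome coordinate."""
        return self.layout.offsets[self.chrom_ids] + self.pos

    def subset(self, idx) -> "SiteSet":
        strand = self.strand[idx] if self.strand is not None else None
        return SiteSet(self.label, self.layout, self.chrom_ids[idx], self.pos[idx], strand)


@dataclass
class PeakSet:
    """Scored genomic intervals with summits (one set per chromatin marker)."""

    label: str
    layout: ChromLayout
    chrom_ids: np.ndarray
    start: np.ndarray
    end: np.ndarray
    summit: np.ndarray
    amplitude: np.ndarray
    n_rejected: int = 0

    def __post_init__(self):
        self.chrom_ids = _as_int_array(self.chrom_ids)
        self.start = _as_int_array(self.start)
        self.end = _as_int_array(self.end)
        self.summit = _as_int_array(self.summit)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        n = self.n
        for arr, name in [(self.start, "start"), (self.end, "end"),
                          (self.summit, "summit"), (self.amplitude, "amplitude")]:
            if arr.size != n:
                raise InputError(f"{self.label}: {name} has wrong length")
        if n > 0:
            if np.any(self.start >= self.end):
                raise InputError(f"{self.label}: peaks with start >= end")
            if np.any((self.summit < self.start) | (self.summit >= self.end)):
                raise InputError(f"{self.label}: summit outside its interval")
            if np.any(self.amplitude < 0):
                raise InputError(f"{self.label}: negative amplitudes")
            bad = (self.start < 0) | (self.end > self.layout.lengths[self.chrom_ids])
            if np.any(bad):
                raise InputError(f"{self.label}: {int(bad.sum())} peaks outside chromosome bounds")
        self._summit_cache: dict[int, np.ndarray] | None = None
        self._interval_cache: dict[int, tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def n(self) -> int:
        return int(self.chrom_ids.size)

    def __len__(self) -> int:
        return self.n

    @property
    def mean_width(self) -> float:
        """Arithmetic mean of peak widths (end - start), bp."""
        if self.n == 0:
            raise InputError(f"{self.label}: empty peak set has no mean width")
        return float((self.end - self.start).mean())

    def summits_by_chrom(self) -> dict[int, np.ndarray]:
        if self._summit_cache is None:
            out = {}
            for cid in np.unique(self.chrom_ids):
                out[int(cid)] = np.sort(self.summit[self.chrom_ids == cid])
            self._summit_cache = out
        return self._summit_cache

    def merged_intervals_by_chrom(self) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        """Per chromosome: (starts, ends) of the union of peak intervals, sorted."""
        if self._interval_cache is None:
            out = {}
            for cid in np.unique(self.chrom_ids):
                mask = self.chrom_ids == cid
                out[int(cid)] = _merge_intervals(self.start[mask], self.end[mask])
            self._interval_cache = out
        return self._interval_cache

    def subset(self, idx) -> "PeakSet":
        return PeakSet(self.label, self.layout, self.chrom_ids[idx], self.start[idx],
                       self.end[idx], self.summit[idx], self.amplitude[idx])


@dataclass(frozen=True)
class Region:
    """A query window [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InputError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    @classmethod
    def parse(cls, text: str) -> "Region":
        """Parse 'chr11:33,850,000-33,920,000' style strings."""
        try:
            chrom, span = text.split(":")
            lo, hi = span.replace(",", "").split("-")
            return cls(chrom, int(lo), int(hi))
        except (ValueError, InputError) as e:
            raise InputError(f"cannot parse region {text!r}: {e}") from None


def _merge_intervals(start: np.ndarray, end: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(start, kind="stable")
    s, e = start[order], end[order]
    out_s, out_e = [], []
    cur_s, cur_e = int(s[0]), int(e[0])
    for i in range(1, len(s)):
        if s[i] <= cur_e:  # touching intervals merge too (half-open union)
            cur_e = max(cur_e, int(e[i]))
        else:
            out_s.append(cur_s)
            out_e.append(cur_e)
            cur_s, cur_e = int(s[i]), int(e[i])
    out_s.append(cur_s)
    out_e.append(cur_e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


# ---------------------------------------------------------------------------
# BED readers / writers
# ---------------------------------------------------------------------------

def _iter_bed(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def read_sites(path, layout: ChromLayout, label: str | None = None) -> SiteSet:
    """Read point sites from BED3/BED6; an interval collapses to its midpoint.

    Records on unknown chromosomes or outside bounds are rejected; the count
    is logged and kept on the returned set as ``n_rejected``.
    """
    chrom_ids, pos, strands = [], [], []
    rejected = 0
    for lineno, parts in _iter_bed(path):
        if len(parts) < 3:
            raise InputError(f"{path}:{lineno}: expected at least 3 BED columns")
        name, s, e = parts[0], parts[1], parts[2]
        try:
            s, e = int(s), int(e)
        except ValueError:
            raise InputError(f"{path}:{lineno}: non-integer coordinates") from None
        if name not in layout:
            rejected += 1
            continue
        cid = layout.index(name)
        p = (s + e) // 2
        if not (0 <= p < layout.lengths[cid]):
            rejected += 1
            continue
        chrom_ids.append(cid)
        pos.append(p)
        strands.append(parts[5] if len(parts) >= 6 else ".")
    if rejected:
        logger.warning("%s: rejected %d out-of-layout records", path, rejected)
    return SiteSet(label or Path(path).stem, layout,
                   np.array(chrom_ids, dtype=np.int64), np.array(pos, dtype=np.int64),
                   np.array(strands), n_rejected=rejected)


def read_peaks(path, layout: ChromLayout, label: str | None = None) -> PeakSet:
    """Read peaks from BED3/BED6, optionally with an absolute summit in column 7.

    Column 5 (score), when present, is the peak amplitude; otherwise 1.0.
    Without a summit column the interval midpoint is used.
    """
    chrom_ids, start, end, summit, amp = [], [], [], [], []
    rejected = 0
    for lineno, parts in _iter_bed(path):
        if len(parts) < 3:
            raise InputError(f"{path}:{lineno}: expected at least 3 BED columns")
        name = parts[0]
        try:
            s, e = int(parts[1]), int(parts[2])
        except ValueError:
            raise InputError(f"{path}:{lineno}: non-integer coordinates") from None
        if name not in layout:
            rejected += 1
            continue
        cid = layout.index(name)
        if s < 0 or e > layout.lengths[cid] or s >= e:
            rejected += 1
            continue
        a = 1.0
        if len(parts) >= 5:
            try:
                a = float(parts[4])
            except ValueError:
                a = 1.0
        sm = (s + e) // 2
        if len(parts) >= 7:
            try:
                sm = int(parts[6])
            except ValueError:
                pass
        if not (s <= sm < e):
            rejected += 1
            continue
        chrom_ids.append(cid)
        start.append(s)
        end.append(e)
        summit.append(sm)
        amp.append(max(a, 0.0))
    if rejected:
        logger.warning("%s: rejected %d out-of-layout records", path, rejected)
    return PeakSet(label or Path(path).stem, layout,
                   np.array(chrom_ids, dtype=np.int64), np.array(start, dtype=np.int64),
                   np.array(end, dtype=np.int64), np.array(summit, dtype=np.int64),
                   np.array(amp, dtype=float), n_rejected=rejected)


def write_sites(sites: SiteSet, path) -> None:
    """Write sites as BED6 single-bp intervals (exact round trip)."""
    with open(path, "w") as fh:
        for i in range(sites.n):
            name = sites.layout.names[sites.chrom_ids[i]]
            strand = sites.strand[i] if sites.strand is not None else "."
            p = int(sites.pos[i])
            fh.write(f"{name}\t{p}\t{p + 1}\t{sites.label}\t0\t{strand}\n")


def write_peaks(peaks: PeakSet, path) -> None:
    """Write peaks as BED6 + absolute summit column (exact round trip)."""
    with open(path, "w") as fh:
        for i in range(peaks.n):
            name = peaks.layout.names[peaks.chrom_ids[i]]
            fh.write(f"{name}\t{int(peaks.start[i])}\t{int(peaks.end[i])}\t"
                     f"{peaks.label}\t{peaks.amplitude[i]:g}\t.\t{int(peaks.summit[i])}\n")


# ---------------------------------------------------------------------------
# set algebra
# ---------------------------------------------------------------------------

def merge_peak_sets(a: PeakSet, b: PeakSet, label: str | None = None) -> PeakSet:
    """Union of two peak sets over the same layout; overlapping intervals merge.

    Used e.g. to combine CpG islands and TSS annotations into one marker.
    A merged interval's summit is its midpoint; its amplitude is the maximum
    of the constituents.
    """
    if a.layout is not b.layout and a.layout.to_dict() != b.layout.to_dict():
        raise InputError("cannot merge peak sets on different layouts")
    layout = a.layout
    chrom_ids = np.concatenate([a.chrom_ids, b.chrom_ids])
    start = np.concatenate([a.start, b.start])
    end = np.concatenate([a.end, b.end])
    amp = np.concatenate([a.amplitude, b.amplitude])

    out = {"chrom": [], "start": [], "end": [], "amp": []}
    for cid in np.unique(chrom_ids):
        mask = chrom_ids == cid
        s, e, am = start[mask], end[mask], amp[mask]
        order = np.argsort(s, kind="stable")
        s, e, am = s[order], e[order], am[order]
        cur_s, cur_e, cur_a = int(s[0]), int(e[0]), float(am[0])
        for i in range(1, len(s)):
            if s[i] < cur_e:  # strict overlap merges; touching intervals stay separate
                cur_e = max(cur_e, int(e[i]))
                cur_a = max(cur_a, float(am[i]))
            else:
                out["chrom"].append(cid)
                out["start"].append(cur_s)
                out["end"].append(cur_e)
                out["amp"].append(cur_a)
                cur_s, cur_e, cur_a = int(s[i]), int(e[i]), float(am[i])
        out["chrom"].append(cid)
        out["start"].append(cur_s)
        out["end"].append(cur_e)
        out["amp"].append(cur_a)

    start = np.array(out["start"], dtype=np.int64)
    end = np.array(out["end"], dtype=np.int64)
    return PeakSet(label or f"{a.label}+{b.label}", layout,
                   np.array(out["chrom"], dtype=np.int64), start, end,
                   (start + end) // 2, np.array(out["amp"], dtype=float))


# ---------------------------------------------------------------------------
# restriction-motif scanning
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _find_all(seq: str, motif: str) -> list[int]:
    """All (overlapping) 0-based occurrences of motif in seq."""
    hits = []
    i = seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def scan_restriction_sites(fasta_path, motif: str, layout: ChromLayout,
                           label: str | None = None) -> SiteSet:
    """Exact occurrences of a restriction motif (both strands) in a genome FASTA.

    Positions are the 0-based starts of matches of the motif or of its reverse
    complement on the forward strand; palindromic duplicates are removed and
    overlapping occurrences are all reported.
    """
    from Bio import SeqIO

    motif = motif.upper()
    if not motif or any(c not in "ACGT" for c in motif):
        raise InputError(f"motif must be non-empty over A/C/G/T, got {motif!r}")
    rc = reverse_complement(motif)

    chrom_ids, pos = [], []
    seen = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in layout:
            continue
        cid = layout.index(rec.id)
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        hits = set(_find_all(seq, motif))
        if rc != motif:
            hits |= set(_find_all(seq, rc))
        for p in sorted(hits):
            chrom_ids.append(cid)
            pos.append(p)
    missing = [n for n in layout.names if n not in seen]
    if missing:
        raise InputError(f"FASTA {fasta_path} missing sequences for: {', '.join(missing)}")
    return SiteSet(label or f"{motif}-sites", layout,
                   np.array(chrom_ids, dtype=np.int64), np.array(pos, dtype=np.int64))
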
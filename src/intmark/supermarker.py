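"""Composite integration-probability density ("supermarker") over several markers.

Each marker's genomic distribution is modeled as a mixture of Gaussians, one
per ChIP-seq peak, centered on the peak summit with a kernel scale tied to the
marker's mean peak width.  Candidate markers are combined into a composite
density by weighting each marker's mixture with a monotone function of its
training F score (default: odds, F/(1-F)).  Local maxima of the composite are
extracted on a fine grid and ranked by amplitude; keeping only the top-k peaks
and choosing k to maximize the training F score yields the reduced peak set
Gamma* — the supermarker — which supports base-pair-resolution queries:
probability of integration within an arbitrary locus (closed-form Gaussian
CDF sums) and genome-wide density/site-count correlation.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr  # fast standard normal CDF
from scipy.stats import pearsonr

from .core_io import ChromLayout, InputError, PeakSet, Region, SiteSet
from .controls import ControlSet
from .association import (DEFAULT_BETA, DEFAULT_WINDOW, _coerce_sites, associate,
                          build_table, f_score, fisher_pvalue, PValue)

logger = logging.getLogger("intmark")

__all__ = [
    "MarkerComponent", "CompositeDensity", "CompositePeaks", "SupermarkerModel",
    "CVReport", "FitResult",
    "make_component", "composite_density", "extract_peaks", "select_threshold",
    "fit_supermarker", "evaluate_model", "crossvalidate",
    "locus_probability", "density_correlation",
    "WEIGHT_FUNCTIONS", "SIGMA_POLICIES", "kernel_sigma",
]

DEFAULT_GRID_STEP = 10  # bp; base-pair-scale peak extraction


# ---------------------------------------------------------------------------
# components and weights
# ---------------------------------------------------------------------------

def _weight_odds(f: float) -> float:
    return f / (1.0 - f)


def _weight_linear(f: float) -> float:
    return f


def _weight_log_odds(f: float) -> float:
    return float(np.log1p(f / (1.0 - f)))


WEIGHT_FUNCTIONS = {"odds": _weight_odds, "linear": _weight_linear,
                    "log-odds": _weight_log_odds}
SIGMA_POLICIES = ("width", "sqrt-width", "fixed")


def kernel_sigma(peaks: PeakSet, policy: str = "width") -> float:
    """Kernel scale from the marker's peak geometry.

    'width': sigma = mean peak width (bp) — kernel support on the natural
    10^2-10^3 bp scale of ChIP-seq peaks; 'sqrt-width': sigma = sqrt(mean
    width); 'fixed:N': sigma = N bp.
    """
    if policy == "width":
        return peaks.mean_width
    if policy == "sqrt-width":
        return float(np.sqrt(peaks.mean_width))
    if policy.startswith("fixed:"):
        sigma = float(policy.split(":", 1)[1])
        if sigma <= 0:
            raise InputError("fixed sigma must be positive")
        return sigma
    raise InputError(f"unknown sigma policy {policy!r}")


@dataclass
class MarkerComponent:
    """One marker's Gaussian-mixture density plus its composite weight."""

    label: str
    peaks: PeakSet
    f: float          # training F score; must lie strictly in (0, 1)
    sigma: float      # kernel scale, bp
    lam: float = 0.0  # normalized mixture weight (set by composite_density)

    def __post_init__(self):
        if self.peaks.n == 0:
            raise InputError(f"{self.label}: empty peak set")
        if self.sigma <= 0:
            raise InputError(f"{self.label}: sigma must be positive")

    def density(self, chrom_id: int, x: np.ndarray) -> np.ndarray:
        """Marker density p(M = x) on one chromosome: mean of peak Gaussians.

        Normalized genome-wide (each peak Gaussian carries mass 1/|peaks|);
        mass beyond chromosome ends is not re-folded (negligible for peaks
        away from ends).
        """
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        summits = self.peaks.summits_by_chrom().get(int(chrom_id))
        if summits is None:
            return out
        norm = 1.0 / (self.peaks.n * self.sigma * np.sqrt(2 * np.pi))
        cut = 6.0 * self.sigma
        for s in summits:
            lo = np.searchsorted(x, s - cut)
            hi = np.searchsorted(x, s + cut)
            if hi > lo:
                z = (x[lo:hi] - s) / self.sigma
                out[lo:hi] += norm * np.exp(-0.5 * z * z)
        return out


def make_component(peaks: PeakSet, f: float, sigma_policy: str = "width") -> MarkerComponent:
    return MarkerComponent(peaks.label, peaks, f, kernel_sigma(peaks, sigma_policy))


@dataclass
class CompositeDensity:
    """Weighted mixture of marker densities; weights sum to 1."""

    components: list[MarkerComponent]
    layout: ChromLayout
    weight_fn: str = "odds"

    def evaluate(self, chrom_id: int, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for comp in self.components:
            out += comp.lam * comp.density(chrom_id, x)
        return out


def composite_density(components: list[MarkerComponent],
                      weight_fn: str = "odds") -> CompositeDensity:
    """Combine marker components; lam_j proportional to weight_fn(F_j).

    With the default odds weighting, any component whose F score is not
    strictly inside (0, 1) is rejected: exclude such markers before combining.
    """
    if not components:
        raise InputError("need at least one marker component")
    try:
        wfun = WEIGHT_FUNCTIONS[weight_fn]
    except KeyError:
        raise InputError(f"unknown weight function {weight_fn!r}") from None
    for c in components:
        if not (0.0 < c.f < 1.0):
            raise InputError(
                f"marker {c.label!r} has F = {c.f:g} outside (0, 1); "
                f"exclude it before building the composite")
    raw = np.array([wfun(c.f) for c in components])
    lam = raw / raw.sum()
    for c, l in zip(components, lam):
        c.lam = float(l)
    return CompositeDensity(list(components), components[0].peaks.layout, weight_fn)


# ---------------------------------------------------------------------------
# peak extraction
# ---------------------------------------------------------------------------

@dataclass
class CompositePeaks:
    """Composite-density local maxima, sorted by amplitude (descending)."""

    layout: ChromLayout
    chrom_ids: np.ndarray
    pos: np.ndarray
    amplitude: np.ndarray
    grid_step: float

    @property
    def n(self) -> int:
        return int(self.pos.size)

    def top(self, k: int) -> "CompositePeaks":
        return CompositePeaks(self.layout, self.chrom_ids[:k], self.pos[:k],
                              self.amplitude[:k], self.grid_step)

    def to_peakset(self, label: str = "supermarker") -> PeakSet:
        """Point peaks (1 bp) for distance/association computations."""
        start = self.pos
        return PeakSet(label, self.layout, self.chrom_ids, start, start + 1,
                       start, self.amplitude)


def _local_maxima(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if y.size == 1:
        return x, y
    left = np.concatenate([[-np.inf], y[:-1]])
    right = np.concatenate([y[1:], [-np.inf]])
    is_max = (y > left) & (y >= right)  # plateau: keep the first point
    return x[is_max], y[is_max]


def extract_peaks(density: CompositeDensity, grid_step: float = DEFAULT_GRID_STEP) -> CompositePeaks:
    """Local maxima of the composite density, ranked by amplitude.

    The grid is restricted to the union of component-peak neighborhoods
    (summit +/- 4 sigma); the step is clamped to min(sigma)/4 so no kernel is
    under-resolved.  Maxima closer than min(sigma) merge, keeping the larger.
    """
    sigmas = np.array([c.sigma for c in density.components])
    min_sigma = float(sigmas.min())
    step = float(min(grid_step, min_sigma / 4.0))
    layout = density.layout

    all_cids, all_pos, all_amp = [], [], []
    for cid in range(layout.n_chrom):
        # union of +/-4 sigma neighborhoods across components
        lo_list, hi_list = [], []
        for comp in density.components:
            summits = comp.peaks.summits_by_chrom().get(cid)
            if summits is None:
                continue
            lo_list.append(np.maximum(summits - 4 * comp.sigma, 0))
            hi_list.append(np.minimum(summits + 4 * comp.sigma, layout.lengths[cid] - 1))
        if not lo_list:
            continue
        lo = np.concatenate(lo_list)
        hi = np.concatenate(hi_list)
        order = np.argsort(lo)
        lo, hi = lo[order], hi[order]
        merged = []
        cur_lo, cur_hi = lo[0], hi[0]
        for i in range(1, lo.size):
            if lo[i] <= cur_hi:
                cur_hi = max(cur_hi, hi[i])
            else:
                merged.append((cur_lo, cur_hi))
                cur_lo, cur_hi = lo[i], hi[i]
        merged.append((cur_lo, cur_hi))

        cand_pos, cand_amp = [], []
        for a, b in merged:
            grid = np.arange(a, b + step, step)
            y = density.evaluate(cid, grid)
            px, py = _local_maxima(grid, y)
            cand_pos.append(px)
            cand_amp.append(py)
        if not cand_pos:
            continue
        pos = np.concatenate(cand_pos)
        amp = np.concatenate(cand_amp)
        # merge maxima closer than min sigma, keeping the larger amplitude
        order = np.argsort(pos)
        pos, amp = pos[order], amp[order]
        keep_pos, keep_amp = [], []
        for p, a in zip(pos, amp):
            if keep_pos and p - keep_pos[-1] < min_sigma:
                if a > keep_amp[-1]:
                    keep_pos[-1], keep_amp[-1] = p, a
            else:
                keep_pos.append(p)
                keep_amp.append(a)
        # report integer coordinates; re-evaluate so amplitude matches exactly
        pos_int = np.rint(np.array(keep_pos)).astype(np.int64)
        all_cids.append(np.full(pos_int.size, cid, dtype=np.int64))
        all_pos.append(pos_int)
        all_amp.append(density.evaluate(cid, pos_int.astype(float)))

    if not all_pos:
        raise InputError("composite density has empty support")
    cids = np.concatenate(all_cids)
    pos = np.concatenate(all_pos).astype(np.int64)
    amp = np.concatenate(all_amp)
    order = np.argsort(-amp, kind="stable")
    return CompositePeaks(layout, cids[order], pos[order], amp[order], step)


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

def _min_rank_within(peaks: CompositePeaks, query: SiteSet, w: float) -> np.ndarray:
    """For each query point: smallest amplitude-rank (1-based) of any composite
    peak within w; +inf if none.  tp(k) = #(min_rank <= k), so one pass gives
    the F score for every k."""
    ranks = np.arange(1, peaks.n + 1)
    by_chrom: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for cid in np.unique(peaks.chrom_ids):
        mask = peaks.chrom_ids == cid
        p = peaks.pos[mask]
        r = ranks[mask]
        order = np.argsort(p)
        by_chrom[int(cid)] = (p[order], r[order])
    out = np.full(query.n, np.inf)
    for i in range(query.n):
        entry = by_chrom.get(int(query.chrom_ids[i]))
        if entry is None:
            continue
        p, r = entry
        lo = np.searchsorted(p, query.pos[i] - w)
        hi = np.searchsorted(p, query.pos[i] + w, side="right")
        if hi > lo:
            out[i] = r[lo:hi].min()
    return out


def _k_grid(n_peaks: int, full_limit: int = 500, n_coarse: int = 50) -> np.ndarray:
    if n_peaks <= full_limit:
        return np.arange(1, n_peaks + 1)
    return np.unique(np.round(np.geomspace(1, n_peaks, n_coarse)).astype(int))


def select_threshold(peaks: CompositePeaks, sites: SiteSet, controls,
                     w: float = DEFAULT_WINDOW, beta: float = DEFAULT_BETA
                     ) -> tuple[int, CompositePeaks, float]:
    """Choose k maximizing the training F of the top-k peak set; ties -> smallest k.

    Evaluates every k when there are <= 500 peaks, else ~50 log-spaced values
    refined around the best.  Returns (k*, Gamma*, F(k*)).
    """
    controls_s = _coerce_sites(controls)
    if sites.n == 0 or controls_s.n == 0:
        raise InputError("threshold selection needs non-empty training sets")
    mr_sites = np.sort(_min_rank_within(peaks, sites, w))
    mr_ctrls = np.sort(_min_rank_within(peaks, controls_s, w))
    V, C = sites.n, controls_s.n
    b2 = beta * beta

    def f_at(ks: np.ndarray) -> np.ndarray:
        tp = np.searchsorted(mr_sites, ks, side="right").astype(float)
        fp = np.searchsorted(mr_ctrls, ks, side="right").astype(float)
        fpn = fp * V / C
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(tp + fpn > 0, tp / (tp + fpn), 0.0)
            R = tp / V
            F = np.where(b2 * P + R > 0, (1 + b2) * P * R / (b2 * P + R), 0.0)
        return F

    ks = _k_grid(peaks.n)
    fs = f_at(ks)
    best = int(np.argmax(fs))
    if peaks.n > 500:  # refine around the coarse optimum
        lo = ks[max(best - 1, 0)]
        hi = ks[min(best + 1, ks.size - 1)]
        ks = np.arange(lo, hi + 1)
        fs = f_at(ks)
        best = int(np.argmax(fs))
    if fs[best] <= 0:
        raise InputError(
            f"no peak-count threshold achieves F > 0 (best k = {ks[best]}, "
            f"V = {V}, C = {C}, window = {w}); the composite does not "
            f"separate sites from controls")
    k_star = int(ks[best])  # argmax returns the first (smallest-k) maximum
    return k_star, peaks.top(k_star), float(fs[best])


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

@dataclass
class SupermarkerModel:
    """Thresholded composite density: the reduced peak set Gamma* plus metadata.

    The predictive density is a Gaussian mixture over Gamma* with per-peak
    weight proportional to composite amplitude, truncated and renormalized to
    the genome so it integrates to exactly 1.
    """

    layout: ChromLayout
    chrom_ids: np.ndarray      # Gamma* positions
    pos: np.ndarray
    amplitude: np.ndarray
    sigma: float               # lam-weighted mean component sigma
    k_star: int
    f_train: float
    window: float
    beta: float
    marker_labels: tuple[str, ...]
    marker_f: tuple[float, ...]
    weight_fn: str = "odds"
    sigma_policy: str = "width"
    seed: int | None = None

    def __post_init__(self):
        self.chrom_ids = np.asarray(self.chrom_ids, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.pos.size == 0:
            raise InputError("empty supermarker peak set")
        self._Z: float | None = None

    @property
    def n_peaks(self) -> int:
        return int(self.pos.size)

    def peakset(self, label: str = "supermarker") -> PeakSet:
        start = self.pos
        return PeakSet(label, self.layout, self.chrom_ids, start, start + 1,
                       start, self.amplitude)

    # -- closed-form Gaussian-CDF machinery -------------------------------

    def _peak_mass(self, chrom_id, lo, hi) -> np.ndarray:
        """Mass of each Gamma* Gaussian inside [lo, hi) of one chromosome."""
        mask = self.chrom_ids == chrom_id
        mu = self.pos[mask].astype(float)
        a = self.amplitude[mask]
        if mu.size == 0:
            return np.zeros(np.broadcast_shapes(np.shape(lo), np.shape(hi)))
        z_hi = (np.asarray(hi, dtype=float)[..., None] - mu) / self.sigma
        z_lo = (np.asarray(lo, dtype=float)[..., None] - mu) / self.sigma
        return ((ndtr(z_hi) - ndtr(z_lo)) * a).sum(axis=-1)

    @property
    def normalization(self) -> float:
        """Total truncated mass over the genome (the normalization constant)."""
        if self._Z is None:
            z = 0.0
            for cid in range(self.layout.n_chrom):
                z += float(self._peak_mass(cid, 0.0, float(self.layout.lengths[cid])))
            self._Z = z
        return self._Z

    def region_probability(self, region: Region) -> float:
        cid = self.layout.index(region.chrom)
        end = min(region.end, int(self.layout.lengths[cid]))
        return float(self._peak_mass(cid, float(region.start), float(end))) / self.normalization

    def window_masses(self, window: float) -> tuple[np.ndarray, np.ndarray]:
        """(global window index, probability mass) over non-overlapping windows
        tiling every chromosome; windows shorter than ``window`` at chromosome
        ends are dropped."""
        masses = []
        for cid in range(self.layout.n_chrom):
            n_win = int(self.layout.lengths[cid] // window)
            if n_win == 0:
                continue
            edges = np.arange(n_win + 1) * window
            m = self._peak_mass(cid, edges[:-1], edges[1:])
            masses.append(m)
        if not masses:
            raise InputError("window larger than every chromosome")
        mass = np.concatenate(masses) / self.normalization
        return np.arange(mass.size), mass

    # -- serialization ----------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "format": "intmark-supermarker-v1",
            "layout": {"names": list(self.layout.names),
                       "lengths": [int(x) for x in self.layout.lengths]},
            "chrom_ids": self.chrom_ids.tolist(),
            "pos": self.pos.tolist(),
            "amplitude": self.amplitude.tolist(),
            "sigma": self.sigma, "k_star": self.k_star, "f_train": self.f_train,
            "window": self.window, "beta": self.beta,
            "marker_labels": list(self.marker_labels),
            "marker_f": list(self.marker_f),
            "weight_fn": self.weight_fn, "sigma_policy": self.sigma_policy,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SupermarkerModel":
        if isinstance(source, (str, bytes)) and "{" in str(source):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        layout = ChromLayout(tuple(payload["layout"]["names"]),
                             np.array(payload["layout"]["lengths"], dtype=np.int64))
        return cls(layout, np.array(payload["chrom_ids"]), np.array(payload["pos"]),
                   np.array(payload["amplitude"]), payload["sigma"], payload["k_star"],
                   payload["f_train"], payload["window"], payload["beta"],
                   tuple(payload["marker_labels"]), tuple(payload["marker_f"]),
                   payload["weight_fn"], payload["sigma_policy"], payload["seed"])


def locus_probability(model: SupermarkerModel, region: Region) -> float:
    """Probability that an integration falls inside the region, under the model."""
    return model.region_probability(region)


def density_correlation(model: SupermarkerModel, sites: SiteSet,
                        window: float = 10_000) -> tuple[float, float]:
    """Pearson r between supermarker density and site counts, both aggregated
    over non-overlapping windows tiling the genome.  Returns (r, p)."""
    if window <= 0:
        raise InputError("window must be positive")
    _, mass = model.window_masses(window)
    counts = []
    for cid in range(model.layout.n_chrom):
        n_win = int(model.layout.lengths[cid] // window)
        if n_win == 0:
            continue
        p = sites.pos[sites.chrom_ids == cid]
        c, _ = np.histogram(p, bins=n_win, range=(0, n_win * window))
        counts.append(c)
    counts = np.concatenate(counts)
    if mass.size < 3:
        raise InputError("need at least 3 windows for a correlation")
    r, p = pearsonr(mass, counts)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: SupermarkerModel
    search: list[dict] = field(default_factory=list)  # one row per evaluated subset


def _fit_subset(components: list[MarkerComponent], sites, controls, w, beta,
                weight_fn, grid_step) -> tuple[int, CompositePeaks, float]:
    dens = composite_density(components, weight_fn)
    peaks = extract_peaks(dens, grid_step)
    return select_threshold(peaks, sites, controls, w, beta)


def fit_supermarker(markers: list[PeakSet], sites: SiteSet, controls,
                    w: float = DEFAULT_WINDOW, beta: float = DEFAULT_BETA,
                    weight_fn: str = "odds", sigma_policy: str = "width",
                    grid_step: float = DEFAULT_GRID_STEP, max_subset: int = 8,
                    mode: str = "summit", seed: int | None = None) -> FitResult:
    """Exhaustive subset search over candidate markers for the best supermarker.

    Every non-empty subset of the candidates is combined, its composite peaks
    extracted and thresholded, and its training F recorded; the subset (and
    threshold) with maximal training F wins.  Ties prefer fewer markers, then
    fewer retained peaks.  Candidates whose single-marker F falls outside
    (0, 1) cannot carry an odds weight and are excluded with a warning.
    """
    if not markers:
        raise InputError("no candidate markers")
    if len(markers) > max_subset:
        raise InputError(
            f"{len(markers)} candidates would need {2 ** len(markers) - 1} fits; "
            f"pre-filter by single-marker F to at most {max_subset}")
    components = []
    marker_f = {}
    for m in markers:
        _, _, f = f_score(build_table(sites, controls, m, w, mode), beta)
        marker_f[m.label] = f
        if not (0.0 < f < 1.0):
            logger.warning("excluding marker %s with F = %g outside (0, 1)", m.label, f)
            continue
        components.append(make_component(m, f, sigma_policy))
    if not components:
        raise InputError("no candidate marker has F strictly inside (0, 1)")

    best = None
    search = []
    for size in range(1, len(components) + 1):
        for subset in itertools.combinations(components, size):
            k_star, gamma, f_train = _fit_subset(list(subset), sites, controls,
                                                 w, beta, weight_fn, grid_step)
            labels = tuple(c.label for c in subset)
            search.append({"markers": labels, "k_star": k_star, "f_train": f_train})
            key = (-f_train, size, k_star)
            if best is None or key < best[0]:
                best = (key, subset, k_star, gamma, f_train)

    _, subset, k_star, gamma, f_train = best
    lam = np.array([c.lam for c in subset])
    sigma_star = float(np.sum(lam * np.array([c.sigma for c in subset])) / lam.sum())
    model = SupermarkerModel(
        gamma.layout, gamma.chrom_ids, gamma.pos, gamma.amplitude, sigma_star,
        k_star, f_train, w, beta,
        tuple(c.label for c in subset), tuple(c.f for c in subset),
        weight_fn, sigma_policy, seed)
    return FitResult(model, search)


def evaluate_model(model: SupermarkerModel, sites: SiteSet, controls,
                   mode: str = "summit"):
    """Score a frozen supermarker against an external site/control pair."""
    return associate(sites, controls, model.peakset(), w=model.window,
                     beta=model.beta, mode=mode)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    folds: int
    seed: int
    fold_of_site: np.ndarray
    test_f: np.ndarray
    test_wi: np.ndarray
    test_log10_p: np.ndarray
    train_f: np.ndarray

    @property
    def mean_f(self) -> float:
        return float(self.test_f.mean())

    @property
    def std_f(self) -> float:
        return float(self.test_f.std(ddof=1))

    def frame(self):
        import pandas as pd
        return pd.DataFrame({"fold": np.arange(self.folds), "train_F": self.train_f,
                             "test_F": self.test_f, "test_wi_pct": 100 * self.test_wi,
                             "test_log10_p": self.test_log10_p})


def crossvalidate(markers: list[PeakSet], sites: SiteSet, controls: ControlSet,
                  folds: int = 10, seed: int = 0, w: float = DEFAULT_WINDOW,
                  beta: float = DEFAULT_BETA, weight_fn: str = "odds",
                  sigma_policy: str = "width", grid_step: float = DEFAULT_GRID_STEP,
                  subset_search: bool = False, mode: str = "summit") -> CVReport:
    """k-fold cross-validation of the full fitting pipeline.

    Sites are partitioned into folds (sizes differing by at most 1) by a
    seeded shuffle; each control travels with the experimental site it was
    matched to, keeping folds independent.  Per fold the composite weights and
    threshold (and, optionally, the marker subset) are re-fit on the training
    9/10 and scored on the held-out 1/10.
    """
    if not isinstance(controls, ControlSet):
        raise InputError("cross-validation needs a ControlSet with provenance")
    if sites.n < folds:
        raise InputError(f"{folds} folds but only {sites.n} sites")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(sites.n)
    fold_of_site = np.empty(sites.n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        fold_of_site[chunk] = f

    test_f, test_wi, test_p, train_f = [], [], [], []
    for f in range(folds):
        train_ids = np.nonzero(fold_of_site != f)[0]
        test_ids = np.nonzero(fold_of_site == f)[0]
        tr_sites = sites.subset(fold_of_site != f)
        te_sites = sites.subset(fold_of_site == f)
        tr_ctrl = controls.subset_for_sources(train_ids)
        te_ctrl = controls.subset_for_sources(test_ids)
        if subset_search:
            fit = fit_supermarker(markers, tr_sites, tr_ctrl, w, beta, weight_fn,
                                  sigma_policy, grid_step, mode=mode, seed=seed)
            model = fit.model
        else:
            components = []
            for m in markers:
                _, _, fj = f_score(build_table(tr_sites, tr_ctrl, m, w, mode), beta)
                if 0.0 < fj < 1.0:
                    components.append(make_component(m, fj, sigma_policy))
            if not components:
                raise InputError("no usable marker in a training fold")
            k_star, gamma, ftr = _fit_subset(components, tr_sites, tr_ctrl, w, beta,
                                             weight_fn, grid_step)
            lam = np.array([c.lam for c in components])
            sigma_star = float(np.sum(lam * np.array([c.sigma for c in components])) / lam.sum())
            model = SupermarkerModel(gamma.layout, gamma.chrom_ids, gamma.pos,
                                     gamma.amplitude, sigma_star, k_star, ftr, w, beta,
                                     tuple(c.label for c in components),
                                     tuple(c.f for c in components),
                                     weight_fn, sigma_policy, seed)
        res = evaluate_model(model, te_sites, te_ctrl, mode)
        test_f.append(res.f)
        test_wi.append(res.wi)
        test_p.append(res.p.log10)
        train_f.append(model.f_train)

    return CVReport(folds, seed, fold_of_site, np.array(test_f), np.array(test_wi),
                    np.array(test_p), np.array(train_f))
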
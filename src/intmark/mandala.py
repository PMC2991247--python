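"""Chromosome-projection mandala: a circular genome view of marker proximity.

The chromosome (or the whole genome, chromosomes concatenated in layout order
with no gaps) is circularized; each integration site becomes a point at angle
proportional to its genomic position.  Radius encodes distance to the nearest
marker on a log scale spanning 1 bp (on the contour) to 1 Mb (at the center):
r = R_max * (1 - log10(max(d, 1)) / 6), clipped to [0, R_max].  Sites within
the association window draw blue, the rest red; a circle marks the window
radius, and an optional gray annulus between the window circle and the contour
shades supermarker density by angular position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ChromLayout, InputError, SiteSet

__all__ = ["MandalaCoords", "polar_coords", "render_mandala", "radial_map", "LOG_RANGE"]

LOG_RANGE = 6.0  # decades: 1 bp .. 1 Mb


def radial_map(distances: np.ndarray, r_max: float = 1.0) -> np.ndarray:
    """Log-radial mapping; monotone decreasing and invertible on [1, 1e6] bp."""
    d = np.maximum(np.asarray(distances, dtype=float), 1.0)
    with np.errstate(divide="ignore"):
        r = r_max * (1.0 - np.log10(d) / LOG_RANGE)
    return np.clip(r, 0.0, r_max)


@dataclass
class MandalaCoords:
    theta: np.ndarray          # [0, 2pi)
    r: np.ndarray              # [0, r_max]
    within: np.ndarray         # bool: distance <= window
    distances: np.ndarray
    window: float
    r_max: float
    scope: str


def polar_coords(sites: SiteSet, distances: np.ndarray, layout: ChromLayout,
                 scope: str = "genome", window: float = 2000.0,
                 r_max: float = 1.0) -> MandalaCoords:
    """Map sites to mandala polar coordinates.

    scope is either 'genome' (chromosomes concatenated, arc length proportional
    to chromosome length) or one chromosome name.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size != sites.n:
        raise InputError("one distance per site required")
    if np.any(np.isnan(distances)):
        raise InputError("missing distances")
    if scope == "genome":
        gpos = sites.global_pos.astype(float)
        total = float(layout.total)
    else:
        cid = layout.index(scope)
        mask = sites.chrom_ids == cid
        sites = sites.subset(mask)
        distances = distances[mask]
        gpos = sites.pos.astype(float)
        total = float(layout.lengths[cid])
    theta = 2.0 * np.pi * gpos / total
    r = radial_map(distances, r_max)
    return MandalaCoords(theta, r, distances <= window, distances, window, r_max, scope)


def render_mandala(coords: MandalaCoords, out_path, density_model=None,
                   annotation: dict | None = None, n_shade_bins: int = 360,
                   point_size: float = 6.0) -> None:
    """Render the mandala to SVG/PNG (format chosen by the file extension).

    ``density_model`` (a SupermarkerModel) shades the annulus between the
    window circle and the contour in gray, linear in the angular density mass.
    ``annotation`` entries (e.g. F score, wi2kB%) print in a caption strip.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r_max = coords.r_max
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5.4))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)

    r_window = float(radial_map(np.array([coords.window]), r_max)[0])
    if density_model is not None:
        # angular density: window-aggregated mass re-binned on the circle
        _, mass = density_model.window_masses(max(density_model.layout.total
                                                 // (n_shade_bins * 4), 1000))
        bins = np.linspace(0, mass.size, n_shade_bins + 1).astype(int)
        shade = np.array([mass[a:b].sum() for a, b in zip(bins[:-1], bins[1:])])
        shade = shade / shade.max() if shade.max() > 0 else shade
        width = 2 * np.pi / n_shade_bins
        centers = (np.arange(n_shade_bins) + 0.5) * width
        ax.bar(centers, np.full(n_shade_bins, r_max - r_window), width=width,
               bottom=r_window, color=plt.cm.Greys(0.15 + 0.75 * shade),
               edgecolor="none", zorder=0)

    circle_theta = np.linspace(0, 2 * np.pi, 512)
    ax.plot(circle_theta, np.full_like(circle_theta, r_max), color="black", lw=1.2)
    ax.plot(circle_theta, np.full_like(circle_theta, r_window), color="gray",
            lw=0.8, ls="--")

    blue = coords.within
    ax.scatter(coords.theta[blue], coords.r[blue], s=point_size, c="tab:blue",
               zorder=3, linewidths=0)
    ax.scatter(coords.theta[~blue], coords.r[~blue], s=point_size, c="tab:red",
               zorder=3, linewidths=0)
    ax.set_rlim(0, r_max * 1.05)
    ax.set_xticks([])
    ax.set_yticks([])

    caption = f"scope: {coords.scope}   window: {coords.window:g} bp"
    if annotation:
        caption += "   " + "   ".join(f"{k}: {v}" for k, v in annotation.items())
    fig.text(0.5, 0.02, caption, ha="center", fontsize=8)
    try:
        fig.savefig(out_path)
    except OSError as e:
        raise InputError(f"cannot write {out_path}: {e}") from None
    finally:
        plt.close(fig)
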
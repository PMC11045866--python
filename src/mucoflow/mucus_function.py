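"""Ex vivo mucus function metrics: growth rate and penetrability.

Growth rate comes from timed micropipette thickness measurements on viable
colon explants: thickness is read at five sites per tissue at 0 and 45
minutes, each timepoint averaged over sites, and the rate is the thickness
change per minute (um/min).

Penetrability comes from confocal z-stacks of bacteria-sized (1 um) beads
sedimented onto the mucus: after segmentation each bead is a 3D coordinate
and the epithelium a height field h(x, y).  The per-bead distance is the
vertical offset z - h(x, y); the mucus surface is the modal bin of the
bead-distance histogram (beads accumulate on the impenetrable surface); the
penetrability summary is the fraction of in-mucus beads within a 10 um zone
of the epithelium, where bacterial contact with the host is most likely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator

__all__ = [
    "BeadCloud",
    "PenetrabilityResult",
    "growth_rate",
    "bead_distances",
    "mucus_surface",
    "penetrability",
    "penetrability_per_mouse",
    "distance_distribution",
]


@dataclass
class BeadCloud:
    """Per-image bead coordinates plus an epithelial reference surface.

    ``epithelium`` is either a scalar (flat plane z = h0), a tuple
    (a, b, c) describing the plane h = a*x + b*y + c, or a DataFrame with
    columns x_um, y_um, h_um sampled on the epithelial surface (linearly
    interpolated).  z increases toward the gut lumen.
    """

    image_id: str
    mouse_id: str
    beads: pd.DataFrame  # columns x_um, y_um, z_um
    epithelium: object = 0.0

    def __post_init__(self):
        self.beads = pd.DataFrame(self.beads)
        for col in ("x_um", "y_um", "z_um"):
            if col not in self.beads.columns:
                raise ValueError(f"beads table lacks column {col!r}")
        if not np.all(np.isfinite(self.beads[["x_um", "y_um", "z_um"]])):
            raise ValueError("bead coordinates must be finite")

    def height_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        e = self.epithelium
        if np.isscalar(e):
            return np.full_like(np.asarray(x, dtype=float), float(e))
        if isinstance(e, tuple) and len(e) == 3:
            a, b, c = e
            return a * np.asarray(x, float) + b * np.asarray(y, float) + c
        grid = pd.DataFrame(e)
        interp = LinearNDInterpolator(
            grid[["x_um", "y_um"]].to_numpy(), grid["h_um"].to_numpy()
        )
        h = interp(np.asarray(x, float), np.asarray(y, float))
        if np.any(np.isnan(h)):
            raise ValueError("bead outside the epithelial height-field domain")
        return h


@dataclass
class PenetrabilityResult:
    image_id: str
    mouse_id: str
    mucus_surface_um: float
    distances_um: np.ndarray  # in-mucus bead distances
    fraction_within_zone: float
    n_beads_in_mucus: int
    zone_um: float = 10.0
    n_beads_negative: int = 0  # below epithelium, excluded (QC)
    n_beads_above_surface: int = 0  # unwashed excess, excluded


def growth_rate(series: pd.DataFrame) -> pd.Series:
    """Mucus growth rate per mouse (um/min).

    ``series`` columns: mouse_id, site, time_min, thickness_um with the two
    timepoints 0 and 45 (any two distinct times are accepted).  The rate is
    (mean thickness at the late time - mean at the early time) divided by
    the elapsed minutes, each mean taken over the measured sites.
    """
    required = {"mouse_id", "site", "time_min", "thickness_um"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"thickness table lacks columns: {sorted(missing)}")
    if not np.all(np.isfinite(series["thickness_um"])):
        raise ValueError("thickness values must be finite")
    rates = {}
    for mouse, sub in series.groupby("mouse_id"):
        times = np.sort(sub["time_min"].unique())
        if len(times) != 2:
            raise ValueError(
                f"mouse {mouse!r}: need exactly two timepoints, got {times}"
            )
        t0, t1 = float(times[0]), float(times[1])
        m0 = sub.loc[sub["time_min"] == t0, "thickness_um"].mean()
        m1 = sub.loc[sub["time_min"] == t1, "thickness_um"].mean()
        rates[mouse] = (m1 - m0) / (t1 - t0)
    return pd.Series(rates, name="growth_rate_um_per_min")


def bead_distances(cloud: BeadCloud) -> np.ndarray:
    """Vertical distance of each bead to the interpolated epithelial height.

    Negative distances (beads below the epithelial surface, typically crypt
    artifacts) are returned as-is; downstream summaries exclude and count
    them rather than silently keeping them.
    """
    h = cloud.height_at(
        cloud.beads["x_um"].to_numpy(), cloud.beads["y_um"].to_numpy()
    )
    return cloud.beads["z_um"].to_numpy() - h


def mucus_surface(distances, bin_um: float = 5.0, min_beads: int = 50) -> float:
    """Mucus surface as the modal bin of the bead-distance histogram.

    Beads sediment onto the impenetrable mucus surface, so the location of
    highest bead density marks the luminal mucus boundary.  Ties between
    equally tall bins are broken toward the larger distance (the outermost
    mode), so a surface accumulation wins over a crypt-floor artifact.
    """
    d = np.asarray(distances, dtype=float)
    d = d[d >= 0]
    if len(d) < min_beads:
        raise ValueError(
            f"only {len(d)} nonnegative bead distances (< {min_beads}); "
            "supply the mucus surface z-position directly instead"
        )
    if bin_um <= 0:
        raise ValueError("bin_um must be > 0")
    edges = np.arange(0.0, d.max() + bin_um, bin_um)
    if len(edges) < 2:
        edges = np.array([0.0, bin_um])
    hist, edges = np.histogram(d, bins=edges)
    modal = len(hist) - 1 - int(np.argmax(hist[::-1]))  # outermost max
    return float((edges[modal] + edges[modal + 1]) / 2.0)


def penetrability(
    cloud: BeadCloud,
    zone_um: float = 10.0,
    surface_um: float | None = None,
    bin_um: float = 5.0,
) -> PenetrabilityResult:
    """Fraction of in-mucus beads within ``zone_um`` of the epithelium.

    In-mucus beads are those with distance in [0, surface]; beads above the
    detected surface (excess, unwashed) and below the epithelium are
    excluded from the denominator and counted in the QC fields.
    """
    d = bead_distances(cloud)
    n_neg = int(np.sum(d < 0))
    d_pos = d[d >= 0]
    if surface_um is None:
        surface_um = mucus_surface(d_pos, bin_um=bin_um)
    if surface_um < 0:
        raise ValueError("mucus surface must be >= 0")
    in_mucus = d_pos[d_pos <= surface_um]
    n_above = int(len(d_pos) - len(in_mucus))
    if len(in_mucus) == 0:
        frac = float("nan")
    else:
        frac = float(np.mean(in_mucus <= zone_um))
    return PenetrabilityResult(
        cloud.image_id,
        cloud.mouse_id,
        float(surface_um),
        in_mucus,
        frac,
        len(in_mucus),
        zone_um=zone_um,
        n_beads_negative=n_neg,
        n_beads_above_surface=n_above,
    )


def penetrability_per_mouse(results) -> pd.Series:
    """Per-mouse penetrability: mean fraction over that mouse's images."""
    rows = {}
    for r in results:
        rows.setdefault(r.mouse_id, []).append(r.fraction_within_zone)
    return pd.Series(
        {m: float(np.nanmean(v)) for m, v in rows.items()},
        name="fraction_within_zone",
    )


def distance_distribution(results, by: str = "mouse", groups: dict | None = None) -> pd.DataFrame:
    """Median and quartiles of pooled in-mucus bead distances.

    ``by`` is "mouse" or "group"; for "group" a mapping mouse -> group is
    required.  Quartiles use linear interpolation.
    """
    if not results:
        raise ValueError("no penetrability results supplied")
    pools: dict[str, list] = {}
    for r in results:
        if by == "mouse":
            key = r.mouse_id
        elif by == "group":
            if groups is None:
                raise ValueError("grouping by 'group' requires a mouse->group map")
            key = groups[r.mouse_id]
        else:
            raise ValueError("by must be 'mouse' or 'group'")
        pools.setdefault(key, []).append(np.asarray(r.distances_um))
    rows = {}
    for key, chunks in pools.items():
        d = np.concatenate(chunks)
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        rows[key] = {"q1_um": q1, "median_um": med, "q3_um": q3, "n_beads": len(d)}
    return pd.DataFrame.from_dict(rows, orient="index")
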
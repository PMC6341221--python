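"""Architecture descriptors for cross-linked filament networks.

The central statistic is a Clark-Evans-type randomness index

    R = R_NN / r_rand,        r_rand = 1 / (2 sqrt(sigma)),

where ``R_NN`` is the mean nearest-neighbour distance among junction (or
focus) centroids and ``sigma`` their density per unit area.  R is ~0 for
aggregated points, 1 for a homogeneous Poisson pattern, and rises to its
maximum for an evenly spaced hexagonal (triangular-packing) lattice.

Cable-level descriptors: mean snake intensity Q (a proxy for bundling,
since intensity adds over filaments in a diffraction-limited cable),
skewness S of the Q distribution, mean unsigned curvature K from tangent
differences at a sampling distance delta_s, and the persistence length
l_p obtained from the worm-like-chain half-normal curvature density

    P(K) = sqrt(2 l_p c / pi) * exp(-l_p c K^2 / 2),   K >= 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull, cKDTree

from .field import FieldSpec
from .network_io import NetworkModel, Snake


@dataclass
class PointPattern:
    """Point centroids (junctions or foci) in a bounded 2-D field."""

    points: np.ndarray
    field: FieldSpec
    ground_truth: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = np.empty((0, 2))
        if self.points.shape[1] != 2:
            raise ValueError("points must be (N, 2)")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ArchitectureSummary:
    """Per-field architecture descriptors."""

    sigma: float  # junction density, points/um^2
    R_NN: float  # mean nearest-neighbour distance, um
    r_rand: float  # Poisson reference distance, um
    R: float  # randomness index, dimensionless
    Q: float | None = None  # mean cable intensity, counts/pixel
    S: float | None = None  # skewness of the Q distribution
    K_mean: float | None = None  # mean curvature, rad/um
    l_p: float | None = None  # persistence length, um
    delta_s: float | None = None  # curvature sampling distance, um
    n_points: int = 0
    provenance: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "sigma": self.sigma,
            "R_NN": self.R_NN,
            "r_rand": self.r_rand,
            "R": self.R,
            "Q": self.Q,
            "S": self.S,
            "K_mean": self.K_mean,
            "l_p": self.l_p,
            "delta_s": self.delta_s,
            "n_points": self.n_points,
            "provenance": self.provenance,
        }
        return d


# ---------------------------------------------------------------------------
# Point-pattern statistics
# ---------------------------------------------------------------------------

def junction_density(pattern: PointPattern, area_mode: str = "field") -> float:
    """Point density sigma in points/um^2.

    ``area_mode='field'`` divides by the full field-of-view area;
    ``'hull'`` divides by the convex-hull area of the points themselves
    (useful when the imaged region is cropped).
    """
    n = len(pattern)
    if n < 1:
        raise ValueError("density undefined for an empty pattern")
    if area_mode == "field":
        area = pattern.field.area
    elif area_mode == "hull":
        if n < 3:
            raise ValueError("hull area needs >= 3 points")
        area = ConvexHull(pattern.points).volume  # 2-D hull 'volume' is area
        if area <= 0:
            raise ValueError("degenerate (collinear) hull has zero area")
    else:
        raise ValueError(f"unknown area_mode {area_mode!r}")
    return n / area


def mean_nn_distance(
    pattern: PointPattern, guard: float | None = None
) -> tuple[float, np.ndarray]:
    """Mean nearest-neighbour distance R_NN and the per-point r_NN list.

    Each point's nearest-neighbour distance is the minimum over all
    pairwise separations l_x involving that point; R_NN is their
    arithmetic mean.  Results are identical to exhaustive all-pairs
    search (a k-d tree is used only as an accelerator).

    ``guard`` optionally excludes points within that margin of the field
    border as nearest-neighbour *sources* (they remain available as
    targets), a simple guard-zone edge correction.
    """
    pts = pattern.points
    if len(pts) < 2:
        raise ValueError("nearest-neighbour statistics need >= 2 points")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    r_nn = d[:, 1]
    if guard is not None:
        f = pattern.field
        inner = (
            (pts[:, 0] >= guard)
            & (pts[:, 0] <= f.width - guard)
            & (pts[:, 1] >= guard)
            & (pts[:, 1] <= f.height - guard)
        )
        if not np.any(inner):
            raise ValueError("guard zone excludes every point")
        r_nn = r_nn[inner]
    return float(np.mean(r_nn)), r_nn


def random_reference(sigma: float) -> float:
    """Expected nearest-neighbour distance for a Poisson pattern: 1/(2 sqrt(sigma))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 1.0 / (2.0 * np.sqrt(sigma))


def randomness_index(
    pattern: PointPattern, area_mode: str = "field", guard: float | None = None
) -> float:
    """Randomness index R = R_NN / r_rand.

    ~0 for aggregated points, ~1 for Poisson, up to the hexagonal-lattice
    maximum for an optimally spaced arrangement.  No edge correction is
    applied by default; ``guard`` enables guard-zone exclusion.
    """
    r_nn_mean, _ = mean_nn_distance(pattern, guard=guard)
    sigma = junction_density(pattern, area_mode=area_mode)
    return r_nn_mean / random_reference(sigma)


def summarize_pattern(
    pattern: PointPattern, area_mode: str = "field", guard: float | None = None
) -> ArchitectureSummary:
    """Density, R_NN, r_rand and R for one point pattern."""
    sigma = junction_density(pattern, area_mode=area_mode)
    r_nn_mean, r_nn = mean_nn_distance(pattern, guard=guard)
    r_rand = random_reference(sigma)
    return ArchitectureSummary(
        sigma=sigma,
        R_NN=r_nn_mean,
        r_rand=r_rand,
        R=r_nn_mean / r_rand,
        n_points=len(pattern),
        provenance={"area_mode": area_mode, "guard": guard, "n_rNN": int(len(r_nn))},
    )


# ---------------------------------------------------------------------------
# Cable intensity and skewness
# ---------------------------------------------------------------------------

def cable_intensity(
    net: NetworkModel,
    image: np.ndarray | None = None,
    background: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Per-snake mean intensity Q and the field mean, counts/pixel.

    With ``image=None`` the per-point intensities stored on the snakes
    (from the tracer output) are averaged; otherwise the image is sampled
    along each snake path by nearest-pixel lookup.  ``background`` is
    subtracted from every per-snake mean.
    """
    if not net.snakes:
        raise ValueError("network has no snakes")
    q = np.empty(len(net.snakes))
    for i, s in enumerate(net.snakes):
        if image is None:
            q[i] = s.mean_intensity
        else:
            cols = np.round(s.xy[:, 0] / net.field.pixel_size).astype(int)
            rows = np.round(s.xy[:, 1] / net.field.pixel_size).astype(int)
            ny, nx = image.shape
            if np.any((cols < 0) | (cols >= nx) | (rows < 0) | (rows >= ny)):
                raise ValueError(f"snake {s.snake_id!r} extends outside the image")
            q[i] = float(np.mean(image[rows, cols]))
    q = q - background
    return q, float(np.mean(q))


def intensity_skewness(q_values: np.ndarray) -> float:
    """Adjusted Fisher-Pearson sample skewness S of the Q distribution.

    The small-sample-corrected definition (the one spreadsheet SKEW uses):
    S = 0 for a symmetric distribution with mean = mode.
    """
    q = np.asarray(q_values, dtype=float)
    if len(q) < 3:
        raise ValueError("skewness needs >= 3 values")
    if np.ptp(q) == 0 or np.std(q) == 0:
        raise ValueError("skewness undefined for a constant sample")
    return float(stats.skew(q, bias=False))


# ---------------------------------------------------------------------------
# Curvature and persistence length
# ---------------------------------------------------------------------------

def _resample_polyline(xy: np.ndarray, delta_s: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing delta_s."""
    seg = np.hypot(*np.diff(xy, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n = int(np.floor(total / delta_s))
    s = np.arange(n + 1) * delta_s
    x = np.interp(s, arclen, xy[:, 0])
    y = np.interp(s, arclen, xy[:, 1])
    return np.column_stack([x, y])


def snake_curvature(snake: Snake, delta_s: float) -> tuple[float, np.ndarray]:
    """Mean unsigned curvature K (rad/um) and the tangent-difference list.

    The snake is resampled at arc-length intervals ``delta_s``; dT is the
    unsigned angle in [0, pi] between consecutive tangent vectors and
    K = mean(dT) / delta_s.  Raises for snakes shorter than 2 * delta_s
    (no tangent pair available).
    """
    if delta_s <= 0:
        raise ValueError("delta_s must be positive")
    if snake.length < 2 * delta_s:
        raise ValueError(
            f"snake {snake.snake_id!r} shorter than 2*delta_s; excluded from curvature"
        )
    pts = _resample_polyline(snake.xy, delta_s)
    tang = np.diff(pts, axis=0)
    ang = np.arctan2(tang[:, 1], tang[:, 0])
    dT = np.abs(np.angle(np.exp(1j * np.diff(ang))))  # unsigned, wrapped to [0, pi]
    if len(dT) == 0:
        raise ValueError(f"snake {snake.snake_id!r} yields no tangent pairs")
    return float(np.mean(dT) / delta_s), dT


def network_curvatures(
    net: NetworkModel, delta_s: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-step curvature samples K = dT/delta_s over all snakes.

    Snakes too short for the sampling distance are skipped with a warning.
    Returns (per-snake mean K array, pooled per-step K samples).
    """
    ds = net.c if delta_s is None else delta_s
    k_mean, pooled = [], []
    for s in net.snakes:
        try:
            k, dT = snake_curvature(s, ds)
        except ValueError:
            warnings.warn(f"snake {s.snake_id!r} too short for delta_s={ds}; skipped",
                          stacklevel=2)
            continue
        k_mean.append(k)
        pooled.append(dT / ds)
    return np.array(k_mean), (np.concatenate(pooled) if pooled else np.empty(0))


def wlc_curvature_pdf(k: np.ndarray, l_p: float, c: float) -> np.ndarray:
    """Worm-like-chain half-normal curvature density P(K)."""
    k = np.asarray(k, dtype=float)
    return np.sqrt(2.0 * l_p * c / np.pi) * np.exp(-l_p * c * k**2 / 2.0)


def fit_persistence_length(curvatures: np.ndarray, c: float) -> tuple[float, dict]:
    """Maximum-likelihood persistence length from curvature samples.

    Under the worm-like-chain model the sampled curvature magnitude is
    half-normal with E[K^2] = 1/(l_p c), so the MLE is

        l_p = 1 / (c * mean(K^2)).

    Returns the raw MLE (no bias correction; finite sampling distance is
    known to underestimate l_p slightly — flagged in the fit info) plus a
    Kolmogorov-Smirnov goodness-of-fit against the half-normal density.
    """
    k = np.asarray(curvatures, dtype=float)
    if len(k) < 10:
        raise ValueError("persistence-length fit needs >= 10 curvature samples")
    if c <= 0:
        raise ValueError("sampling distance c must be positive")
    msq = float(np.mean(k**2))
    if msq == 0.0:
        raise ValueError("all curvatures zero: straight filaments, l_p is infinite")
    l_p = 1.0 / (c * msq)
    scale = 1.0 / np.sqrt(l_p * c)
    ks = stats.kstest(np.abs(k), stats.halfnorm(scale=scale).cdf)
    info = {
        "n": int(len(k)),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "bias_corrected": False,
    }
    return l_p, info


# ---------------------------------------------------------------------------
# One-call field summary
# ---------------------------------------------------------------------------

def summarize_network(
    net: NetworkModel,
    image: np.ndarray | None = None,
    background: float = 0.0,
    delta_s: float | None = None,
    area_mode: str = "field",
    guard: float | None = None,
) -> ArchitectureSummary:
    """Full architecture summary for one network: sigma, R_NN, r_rand, R, Q, S, K, l_p."""
    ds = net.c if delta_s is None else delta_s
    coords = net.junction_coords()
    if len(coords) >= 2:
        summ = summarize_pattern(PointPattern(coords, net.field), area_mode=area_mode,
                                 guard=guard)
    else:
        summ = ArchitectureSummary(sigma=float("nan"), R_NN=float("nan"),
                                   r_rand=float("nan"), R=float("nan"))
        summ.provenance["warning"] = "fewer than 2 junctions; R undefined"
    if net.snakes:
        q, q_mean = cable_intensity(net, image=image, background=background)
        summ.Q = q_mean
        if len(q) >= 3 and np.std(q) > 0:
            summ.S = intensity_skewness(q)
        k_mean, pooled = network_curvatures(net, delta_s=ds)
        if len(k_mean):
            summ.K_mean = float(np.mean(k_mean))
        if len(pooled) >= 10 and np.mean(pooled**2) > 0:
            summ.l_p, lp_info = fit_persistence_length(pooled, c=ds)
            summ.provenance["l_p_fit"] = lp_info
        summ.delta_s = ds
    return summ


__all__ = [
    "PointPattern",
    "ArchitectureSummary",
    "junction_density",
    "mean_nn_distance",
    "random_reference",
    "randomness_index",
    "summarize_pattern",
    "cable_intensity",
    "intensity_skewness",
    "snake_curvature",
    "network_curvatures",
    "wlc_curvature_pdf",
    "fit_persistence_length",
    "summarize_network",
]
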
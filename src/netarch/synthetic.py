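"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be produced here with its
generating parameters recorded, so each downstream estimator has a
recovery target:

* junction point patterns — homogeneous Poisson, Thomas-process clustered
  (aggregated limit), and jittered triangular ("hexagonal-packing")
  lattices (optimally spaced limit);
* worm-like-chain filaments and rendered network images (Gaussian PSF,
  multiplicity-scaled intensity for bundles, Poisson shot noise);
* mono/bi-exponential dwell times quantized at the video frame rate and
  right-censored by the observation window;
* Brownian particle tracks with localization noise;
* Gaussian foci images for the compaction stage.

All generators are pure functions of their parameters and the field seed:
the same seed gives bit-identical output.  Ground truth is attached to
the returned object and written as a JSON sidecar by the writers.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .field import DEFAULT_FRAME_INTERVAL, FieldSpec
from .kinetics import DwellTimeSet, TrackSet
from .metrics import PointPattern
from .network_io import Snake

# seed streams per generator family, so a single field seed yields
# independent draws for patterns, chains, dwells, tracks and noise
_STREAM = {"pattern": 0, "wlc": 1, "render": 2, "dwell": 3, "track": 4, "foci": 5}


def _rng(field: FieldSpec, kind: str, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    ss = np.random.SeedSequence(entropy=field.seed, spawn_key=(_STREAM[kind],))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Point patterns
# ---------------------------------------------------------------------------

def gen_poisson_pattern(
    density: float, field: FieldSpec, rng: np.random.Generator | None = None
) -> PointPattern:
    """Homogeneous Poisson pattern: every position equiprobable and
    independent of all other points.  Count ~ Poisson(density * area)."""
    if density <= 0:
        raise ValueError("density must be positive")
    g = _rng(field, "pattern", rng)
    n = g.poisson(density * field.area)
    pts = np.column_stack([g.uniform(0, field.width, n), g.uniform(0, field.height, n)])
    return PointPattern(
        pts, field, ground_truth={"pattern_kind": "poisson", "density": density}
    )


def gen_clustered_pattern(
    parent_density: float,
    mean_offspring: float,
    cluster_sd: float,
    field: FieldSpec,
    rng: np.random.Generator | None = None,
) -> PointPattern:
    """Thomas-process clustered (aggregated) pattern.

    Parents are Poisson(parent_density); each parent spawns
    Poisson(mean_offspring) offspring displaced by an isotropic Gaussian
    of width ``cluster_sd``.  Only offspring inside the field are
    returned.  The process intensity is parent_density * mean_offspring.
    As cluster_sd -> 0 the points coalesce (randomness index -> 0); as
    cluster_sd grows beyond the field the pattern approaches Poisson.
    """
    if parent_density <= 0 or mean_offspring <= 0 or cluster_sd <= 0:
        raise ValueError("Thomas-process parameters must be positive")
    g = _rng(field, "pattern", rng)
    n_parents = g.poisson(parent_density * field.area)
    pts = []
    for _ in range(n_parents):
        parent = np.array([g.uniform(0, field.width), g.uniform(0, field.height)])
        k = g.poisson(mean_offspring)
        if k:
            pts.append(parent + g.normal(0.0, cluster_sd, size=(k, 2)))
    xy = np.vstack(pts) if pts else np.empty((0, 2))
    xy = xy[(xy[:, 0] >= 0) & (xy[:, 0] <= field.width)
            & (xy[:, 1] >= 0) & (xy[:, 1] <= field.height)]
    return PointPattern(
        xy,
        field,
        ground_truth={
            "pattern_kind": "clustered",
            "parent_density": parent_density,
            "mean_offspring": mean_offspring,
            "cluster_sd": cluster_sd,
            "intensity": parent_density * mean_offspring,
        },
    )


def gen_hexagonal_pattern(
    density: float,
    field: FieldSpec,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> PointPattern:
    """Triangular (hexagonal-packing) lattice, the optimally spaced limit.

    Lattice spacing a = sqrt(2 / (sqrt(3) * density)); rows are offset by
    a/2 and separated by a*sqrt(3)/2, so every interior point has six
    nearest neighbours at distance a.  Optional isotropic Gaussian jitter
    degrades the order toward a random pattern.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    a = np.sqrt(2.0 / (np.sqrt(3.0) * density))
    row_h = a * np.sqrt(3.0) / 2.0
    n_rows = int(np.floor(field.height / row_h)) + 1
    n_cols = int(np.floor(field.width / a)) + 1
    if n_rows < 2 or n_cols < 2:
        raise ValueError("field too small for >= 2 lattice rows at this density")
    pts = []
    for r in range(n_rows):
        y = r * row_h
        x0 = (a / 2.0) if (r % 2) else 0.0
        xs = x0 + np.arange(n_cols) * a
        keep = xs <= field.width
        pts.append(np.column_stack([xs[keep], np.full(keep.sum(), y)]))
    xy = np.vstack(pts)
    if jitter_sd > 0:
        g = _rng(field, "pattern", rng)
        xy = xy + g.normal(0.0, jitter_sd, size=xy.shape)
    xy = xy[(xy[:, 0] >= 0) & (xy[:, 0] <= field.width)
            & (xy[:, 1] >= 0) & (xy[:, 1] <= field.height)]
    return PointPattern(
        xy,
        field,
        ground_truth={
            "pattern_kind": "hexagonal",
            "density": density,
            "jitter_sd": jitter_sd,
            "spacing": a,
        },
    )


def interior_mask(pattern: PointPattern, margin: float) -> np.ndarray:
    """Boolean mask of points at least ``margin`` from every field edge."""
    p, f = pattern.points, pattern.field
    return (
        (p[:, 0] >= margin)
        & (p[:, 0] <= f.width - margin)
        & (p[:, 1] >= margin)
        & (p[:, 1] <= f.height - margin)
    )


# ---------------------------------------------------------------------------
# Worm-like-chain filaments and image rendering
# ---------------------------------------------------------------------------

def gen_wlc_snake(
    l_p: float,
    step: float,
    n_steps: int,
    field: FieldSpec,
    snake_id: str = "wlc0",
    rng: np.random.Generator | None = None,
) -> Snake:
    """Discrete 2-D worm-like chain.

    Tangent-angle increments are i.i.d. Gaussian with variance
    step / l_p, the discretization of a chain with persistence length
    ``l_p``; contour length is n_steps * step.  The chain starts at a
    uniform position and heading and may leave the field (the renderer
    clips).
    """
    if l_p <= 0 or step <= 0:
        raise ValueError("l_p and step must be positive")
    if n_steps < 2:
        raise ValueError("need >= 2 steps")
    g = _rng(field, "wlc", rng)
    theta0 = g.uniform(0, 2 * np.pi)
    dtheta = g.normal(0.0, np.sqrt(step / l_p), size=n_steps - 1)
    theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])
    start = np.array([g.uniform(0, field.width), g.uniform(0, field.height)])
    steps = np.column_stack([step * np.cos(theta), step * np.sin(theta)])
    xy = np.vstack([start, start + np.cumsum(steps, axis=0)])
    pts = np.column_stack([xy, np.zeros(len(xy))])
    return Snake(
        snake_id=snake_id,
        points=pts,
        ground_truth={"l_p": l_p, "step": step, "n_steps": n_steps},
    )


def render_network_image(
    snakes: Sequence[Snake],
    field: FieldSpec,
    multiplicity: Sequence[int] | None = None,
    psf_sd: float = 0.12,
    intensity_per_filament: float = 200.0,
    background: float = 100.0,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render snakes into a camera image.

    Each snake's path is integrated onto the pixel grid (counts
    proportional to path length per pixel), scaled by
    ``intensity_per_filament * multiplicity`` — bundle intensities add,
    so a multiplicity-2 cable is exactly twice as bright as a single
    filament — then convolved with a Gaussian PSF of width ``psf_sd``
    (um), offset by ``background`` and, if ``noise``, Poisson-sampled.
    Path samples outside the field are clipped with a warning.
    """
    if psf_sd <= 0:
        raise ValueError("psf_sd must be positive")
    ny, nx = field.shape
    img = np.zeros((ny, nx), dtype=float)
    mult = np.ones(len(snakes)) if multiplicity is None else np.asarray(multiplicity, float)
    clipped = False
    for s, m in zip(snakes, mult):
        fine = _densify(s.xy, field.pixel_size / 4.0)
        cols = np.floor(fine[:, 0] / field.pixel_size).astype(int)
        rows = np.floor(fine[:, 1] / field.pixel_size).astype(int)
        ok = (cols >= 0) & (cols < nx) & (rows >= 0) & (rows < ny)
        if not np.all(ok):
            clipped = True
        # each fine sample spans pixel_size/4 of path -> 1/4 count-unit
        np.add.at(img, (rows[ok], cols[ok]), intensity_per_filament * m * 0.25)
    if clipped:
        warnings.warn("snake path extends outside the field; clipped", stacklevel=2)
    img = ndimage.gaussian_filter(img, sigma=psf_sd / field.pixel_size, mode="constant")
    img = img + background
    if noise:
        g = _rng(field, "render", rng)
        img = g.poisson(img).astype(float)
    return img


def _densify(xy: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.hypot(*np.diff(xy, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(np.ceil(arclen[-1] / spacing)) + 1)
    s = np.linspace(0.0, arclen[-1], n)
    return np.column_stack([np.interp(s, arclen, xy[:, 0]), np.interp(s, arclen, xy[:, 1])])


# ---------------------------------------------------------------------------
# Dwell times
# ---------------------------------------------------------------------------

def gen_dwell_times(
    components: Sequence[tuple[float, float]],
    n: int,
    field: FieldSpec,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    window: float = 20.0,
    rng: np.random.Generator | None = None,
) -> DwellTimeSet:
    """Mono/multi-exponential dwell times as the camera records them.

    ``components`` is a list of (amplitude, rate 1/s) pairs; amplitudes
    must sum to 1.  Exact exponential durations are quantized to whole
    frames by ceiling (a molecule visible during any part of a frame is
    counted for that frame) and right-censored at the observation
    ``window`` (seconds), matching a finite video record.
    """
    amps = np.array([a for a, _ in components], dtype=float)
    rates = np.array([k for _, k in components], dtype=float)
    if np.any(amps < 0) or not np.isclose(amps.sum(), 1.0, atol=1e-6):
        raise ValueError("mixture amplitudes must be >= 0 and sum to 1")
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    if frame_interval <= 0 or window <= 0 or n < 1:
        raise ValueError("frame_interval, window and n must be positive")
    g = _rng(field, "dwell", rng)
    comp = g.choice(len(amps), size=n, p=amps / amps.sum())
    exact = g.exponential(1.0 / rates[comp])
    frames = np.ceil(exact / frame_interval).astype(int)
    frames = np.maximum(frames, 1)
    window_frames = int(np.floor(window / frame_interval))
    censored = frames > window_frames
    frames = np.minimum(frames, window_frames)
    return DwellTimeSet(
        durations=frames * frame_interval,
        censored=censored,
        frame_interval=frame_interval,
        quantized=True,
        ground_truth={
            "components": [(float(a), float(k)) for a, k in components],
            "window_s": window,
            "frame_interval_s": frame_interval,
            "mean_s": float(np.sum(amps / rates)),
        },
    )


# ---------------------------------------------------------------------------
# Brownian tracks
# ---------------------------------------------------------------------------

def gen_tracks(
    D: float,
    n_tracks: int,
    n_frames: int,
    field: FieldSpec,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    loc_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TrackSet:
    """2-D Brownian tracks with Gaussian localization noise.

    Per-axis increment variance is 2 * D * frame_interval, so the
    population MSD is 4 D dT; localization noise adds an offset of about
    4 * loc_noise_sd**2 to the observed MSD.
    """
    if D < 0 or loc_noise_sd < 0:
        raise ValueError("D and loc_noise_sd must be >= 0")
    if n_frames < 2 or n_tracks < 1:
        raise ValueError("need n_frames >= 2 and n_tracks >= 1")
    g = _rng(field, "track", rng)
    sd = np.sqrt(2.0 * D * frame_interval)
    rows = []
    for tid in range(n_tracks):
        start = np.array([g.uniform(0, field.width), g.uniform(0, field.height)])
        steps = g.normal(0.0, sd, size=(n_frames - 1, 2)) if sd > 0 else np.zeros((n_frames - 1, 2))
        true_xy = start + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        obs = true_xy + (g.normal(0.0, loc_noise_sd, size=true_xy.shape)
                         if loc_noise_sd > 0 else 0.0)
        for f in range(n_frames):
            rows.append((tid, f, obs[f, 0], obs[f, 1], 1.0))
    df = pd.DataFrame(rows, columns=TrackSet.COLUMNS)
    return TrackSet(
        df,
        frame_interval=frame_interval,
        ground_truth={"D": D, "loc_noise_sd": loc_noise_sd, "n_tracks": n_tracks,
                      "n_frames": n_frames},
    )


# ---------------------------------------------------------------------------
# Foci images
# ---------------------------------------------------------------------------

def gen_foci_image(
    foci_true: Sequence[tuple[tuple[float, float], float, float]],
    field: FieldSpec,
    background: float = 100.0,
    noise: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Gaussian foci on a flat background.

    ``foci_true`` entries are ((x, y) um, radius um, peak counts); each
    focus is an isotropic Gaussian of width ``radius`` above background.
    The ground truth records the analytic area above half-peak,
    2 * pi * radius^2 * ln 2, and flags overlapping pairs (half-maximum
    disks intersecting).
    """
    for _, r, p in foci_true:
        if r <= 0:
            raise ValueError("focus radii must be positive")
        if p <= 0:
            raise ValueError("focus peaks must be positive")
    ny, nx = field.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    x_um = xx * field.pixel_size
    y_um = yy * field.pixel_size
    img = np.full((ny, nx), float(background))
    gt_foci = []
    for (cx, cy), r, peak in foci_true:
        img += peak * np.exp(-((x_um - cx) ** 2 + (y_um - cy) ** 2) / (2.0 * r**2))
        gt_foci.append(
            {
                "centroid": [cx, cy],
                "radius": r,
                "peak": peak,
                "area_above_half_max_um2": 2.0 * np.pi * r**2 * np.log(2.0),
            }
        )
    overlap = False
    hw = 1.17741  # half-FWHM in units of sigma
    for i in range(len(gt_foci)):
        for j in range(i + 1, len(gt_foci)):
            d = np.hypot(
                gt_foci[i]["centroid"][0] - gt_foci[j]["centroid"][0],
                gt_foci[i]["centroid"][1] - gt_foci[j]["centroid"][1],
            )
            if d < hw * (gt_foci[i]["radius"] + gt_foci[j]["radius"]):
                overlap = True
    if noise:
        g = _rng(field, "foci", rng)
        img = g.poisson(img).astype(float)
    gt = {"foci": gt_foci, "background": background, "overlapping": overlap,
          "n_foci": len(gt_foci)}
    return img, gt


# ---------------------------------------------------------------------------
# Writers (CSV/TIFF + JSON ground-truth sidecars)
# ---------------------------------------------------------------------------

def _sidecar(path: Path, ground_truth: dict, field: FieldSpec | None = None) -> None:
    doc = dict(ground_truth)
    if field is not None:
        doc["field"] = field.to_dict()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(doc, indent=1))


def write_pattern_csv(pattern: PointPattern, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(pattern.points, columns=["x_um", "y_um"]).to_csv(path, index=False)
    _sidecar(path, pattern.ground_truth, pattern.field)


def write_image_tiff(
    image: np.ndarray, path: str | Path, field: FieldSpec, ground_truth: dict | None = None
) -> None:
    """Write a single- or multi-page 16-bit grayscale TIFF with pixel size
    in the resolution tags (pixels per cm) and a JSON sidecar."""
    path = Path(path)
    arr = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    px_per_cm = 1e4 / field.pixel_size
    tifffile.imwrite(
        path,
        arr,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        metadata={"pixel_size_um": field.pixel_size},
    )
    _sidecar(path, ground_truth or {}, field)


def write_tracks_csv(tracks: TrackSet, path: str | Path) -> None:
    path = Path(path)
    tracks.to_csv(path)
    _sidecar(path, {**tracks.ground_truth, "frame_interval_s": tracks.frame_interval})


def write_dwells_csv(dwells: DwellTimeSet, path: str | Path) -> None:
    path = Path(path)
    dwells.to_frame().to_csv(path, index=False)
    _sidecar(path, {**dwells.ground_truth, "frame_interval_s": dwells.frame_interval})


__all__ = [
    "gen_poisson_pattern",
    "gen_clustered_pattern",
    "gen_hexagonal_pattern",
    "interior_mask",
    "gen_wlc_snake",
    "render_network_image",
    "gen_dwell_times",
    "gen_tracks",
    "gen_foci_image",
    "write_pattern_csv",
    "write_image_tiff",
    "write_tracks_csv",
    "write_dwells_csv",
]
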
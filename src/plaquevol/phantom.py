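"""Synthetic multi-echo T2* phantom with known plaque ground truth.

The generator emulates a multi-slice gradient-echo mouse-brain acquisition:
an elliptical "brain" of uniform tissue on an air background, imaged at a
ladder of echo times under mono-exponential T2* decay, with SPIO-laden
plaques rendered as spheres that locally raise the decay rate R2*.  Plaque
diameters sit at or below the voxel scale, so spheres are rendered with
fractional (partial-volume) fill: a voxel's added decay rate is the plaque's
``delta_r2star`` scaled by the fraction of the voxel inside the sphere.
Magnitude images carry Rician noise.

Conventions shared by the whole package: arrays are indexed
``(slice, row, col)``; spacing tuples are ordered ``(row, col, slice)`` in
mm; world coordinates are mm from the volume corner with voxel centers at
``(i + 0.5) * spacing``; echo times are ms and decay rates ms^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PlaqueTruth",
    "PhantomSpec",
    "MultiEchoVolume",
    "signal_at_te",
    "brain_ellipse_mask",
    "render_plaque_fraction",
    "plaque_peak_fraction",
    "generate_phantom",
    "study_phantom_spec",
    "add_single_echo_speckles",
]

#: fraction of the field of view spanned by each brain-ellipse semi-axis
BRAIN_AXIS_FRACTION = 0.45


@dataclass
class PlaqueTruth:
    """Ground-truth sphere: center (mm, world), radius (mm), added R2* (ms^-1)."""

    center: tuple[float, float, float]  # (row, col, slice) world mm
    radius: float
    delta_r2star: float
    overlaps_another: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.delta_r2star <= 0:
            raise ValueError(f"delta_r2star must be > 0, got {self.delta_r2star}")

    @property
    def true_volume(self) -> float:
        """Sphere volume in mm^3."""
        return (4.0 / 3.0) * math.pi * self.radius**3


@dataclass
class PhantomSpec:
    """Full description of a synthetic acquisition; a pure function input."""

    matrix_rows: int = 256
    matrix_cols: int = 256
    n_slices: int = 22
    spacing: tuple[float, float, float] = (0.0625, 0.0625, 0.5)  # (row, col, slice) mm
    te_list: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0)  # ms
    tissue_s0: float = 100.0
    tissue_r2star: float = 0.04  # ms^-1 (T2* = 25 ms)
    plaques: list[PlaqueTruth] = field(default_factory=list)
    noise_sigma: float = 0.02  # fraction of tissue_s0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.matrix_rows, self.matrix_cols, self.n_slices) < 1:
            raise ValueError("matrix dimensions must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        te = np.asarray(self.te_list, dtype=float)
        if te.size < 1 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("te_list must be strictly increasing and all > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.tissue_s0 < 0 or self.tissue_r2star < 0:
            raise ValueError("tissue_s0 and tissue_r2star must be >= 0")
        for p in self.plaques:
            self._check_plaque(p)

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extent (row, col, slice) in mm."""
        return (
            self.matrix_rows * self.spacing[0],
            self.matrix_cols * self.spacing[1],
            self.n_slices * self.spacing[2],
        )

    def _check_plaque(self, p: PlaqueTruth) -> None:
        ex, ey, ez = self.extent
        x, y, z = p.center
        if not (p.radius <= x <= ex - p.radius
                and p.radius <= y <= ey - p.radius
                and p.radius <= z <= ez - p.radius):
            raise ValueError(f"plaque at {p.center} (r={p.radius}) extends outside the volume")
        a, b = BRAIN_AXIS_FRACTION * ex, BRAIN_AXIS_FRACTION * ey
        if ((x - ex / 2) / a) ** 2 + ((y - ey / 2) / b) ** 2 > 1.0:
            raise ValueError(f"plaque center {p.center} lies outside the brain ellipse")


@dataclass
class MultiEchoVolume:
    """Aligned 3D magnitude volumes, one per echo time."""

    volumes: list[np.ndarray]  # each (n_slices, rows, cols)
    spacing: tuple[float, float, float]  # (row, col, slice) mm
    te_list: tuple[float, ...]  # ms, ascending
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.te_list):
            raise ValueError("one volume per echo time required")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) != 1:
            raise ValueError(f"all echo volumes must share a shape, got {shapes}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    def echo(self, te: float) -> np.ndarray:
        """The volume acquired at echo time ``te`` (ms, exact match)."""
        for t, v in zip(self.te_list, self.volumes):
            if t == te:
                return v
        raise KeyError(f"no echo at TE={te} ms (have {self.te_list})")


def signal_at_te(s0, r2star, te):
    """Mono-exponential gradient-echo magnitude: ``s0 * exp(-r2star * te)``.

    All arguments may be scalars or broadcastable arrays; ``s0`` in arbitrary
    signal units, ``r2star`` in ms^-1, ``te`` in ms.
    """
    s0 = np.asarray(s0, dtype=float)
    r2star = np.asarray(r2star, dtype=float)
    te = np.asarray(te, dtype=float)
    if np.any(s0 < 0) or np.any(r2star < 0) or np.any(te < 0):
        raise ValueError("signal_at_te requires s0 >= 0, r2star >= 0, te >= 0")
    out = s0 * np.exp(-r2star * te)
    return float(out) if out.ndim == 0 else out


def brain_ellipse_mask(spec: PhantomSpec) -> np.ndarray:
    """Binary brain mask: the same centered ellipse on every slice.

    Semi-axes are ``BRAIN_AXIS_FRACTION`` of the in-plane extent, so the
    section covers ~64% of the field, approximating a coronal mouse-brain
    section inside the surface-coil field of view.
    """
    ex, ey, _ = spec.extent
    rows = (np.arange(spec.matrix_rows) + 0.5) * spec.spacing[0]
    cols = (np.arange(spec.matrix_cols) + 0.5) * spec.spacing[1]
    a, b = BRAIN_AXIS_FRACTION * ex, BRAIN_AXIS_FRACTION * ey
    rr = ((rows - ex / 2) / a) ** 2
    cc = ((cols - ey / 2) / b) ** 2
    in_plane = rr[:, None] + cc[None, :] <= 1.0
    return np.broadcast_to(in_plane, (spec.n_slices,) + in_plane.shape).copy()


def _voxel_fraction_grid(plaque: PlaqueTruth, spec: PhantomSpec):
    """Bounding-box voxel index slices and per-voxel inside-sphere fractions.

    Boundary voxels are sub-sampled on a midpoint grid fine enough that the
    sub-cell is ~radius/3 along each axis (decay-rate error from the
    fractional fill is then well below the noise floor).
    """
    sr, sc, ss = spec.spacing
    cx, cy, cz = plaque.center
    r = plaque.radius
    shape = (spec.n_slices, spec.matrix_rows, spec.matrix_cols)
    # voxel index ranges (slice, row, col) overlapping the sphere
    lo = [max(0, int((c - r) / s)) for c, s in ((cz, ss), (cx, sr), (cy, sc))]
    hi = [
        min(n, int((c + r) / s) + 1)
        for c, s, n in ((cz, ss, shape[0]), (cx, sr, shape[1]), (cy, sc, shape[2]))
    ]
    if any(l >= h for l, h in zip(lo, hi)):  # degenerate: sphere between grid planes
        lo = [min(l, n - 1) for l, n in zip(lo, shape)]
        hi = [l + 1 for l in lo]
    nsub = [max(4, math.ceil(s / (r / 6.0))) for s in (ss, sr, sc)]
    frac = np.zeros([h - l for l, h in zip(lo, hi)])
    for iz in range(lo[0], hi[0]):
        for ix in range(lo[1], hi[1]):
            for iy in range(lo[2], hi[2]):
                # distance from voxel center to sphere center vs half-diagonal
                vc = np.array([(ix + 0.5) * sr - cx, (iy + 0.5) * sc - cy, (iz + 0.5) * ss - cz])
                half_diag = 0.5 * math.sqrt(sr**2 + sc**2 + ss**2)
                d = math.sqrt(float(vc @ vc))
                if d - half_diag >= r:
                    continue
                if d + half_diag <= r:
                    frac[iz - lo[0], ix - lo[1], iy - lo[2]] = 1.0
                    continue
                zs = (iz + (np.arange(nsub[0]) + 0.5) / nsub[0]) * ss - cz
                xs = (ix + (np.arange(nsub[1]) + 0.5) / nsub[1]) * sr - cx
                ys = (iy + (np.arange(nsub[2]) + 0.5) / nsub[2]) * sc - cy
                d2 = zs[:, None, None] ** 2 + xs[None, :, None] ** 2 + ys[None, None, :] ** 2
                frac[iz - lo[0], ix - lo[1], iy - lo[2]] = float(np.mean(d2 <= r * r))
    return tuple(slice(l, h) for l, h in zip(lo, hi)), frac


def render_plaque_fraction(plaque: PlaqueTruth, spec: PhantomSpec) -> np.ndarray:
    """Full-volume partial-volume fraction field of one plaque (mostly zeros)."""
    sl, frac = _voxel_fraction_grid(plaque, spec)
    out = np.zeros((spec.n_slices, spec.matrix_rows, spec.matrix_cols))
    out[sl] = frac
    return out


def plaque_peak_fraction(plaque: PlaqueTruth, spec: PhantomSpec) -> float:
    """Largest inside-sphere voxel fraction the plaque produces on this grid."""
    _, frac = _voxel_fraction_grid(plaque, spec)
    return float(frac.max())


def generate_phantom(spec: PhantomSpec) -> tuple[MultiEchoVolume, list[PlaqueTruth]]:
    """Render the phantom described by ``spec``.

    Returns the multi-echo volume and the ground-truth plaque list (the
    spec's plaques, with ``overlaps_another`` flagged on geometric overlap).
    Output is a pure function of the spec, including its seed: identical
    specs give bit-identical volumes.
    """
    brain = brain_ellipse_mask(spec)
    r2 = np.where(brain, spec.tissue_r2star, 0.0)
    s0 = np.where(brain, spec.tissue_s0, 0.0)

    truths = [replace(p) for p in spec.plaques]
    for i, a in enumerate(truths):
        for b in truths[i + 1:]:
            d = math.dist(a.center, b.center)
            if d < a.radius + b.radius:
                a.overlaps_another = b.overlaps_another = True
    if any(p.overlaps_another for p in truths):
        warnings.warn(
            "phantom contains overlapping plaques; per-plaque volumes are non-additive",
            stacklevel=2,
        )

    for p in truths:
        sl, frac = _voxel_fraction_grid(p, spec)
        r2[sl] += frac * p.delta_r2star

    rng = np.random.default_rng(spec.seed)
    sigma = spec.noise_sigma * spec.tissue_s0
    vols = []
    for te in spec.te_list:
        clean = signal_at_te(s0, r2, te)
        if sigma > 0:
            # Rician magnitude: Gaussian noise in both quadrature channels
            re = clean + rng.normal(0.0, sigma, clean.shape)
            im = rng.normal(0.0, sigma, clean.shape)
            vols.append(np.hypot(re, im))
        else:
            vols.append(clean)
    mev = MultiEchoVolume(vols, spec.spacing, tuple(float(t) for t in spec.te_list))
    mev.meta["overlapping_plaques"] = int(sum(p.overlaps_another for p in truths))
    return mev, truths


def study_phantom_spec(
    n_plaques: int = 30,
    seed: int = 0,
    radius_range: tuple[float, float] = (0.08, 0.15),
    contrast_te10: float = 0.4,
    noise_sigma: float = 0.02,
    min_separation: float = 1.2,
    detection_te: float = 10.0,
    **spec_kwargs,
) -> PhantomSpec:
    """Reference recovery phantom: disjoint sub-voxel plaques at a calibrated depth.

    Radii are drawn uniformly from ``radius_range`` (mm) and centers uniformly
    inside a margin-shrunk brain ellipse, rejecting draws closer than
    ``min_separation`` mm to an earlier plaque so neighborhood statistics stay
    independent.  Each plaque's ``delta_r2star`` is calibrated so that its
    darkest rendered voxel has a signal ratio of ``contrast_te10`` to tissue
    at the detection echo — i.e. the iron load is set by the contrast depth it
    produces, which is how SPIO-labeled plaques are characterized in vivo.
    """
    base = PhantomSpec(noise_sigma=noise_sigma, seed=seed, **spec_kwargs)
    if not (0 < contrast_te10 < 1):
        raise ValueError("contrast_te10 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ex, ey, ez = base.extent
    a, b = 0.75 * BRAIN_AXIS_FRACTION * ex, 0.75 * BRAIN_AXIS_FRACTION * ey
    z_margin = max(1.0, radius_range[1])
    plaques: list[PlaqueTruth] = []
    attempts = 0
    while len(plaques) < n_plaques:
        attempts += 1
        if attempts > 10000 * n_plaques:
            raise RuntimeError("could not place disjoint plaques; relax min_separation")
        r = float(rng.uniform(*radius_range))
        # uniform in the shrunk ellipse via rejection from its bounding box
        x = float(rng.uniform(ex / 2 - a, ex / 2 + a))
        y = float(rng.uniform(ey / 2 - b, ey / 2 + b))
        if ((x - ex / 2) / a) ** 2 + ((y - ey / 2) / b) ** 2 > 1.0:
            continue
        z = float(rng.uniform(z_margin, ez - z_margin))
        if any(math.dist((x, y, z), p.center) < min_separation for p in plaques):
            continue
        probe = PlaqueTruth(center=(x, y, z), radius=r, delta_r2star=1.0)
        peak = plaque_peak_fraction(probe, base)
        delta = -math.log(contrast_te10) / (detection_te * peak)
        plaques.append(PlaqueTruth(center=(x, y, z), radius=r, delta_r2star=delta))
    return replace(base, plaques=plaques)


def add_single_echo_speckles(
    mev: MultiEchoVolume,
    mask: np.ndarray,
    n: int,
    seed: int,
    depth: float = 0.3,
    te: float | None = None,
    avoid: np.ndarray | None = None,
) -> list[tuple[int, int, int]]:
    """Plant single-echo dark speckles — the noise artifact the long-TE filter rejects.

    Scales ``n`` in-mask voxels of one echo (default: the first) by ``depth``
    while leaving every other echo untouched; a true SPIO plaque darkens all
    echoes, so these are false positives by construction.  Modifies ``mev``
    in place and returns the planted ``(slice, row, col)`` indices.
    """
    rng = np.random.default_rng(seed)
    vol = mev.echo(te if te is not None else mev.te_list[0])
    eligible = mask.copy()
    if avoid is not None:
        eligible &= ~avoid
    idx = np.flatnonzero(eligible)
    if idx.size < n:
        raise ValueError(f"only {idx.size} eligible voxels for {n} speckles")
    chosen = rng.choice(idx, size=n, replace=False)
    coords = [tuple(int(c) for c in np.unravel_index(k, mask.shape)) for k in chosen]
    for c in coords:
        vol[c] *= depth
    return coords
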
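"""Forward model and synthetic fixtures for ion-beam depth-scan imaging.

The detected image at each depth is modeled as

    I(x, y, z) = (P_out / P_in) * [O(x, y, z) (*) PSF(x, y)] * N(x, y, z)

where O is the true object distribution, PSF is a lateral Gaussian beam
kernel (the beam also collects ions from up to ``axial_extent_nm`` of
material below the current etch plane, modeled as a uniform axial box),
P_out/P_in is the ion extraction efficiency (~3%), and N is i.i.d.
multiplicative gamma noise with mean pinned at 1.  Additive background is
negligible in ion-beam imaging and is omitted by default; a small optional
dark-count floor is available for threshold testing.

All fixtures the downstream stages are validated against live here: the
six-molecule array (point sources 200 nm apart imaged at 50 nm pixels with
a 120 nm beam), sharp-edge half-planes, isotope-doped silica nanotag
spheres (~110 nm diameter, emitting identically in two mass channels), and
drifting micron-scale fiducial beads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .stack import AcquisitionGeometry, IonStack

__all__ = [
    "PointSource", "Sphere", "HalfPlane", "ObjectVolume",
    "PSFModel", "NoiseModel", "DriftTrace",
    "simulate_stack", "six_point_fixture", "six_point_geometry",
    "edge_fixture", "nanotag_fixture", "nanotag_pair_fixture",
    "ramp_drift", "apply_drift",
]

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 2.3548200450309493

_SUPERSAMPLE = 3  # sub-pixel sampling for spheres / partial-coverage edges


@dataclass(frozen=True)
class PointSource:
    """A point emitter at (x, y, z) nm emitting ``rate`` counts per slice
    while the etch slab overlaps its depth."""
    x_nm: float
    y_nm: float
    z_nm: float
    rate: float
    channel: int = 0


@dataclass(frozen=True)
class Sphere:
    """A uniform-density sphere; ``rates_per_nm`` gives, per channel, the
    emitted counts per nm of column chord through the sphere."""
    x_nm: float
    y_nm: float
    z_nm: float
    diameter_nm: float
    rates_per_nm: tuple[float, ...]


@dataclass(frozen=True)
class HalfPlane:
    """A uniform half-plane source (x >= edge_x_nm) emitting ``rate`` counts
    per pixel per slice; partial pixel coverage at the edge is resolved by
    supersampling."""
    edge_x_nm: float
    rate: float
    channel: int = 0


@dataclass
class ObjectVolume:
    """Ground-truth source collection for a target geometry."""
    geometry: AcquisitionGeometry
    n_channels: int = 1
    points: list[PointSource] = field(default_factory=list)
    spheres: list[Sphere] = field(default_factory=list)
    half_planes: list[HalfPlane] = field(default_factory=list)

    def __post_init__(self) -> None:
        fx, fy = self.geometry.field_x_nm, self.geometry.field_y_nm
        for p in self.points:
            if p.rate < 0:
                raise ValueError("point source rates must be >= 0")
            if not (0 <= p.x_nm < fx and 0 <= p.y_nm < fy):
                raise ValueError(f"point source at ({p.x_nm}, {p.y_nm}) outside field")
        for s in self.spheres:
            if any(r < 0 for r in s.rates_per_nm):
                raise ValueError("sphere rates must be >= 0")
        for h in self.half_planes:
            if h.rate < 0:
                raise ValueError("half-plane rate must be >= 0")

    def rasterize(self, channel: int, z0_nm: float, z1_nm: float) -> np.ndarray:
        """Expected emitted counts per pixel from material in [z0, z1) nm."""
        g = self.geometry
        img = np.zeros((g.n_pixels_y, g.n_pixels_x), dtype=float)
        dx, dy = g.dx_nm, g.dy_nm
        for p in self.points:
            if p.channel == channel and z0_nm <= p.z_nm < z1_nm:
                j = min(int(p.x_nm / dx), g.n_pixels_x - 1)
                i = min(int(p.y_nm / dy), g.n_pixels_y - 1)
                img[i, j] += p.rate
        for h in self.half_planes:
            if h.channel != channel:
                continue
            # supersampled x coverage fraction per pixel column
            ss = _SUPERSAMPLE
            xs = (np.arange(g.n_pixels_x * ss) + 0.5) * (dx / ss)
            cover = (xs >= h.edge_x_nm).astype(float).reshape(g.n_pixels_x, ss).mean(axis=1)
            img += h.rate * cover[None, :]
        spheres = [s for s in self.spheres
                   if channel < len(s.rates_per_nm) and s.rates_per_nm[channel] > 0]
        if spheres:
            img += self._rasterize_spheres(spheres, channel, z0_nm, z1_nm)
        return img

    def _rasterize_spheres(self, spheres: Sequence[Sphere], channel: int,
                           z0_nm: float, z1_nm: float) -> np.ndarray:
        g = self.geometry
        ss = _SUPERSAMPLE
        dx, dy = g.dx_nm, g.dy_nm
        img = np.zeros((g.n_pixels_y, g.n_pixels_x), dtype=float)
        for s in spheres:
            r = s.diameter_nm / 2.0
            # bounding pixel box
            j0 = max(int((s.x_nm - r) / dx) - 1, 0)
            j1 = min(int((s.x_nm + r) / dx) + 2, g.n_pixels_x)
            i0 = max(int((s.y_nm - r) / dy) - 1, 0)
            i1 = min(int((s.y_nm + r) / dy) + 2, g.n_pixels_y)
            if j0 >= j1 or i0 >= i1:
                continue
            xs = (np.arange(j0 * ss, j1 * ss) + 0.5) * (dx / ss)
            ys = (np.arange(i0 * ss, i1 * ss) + 0.5) * (dy / ss)
            xx, yy = np.meshgrid(xs - s.x_nm, ys - s.y_nm)
            d2 = xx * xx + yy * yy
            half = np.sqrt(np.clip(r * r - d2, 0.0, None))
            # chord through the sphere restricted to the [z0, z1) slab
            lo = np.maximum(s.z_nm - half, z0_nm)
            hi = np.minimum(s.z_nm + half, z1_nm)
            chord = np.clip(hi - lo, 0.0, None)
            block = chord.reshape(i1 - i0, ss, j1 - j0, ss).mean(axis=(1, 3))
            img[i0:i1, j0:j1] += s.rates_per_nm[channel] * block
        return img

    def total_emission_per_slice(self, channel: int, z0_nm: float, z1_nm: float) -> float:
        return float(self.rasterize(channel, z0_nm, z1_nm).sum())


@dataclass(frozen=True)
class PSFModel:
    """Separable beam PSF: Gaussian laterally, uniform box axially.

    ``lateral_fwhm_nm`` is the beam width as a full width at half maximum;
    ``axial_extent_nm`` is the sub-surface depth (default 100 nm) whose
    material still contributes ions to the current scan.
    """
    lateral_fwhm_nm: float
    axial_extent_nm: float = 100.0

    def __post_init__(self) -> None:
        if self.lateral_fwhm_nm <= 0:
            raise ValueError("lateral_fwhm_nm must be > 0")
        if self.axial_extent_nm <= 0:
            raise ValueError("axial_extent_nm must be > 0")

    @property
    def sigma_nm(self) -> float:
        return self.lateral_fwhm_nm / FWHM_TO_SIGMA

    def is_delta(self, dx_nm: float) -> bool:
        """Whether the kernel collapses to a single pixel at this sampling."""
        return self.sigma_nm / dx_nm < 1e-3

    def kernel(self, dx_nm: float) -> np.ndarray:
        """Normalized 2D Gaussian kernel sampled at pixel pitch ``dx_nm``."""
        if self.is_delta(dx_nm):
            return np.ones((1, 1))
        sigma_px = self.sigma_nm / dx_nm
        radius = max(int(np.ceil(4.0 * sigma_px)), 1)
        ax = np.arange(-radius, radius + 1, dtype=float)
        g1 = np.exp(-0.5 * (ax / sigma_px) ** 2)
        k = np.outer(g1, g1)
        return k / k.sum()


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative gamma noise with mean 1 plus extraction efficiency.

    ``gamma_shape`` is the shape k of the gamma factor (scale = 1/k so the
    mean is exactly 1 and the variance 1/k); ``None`` disables the noise.
    ``extraction_efficiency`` is the dimensionless P_out/P_in fraction,
    ~0.03 for the instrument regime modeled here.
    """
    gamma_shape: float | None = 3.0
    extraction_efficiency: float = 0.03
    seed: int = 0
    dark_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0 (or None to disable)")
        if not (0 < self.extraction_efficiency <= 1):
            raise ValueError("extraction_efficiency must be in (0, 1]")

    def factors(self, rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(shape)
        k = self.gamma_shape
        return rng.gamma(shape=k, scale=1.0 / k, size=shape)


@dataclass
class DriftTrace:
    """Per-slice lateral offsets (dx_px, dy_px); slice 0 is (0, 0)."""
    offsets: np.ndarray  # (n_slices, 2), columns (dx, dy) in pixels

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.ndim != 2 or self.offsets.shape[1] != 2:
            raise ValueError("offsets must be (n_slices, 2)")

    def __len__(self) -> int:
        return self.offsets.shape[0]


def simulate_stack(obj: ObjectVolume, psf: PSFModel, noise: NoiseModel,
                   geom: AcquisitionGeometry, n_slices: int,
                   channel_labels: Sequence[str] | None = None) -> IonStack:
    """Run the forward model: rasterize, blur, scale, contaminate.

    Each output slice integrates object content over the axial window
    [z, z + axial_extent) below the current etch plane, convolves it with
    the lateral Gaussian beam kernel (reflective boundaries), scales by the
    extraction efficiency and multiplies by i.i.d. gamma factors.  The
    result is a pure function of (inputs, noise.seed).
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if not psf.is_delta(geom.dx_nm) and geom.dx_nm > psf.lateral_fwhm_nm:
        import warnings
        warnings.warn("pixel size exceeds PSF width; image will be undersampled")
    if channel_labels is None:
        channel_labels = [f"ch{c}" for c in range(obj.n_channels)]
    rng = np.random.default_rng(noise.seed)
    kernel = psf.kernel(geom.dx_nm)
    counts = np.zeros((n_slices, obj.n_channels, geom.n_pixels_y, geom.n_pixels_x))
    for z in range(n_slices):
        z0 = z * geom.z_step_nm
        z1 = z0 + psf.axial_extent_nm
        for c in range(obj.n_channels):
            density = obj.rasterize(c, z0, z1)
            if kernel.shape != (1, 1):
                density = ndimage.convolve(density, kernel, mode="reflect")
            counts[z, c] = noise.extraction_efficiency * density
    counts *= noise.factors(rng, counts.shape)
    if noise.dark_floor > 0:
        counts += rng.poisson(noise.dark_floor, size=counts.shape)
    stack = IonStack(counts=counts, channel_labels=list(channel_labels),
                     geometry=geom, seed=noise.seed)
    stack.log(f"simulate_stack(n_slices={n_slices}, psf_fwhm={psf.lateral_fwhm_nm}nm, "
              f"axial={psf.axial_extent_nm}nm, eff={noise.extraction_efficiency}, "
              f"gamma_k={noise.gamma_shape}, seed={noise.seed})")
    return stack


def six_point_geometry(n_pixels: int = 64, pixel_nm: float = 50.0,
                       beam_width_nm: float = 120.0) -> AcquisitionGeometry:
    """Default geometry for the six-molecule validation array: 50 nm pixels
    paired with a 120 nm beam."""
    area_um = n_pixels * pixel_nm / 1000.0
    return AcquisitionGeometry(scan_area_x_um=area_um, scan_area_y_um=area_um,
                               n_pixels_x=n_pixels, n_pixels_y=n_pixels,
                               beam_width_nm=beam_width_nm)


def six_point_fixture(geom: AcquisitionGeometry, rate: float = 400.0,
                      spacing_nm: float = 200.0, depth_nm: float = 50.0) -> ObjectVolume:
    """Collinear array of six equal-rate virtual molecules 200 nm apart,
    centered in the field."""
    span = 5 * spacing_nm
    if geom.field_x_nm <= span:
        raise ValueError(f"field ({geom.field_x_nm} nm) too small for a "
                         f"{span} nm array")
    x0 = (geom.field_x_nm - span) / 2.0
    y = geom.field_y_nm / 2.0
    points = [PointSource(x_nm=x0 + i * spacing_nm, y_nm=y, z_nm=depth_nm, rate=rate)
              for i in range(6)]
    return ObjectVolume(geometry=geom, n_channels=1, points=points)


def edge_fixture(geom: AcquisitionGeometry, edge_x_nm: float,
                 rate: float = 100.0) -> ObjectVolume:
    """Sharp metal/substrate interface: uniform half-plane for x >= edge."""
    return ObjectVolume(geometry=geom, n_channels=1,
                        half_planes=[HalfPlane(edge_x_nm=edge_x_nm, rate=rate)])


def nanotag_fixture(geom: AcquisitionGeometry, n_tags: int,
                    mean_d_nm: float = 109.8, sd_d_nm: float = 17.6,
                    channels: int = 2, depth_nm: float = 300.0,
                    rate_per_nm: float = 3.0, seed: int = 0,
                    min_gap_nm: float = 0.0,
                    positions_nm: Sequence[tuple[float, float, float]] | None = None,
                    max_tries: int = 10_000) -> ObjectVolume:
    """Isotope-doped silica nanotag spheres emitting identically in all
    channels (a perfectly co-localized ground truth).

    Diameters are sampled from N(109.8, 17.6) nm truncated at > 0; centers
    are rejection-sampled to be non-overlapping (plus ``min_gap_nm``).
    Explicit ``positions_nm`` bypass the sampling for deterministic layouts.
    """
    rng = np.random.default_rng(seed)

    def draw_diameter() -> float:
        for _ in range(1000):
            d = rng.normal(mean_d_nm, sd_d_nm)
            if d > 0:
                return d
        raise RuntimeError("could not sample a positive diameter")

    spheres: list[Sphere] = []
    rates = tuple(rate_per_nm for _ in range(channels))
    if positions_nm is not None:
        if len(positions_nm) != n_tags:
            raise ValueError("positions_nm length must equal n_tags")
        for (x, y, z) in positions_nm:
            spheres.append(Sphere(x, y, z, draw_diameter(), rates))
        return ObjectVolume(geometry=geom, n_channels=channels, spheres=spheres)

    margin = mean_d_nm  # keep tags inside the field
    tries = 0
    while len(spheres) < n_tags:
        if tries >= max_tries:
            raise RuntimeError(f"could not place {n_tags} non-overlapping tags "
                               f"after {max_tries} tries")
        tries += 1
        d = draw_diameter()
        x = rng.uniform(margin, geom.field_x_nm - margin)
        y = rng.uniform(margin, geom.field_y_nm - margin)
        z = rng.uniform(d / 2, depth_nm - d / 2) if depth_nm > d else d / 2
        ok = all(np.hypot(np.hypot(x - s.x_nm, y - s.y_nm), z - s.z_nm)
                 > (d + s.diameter_nm) / 2 + min_gap_nm for s in spheres)
        if ok:
            spheres.append(Sphere(x, y, z, d, rates))
    return ObjectVolume(geometry=geom, n_channels=channels, spheres=spheres)


def nanotag_pair_fixture(geom: AcquisitionGeometry,
                         lateral_sep_nm: float = 115.0,
                         z_top_nm: float = 100.0,
                         z_bottom_nm: float = 320.0,
                         diameter_nm: float = 109.8,
                         rate_per_nm: float = 10.0,
                         channels: int = 2, seed: int = 0) -> ObjectVolume:
    """A nanotag pair closer laterally than the beam width but staggered in
    depth.

    The lateral separation (default 115 nm, below a 120 nm beam FWHM)
    makes the pair a single blob in any raw sum; the depth stagger means
    successive etch scans sample the two tags at different times, which is
    the stochastic separation SILM exploits (the depth axis plays the role
    time plays for blinking fluorophores).  Equal fixed diameters keep the
    two tags equally bright.
    """
    cx, cy = geom.field_x_nm / 2.0, geom.field_y_nm / 2.0
    positions = [(cx - lateral_sep_nm / 2.0, cy, z_top_nm),
                 (cx + lateral_sep_nm / 2.0, cy, z_bottom_nm)]
    return nanotag_fixture(geom, 2, mean_d_nm=diameter_nm, sd_d_nm=0.0,
                           channels=channels, rate_per_nm=rate_per_nm,
                           seed=seed, positions_nm=positions)


def ramp_drift(n_slices: int, total_dx_px: float, total_dy_px: float) -> DriftTrace:
    """Linear drift ramp from (0, 0) at slice 0 to the given total offset."""
    t = np.linspace(0.0, 1.0, n_slices)
    return DriftTrace(np.column_stack([t * total_dx_px, t * total_dy_px]))


def _disc_image(geom: AcquisitionGeometry, cx_nm: float, cy_nm: float,
                radius_nm: float, amplitude: float) -> np.ndarray:
    ss = _SUPERSAMPLE
    xs = (np.arange(geom.n_pixels_x * ss) + 0.5) * (geom.dx_nm / ss)
    ys = (np.arange(geom.n_pixels_y * ss) + 0.5) * (geom.dy_nm / ss)
    xx, yy = np.meshgrid(xs - cx_nm, ys - cy_nm)
    inside = (xx * xx + yy * yy <= radius_nm * radius_nm).astype(float)
    cover = inside.reshape(geom.n_pixels_y, ss, geom.n_pixels_x, ss).mean(axis=(1, 3))
    return amplitude * cover


def apply_drift(stack: IonStack, trace: DriftTrace,
                add_fiducial_um: float | None = None,
                fiducial_amplitude: float = 50.0,
                fiducial_label: str = "55Fe",
                interpolation_order: int = 1) -> IonStack:
    """Shift every slice by its (dx, dy) offset, optionally injecting a
    bright fiducial bead disc into a dedicated channel first.

    Sub-pixel shifts use spline interpolation; results are clipped at 0.
    """
    if len(trace) != stack.n_slices:
        raise ValueError(f"trace length {len(trace)} != n_slices {stack.n_slices}")
    g = stack.geometry
    if np.any(np.abs(trace.offsets[:, 0]) >= g.n_pixels_x) or \
       np.any(np.abs(trace.offsets[:, 1]) >= g.n_pixels_y):
        raise ValueError("drift shift exceeds the field size")
    counts = stack.counts.copy()
    labels = list(stack.channel_labels)
    if add_fiducial_um is not None:
        r_nm = add_fiducial_um * 1000.0 / 2.0
        disc = _disc_image(g, g.field_x_nm * 0.25, g.field_y_nm * 0.25,
                           r_nm, fiducial_amplitude)
        fid = np.broadcast_to(disc, (stack.n_slices, *disc.shape)).copy()
        counts = np.concatenate([counts, fid[:, None]], axis=1)
        labels = labels + [fiducial_label]
    out = np.empty_like(counts)
    for z in range(counts.shape[0]):
        dx, dy = trace.offsets[z]
        for c in range(counts.shape[1]):
            # ndimage.shift convention: shift along (row, col) = (dy, dx)
            out[z, c] = ndimage.shift(counts[z, c], shift=(dy, dx),
                                      order=interpolation_order, mode="constant",
                                      cval=0.0)
    out = np.clip(out, 0.0, None)
    result = IonStack(counts=out, channel_labels=labels, geometry=g,
                      provenance=list(stack.provenance), seed=stack.seed)
    result.log(f"apply_drift(max_offset={np.abs(trace.offsets).max():.3f}px, "
               f"fiducial={add_fiducial_um})")
    return result
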
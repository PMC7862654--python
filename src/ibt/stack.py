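"""Ion-stack data model, acquisition geometry, and TIFF + sidecar I/O.

Axis convention (used by every module in this package): ion-count cubes are
4D arrays indexed ``(slice z, channel c, row y, col x)``, 0-based.  Pixel
coordinates are pixel-center: the physical position of pixel ``(i, j)`` is
``((j + 0.5) * dx, (i + 0.5) * dy)`` in nm from the top-left field corner.

On disk a stack is one multi-page grayscale TIFF per mass channel plus a
JSON sidecar carrying the acquisition geometry, channel labels and seed.
Pixel size is kept unrounded internally; integer-nm rounding happens only
at display time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "AcquisitionGeometry",
    "IonStack",
    "GeometryError",
    "StackFormatError",
    "pixel_size_nm",
    "read_stack",
    "write_stack",
]


class GeometryError(ValueError):
    """Invalid acquisition geometry (non-positive extent or pixel count)."""


class StackFormatError(ValueError):
    """Malformed on-disk stack (shape mismatch, missing metadata)."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical scan geometry of an ion-beam depth series.

    Parameters
    ----------
    scan_area_x_um, scan_area_y_um
        Physical scan extent in µm.
    n_pixels_x, n_pixels_y
        Raster dimensions (number of pixel columns / rows).
    beam_width_nm
        Nominal lateral ion-beam width Δw (FWHM-like figure of merit used
        for the Nyquist check).
    z_step_nm
        Nominal etch depth removed per raster scan.
    beam_current_pA
        Recorded primary-ion current; drives the blind-PSF width.
    dwell_ms
        Dwell time per pixel.
    """

    scan_area_x_um: float
    scan_area_y_um: float
    n_pixels_x: int
    n_pixels_y: int
    beam_width_nm: float = 100.0
    z_step_nm: float = 5.0
    beam_current_pA: float = 1.0
    dwell_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.scan_area_x_um <= 0 or self.scan_area_y_um <= 0:
            raise GeometryError("scan areas must be strictly positive")
        if int(self.n_pixels_x) <= 0 or int(self.n_pixels_y) <= 0:
            raise GeometryError("pixel counts must be strictly positive")
        if self.beam_width_nm <= 0 or self.z_step_nm <= 0:
            raise GeometryError("beam width and z step must be positive")

    @property
    def dx_nm(self) -> float:
        """Pixel size along x in nm: 1000 * scan_area_x_um / n_pixels_x."""
        return 1000.0 * self.scan_area_x_um / self.n_pixels_x

    @property
    def dy_nm(self) -> float:
        return 1000.0 * self.scan_area_y_um / self.n_pixels_y

    @property
    def nyquist_ok(self) -> bool:
        """True iff both pixel sizes are at or below the beam width."""
        return self.dx_nm <= self.beam_width_nm and self.dy_nm <= self.beam_width_nm

    @property
    def field_x_nm(self) -> float:
        return 1000.0 * self.scan_area_x_um

    @property
    def field_y_nm(self) -> float:
        return 1000.0 * self.scan_area_y_um

    def with_pixels(self, n_pixels_x: int, n_pixels_y: int) -> "AcquisitionGeometry":
        return dataclasses.replace(self, n_pixels_x=n_pixels_x, n_pixels_y=n_pixels_y)

    def to_dict(self) -> dict:
        return {
            "scan_area_um": [self.scan_area_x_um, self.scan_area_y_um],
            "n_pixels": [self.n_pixels_x, self.n_pixels_y],
            "beam_width_nm": self.beam_width_nm,
            "z_step_nm": self.z_step_nm,
            "beam_current_pA": self.beam_current_pA,
            "dwell_ms": self.dwell_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        required = {"scan_area_um", "n_pixels", "beam_width_nm", "z_step_nm",
                    "beam_current_pA", "dwell_ms"}
        missing = required - set(d)
        if missing:
            raise StackFormatError(f"sidecar geometry missing fields: {sorted(missing)}")
        ax, ay = d["scan_area_um"]
        nx, ny = d["n_pixels"]
        return cls(scan_area_x_um=ax, scan_area_y_um=ay,
                   n_pixels_x=int(nx), n_pixels_y=int(ny),
                   beam_width_nm=d["beam_width_nm"], z_step_nm=d["z_step_nm"],
                   beam_current_pA=d["beam_current_pA"], dwell_ms=d["dwell_ms"])


def pixel_size_nm(geometry: AcquisitionGeometry) -> tuple[float, float, bool]:
    """Pixel sizes (Δx, Δy) in nm and the Nyquist predicate Δ ≤ Δw_beam.

    Example: a 20 µm scan rastered at 256 pixels gives 78.125 nm internally
    (displayed as 78 nm at integer precision), which satisfies the sampling
    rule for a 100 nm beam.
    """
    return geometry.dx_nm, geometry.dy_nm, geometry.nyquist_ok


@dataclass
class IonStack:
    """A 4D ion-count data cube with its acquisition geometry.

    ``counts`` is indexed (z, channel, y, x) and must be non-negative;
    all channels share one geometry.  ``provenance`` is an append-only log
    of the operations applied to reach this stack.
    """

    counts: np.ndarray
    channel_labels: list[str]
    geometry: AcquisitionGeometry
    provenance: list[str] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 4:
            raise StackFormatError(
                f"counts must be 4D (z, channel, y, x); got {self.counts.ndim}D")
        if self.counts.shape[0] < 1:
            raise StackFormatError("stack needs at least one slice")
        if np.any(self.counts < 0):
            raise StackFormatError("ion counts must be non-negative")
        if len(self.channel_labels) != self.counts.shape[1]:
            raise StackFormatError("channel_labels length must match channel axis")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise StackFormatError("channel labels must be unique")
        gz, gc, gy, gx = self.counts.shape
        if (gy, gx) != (self.geometry.n_pixels_y, self.geometry.n_pixels_x):
            raise StackFormatError(
                f"counts plane {gy}x{gx} does not match geometry "
                f"{self.geometry.n_pixels_y}x{self.geometry.n_pixels_x}")

    @property
    def n_slices(self) -> int:
        return self.counts.shape[0]

    @property
    def n_channels(self) -> int:
        return self.counts.shape[1]

    def channel(self, label: str) -> np.ndarray:
        """The (z, y, x) sub-cube for one mass channel."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.channel_labels}")
        return self.counts[:, idx]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def replace_counts(self, counts: np.ndarray, note: str,
                       geometry: AcquisitionGeometry | None = None) -> "IonStack":
        """New stack with the same metadata, updated counts and provenance."""
        out = IonStack(counts=counts, channel_labels=list(self.channel_labels),
                       geometry=geometry or self.geometry,
                       provenance=list(self.provenance), seed=self.seed)
        out.log(note)
        return out


def _channel_path(directory: Path, label: str) -> Path:
    safe = label.replace("/", "_")
    return directory / f"channel_{safe}.tif"


def write_stack(stack: IonStack, directory: str | Path) -> dict[str, Path]:
    """Write one multi-page grayscale TIFF per channel plus a JSON sidecar.

    Integer count arrays are written as 16-bit unsigned (32-bit if the
    dynamic range requires it); float arrays as 32-bit float.  The
    write-then-read round trip is bit-exact for integer counts.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for c, label in enumerate(stack.channel_labels):
        data = stack.counts[:, c]
        if np.issubdtype(data.dtype, np.integer):
            dtype = np.uint16 if data.max(initial=0) <= np.iinfo(np.uint16).max else np.uint32
            pages = data.astype(dtype)
        else:
            pages = data.astype(np.float32)
        path = _channel_path(directory, label)
        tifffile.imwrite(path, pages, photometric="minisblack")
        paths[label] = path
    sidecar = {
        **stack.geometry.to_dict(),
        "channels": list(stack.channel_labels),
        "seed": stack.seed,
        "provenance": list(stack.provenance),
        "software": "ibt-0.1.0",
    }
    (directory / "stack.json").write_text(json.dumps(sidecar, indent=2))
    paths["__sidecar__"] = directory / "stack.json"
    return paths


def read_stack(directory: str | Path,
               geometry: AcquisitionGeometry | None = None) -> IonStack:
    """Read a per-channel TIFF directory written by :func:`write_stack`.

    The sidecar is required unless a geometry is passed explicitly; missing
    metadata raises rather than being silently defaulted.
    """
    directory = Path(directory)
    sidecar_path = directory / "stack.json"
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        geometry = AcquisitionGeometry.from_dict(sidecar)
        labels = list(sidecar["channels"])
        seed = sidecar.get("seed")
        provenance = list(sidecar.get("provenance", []))
    elif geometry is None:
        raise StackFormatError(
            f"no sidecar at {sidecar_path} and no geometry supplied")
    else:
        labels = sorted(p.stem.removeprefix("channel_")
                        for p in directory.glob("channel_*.tif"))
        seed = None
        provenance = []
    planes = []
    shape = None
    for label in labels:
        path = _channel_path(directory, label)
        if not path.exists():
            raise StackFormatError(f"missing channel file {path}")
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise StackFormatError(
                f"channel {label!r} shape {data.shape} != {shape}")
        planes.append(data)
    if not planes:
        raise StackFormatError(f"no channel TIFFs found in {directory}")
    counts = np.stack(planes, axis=1)
    return IonStack(counts=counts, channel_labels=labels, geometry=geometry,
                    provenance=provenance, seed=seed)
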
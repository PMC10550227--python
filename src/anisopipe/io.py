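"""Reading and writing polarized image stacks.

A polarized acquisition pairs the parallel (I_par) and perpendicular (I_perp)
emission channels pixel by pixel.  Stacks are stored as multi-page grayscale
TIFF with the channel pairs interleaved (or plane-separated), and a plain-text
JSON sidecar records which page is which, the stack axis (z or time), the
axis spacing and the pixel size.  Missing depth/time metadata is synthesized
as index * spacing; it is never inferred from filenames.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .errors import ConfigError

__all__ = [
    "PolarizedFrame",
    "PolarizedStack",
    "CalibrationPair",
    "StackLayout",
    "read_polarized_stack",
    "write_polarized_stack",
]

_AXIS_KINDS = ("z", "time")


@dataclass(frozen=True)
class PolarizedFrame:
    """One paired (I_par, I_perp) image with acquisition metadata.

    Intensities are detector counts and must be non-negative as acquired;
    background subtraction may clamp pixels to zero and flag them in
    ``excluded`` for removal from downstream masks.
    """

    parallel: np.ndarray
    perpendicular: np.ndarray
    depth_um: float | None = None
    time_s: float | None = None
    pixel_size_um: float = 1.0
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        par = np.asarray(self.parallel)
        perp = np.asarray(self.perpendicular)
        if par.ndim != 2 or perp.ndim != 2:
            raise ConfigError("polarized channels must be 2-D rasters")
        if par.shape != perp.shape:
            raise ConfigError(
                f"channel shape mismatch: {par.shape} vs {perp.shape}"
            )
        object.__setattr__(self, "parallel", par)
        object.__setattr__(self, "perpendicular", perp)
        if self.excluded is not None:
            excl = np.asarray(self.excluded, dtype=bool)
            if excl.shape != par.shape:
                raise ConfigError("excluded mask shape mismatch")
            object.__setattr__(self, "excluded", excl)
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.parallel.shape

    def replace(self, **kwargs) -> "PolarizedFrame":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class PolarizedStack:
    """Ordered polarized frames along a z (1 um default) or time (10 s) axis."""

    frames: tuple[PolarizedFrame, ...]
    axis_kind: str
    spacing: float

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise ConfigError("stack must contain at least one frame")
        if self.axis_kind not in _AXIS_KINDS:
            raise ConfigError(f"axis_kind must be one of {_AXIS_KINDS}")
        if self.spacing <= 0:
            raise ConfigError("spacing must be positive")
        shape = frames[0].shape
        px = frames[0].pixel_size_um
        for f in frames:
            if f.shape != shape:
                raise ConfigError("all frames must share the same shape")
            if f.pixel_size_um != px:
                raise ConfigError("all frames must share pixel_size_um")
        object.__setattr__(self, "frames", frames)
        coords = self.coords
        if len(coords) > 1 and not np.all(np.diff(coords) > 0):
            raise ConfigError("axis coordinate must be strictly increasing")

    @property
    def coords(self) -> np.ndarray:
        """Axis coordinate per frame (um for z, s for time)."""
        vals = []
        for i, f in enumerate(self.frames):
            c = f.depth_um if self.axis_kind == "z" else f.time_s
            vals.append(i * self.spacing if c is None else c)
        return np.asarray(vals, dtype=float)

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_arrays(
        cls,
        parallel: np.ndarray,
        perpendicular: np.ndarray,
        axis_kind: str = "z",
        spacing: float = 1.0,
        pixel_size_um: float = 1.0,
        coords: Sequence[float] | None = None,
    ) -> "PolarizedStack":
        """Assemble a stack from (n, H, W) channel arrays."""
        parallel = np.asarray(parallel)
        perpendicular = np.asarray(perpendicular)
        if parallel.shape != perpendicular.shape or parallel.ndim != 3:
            raise ConfigError("expected matching (n, H, W) channel arrays")
        n = parallel.shape[0]
        if coords is None:
            coords = [i * spacing for i in range(n)]
        frames = []
        for i in range(n):
            meta = {"depth_um": coords[i]} if axis_kind == "z" else {"time_s": coords[i]}
            frames.append(
                PolarizedFrame(
                    parallel[i], perpendicular[i], pixel_size_um=pixel_size_um, **meta
                )
            )
        return cls(tuple(frames), axis_kind, spacing)


@dataclass(frozen=True)
class CalibrationPair:
    """Isotropic-dye calibration images taken with and without a half-wave plate."""

    with_hwp: PolarizedFrame
    without_hwp: PolarizedFrame

    def __post_init__(self) -> None:
        if self.with_hwp.shape != self.without_hwp.shape:
            raise ConfigError("calibration frames must share a shape")


@dataclass
class StackLayout:
    """Descriptor mapping file pages onto polarized channel pairs.

    ``interleave='channel'``: pages alternate parallel/perpendicular per plane.
    ``interleave='plane'``: the first half of the pages is one channel, the
    second half the other.  ``parallel_first`` says which channel comes first
    in either dialect.
    """

    interleave: str = "channel"
    parallel_first: bool = True
    axis_kind: str = "z"
    spacing: float = 1.0
    pixel_size_um: float = 1.0
    coords: list[float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.interleave not in ("channel", "plane"):
            raise ConfigError("interleave must be 'channel' or 'plane'")
        if self.axis_kind not in _AXIS_KINDS:
            raise ConfigError(f"axis_kind must be one of {_AXIS_KINDS}")

    @classmethod
    def from_dict(cls, d: dict) -> "StackLayout":
        d = dict(d)
        if "axis" in d:  # tolerated alias
            d["axis_kind"] = d.pop("axis")
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigError(f"unknown layout keys: {sorted(unknown)}")
        return cls(**d)


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_polarized_stack(stack: PolarizedStack, path: str | Path) -> None:
    """Write a stack as interleaved multi-page TIFF plus a JSON sidecar.

    Integer data round-trips bit-exactly; simulated float data is stored as
    32-bit float (values preserved to that precision).
    """
    path = Path(path)
    pages = []
    for f in stack.frames:
        pages.append(f.parallel)
        pages.append(f.perpendicular)
    dtype = np.result_type(*[p.dtype for p in pages])
    if np.issubdtype(dtype, np.floating):
        dtype = np.float32
    data = np.stack([np.asarray(p, dtype=dtype) for p in pages])
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "interleave": "channel",
        "parallel_first": True,
        "axis_kind": stack.axis_kind,
        "spacing": stack.spacing,
        "pixel_size_um": stack.frames[0].pixel_size_um,
        "coords": stack.coords.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_polarized_stack(
    path: str | Path, layout: StackLayout | dict | None = None
) -> PolarizedStack:
    """Read a polarized stack written by :func:`write_polarized_stack`.

    The JSON sidecar next to the file is used when present; an explicit
    ``layout`` overrides it.  Without either, the file cannot be interpreted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout is None:
        sc = _sidecar_path(path)
        if not sc.exists():
            raise ConfigError(
                f"no layout given and no sidecar found at {sc}; "
                "channel semantics are ambiguous"
            )
        layout = StackLayout.from_dict(json.loads(sc.read_text()))
    elif isinstance(layout, dict):
        layout = StackLayout.from_dict(layout)

    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ConfigError(f"expected a stack of 2-D pages, got shape {data.shape}")
    n_pages = data.shape[0]
    if n_pages % 2:
        raise ConfigError(
            f"page count {n_pages} cannot be divided into channel pairs"
        )
    n = n_pages // 2
    if layout.interleave == "channel":
        first, second = data[0::2], data[1::2]
    else:
        first, second = data[:n], data[n:]
    par, perp = (first, second) if layout.parallel_first else (second, first)
    coords = layout.coords
    if coords is not None and len(coords) != n:
        raise ConfigError("layout coords length does not match frame count")
    return PolarizedStack.from_arrays(
        par,
        perp,
        axis_kind=layout.axis_kind,
        spacing=layout.spacing,
        pixel_size_um=layout.pixel_size_um,
        coords=coords,
    )
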
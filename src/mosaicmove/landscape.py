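"""Categorical land-cover rasters and a patchy synthetic landscape generator.

The study system is a fragmented savanna mosaic mapped as a single-band
30 m categorical raster with six land-use/land-cover (LULC) classes:
forest, savanna, wetland, *Eucalyptus* plantation, pasture and "mosaic of
uses" (undifferentiated agriculture).  Pasture is the dominant class and
serves as the baseline everywhere downstream.

Synthetic landscapes are produced by thresholding a smoothed Gaussian
random field at the quantiles of the requested class proportions, which
yields spatially contiguous patches with (near-)exact class shares and a
single knob for patch size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

#: Canonical class order used for covariate vectors, tie-breaks and codes.
#: Pasture is last so that non-baseline covariates are a simple prefix.
CLASS_ORDER: tuple[str, ...] = (
    "forest",
    "savanna",
    "wetland",
    "eucalyptus",
    "mosaic",
    "pasture",
)

#: Integer raster code for each class (1-based, in canonical order).
CLASS_CODES: dict[str, int] = {name: i + 1 for i, name in enumerate(CLASS_ORDER)}

BASELINE_CLASS = "pasture"


class ConfigurationError(ValueError):
    """Raised when user-supplied configuration violates a precondition."""


@dataclass
class LandscapeRaster:
    """Single-band categorical raster on a planar metric grid.

    Row 0 is the *bottom* row: cell (row, col) has its centre at
    ``(x0 + (col + .5) * cell_size, y0 + (row + .5) * cell_size)``.
    ASCII-grid I/O flips rows to match the north-up file convention.
    """

    grid: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    class_table: Mapping[int, str] = field(
        default_factory=lambda: {v: k for k, v in CLASS_CODES.items()}
    )

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ConfigurationError("raster grid must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        codes = set(np.unique(self.grid).tolist())
        unknown = codes - set(self.class_table)
        if unknown:
            raise ConfigurationError(f"grid contains codes without a class name: {unknown}")

    # -- geometry ---------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        x0, y0 = self.origin
        return (
            x0,
            y0,
            x0 + self.n_cols * self.cell_size,
            y0 + self.n_rows * self.cell_size,
        )

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x < xmax and ymin <= y < ymax

    def class_at(self, x: float, y: float) -> str:
        """Class name of the cell containing planar point (x, y)."""
        x0, y0 = self.origin
        col = int((x - x0) // self.cell_size)
        row = int((y - y0) // self.cell_size)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return self.class_table[int(self.grid[row, col])]

    def class_proportions(self) -> dict[str, float]:
        """Realized share of each class over the whole grid."""
        counts = np.bincount(self.grid.ravel(), minlength=max(self.class_table) + 1)
        total = self.grid.size
        return {
            name: counts[code] / total
            for code, name in sorted(self.class_table.items())
        }

    # -- I/O --------------------------------------------------------------

    def to_ascii_grid(self, path: str | Path, legend_path: str | Path | None = None) -> None:
        """Write an Arc/Info ASCII grid (north-up) plus optional JSON legend."""
        path = Path(path)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin[0]}\n"
            f"yllcorner {self.origin[1]}\n"
            f"cellsize {self.cell_size}\n"
            f"NODATA_value -9999\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, self.grid[::-1], fmt="%d")
        if legend_path is not None:
            Path(legend_path).write_text(
                json.dumps({str(k): v for k, v in self.class_table.items()}, indent=2)
            )

    @classmethod
    def from_ascii_grid(
        cls, path: str | Path, legend_path: str | Path | None = None
    ) -> "LandscapeRaster":
        path = Path(path)
        header: dict[str, float] = {}
        with path.open() as fh:
            for _ in range(6):
                pos = fh.tell()
                parts = fh.readline().split()
                if len(parts) == 2 and not parts[0].lstrip("-").isdigit():
                    header[parts[0].lower()] = float(parts[1])
                else:
                    fh.seek(pos)
                    break
            grid = np.loadtxt(fh, dtype=int)
        grid = np.atleast_2d(grid)[::-1]
        if legend_path is not None:
            raw = json.loads(Path(legend_path).read_text())
            table = {int(k): v for k, v in raw.items()}
        else:
            table = {v: k for k, v in CLASS_CODES.items()}
        return cls(
            grid=grid,
            cell_size=header.get("cellsize", 30.0),
            origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
            class_table=table,
        )


def generate_landscape(
    n_rows: int,
    n_cols: int,
    target_proportions: Mapping[str, float],
    patch_scale: float = 10.0,
    rng_seed: int | np.random.Generator = 0,
    cell_size: float = 30.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> LandscapeRaster:
    """Generate a patchy categorical landscape with given class proportions.

    A standard-normal white-noise field is smoothed with a Gaussian kernel of
    standard deviation ``patch_scale`` (in cells) and then sliced at the
    empirical quantiles that correspond to the cumulative target proportions,
    assigning classes in the order the mapping iterates.  Quantile slicing
    makes the realized shares exact up to ties, and the smoothing scale sets
    the typical patch diameter.

    Parameters
    ----------
    target_proportions
        class name -> fraction; must be non-negative and sum to 1 (1e-9).
    patch_scale
        Smoothing kernel sd in cells (>= 1 gives visible patches; values
        below 1 are accepted and give near-white-noise landscapes).
    """
    targets = dict(target_proportions)
    if any(v < 0 for v in targets.values()):
        raise ConfigurationError("target proportions must be non-negative")
    if abs(sum(targets.values()) - 1.0) > 1e-9:
        raise ConfigurationError(
            f"target proportions must sum to 1, got {sum(targets.values())!r}"
        )
    unknown = set(targets) - set(CLASS_CODES)
    if unknown:
        raise ConfigurationError(f"unknown class names: {sorted(unknown)}")

    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    fld = rng.standard_normal((n_rows, n_cols))
    if patch_scale > 0:
        fld = ndimage.gaussian_filter(fld, sigma=patch_scale, mode="wrap")

    # Slice the field at cumulative-proportion quantiles.
    order = np.argsort(fld, axis=None)
    n = fld.size
    grid = np.empty(n, dtype=int)
    cum = 0.0
    start = 0
    items = [(k, v) for k, v in targets.items() if v > 0]
    for i, (name, frac) in enumerate(items):
        cum += frac
        stop = n if i == len(items) - 1 else int(round(cum * n))
        grid[order[start:stop]] = CLASS_CODES[name]
        start = stop
    return LandscapeRaster(
        grid=grid.reshape(n_rows, n_cols),
        cell_size=cell_size,
        origin=origin,
    )
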
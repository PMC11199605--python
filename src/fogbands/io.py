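"""Field readers/writers and run configuration.

Numeric fields travel as CSV grids (full precision, diffable) with a JSON
sidecar carrying the grid metadata (spacings, boundary tags, shape); rasters
can also be written as 16-bit TIFF with the quantization scale recorded in
the sidecar.  Every CLI run writes its resolved configuration next to its
outputs so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .grids import Field2D


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_field(path, field: Field2D) -> Path:
    """Write a field as CSV (lossless) or 16-bit TIFF (quantized) + sidecar."""
    path = Path(path)
    meta = {
        "shape": list(field.values.shape),
        "dx": field.dx,
        "dy": field.dy,
        "bc_x": field.bc_x,
        "bc_y": field.bc_y,
        "format": path.suffix.lstrip("."),
    }
    if path.suffix == ".csv":
        np.savetxt(path, field.values, delimiter=",")
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        lo, hi = float(field.values.min()), float(field.values.max())
        scale = (hi - lo) / 65535.0 if hi > lo else 1.0
        quant = np.round((field.values - lo) / scale).astype(np.uint16)
        # transpose: x along image columns, y upward
        tifffile.imwrite(path, quant.T[::-1])
        meta.update({"offset": lo, "scale": scale})
    else:
        raise ValueError(f"unsupported field format: {path.suffix}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_field(path) -> Field2D:
    """Read a CSV/TIFF field written by :func:`write_field`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata {sidecar}")
    meta = json.loads(sidecar.read_text())
    if path.suffix == ".csv":
        values = np.loadtxt(path, delimiter=",")
        if values.ndim == 1:
            values = values[None, :]
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        quant = tifffile.imread(path).astype(float)
        values = quant[::-1].T * meta["scale"] + meta["offset"]
    else:
        raise ValueError(f"unsupported field format: {path.suffix}")
    if list(values.shape) != meta["shape"]:
        raise ValueError(
            f"shape {values.shape} does not match sidecar {tuple(meta['shape'])}"
        )
    return Field2D(values, dx=meta["dx"], dy=meta["dy"], bc_x=meta["bc_x"], bc_y=meta["bc_y"])


def write_png(path, field: Field2D) -> Path:
    """8-bit grayscale PNG render of a field (x along columns, y upward)."""
    import imageio.v3 as iio

    path = Path(path)
    v = field.values
    lo, hi = v.min(), v.max()
    img = np.zeros_like(v, dtype=np.uint8) if hi <= lo else (
        (255 * (v - lo) / (hi - lo)).astype(np.uint8)
    )
    iio.imwrite(path, img.T[::-1])
    return path


@dataclass
class RunConfig:
    """Resolved configuration of a CLI run; serializes losslessly to JSON."""

    subcommand: str
    parameters: dict = dc_field(default_factory=dict)
    grid: dict = dc_field(default_factory=dict)
    seed: int = 0
    outdir: str = "."
    snapshot_stride: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def write(self, outdir: Path | None = None) -> Path:
        d = Path(outdir if outdir is not None else self.outdir)
        d.mkdir(parents=True, exist_ok=True)
        p = d / "run_config.json"
        p.write_text(self.to_json())
        return p
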
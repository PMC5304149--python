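"""Readers and writers for decay cubes, results and contribution maps.

Conventions, used everywhere: pixel indexing is 0-based, row-major, origin
top-left; channel index 0 is the earliest time bin; lifetimes are exported in
ps and fractions as dimensionless values unless a field name says percent.

The internal container is a single HDF5 file holding the counts plus the
acquisition metadata as attributes, so a measurement travels as one artefact.
TIFF time-stacks (one page per time channel) are supported for exchange, with
the timing metadata in a JSON sidecar or supplied explicitly — a bare TIFF
carries no channel width and is refused rather than guessed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import tifffile

from . import __version__ as _software_version
from .errors import (
    AxisOrderError,
    CapabilityError,
    MissingMetadataError,
    UnknownFormatError,
)
from .geometry import PhasorFitResult
from .medf import MedfCubeResult
from .model import AcquisitionSettings, DecayCube

__all__ = [
    "read_cube",
    "write_cube",
    "write_results",
    "write_alpha_map",
]

_CUBE_SCHEMA = "flimphasor-cube-1"
_CONTAINER_SUFFIXES = {".h5", ".hdf5", ".flim"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def _settings_hash(settings: AcquisitionSettings) -> str:
    payload = json.dumps(asdict(settings), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in _CONTAINER_SUFFIXES:
        return "container"
    if suffix in _TIFF_SUFFIXES:
        return "tiff_stack"
    if suffix == ".sdt":
        return "sdt"
    raise UnknownFormatError(
        f"cannot infer a format from {path.name!r}; pass format= explicitly"
    )


def write_cube(cube: DecayCube, path, format: str = "auto") -> Path:
    """Write a cube as an HDF5 container or a TIFF time-stack + JSON sidecar."""
    path = Path(path)
    fmt = _detect_format(path) if format == "auto" else format
    meta = {
        "repetition_period_ps": cube.settings.repetition_period,
        "n_channels": cube.settings.n_channels,
        "channel_width_ps": cube.settings.channel_width,
        "schema": _CUBE_SCHEMA,
        "software_version": _software_version,
        "settings_hash": _settings_hash(cube.settings),
    }
    if cube.settings.excitation_wavelength is not None:
        meta["excitation_wavelength_nm"] = cube.settings.excitation_wavelength
    if fmt == "container":
        with h5py.File(path, "w") as fh:
            dset = fh.create_dataset("counts", data=cube.counts, compression="gzip")
            for key, value in meta.items():
                dset.attrs[key] = value
    elif fmt == "tiff_stack":
        # pages are time channels of (rows, cols), earliest channel first
        tifffile.imwrite(path, np.moveaxis(cube.counts, 2, 0).astype(np.uint32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    else:
        raise UnknownFormatError(f"cannot write format {fmt!r}")
    return path


def _settings_from_meta(meta: dict, source: str) -> AcquisitionSettings:
    required = ("repetition_period_ps", "n_channels", "channel_width_ps")
    missing = [key for key in required if key not in meta]
    if missing:
        raise MissingMetadataError(
            f"{source}: missing required timing metadata {missing}; "
            "supply settings= or a JSON sidecar with these fields"
        )
    return AcquisitionSettings(
        repetition_period=float(meta["repetition_period_ps"]),
        n_channels=int(meta["n_channels"]),
        channel_width=float(meta["channel_width_ps"]),
        excitation_wavelength=(
            float(meta["excitation_wavelength_nm"])
            if "excitation_wavelength_nm" in meta else None
        ),
    )


def read_cube(
    path,
    format: str = "auto",
    *,
    settings: AcquisitionSettings | None = None,
) -> DecayCube:
    """Read a decay cube.

    ``format`` is one of ``auto | container | tiff_stack | sdt``.  TIFF
    stacks need timing metadata from a sidecar JSON or the ``settings``
    argument.  The vendor ``sdt`` format is available only when the optional
    ``sdtfile`` dependency is installed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "container":
        with h5py.File(path, "r") as fh:
            if "counts" not in fh:
                raise UnknownFormatError(f"{path}: no 'counts' dataset")
            dset = fh["counts"]
            counts = dset[...]
            meta = dict(dset.attrs)
        acq = settings or _settings_from_meta(meta, str(path))
        return DecayCube(counts=counts, settings=acq)
    if fmt == "tiff_stack":
        stack = tifffile.imread(path)
        if stack.ndim != 3:
            raise AxisOrderError(
                f"{path}: expected a 3D time-stack, got ndim={stack.ndim}"
            )
        if settings is None:
            sidecar = path.with_suffix(path.suffix + ".json")
            if not sidecar.exists():
                raise MissingMetadataError(
                    f"{path}: TIFF carries no timing metadata "
                    "(repetition_period_ps, n_channels, channel_width_ps); "
                    "supply settings= or a JSON sidecar"
                )
            settings = _settings_from_meta(json.loads(sidecar.read_text()), str(path))
        n = settings.n_channels
        if stack.shape[0] == n and stack.shape[2] != n:
            counts = np.moveaxis(stack, 0, 2)
        elif stack.shape[2] == n and stack.shape[0] != n:
            counts = stack
        elif stack.shape[0] == n:  # both match: assume pages are channels
            counts = np.moveaxis(stack, 0, 2)
        else:
            raise AxisOrderError(
                f"{path}: no axis of shape {stack.shape} matches "
                f"n_channels={n}"
            )
        return DecayCube(counts=counts, settings=settings)
    if fmt == "sdt":
        try:
            import sdtfile  # noqa: F401
        except ImportError as exc:
            raise CapabilityError(
                "reading vendor .sdt files requires the optional 'sdtfile' "
                "package (pip install flimphasor[sdt])"
            ) from exc
        sdt = sdtfile.SdtFile(str(path))
        data = np.asarray(sdt.data[0])
        if data.ndim != 3:
            raise AxisOrderError(f"{path}: unexpected sdt data ndim={data.ndim}")
        if settings is None:
            times = np.asarray(sdt.times[0])
            width = float(times[1] - times[0]) * 1e12  # s -> ps
            settings = AcquisitionSettings(
                repetition_period=width * data.shape[-1],
                n_channels=data.shape[-1],
                channel_width=width,
            )
        return DecayCube(counts=data, settings=settings)
    raise UnknownFormatError(f"unsupported format {fmt!r}")


_RESULT_SCHEMA = "flimphasor-results-1"


def write_results(result, path, layout: str = "json") -> Path:
    """Serialise a :class:`PhasorFitResult` or :class:`MedfCubeResult`.

    JSON carries the full bundle (phasor) or the converged-pixel aggregate
    (MEDF); CSV is a one-row flat summary for phasor results and the
    per-pixel table (0-based row-major pixel coordinates) for MEDF results.
    """
    path = Path(path)
    if isinstance(result, PhasorFitResult):
        if layout == "json":
            payload = result.to_dict()
            payload["schema"] = _RESULT_SCHEMA
            path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        elif layout == "csv":
            header, row = result.to_csv_row()
            path.write_text(header + "\n" + row + "\n")
        else:
            raise UnknownFormatError(f"unknown layout {layout!r}")
    elif isinstance(result, MedfCubeResult):
        if layout == "json":
            payload = result.aggregate()
            payload["schema"] = _RESULT_SCHEMA
            path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        elif layout == "csv":
            result.dataframe().to_csv(path, index=False)
        else:
            raise UnknownFormatError(f"unknown layout {layout!r}")
    else:
        raise TypeError(f"cannot serialise {type(result).__name__}")
    return path


def write_alpha_map(
    alpha,
    tiff_path=None,
    png_path=None,
    *,
    vmin: float = 0.65,
    vmax: float = 0.80,
    cmap: str = "RdYlBu",
) -> None:
    """Export a short-lifetime contribution map.

    The 16-bit greyscale TIFF maps ``[vmin, vmax]`` linearly onto the full
    integer range; the 8-bit PNG applies a red-to-blue false-colour scale
    (defaults 65%-80%, the conventional display range for NADH alpha1 maps).
    NaN pixels (not fitted) render as 0 / black.
    """
    import imageio.v3 as iio
    from matplotlib import colormaps

    alpha = np.asarray(alpha, dtype=float)
    if vmax <= vmin:
        raise ValueError("vmax must exceed vmin")
    norm = np.clip((alpha - vmin) / (vmax - vmin), 0.0, 1.0)
    invalid = ~np.isfinite(norm)
    norm = np.where(invalid, 0.0, norm)
    if tiff_path is not None:
        tifffile.imwrite(
            Path(tiff_path), (norm * 65535).round().astype(np.uint16)
        )
    if png_path is not None:
        rgba = colormaps[cmap](norm)
        rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
        rgb[invalid] = 0
        iio.imwrite(Path(png_path), rgb)
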
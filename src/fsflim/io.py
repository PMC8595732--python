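"""HDF5 container read/write for FS-FLIM cubes, plus TIFF/JSON exports.

Layout (schema ``fsflim-cube-1``)::

    /counts            uint32, shape (rows, cols, n_channels, n_bins)
    /axes/spectral     attrs: n_channels, lambda_min, lambda_max
    /axes/time         attrs: n_bins, bin_width, t0_offset, laser_period
    /sensor            attrs: bit_depth, pde_peak, irf_fwhm
                       datasets: dark_count_rate, pde_curve (optional)
    /provenance        attrs: free-form string metadata

Round trips are lossless: counts and all metadata are reproduced bit-exactly.
Readers reject unknown schema versions and any file whose dataset extents
contradict the declared axes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .datamodel import FlimCube, SensorConfig, SpectralAxis, TimeAxis

__all__ = [
    "write_cube",
    "read_cube",
    "export_tiff",
    "write_json_sidecar",
    "write_lifetime_cube",
    "read_lifetime_cube",
    "FormatError",
]

SCHEMA_VERSION = "fsflim-cube-1"


class FormatError(ValueError):
    """Raised when a container file violates the schema or a cube invariant."""


def write_cube(cube: FlimCube, path: str | Path, sensor: SensorConfig | None = None) -> None:
    """Write a validated cube to an HDF5 container."""
    cube.validate()
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset(
            "counts",
            data=cube.counts.astype(np.uint32),
            chunks=_chunk_shape(cube.counts.shape),
            compression="gzip",
            compression_opts=1,
        )
        f.attrs["chained"] = bool(cube.chained)
        f.attrs["dwell_time_us"] = float(cube.dwell_time)

        g = f.create_group("axes/spectral")
        g.attrs["n_channels"] = cube.spectral_axis.n_channels
        g.attrs["lambda_min"] = cube.spectral_axis.lambda_min
        g.attrs["lambda_max"] = cube.spectral_axis.lambda_max

        g = f.create_group("axes/time")
        g.attrs["n_bins"] = cube.time_axis.n_bins
        g.attrs["bin_width"] = cube.time_axis.bin_width
        g.attrs["t0_offset"] = cube.time_axis.t0_offset
        g.attrs["laser_period"] = cube.time_axis.laser_period

        g = f.create_group("sensor")
        if sensor is not None:
            g.attrs["bit_depth"] = sensor.bit_depth
            g.attrs["pde_peak"] = sensor.pde_peak
            g.attrs["irf_fwhm"] = sensor.irf_fwhm
            g.create_dataset("dark_count_rate", data=np.asarray(sensor.dark_count_rate))
            if sensor.pde_curve is not None:
                g.create_dataset("pde_curve", data=np.asarray(sensor.pde_curve))

        g = f.create_group("provenance")
        for key, value in cube.provenance.items():
            g.attrs[str(key)] = str(value)


def read_cube(path: str | Path) -> FlimCube:
    """Read a cube, validating schema version, extents and count invariants.

    Raises
    ------
    FormatError
        Naming the failed invariant, on any schema or consistency violation.
    """
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise FormatError(
                f"unsupported schema version {version!r} (expected {SCHEMA_VERSION!r})"
            )
        if "counts" not in f:
            raise FormatError("missing /counts dataset")
        counts = f["counts"][()]

        try:
            sg = f["axes/spectral"].attrs
            tg = f["axes/time"].attrs
            spectral = SpectralAxis(
                n_channels=int(sg["n_channels"]),
                lambda_min=float(sg["lambda_min"]),
                lambda_max=float(sg["lambda_max"]),
            )
            time = TimeAxis(
                n_bins=int(tg["n_bins"]),
                bin_width=float(tg["bin_width"]),
                t0_offset=float(tg["t0_offset"]),
                laser_period=float(tg["laser_period"]),
            )
        except KeyError as exc:
            raise FormatError(f"missing axis metadata: {exc}") from exc

        provenance = {k: v for k, v in f["provenance"].attrs.items()} if "provenance" in f else {}
        chained = bool(f.attrs.get("chained", False))
        dwell = float(f.attrs.get("dwell_time_us", 500.0))

    if counts.shape[2] != spectral.n_channels:
        raise FormatError(
            f"spectral extent {counts.shape[2]} != declared n_channels "
            f"{spectral.n_channels}"
        )
    if counts.shape[3] != time.n_bins:
        raise FormatError(
            f"time extent {counts.shape[3]} != declared n_bins {time.n_bins}"
        )
    try:
        return FlimCube(
            counts=counts,
            spectral_axis=spectral,
            time_axis=time,
            chained=chained,
            dwell_time=dwell,
            provenance=provenance,
        )
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def export_tiff(cube: FlimCube, path: str | Path, channels: list[int] | None = None) -> None:
    """Lossless multi-page TIFF export: one page per (channel, time bin).

    ``channels`` restricts the export to selected spectral channels (all by
    default — beware: a full 512-channel cube makes a very large TIFF).
    """
    import tifffile

    if channels is None:
        channels = list(range(cube.spectral_axis.n_channels))
    pages = cube.counts[:, :, channels, :]  # (rows, cols, K, bins)
    stack = np.moveaxis(pages, (2, 3), (0, 1))  # (K, bins, rows, cols)
    tifffile.imwrite(
        path,
        stack.astype(np.uint32),
        photometric="minisblack",
        metadata={
            "axes": "CTYX",
            "channels_exported": channels,
            "schema_version": SCHEMA_VERSION,
        },
    )


def write_json_sidecar(cube: FlimCube, path: str | Path) -> None:
    """Metadata-only JSON summary for inspection without an HDF5 reader."""
    meta = {
        "schema_version": SCHEMA_VERSION,
        "shape": list(cube.shape),
        "chained": cube.chained,
        "dwell_time_us": cube.dwell_time,
        "spectral_axis": {
            "n_channels": cube.spectral_axis.n_channels,
            "lambda_min_nm": cube.spectral_axis.lambda_min,
            "lambda_max_nm": cube.spectral_axis.lambda_max,
        },
        "time_axis": {
            "n_bins": cube.time_axis.n_bins,
            "bin_width_ns": cube.time_axis.bin_width,
            "t0_offset_ns": cube.time_axis.t0_offset,
            "laser_period_ns": cube.time_axis.laser_period,
        },
        "total_counts": int(cube.counts.sum(dtype=np.uint64)),
        "provenance": {str(k): str(v) for k, v in cube.provenance.items()},
    }
    Path(path).write_text(json.dumps(meta, indent=2))


LIFETIME_SCHEMA_VERSION = "fsflim-lifetime-1"


def write_lifetime_cube(ltc, path: str | Path) -> None:
    """Write a fitted LifetimeCube (tau/intensity maps + policy) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = LIFETIME_SCHEMA_VERSION
        f.create_dataset("tau_map", data=ltc.tau_map, compression="gzip", compression_opts=1)
        f.create_dataset(
            "intensity_map", data=ltc.intensity_map, compression="gzip", compression_opts=1
        )
        if ltc.mask is not None:
            f.create_dataset("mask", data=ltc.mask.astype(np.uint8))
        g = f.create_group("policy")
        g.attrs["background_multiple"] = ltc.policy.background_multiple
        g.attrs["absolute_min_counts"] = ltc.policy.absolute_min_counts
        g.attrs["smoothing_width"] = ltc.policy.smoothing_width
        g.attrs["smoothing_mode"] = ltc.policy.smoothing_mode
        g.attrs["edge_channels"] = ltc.policy.edge_channels
        f.attrs["n_candidates"] = ltc.n_candidates
        f.attrs["n_attempted"] = ltc.n_attempted
        g = f.create_group("provenance")
        for key, value in ltc.provenance.items():
            g.attrs[str(key)] = str(value)


def read_lifetime_cube(path: str | Path):
    """Read a LifetimeCube written by :func:`write_lifetime_cube`."""
    from .lifetime import LifetimeCube, ThresholdPolicy

    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != LIFETIME_SCHEMA_VERSION:
            raise FormatError(
                f"unsupported schema version {version!r} "
                f"(expected {LIFETIME_SCHEMA_VERSION!r})"
            )
        g = f["policy"].attrs
        policy = ThresholdPolicy(
            background_multiple=float(g["background_multiple"]),
            absolute_min_counts=float(g["absolute_min_counts"]),
            smoothing_width=int(g["smoothing_width"]),
            smoothing_mode=str(g["smoothing_mode"]),
            edge_channels=int(g["edge_channels"]),
        )
        return LifetimeCube(
            tau_map=f["tau_map"][()],
            intensity_map=f["intensity_map"][()],
            policy=policy,
            mask=f["mask"][()].astype(bool) if "mask" in f else None,
            n_candidates=int(f.attrs.get("n_candidates", 0)),
            n_attempted=int(f.attrs.get("n_attempted", 0)),
            provenance={k: v for k, v in f["provenance"].attrs.items()},
        )


def _chunk_shape(shape: tuple[int, ...]) -> tuple[int, ...]:
    """Pixel-row chunks: full spectral/time extents, bounded row blocks."""
    rows, cols, k, b = shape
    return (min(rows, 16), min(cols, 256), k, b)
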
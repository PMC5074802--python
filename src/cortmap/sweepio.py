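"""HDF5 sweep container and image/annotation readers.

Layout (schema 1.0)::

    /                       attrs: schema_version, units_*, sampling_rate,
                            pixel_pitch, pia_offset, layer_boundaries
    /cells/<id>             attrs: cell_type, layer, conductance, soma_depth,
                            soma_lateral, slice_id, pair_id, grid_rows/cols
    /cells/<id>/sites/rRRcCC   dataset (reps, n) pA, attrs: stim_onset
    /pairs/<id>             attrs: layer, distance, step_onset, step_duration
    /pairs/<id>/pv/step_SSS    dataset (reps, n) mV
    /pairs/<id>/pyr/step_SSS   dataset (reps, n) pA

Datasets are written with ``track_times=False`` so identical content gives
bit-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .exceptions import SchemaError
from .hierarchy import DensityImage, LayerBands
from .paired import PairedRecording
from .scracm import CellRecording
from .trace import SweepTrace, stack_reps

__all__ = [
    "SCHEMA_VERSION",
    "write_container",
    "read_container",
    "read_image_with_bands",
]

SCHEMA_VERSION = "1.0"

_UNITS = {
    "units_current": "pA",
    "units_voltage": "mV",
    "units_time": "ms",
    "units_distance": "um",
}


def write_container(
    path: str | Path,
    recordings: list[CellRecording] | None = None,
    pairs: list[PairedRecording] | None = None,
    global_attrs: dict | None = None,
) -> None:
    """Write sCRACM recordings and/or paired recordings to one HDF5 file."""
    recordings = recordings or []
    pairs = pairs or []
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for key, value in _UNITS.items():
            f.attrs[key] = value
        for key, value in (global_attrs or {}).items():
            f.attrs[key] = value

        if recordings:
            cells = f.create_group("cells")
            for rec in recordings:
                g = cells.create_group(rec.cell_id)
                g.attrs["cell_type"] = rec.cell_type
                g.attrs["layer"] = rec.layer
                g.attrs["conductance"] = rec.conductance
                g.attrs["soma_depth"] = rec.soma_xy[0]
                g.attrs["soma_lateral"] = rec.soma_xy[1]
                g.attrs["slice_id"] = rec.slice_id
                g.attrs["pair_id"] = rec.pair_id if rec.pair_id is not None else ""
                g.attrs["grid_rows"] = rec.grid_shape[0]
                g.attrs["grid_cols"] = rec.grid_shape[1]
                g.attrs["pixel_pitch"] = rec.pixel_pitch
                g.attrs["pia_offset"] = rec.pia_offset
                sites = g.create_group("sites")
                for (r, c), reps in sorted(rec.sweeps.items()):
                    block = stack_reps(reps)
                    d = sites.create_dataset(
                        f"r{r:02d}c{c:02d}", data=block, track_times=False
                    )
                    d.attrs["stim_onset"] = reps[0].stim_onset
                    d.attrs["sampling_rate"] = reps[0].sampling_rate
                    vhold = reps[0].holding_potential
                    d.attrs["holding_potential"] = np.nan if vhold is None else vhold

        if pairs:
            pg = f.create_group("pairs")
            for pair in pairs:
                g = pg.create_group(pair.pair_id)
                g.attrs["layer"] = pair.layer
                g.attrs["distance"] = pair.distance
                g.attrs["step_onset"] = pair.step_onset
                g.attrs["step_duration"] = pair.step_duration
                g.attrs["sampling_rate"] = pair.sampling_rate
                g.attrs["steps"] = np.asarray(pair.steps, dtype=np.int64)
                gv = g.create_group("pv")
                gi = g.create_group("pyr")
                for step in pair.steps:
                    gv.create_dataset(
                        f"step_{step:03d}", data=pair.pv_traces[step], track_times=False
                    )
                    gi.create_dataset(
                        f"step_{step:03d}", data=pair.pyr_traces[step], track_times=False
                    )


def _check_header(f: h5py.File) -> None:
    if "schema_version" not in f.attrs:
        raise SchemaError("missing schema_version attribute")
    version = str(f.attrs["schema_version"])
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema version {version!r} (expected {SCHEMA_VERSION!r})"
        )
    for key in _UNITS:
        if key not in f.attrs:
            raise SchemaError(f"missing units attribute {key!r}")


def read_container(
    path: str | Path,
) -> tuple[list[CellRecording], list[PairedRecording], dict]:
    """Read a sweep container; returns (cells, pairs, global attrs)."""
    recordings: list[CellRecording] = []
    pairs: list[PairedRecording] = []
    with h5py.File(path, "r") as f:
        _check_header(f)
        attrs = {k: f.attrs[k] for k in f.attrs}

        for cell_id in sorted(f.get("cells", {})):
            g = f["cells"][cell_id]
            sweeps: dict[tuple[int, int], list[SweepTrace]] = {}
            for name in sorted(g["sites"]):
                d = g["sites"][name]
                r, c = int(name[1:3]), int(name[4:6])
                vhold = float(d.attrs["holding_potential"])
                block = d[()]
                sweeps[(r, c)] = [
                    SweepTrace(
                        samples=block[k],
                        sampling_rate=float(d.attrs["sampling_rate"]),
                        stim_onset=float(d.attrs["stim_onset"]),
                        holding_potential=None if np.isnan(vhold) else vhold,
                    )
                    for k in range(block.shape[0])
                ]
            pair_id = str(g.attrs["pair_id"]) or None
            recordings.append(
                CellRecording(
                    cell_id=cell_id,
                    cell_type=str(g.attrs["cell_type"]),
                    layer=str(g.attrs["layer"]),
                    conductance=float(g.attrs["conductance"]),
                    sweeps=sweeps,
                    soma_xy=(float(g.attrs["soma_depth"]), float(g.attrs["soma_lateral"])),
                    slice_id=str(g.attrs["slice_id"]),
                    pair_id=pair_id,
                    grid_shape=(int(g.attrs["grid_rows"]), int(g.attrs["grid_cols"])),
                    pixel_pitch=float(g.attrs["pixel_pitch"]),
                    pia_offset=float(g.attrs["pia_offset"]),
                )
            )

        for pair_id in sorted(f.get("pairs", {})):
            g = f["pairs"][pair_id]
            steps = tuple(int(s) for s in g.attrs["steps"])
            pairs.append(
                PairedRecording(
                    pair_id=pair_id,
                    pv_traces={s: g["pv"][f"step_{s:03d}"][()] for s in steps},
                    pyr_traces={s: g["pyr"][f"step_{s:03d}"][()] for s in steps},
                    steps=steps,
                    sampling_rate=float(g.attrs["sampling_rate"]),
                    step_onset=float(g.attrs["step_onset"]),
                    step_duration=float(g.attrs["step_duration"]),
                    layer=str(g.attrs["layer"]),
                    distance=float(g.attrs["distance"]),
                )
            )
    return recordings, pairs, attrs


def read_image_with_bands(
    image_path: str | Path, sidecar_path: str | Path | None = None
) -> tuple[DensityImage, LayerBands]:
    """Read a TIFF/PNG projection image and its JSON annotation sidecar.

    The sidecar (default: image path with a ``.json`` suffix) must provide
    ``pixel_size`` (um/px) and ``bands`` ({name: [upper, lower] um from
    pia}); ``source``/``target``/``slice_id`` labels are optional.
    """
    image_path = Path(image_path)
    sidecar_path = (
        Path(sidecar_path) if sidecar_path is not None else image_path.with_suffix(".json")
    )
    if not sidecar_path.exists():
        raise SchemaError(f"missing annotation sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("pixel_size", "bands"):
        if key not in meta:
            raise SchemaError(f"sidecar {sidecar_path} missing {key!r}")

    suffix = image_path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(image_path)
    else:
        import imageio.v3 as iio

        pixels = iio.imread(image_path)
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim == 3:  # collapse any colour channels
        pixels = pixels.mean(axis=-1)

    image = DensityImage(
        pixels=pixels,
        pixel_size=float(meta["pixel_size"]),
        slice_id=str(meta.get("slice_id", image_path.stem)),
        source_area=str(meta.get("source", "SRC")),
        target_area=str(meta.get("target", "TGT")),
    )
    bands = LayerBands({k: (float(v[0]), float(v[1])) for k, v in meta["bands"].items()})
    return image, bands
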
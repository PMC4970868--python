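"""Readers, writers and report generation.

Echo datasets are stored as an HDF5 array container with axes
[position, direction, repeat, mic, sample] plus a JSON sidecar recording the
device specification, direction grid, sampling design and seeds.  Template
sets round-trip through CSV (one row per template: position_index,
direction_index, az, el, v0..v96) with a JSON provenance header file.
Angles are degrees, distances metres, times seconds; direction indices are
0-based, elevation-major then azimuth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .catchment import CatchmentSummary, TradeoffReport
from .classification import ClassificationResult
from .scene import DeviceSpec, DirectionGrid, EchoTrain, SamplingDesign
from .templates import Template, TemplateSet

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Container and sidecar are inconsistent or malformed."""


def _spec_to_dict(spec: DeviceSpec) -> dict:
    return {
        "call_sweep_hz": list(spec.call_sweep),
        "call_duration_s": spec.call_duration,
        "record_duration_s": spec.record_duration,
        "sample_rate": spec.sample_rate,
        "n_mics": spec.n_mics,
        "mic_offsets_m": spec.mic_offsets.tolist(),
        "n_repeats": spec.n_repeats,
        "beam_width_3db_deg": spec.beam_width_3db,
        "beam_ref_freq_hz": spec.beam_ref_freq,
        "self_noise_level": spec.self_noise_level,
        "speed_of_sound_m_s": spec.speed_of_sound,
        "grid": {
            "azimuths_deg": spec.grid.azimuths.tolist(),
            "elevations_deg": spec.grid.elevations.tolist(),
        },
    }


def _spec_from_dict(d: dict) -> DeviceSpec:
    return DeviceSpec(
        call_sweep=tuple(d["call_sweep_hz"]),
        call_duration=d["call_duration_s"],
        record_duration=d["record_duration_s"],
        sample_rate=d["sample_rate"],
        n_mics=d["n_mics"],
        mic_offsets=np.asarray(d["mic_offsets_m"]),
        grid=DirectionGrid(
            azimuths=np.asarray(d["grid"]["azimuths_deg"]),
            elevations=np.asarray(d["grid"]["elevations_deg"]),
        ),
        n_repeats=d["n_repeats"],
        beam_width_3db=d["beam_width_3db_deg"],
        beam_ref_freq=d["beam_ref_freq_hz"],
        self_noise_level=d["self_noise_level"],
        speed_of_sound=d["speed_of_sound_m_s"],
    )


def write_echo_dataset(
    path: str | Path,
    echo_trains: Iterable[EchoTrain],
    spec: DeviceSpec,
    design: SamplingDesign,
    seed: int = 0,
) -> Path:
    """Write a dataset to ``<path>.h5`` plus a ``<path>.json`` sidecar."""
    path = Path(path)
    h5_path = path.with_suffix(".h5")
    shape = (
        design.n_positions,
        spec.grid.n_directions,
        spec.n_repeats,
        spec.n_mics,
        spec.n_samples,
    )
    with h5py.File(h5_path, "w") as f:
        dset = f.create_dataset("echo_trains", shape=shape, dtype="f8")
        for tr in echo_trains:
            dset[
                tr.position_index, tr.direction_index, tr.repeat_index, tr.mic_index
            ] = tr.waveform
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "axes": ["position", "direction", "repeat", "mic", "sample"],
        "device_spec": _spec_to_dict(spec),
        "design": {
            "design_name": design.design_name,
            "poses_m": design.poses.tolist(),
            "spacing_m": design.spacing,
        },
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return h5_path


def read_echo_dataset(path: str | Path):
    """Read a dataset container; returns (echo_trains, spec, design, seed).

    Round-trips with :func:`write_echo_dataset`; a sidecar/container mismatch
    raises :class:`FormatError` naming the offending axis.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    spec = _spec_from_dict(meta["device_spec"])
    d = meta["design"]
    design = SamplingDesign(
        poses=np.asarray(d["poses_m"]),
        design_name=d["design_name"],
        spacing=d["spacing_m"],
    )
    with h5py.File(path.with_suffix(".h5"), "r") as f:
        data = f["echo_trains"][...]
    expected = (
        design.n_positions,
        spec.grid.n_directions,
        spec.n_repeats,
        spec.n_mics,
        spec.n_samples,
    )
    names = ("position", "direction", "repeat", "mic", "sample")
    for name, got, want in zip(names, data.shape, expected):
        if got != want:
            raise FormatError(
                f"axis {name!r}: container has {got}, sidecar implies {want}"
            )
    trains = [
        EchoTrain(
            waveform=data[p, di, r, m].astype(float),
            sample_rate=spec.sample_rate,
            position_index=p,
            direction_index=di,
            mic_index=m,
            repeat_index=r,
        )
        for p in range(expected[0])
        for di in range(expected[1])
        for r in range(expected[2])
        for m in range(expected[3])
    ]
    return trains, spec, design, meta["seed"]


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


def write_templates_csv(path: str | Path, tset: TemplateSet, provenance: dict | None = None) -> Path:
    path = Path(path)
    dirs = tset.directions()
    n_v = tset.matrix.shape[1]
    df = pd.DataFrame(
        {
            "position_index": tset.position_indices,
            "direction_index": tset.direction_indices,
            "az": dirs[:, 0],
            "el": dirs[:, 1],
        }
    )
    for k in range(n_v):
        df[f"v{k}"] = tset.matrix[:, k]
    # %.17g round-trips float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")
    header = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "grid": {
            "azimuths_deg": tset.grid.azimuths.tolist(),
            "elevations_deg": tset.grid.elevations.tolist(),
        },
        "design": None
        if tset.design is None
        else {
            "design_name": tset.design.design_name,
            "poses_m": tset.design.poses.tolist(),
            "spacing_m": tset.design.spacing,
        },
        "provenance": provenance or {},
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return path


def read_templates_csv(path: str | Path) -> TemplateSet:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = DirectionGrid(
        azimuths=np.asarray(meta["grid"]["azimuths_deg"]),
        elevations=np.asarray(meta["grid"]["elevations_deg"]),
    )
    design = None
    if meta["design"] is not None:
        d = meta["design"]
        design = SamplingDesign(
            poses=np.asarray(d["poses_m"]),
            design_name=d["design_name"],
            spacing=d["spacing_m"],
        )
    vcols = [c for c in df.columns if c.startswith("v")]
    templates = [
        Template(
            row[vcols].to_numpy(dtype=float),
            position_index=int(row["position_index"]),
            direction_index=int(row["direction_index"]),
        )
        for _, row in df.iterrows()
    ]
    return TemplateSet(templates, grid, design)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_classification_tsv(
    path: str | Path, tset: TemplateSet, result: ClassificationResult
) -> Path:
    path = Path(path)
    dirs = tset.directions()
    pd.DataFrame(
        {
            "template": np.arange(len(tset)),
            "position_index": tset.position_indices,
            "az": dirs[:, 0],
            "el": dirs[:, 1],
            "pc": result.pc,
            "angular_error_deg": result.angular_error,
            "n_draws": result.n_draws,
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def write_catchment_tsv(
    path: str | Path, grid: DirectionGrid, summary: CatchmentSummary,
    direction_indices: np.ndarray | None = None,
) -> Path:
    path = Path(path)
    d_idx = (
        np.arange(len(summary.per_direction_median))
        if direction_indices is None
        else np.asarray(direction_indices)
    )
    dirs = grid.directions[d_idx]
    pd.DataFrame(
        {
            "direction_index": d_idx,
            "az": dirs[:, 0],
            "el": dirs[:, 1],
            "median_catchment_m": summary.per_direction_median,
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def write_report(outdir: str | Path, results: dict, config_snapshot: dict, seed: int) -> Path:
    """Write the TSV/JSON report bundle and its run manifest.

    ``results`` may contain any of: ("templates", TemplateSet),
    ("classification", ClassificationResult), ("catchment",
    (grid, CatchmentSummary, direction_indices)), ("tradeoff",
    TradeoffReport).  Missing sections are flagged explicitly in the
    manifest rather than silently skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inventory: dict[str, str] = {}
    flags: dict[str, str] = {}

    def _register(p: Path):
        inventory[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    tset = results.get("templates")
    if tset is not None:
        _register(write_templates_csv(outdir / "templates.csv", tset))
        _register(outdir / "templates.json")
    cls = results.get("classification")
    if cls is not None and tset is not None:
        _register(write_classification_tsv(outdir / "classification.tsv", tset, cls))
    else:
        flags["classification"] = "no classification results"
    catch = results.get("catchment")
    if catch is not None:
        grid, summary, d_idx = catch
        _register(write_catchment_tsv(outdir / "catchment.tsv", grid, summary, d_idx))
    else:
        flags["catchment"] = "no transect data"
        (outdir / "catchment.tsv").write_text(
            "direction_index\taz\tel\tmedian_catchment_m\n"
        )
        _register(outdir / "catchment.tsv")
    trade = results.get("tradeoff")
    if trade is not None:
        (outdir / "tradeoff.json").write_text(json.dumps(asdict(trade), indent=1))
        _register(outdir / "tradeoff.json")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": seed,
        "config": config_snapshot,
        "flags": flags,
        "files": inventory,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath
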
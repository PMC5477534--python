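"""File formats and run configuration.

One canonical CSV dialect (comma, header row, UTF-8) is used for all
tables.  Molecule records: ``molecule_id, looped, rnap_bp, laci_near,
laci_far, template``.  Traces: ``time_s, extension_um``.  Bead stacks
are multi-page TIFF; lookup tables are single-file ``.npz`` containers
holding the z grid, the binning descriptor, and the profiles.  Every
analysis can write a provenance block (config hash, seed, versions)
beside its results so a run is reproducible from its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import ValidationError
from .sfm import MoleculeRecord
from .templates import TemplateMap
from .tracking import LookupTable
from .traces import ExtensionTrace

__all__ = [
    "write_records",
    "read_records",
    "write_trace",
    "read_trace",
    "write_stack",
    "read_stack",
    "write_lut",
    "read_lut",
    "load_config",
    "save_config",
    "provenance",
]

_RECORD_COLUMNS = ["molecule_id", "looped", "rnap_bp", "laci_near", "laci_far", "template"]


def write_records(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write molecule records to CSV in the canonical column order."""
    rows = []
    for r in records:
        laci = sorted(r.laci_positions)
        rows.append(
            {
                "molecule_id": r.molecule_id,
                "looped": r.looped,
                "rnap_bp": r.rnap_bp,
                "laci_near": laci[0] if laci else np.nan,
                "laci_far": laci[1] if len(laci) > 1 else np.nan,
                "template": r.template.name if r.template is not None else "",
            }
        )
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(path, index=False)


def read_records(path: str | Path, template: TemplateMap | None = None) -> list[MoleculeRecord]:
    """Read molecule records; missing/extra columns are reported by name."""
    df = pd.read_csv(path)
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"records file {path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        laci = [float(row[c]) for c in ("laci_near", "laci_far") if pd.notna(row[c])]
        records.append(
            MoleculeRecord(
                molecule_id=str(row["molecule_id"]),
                rnap_bp=None if pd.isna(row["rnap_bp"]) else float(row["rnap_bp"]),
                laci_positions=laci,
                looped=bool(row["looped"]),
                template=template,
            )
        )
    return records


def write_trace(trace: ExtensionTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "extension_um": trace.extension}).to_csv(
        path, index=False
    )


def read_trace(path: str | Path, bead_id: str = "") -> ExtensionTrace:
    """Read a trace CSV; non-uniform timestamps are rejected with the
    first offending row index."""
    df = pd.read_csv(path)
    for col in ("time_s", "extension_um"):
        if col not in df.columns:
            raise ValidationError(f"trace file {path}: missing column {col!r}")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValidationError(f"trace file {path}: needs at least 2 samples")
    dt = np.diff(t)
    bad = ~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-9)
    if dt[0] <= 0 or bad.any():
        idx = int(np.argmax(bad)) + 1 if bad.any() else 1
        raise ValidationError(f"trace file {path}: non-uniform timestamp at row {idx}")
    return ExtensionTrace(
        time=t,
        extension=df["extension_um"].to_numpy(float),
        sample_rate=1.0 / dt[0],
        bead_id=bead_id or Path(path).stem,
        history=[f"read_trace({Path(path).name})"],
    )


def write_stack(frames: list[np.ndarray], path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32), photometric="minisblack")


def read_stack(path: str | Path) -> list[np.ndarray]:
    """Read a multi-page TIFF; malformed pages are rejected with their
    page index."""
    try:
        with tifffile.TiffFile(path) as tif:
            frames = []
            for i, page in enumerate(tif.pages):
                try:
                    frames.append(np.asarray(page.asarray(), dtype=float))
                except Exception as err:
                    raise ValidationError(f"stack {path}: malformed TIFF page {i}: {err}") from err
    except tifffile.TiffFileError as err:
        raise ValidationError(f"stack {path}: not a readable TIFF: {err}") from err
    if not frames:
        raise ValidationError(f"stack {path}: contains no pages")
    return frames


def write_lut(lut: LookupTable, path: str | Path) -> None:
    np.savez(path, z_values=lut.z_values, profiles=lut.profiles, bin_width=lut.bin_width)


def read_lut(path: str | Path) -> LookupTable:
    with np.load(path) as data:
        return LookupTable(
            z_values=data["z_values"],
            profiles=data["profiles"],
            bin_width=float(data["bin_width"]),
        )


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration as a plain dict."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path}: top level must be a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def provenance(config: dict, seed: int | None = None) -> dict:
    """Machine-readable provenance block for a result directory."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
    }
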
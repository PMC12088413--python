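"""Standard-format I/O: OME-TIFF stacks with JSON sidecars, CSV tables,
YAML/JSON configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .stack import CHANNELS, Stack3C

__all__ = ["write_stack", "read_stack", "read_stacks", "write_table", "read_table",
           "load_config"]


def write_stack(stack: Stack3C, path, truth: dict | None = None) -> Path:
    """Write a stack as OME-TIFF (CZYX) with voxel sizes, plus a JSON sidecar.

    The sidecar carries the voxel size, labels and (optionally) the cell's
    ground truth; embedded OME pixel sizes are written as well.
    """
    path = Path(path)
    data = np.stack([getattr(stack, ch) for ch in CHANNELS]).astype(np.float32)
    vz, vy, vx = stack.voxel_size
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": vz,
            "PhysicalSizeY": vy,
            "PhysicalSizeX": vx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(CHANNELS)},
        },
    )
    sidecar = {
        "voxel_size_um": list(stack.voxel_size),
        "channels": list(CHANNELS),
        "cell_id": stack.cell_id,
        "plant_id": stack.plant_id,
        "genotype": stack.genotype,
    }
    if truth is not None:
        sidecar["truth"] = truth
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def _voxel_size_from_ome(tif) -> tuple[float, float, float] | None:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        return tuple(
            float(px.attrib[f"PhysicalSize{ax}"]) for ax in ("Z", "Y", "X")
        )
    except Exception:  # noqa: BLE001 - absent/partial metadata is expected
        return None


def read_stack(path, channel_order: tuple[str, ...] = CHANNELS) -> Stack3C:
    """Read one 3-channel OME-TIFF; sidecar JSON voxel sizes take precedence.

    A missing voxel size is an error, never a silent default.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        vs_embedded = _voxel_size_from_ome(tif) if tif.is_ome else None
    if data.ndim != 4 or data.shape[0] != 3:
        raise ValueError(
            f"{path.name}: expected 3 channels (CZYX), got shape {data.shape}"
        )
    sidecar = {}
    sc_path = path.with_suffix(".json")
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())
    voxel = sidecar.get("voxel_size_um") or vs_embedded
    if voxel is None:
        raise ValueError(f"{path.name}: voxel size missing from metadata and sidecar")
    chans = {name: data[i].astype(float) for i, name in enumerate(channel_order)}
    return Stack3C(
        hei10=chans["hei10"], asy1=chans["asy1"], zyp1=chans["zyp1"],
        voxel_size=tuple(voxel),
        cell_id=sidecar.get("cell_id", path.stem),
        plant_id=sidecar.get("plant_id", ""),
        genotype=sidecar.get("genotype", ""),
    )


def read_stacks(path, channel_order: tuple[str, ...] = CHANNELS) -> list[Stack3C]:
    """Read all OME-TIFF stacks in a directory (sorted by name)."""
    path = Path(path)
    files = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff")) + \
        sorted(path.glob("*.ome.tif"))
    if not files:
        raise ValueError(f"no TIFF stacks found under {path}")
    return [read_stack(f, channel_order) for f in dict.fromkeys(files)]


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
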
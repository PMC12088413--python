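"""Container for one imaged meiocyte: three 3D channels plus voxel sizes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Stack3C", "CHANNELS"]

CHANNELS = ("hei10", "asy1", "zyp1")


@dataclass
class Stack3C:
    """One 3-channel 3D image of a meiocyte.

    Channels: HEI10 (recombination foci), ASY1 (unsynapsed axis), ZYP1
    (synaptonemal-complex transverse filament). ``voxel_size`` is the
    physical voxel extent in µm as (z, y, x); anisotropy with z >= xy is
    typical of optical sectioning.
    """

    hei10: np.ndarray
    asy1: np.ndarray
    zyp1: np.ndarray
    voxel_size: tuple[float, float, float]
    cell_id: str = ""
    plant_id: str = ""
    genotype: str = ""

    def __post_init__(self):
        self.hei10 = np.asarray(self.hei10, dtype=float)
        self.asy1 = np.asarray(self.asy1, dtype=float)
        self.zyp1 = np.asarray(self.zyp1, dtype=float)
        if not (self.hei10.shape == self.asy1.shape == self.zyp1.shape):
            raise ValueError("channel shapes differ")
        if self.hei10.ndim != 3:
            raise ValueError("channels must be 3D (z, y, x)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive values (z, y, x)")
        for name in CHANNELS:
            ch = getattr(self, name)
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"non-finite intensities in channel {name!r}")
            if np.any(ch < 0):
                raise ValueError(f"negative intensities in channel {name!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hei10.shape

    def channels(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CHANNELS}
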
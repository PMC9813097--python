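"""Serial-section volume morphometry of Purkinje-cell somata and dendrites.

Volumes are approximated from labeled serial sections as area x slice
thickness summed over slices: each slice contributes (pixel count) x
(pixel size)^2 x thickness.  No overlap correction between adjacent slices
is applied -- the summation assumes each physical slice contributes its full
thickness.  The dendrite/soma volume ratio is the developmental readout of
disproportionate dendritic-tree growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
import yaml


@dataclass
class MaskStack:
    """Per-slice binary label masks with physical calibration.

    ``soma`` and ``dendrite`` are boolean arrays (slices, rows, cols);
    ``pixel_size_um`` is the in-plane sampling (um/pixel) and
    ``thickness_um`` the physical slice thickness (typically 10 or 30 um).
    """

    soma: np.ndarray
    dendrite: np.ndarray
    pixel_size_um: float
    thickness_um: float

    def __post_init__(self) -> None:
        self.soma = np.asarray(self.soma, dtype=bool)
        self.dendrite = np.asarray(self.dendrite, dtype=bool)
        if self.soma.ndim != 3 or self.dendrite.ndim != 3:
            raise ValueError("mask stacks must be 3-D (slices, rows, cols)")
        if self.soma.shape != self.dendrite.shape:
            raise ValueError("soma and dendrite stacks must have the same shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.thickness_um <= 0:
            raise ValueError("slice thickness must be positive")

    @property
    def n_slices(self) -> int:
        return self.soma.shape[0]


@dataclass(frozen=True)
class VolumeResult:
    soma_volume_um3: float
    dendrite_volume_um3: float
    ratio: float

    def to_dict(self) -> dict:
        return {
            "soma_volume_um3": self.soma_volume_um3,
            "dendrite_volume_um3": self.dendrite_volume_um3,
            "dendrite_soma_ratio": self.ratio,
        }


def stack_volume(stack: MaskStack, label: str) -> float:
    """Volume (um^3) of one label: sum over slices of area x thickness."""
    if label not in ("soma", "dendrite"):
        raise ValueError(f"unknown label {label!r}; expected 'soma' or 'dendrite'")
    masks = getattr(stack, label)
    area_per_slice = masks.sum(axis=(1, 2)) * stack.pixel_size_um**2
    return float(area_per_slice.sum() * stack.thickness_um)


def dendrite_soma_ratio(stack: MaskStack) -> VolumeResult:
    """Soma and dendrite volumes plus their ratio (dendrite / soma)."""
    soma = stack_volume(stack, "soma")
    dendrite = stack_volume(stack, "dendrite")
    if soma <= 0:
        raise ValueError("zero soma volume: ratio undefined")
    return VolumeResult(
        soma_volume_um3=soma,
        dendrite_volume_um3=dendrite,
        ratio=dendrite / soma,
    )


def write_mask_stack(stack: MaskStack, tiff_path, yaml_path) -> None:
    """Two-label 8-bit TIFF (soma=1, dendrite=2, overlap=3) + YAML metadata."""
    encoded = stack.soma.astype(np.uint8) + 2 * stack.dendrite.astype(np.uint8)
    tifffile.imwrite(tiff_path, encoded, photometric="minisblack")
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(
            {
                "pixel_size_um": float(stack.pixel_size_um),
                "thickness_um": float(stack.thickness_um),
            },
            fh,
        )


def read_mask_stack(tiff_path, yaml_path) -> MaskStack:
    encoded = tifffile.imread(tiff_path)
    if encoded.ndim == 2:
        encoded = encoded[None]
    with open(yaml_path) as fh:
        meta = yaml.safe_load(fh)
    return MaskStack(
        soma=(encoded & 1).astype(bool),
        dendrite=(encoded & 2).astype(bool),
        pixel_size_um=float(meta["pixel_size_um"]),
        thickness_um=float(meta["thickness_um"]),
    )
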
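"""Aligned random-crop augmentation for multimodal plot chips.

A fixed field-of-view window (the actual plot size, 176 × 25 pixels at 3 cm
for the full-scale trial) is sliced at random offsets from each training
plot's (slightly larger) chip.  Within one crop iteration the pixel offset
is identical across every modality so the streams keep seeing the same
ground region; augmentation applies to training plots only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import reference


@dataclass
class AugmentationSpec:
    window: tuple[int, int] = reference.CROP_WINDOW
    n_crops: int = 20
    train_only: bool = True

    def validate(self) -> None:
        if self.window[0] < 1 or self.window[1] < 1:
            raise ValueError("window must be at least 1x1")
        if self.n_crops < 0:
            raise ValueError("n_crops must be >= 0")


def crop_offsets(
    chip_shape: tuple[int, int], window: tuple[int, int], n_crops: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random (row, col) offsets; degenerate geometry forces offset 0."""
    max_r = chip_shape[0] - window[0]
    max_c = chip_shape[1] - window[1]
    if max_r < 0 or max_c < 0:
        raise ValueError(
            f"chip {chip_shape} smaller than the crop window {window}"
        )
    rows = rng.integers(0, max_r + 1, size=n_crops)
    cols = rng.integers(0, max_c + 1, size=n_crops)
    return np.column_stack([rows, cols])


def augment_crops(
    chipset: dict[str, np.ndarray],
    spec: AugmentationSpec,
    seed: int,
) -> tuple[list[dict[str, np.ndarray]], np.ndarray]:
    """Slice ``n_crops`` aligned windows from one plot's modality chips.

    ``chipset`` maps modality name to an array whose two leading axes are
    spatial (rows, cols); all modalities of one plot must share that spatial
    shape.  Returns the crops and the per-iteration offsets (identical across
    modalities by construction: one offset array drives every modality).
    """
    spec.validate()
    shapes = {name: arr.shape[:2] for name, arr in chipset.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"modality chips disagree on spatial shape: {shapes}")
    chip_shape = next(iter(shapes.values()))
    rng = np.random.default_rng(seed)
    offsets = crop_offsets(chip_shape, spec.window, spec.n_crops, rng)
    crops = []
    for r, c in offsets:
        crops.append(
            {
                name: arr[r : r + spec.window[0], c : c + spec.window[1]]
                for name, arr in chipset.items()
            }
        )
    return crops, offsets


def center_crop(chipset: dict[str, np.ndarray], window: tuple[int, int]) -> dict[str, np.ndarray]:
    """Deterministic centered window, used at prediction time."""
    out = {}
    for name, arr in chipset.items():
        r = (arr.shape[0] - window[0]) // 2
        c = (arr.shape[1] - window[1]) // 2
        if r < 0 or c < 0:
            raise ValueError(f"chip smaller than window for modality {name}")
        out[name] = arr[r : r + window[0], c : c + window[1]]
    return out
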
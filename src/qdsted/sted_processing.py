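"""STED - STEDonly subtraction and line-repeat accumulation.

A STED acquisition of a quantum dot contains, besides the super-resolved
central spot, a donut-shaped halo caused by direct excitation by the
depletion beam. Recording a second image with the depletion beam alone
(the "STEDonly" image) captures that halo on its own, and subtracting it
pixel-wise recovers the clean super-resolved image ("STEDsub").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .imaging_model import ScanConfig

__all__ = ["ImageStack", "accumulate_line_repeats", "compute_stedsub"]

#: canonical channel role labels
CHANNEL_ROLES = ("confocal", "STED", "STEDonly", "STEDsub")


@dataclass
class ImageStack:
    """Registered multi-channel image with per-channel role labels.

    ``channels`` maps a role label (``confocal``, ``STED``, ``STEDonly``,
    ``STEDsub``, or a dye channel name) to a 2D count array. All channels
    share one shape. ``line_repeat_stack`` optionally keeps the per-repeat
    3D array ``(repeat, row, col)`` for channels where it was retained.
    """

    channels: dict[str, np.ndarray]
    config: ScanConfig
    line_repeat_stack: dict[str, np.ndarray] = field(default_factory=dict)
    acquisition_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise InputError("ImageStack requires at least one channel")
        shapes = {name: np.asarray(img).shape for name, img in self.channels.items()}
        unique = set(shapes.values())
        if len(unique) != 1:
            raise InputError(f"channel shapes differ: {shapes}")
        shape = unique.pop()
        for name, stack in self.line_repeat_stack.items():
            stack = np.asarray(stack)
            if stack.ndim != 3 or stack.shape[1:] != shape:
                raise InputError(
                    f"line_repeat_stack[{name!r}] has shape {stack.shape}, "
                    f"expected (repeats, {shape[0]}, {shape[1]})"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def accumulate_line_repeats(line_repeat_stack: np.ndarray) -> np.ndarray:
    """Sum a ``(repeat, row, col)`` count stack over the repeat axis."""
    stack = np.asarray(line_repeat_stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise InputError(f"expected a non-empty (repeat, row, col) stack, got shape {stack.shape}")
    return stack.sum(axis=0)


def compute_stedsub(
    sted: np.ndarray,
    stedonly: np.ndarray,
    scale: float = 1.0,
    clip_negative: bool = False,
) -> np.ndarray:
    """Compute ``STEDsub = STED - scale * STEDonly``.

    ``scale`` defaults to 1 (both images acquired with identical settings);
    it compensates unequal dwell time or power between the two passes.
    Shot noise makes negative differences inevitable, so the default keeps
    the signed image — fits and statistics should run unclipped to avoid
    bias — while ``clip_negative=True`` floors at 0 for display and
    detection.
    """
    sted = np.asarray(sted, dtype=float)
    stedonly = np.asarray(stedonly, dtype=float)
    if sted.shape != stedonly.shape:
        raise InputError(f"shape mismatch: STED {sted.shape} vs STEDonly {stedonly.shape}")
    sub = sted - scale * stedonly
    if clip_negative:
        sub = np.clip(sub, 0.0, None)
    return sub
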
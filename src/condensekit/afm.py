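"""AFM height-map processing: plane leveling and median projection.

High-speed AFM captures several height-map frames per structure.  Two
corrections are applied before interpretation: subtraction of the
least-squares first-order plane (sample tilt), and a per-pixel median
projection across frames, which rejects transient artifacts affecting
fewer than half the frames.  Heights are in nm.  Optional per-scanline
median leveling (each row shifted to zero median) is available behind a
flag for maps with line-to-line offsets.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plane_level", "median_project", "level_and_project"]


def plane_level(frame: np.ndarray, line_level: bool = False) -> np.ndarray:
    """Subtract the least-squares first-order plane a·x + b·y + c.

    Idempotent: re-leveling a leveled frame is a no-op up to numerical
    precision.  With ``line_level`` each row's median is additionally
    subtracted after plane removal.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("expected a 2-D height map")
    rows, cols = frame.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    A = np.column_stack([xx.ravel(), yy.ravel(), np.ones(frame.size)])
    coef, *_ = np.linalg.lstsq(A, frame.ravel(), rcond=None)
    out = frame - (A @ coef).reshape(rows, cols)
    if line_level:
        out = out - np.median(out, axis=1, keepdims=True)
    return out


def median_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel median across frames (midpoint convention for even n).

    Permutation-invariant in frame order; exact outlier rejection when
    fewer than half the frames are corrupted (odd n, noise-free).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a (n_frames, rows, cols) stack with n_frames >= 1")
    return np.median(stack, axis=0)


def level_and_project(stack: np.ndarray, line_level: bool = False) -> np.ndarray:
    """Plane-level every frame, then median-project.

    Leveling precedes projection so that a drifting tilt cannot bias the
    median; a single-frame stack reduces to ``plane_level`` of that frame.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    leveled = np.stack([plane_level(f, line_level=line_level) for f in stack])
    return median_project(leveled)
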
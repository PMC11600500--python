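"""Per-nucleotide rigid frames and the frame algebra used by invariant point attention.

A frame ``T = (R, t)`` maps a point expressed in the nucleotide's local
coordinate system into the global one: ``x_global = R @ x_local + t``.
Frames are built from the P, C4' and glycosidic-N anchor atoms by the
Gram-Schmidt three-point construction, with all input coordinates scaled
by 0.1 so downstream point-distance terms operate in nm-like units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Scale applied to Angstrom coordinates before frame construction (and to
#: every 3D point entering the attention module).
COORD_SCALE = 0.1

_DEGENERACY_TOL = 1e-8


class DegenerateFrameError(ValueError):
    """Raised when the three anchor points are collinear or coincident."""


@dataclass(frozen=True)
class Frame:
    """Rigid transform: 3x3 rotation ``R`` and translation ``t`` (0.1-Angstrom units)."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))

    @staticmethod
    def identity() -> "Frame":
        return Frame(np.eye(3), np.zeros(3))


def rigid_from_three_points(x1, x2, x3, scale: float = COORD_SCALE) -> Frame:
    """Gram-Schmidt frame from three anchor points (P, C4', glycosidic N).

    ``x1``, ``x2``, ``x3`` are 3-vectors in Angstrom. The translation is
    assigned to the center atom ``x2``. Raises :class:`DegenerateFrameError`
    for collinear or coincident triples.
    """
    x1 = np.asarray(x1, dtype=float) * scale
    x2 = np.asarray(x2, dtype=float) * scale
    x3 = np.asarray(x3, dtype=float) * scale
    v1 = x3 - x2
    v2 = x1 - x2
    n1 = np.linalg.norm(v1)
    if n1 < _DEGENERACY_TOL:
        raise DegenerateFrameError("coincident anchor points x2, x3")
    e1 = v1 / n1
    u2 = v2 - np.dot(e1, v2) * e1
    n2 = np.linalg.norm(u2)
    if n2 < _DEGENERACY_TOL:
        raise DegenerateFrameError("collinear anchor points")
    e2 = u2 / n2
    e3 = np.cross(e1, e2)
    R = np.stack([e1, e2, e3], axis=1)
    return Frame(R, x2)


def apply_frame(T: Frame, x_local) -> np.ndarray:
    """Map local coordinates to global: ``R @ x + t`` (broadcasts over leading axes)."""
    x = np.asarray(x_local, dtype=float)
    return x @ T.R.T + T.t


def invert_frame(T: Frame) -> Frame:
    """Inverse transform ``(R^T, -R^T t)``."""
    Rt = T.R.T
    return Frame(Rt, -Rt @ T.t)


def compose_frames(A: Frame, B: Frame) -> Frame:
    """``(A o B)(x) = A(B(x))``."""
    return Frame(A.R @ B.R, A.R @ B.t + A.t)


def frames_from_structure(structure, scale: float = COORD_SCALE) -> list[Frame]:
    """One frame per nucleotide using the (P-or-fallback, C4', N) anchor triple.

    5'-terminal nucleotides often lack P: O5' substitutes as the first
    point, and if that is also absent the C4' position is used (the frame
    then degenerates and raises, which callers surface per-residue).
    """
    out = []
    for nt in structure.nucleotides:
        x1, x2, x3 = structure.anchor_triple(nt)
        if np.array_equal(x1, x2):
            out.append(_frame_from_two_points(x2, x3, scale))
        else:
            out.append(rigid_from_three_points(x1, x2, x3, scale=scale))
    return out


def _frame_from_two_points(x2, x3, scale: float) -> Frame:
    # anchor_triple fell back to C4' for x1: only the C4'->N direction is
    # defined, so complete the basis with the coordinate axis least aligned
    # with it (deterministic, but not equivariant — acceptable only for the
    # rare P-and-O5'-free 5' terminus).
    x2 = np.asarray(x2, dtype=float) * scale
    x3 = np.asarray(x3, dtype=float) * scale
    v1 = x3 - x2
    n1 = np.linalg.norm(v1)
    if n1 < _DEGENERACY_TOL:
        raise DegenerateFrameError("coincident anchor points x2, x3")
    e1 = v1 / n1
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(e1)))] = 1.0
    u2 = axis - np.dot(axis, e1) * e1
    e2 = u2 / np.linalg.norm(u2)
    e3 = np.cross(e1, e2)
    return Frame(np.stack([e1, e2, e3], axis=1), x2)


def stack_frames(frames: list[Frame]) -> tuple[np.ndarray, np.ndarray]:
    """Pack a list of frames into ``(L,3,3)`` rotations and ``(L,3)`` translations."""
    R = np.stack([f.R for f in frames])
    t = np.stack([f.t for f in frames])
    return R, t
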
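"""Built-in target morphologies and population initialization.

The target patterns stand in for the binary images used as morphogenetic
goals: a smiling face (two filled eye blocks, a one-cell-thick smile arc and a
small nose), a thumbs-up, and the face's sub-feature decomposition used by the
sequential-morphogenesis experiment (left eye only, right eye only, both eyes,
eyes and smile, complete face).  All patterns are procedural and deterministic
in ``(kind, N)``: feature positions are fixed fractions of the grid side, so
the same call always yields a byte-identical grid.

``scramble`` produces the random initial condition of every experiment: a
seeded uniform permutation of the target's cells, which preserves the per-type
cell counts exactly.
"""

from __future__ import annotations

import numpy as np

from .grid import Grid, TargetPattern

__all__ = ["PATTERN_KINDS", "SUBTARGET_SEQUENCE", "make_pattern", "scramble"]

#: Kinds accepted by :func:`make_pattern`.
PATTERN_KINDS = (
    "face",
    "thumbs_up",
    "left_eye",
    "right_eye",
    "eyes",
    "eyes_and_smile",
)

#: Default 5-stage sub-target sequence for sequential morphogenesis,
#: ending in the complete face.
SUBTARGET_SEQUENCE = ("left_eye", "right_eye", "eyes", "eyes_and_smile", "face")

#: 4-stage variant (no single-eye warm-up beyond the left eye).
SUBTARGET_SEQUENCE_4 = ("left_eye", "eyes", "eyes_and_smile", "face")


def _face_features(n: int) -> dict[str, list[tuple[int, int]]]:
    """Cell coordinates of each face feature on an ``n x n`` grid."""
    eye = max(1, round(n / 7.5))  # eye block side
    eye_top = round(0.28 * n)
    left = round(0.2 * n)
    right = n - left - eye  # mirror of the left block
    left_eye = [
        (r, c) for r in range(eye_top, eye_top + eye) for c in range(left, left + eye)
    ]
    right_eye = [
        (r, c) for r in range(eye_top, eye_top + eye) for c in range(right, right + eye)
    ]
    # Smile: one cell per column along the lower arc of an ellipse.
    c0 = round(0.23 * n)
    c1 = n - 1 - c0
    cc = (n - 1) / 2.0
    half_w = (c1 - c0) / 2.0
    smile = []
    for c in range(c0, c1 + 1):
        u = (c - cc) / half_w
        r = round(0.62 * n + 0.13 * n * (1.0 - u * u))
        smile.append((min(r, n - 1), c))
    # Nose: a small block at the grid center (keeps eyes+smile a proper
    # subset of the full face).
    half = max(1, n // 15)
    nr = round(0.47 * n)
    nc = round((n - half) / 2)
    nose = [(r, c) for r in range(nr, nr + half) for c in range(nc, nc + half)]
    return {
        "left_eye": left_eye,
        "right_eye": right_eye,
        "smile": smile,
        "nose": nose,
    }


_KIND_FEATURES = {
    "left_eye": ("left_eye",),
    "right_eye": ("right_eye",),
    "eyes": ("left_eye", "right_eye"),
    "eyes_and_smile": ("left_eye", "right_eye", "smile"),
    "face": ("left_eye", "right_eye", "smile", "nose"),
}


def _thumbs_up(n: int) -> np.ndarray:
    cells = np.zeros((n, n), dtype=np.uint8)
    # Fist: filled block in the lower-centre of the grid.
    r0, r1 = round(0.45 * n), round(0.80 * n)
    c0, c1 = round(0.30 * n), round(0.62 * n)
    cells[r0:r1, c0:c1] = 1
    # Thumb: vertical bar rising from the fist's right edge.
    t0 = round(0.18 * n)
    tw = max(1, round(0.10 * n))
    cells[t0:r0, c1 : c1 + tw] = 1
    return cells


def make_pattern(kind: str, n: int) -> TargetPattern:
    """Build the named target pattern on an ``n x n`` grid.

    Every sub-target equals the face with the omitted features replaced by
    background.  Raises ``ValueError`` for an unknown kind or ``n < 10``
    (features are not drawable below that).
    """
    if kind not in PATTERN_KINDS:
        raise ValueError(f"unknown pattern kind {kind!r}; expected one of {PATTERN_KINDS}")
    if n < 10:
        raise ValueError(f"grid side {n} too small to draw features (need N >= 10)")
    if kind == "thumbs_up":
        cells = _thumbs_up(n)
    else:
        feats = _face_features(n)
        cells = np.zeros((n, n), dtype=np.uint8)
        for name in _KIND_FEATURES[kind]:
            for r, c in feats[name]:
                cells[r, c] = 1
    return TargetPattern(f"{kind}{n}", Grid(cells))


def scramble(target: TargetPattern | Grid, seed: int) -> Grid:
    """Uniformly random permutation of the target's cells under ``seed``.

    Per-type cell counts equal the target's counts, so the scramble differs
    from the target only in cell placement.
    """
    cells = target.cells if isinstance(target, (TargetPattern, Grid)) else np.asarray(target)
    rng = np.random.default_rng(seed)
    flat = rng.permutation(cells.ravel())
    return Grid(flat.reshape(cells.shape))
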
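"""Pustell-style sliding-window dot-matrix comparison of two S regions.

Every window pair (i, j) whose ungapped (Hamming) identity reaches the
threshold is recorded, optionally in both direct and reverse-complement
orientation.  The brute-force window definition *is* the contract; at
switch-region scale (<= 10 kb) the O(|A|*|B|*w) cost is acceptable and the
computation is vectorized over the full window-pair grid.  Shared repeats
such as the AGCTGAGCTG units of Smu and sigma-delta appear as dotted
diagonals and are the substrate on which junctional microhomologies form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .junction_call import encode
from .refio import SRegionRef, write_tsv

ORIENT_DIRECT = "direct"
ORIENT_REVCOMP = "revcomp"

_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass(frozen=True)
class DotMatrix:
    seq_a_name: str
    seq_b_name: str
    window: int
    min_identity: float
    matches: tuple[tuple[int, int, float, str], ...]  # (a_start, b_start, identity, orientation)
    density: float  # matches per 1e6 window-pair comparisons


def _revcomp8(s8: np.ndarray) -> np.ndarray:
    out = s8[::-1].copy()
    for k, v in _COMPLEMENT.items():
        out[s8[::-1] == k] = v
    return out


def _window_identity(a8: np.ndarray, b8: np.ndarray, window: int) -> np.ndarray:
    """Identity count matrix over all window pairs: ident[i, j] = number of
    matching bases between a[i:i+w] and b[j:j+w]."""
    na = a8.size - window + 1
    nb = b8.size - window + 1
    ident = np.zeros((na, nb), dtype=np.int32)
    for k in range(window):
        ident += a8[k : k + na, None] == b8[None, k : k + nb]
    return ident


def compute_matrix(
    a: SRegionRef,
    b: SRegionRef,
    window: int = 8,
    min_identity: float = 0.75,
    orientations: Sequence[str] = (ORIENT_DIRECT, ORIENT_REVCOMP),
) -> DotMatrix:
    """All window pairs of ``a`` vs ``b`` with Hamming identity >=
    ``min_identity``.  Reverse-complement matches report the window start on
    the original (forward) ``b`` coordinates.  Density is normalized by
    (len(a)-w+1)*(len(b)-w+1) per orientation, in matches per 1e6 cells."""
    if window < 4:
        raise ValueError("window must be >= 4")
    if not 0.5 <= min_identity <= 1.0:
        raise ValueError("min_identity must lie in [0.5, 1]")
    if window > len(a) or window > len(b):
        raise ValueError("window longer than a sequence")
    for o in orientations:
        if o not in (ORIENT_DIRECT, ORIENT_REVCOMP):
            raise ValueError(f"unknown orientation {o!r}")

    a8, b8 = encode(a.sequence), encode(b.sequence)
    na = a8.size - window + 1
    nb = b8.size - window + 1
    threshold = min_identity * window - 1e-9
    matches: list[tuple[int, int, float, str]] = []

    if ORIENT_DIRECT in orientations:
        ident = _window_identity(a8, b8, window)
        for i, j in np.argwhere(ident >= threshold):
            matches.append((int(i), int(j), float(ident[i, j]) / window, ORIENT_DIRECT))
    if ORIENT_REVCOMP in orientations:
        brc = _revcomp8(b8)
        ident = _window_identity(a8, brc, window)
        for i, jr in np.argwhere(ident >= threshold):
            j = b8.size - window - int(jr)  # forward-strand window start
            matches.append((int(i), j, float(ident[i, jr]) / window, ORIENT_REVCOMP))

    matches.sort(key=lambda m: (m[0], m[1], m[3]))
    n_cells = na * nb * len(orientations)
    density = 1e6 * len(matches) / n_cells if n_cells else 0.0
    return DotMatrix(
        seq_a_name=a.name,
        seq_b_name=b.name,
        window=window,
        min_identity=min_identity,
        matches=tuple(matches),
        density=density,
    )


def matrix_frame(matrix: DotMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "a_start": [m[0] for m in matrix.matches],
            "b_start": [m[1] for m in matrix.matches],
            "identity": [m[2] for m in matrix.matches],
            "orientation": [m[3] for m in matrix.matches],
        }
    )


def export_coords(matrix: DotMatrix, path: str | Path) -> Path:
    """Write one row per match (deterministic order: a_start, then b_start)."""
    path = Path(path)
    write_tsv(matrix_frame(matrix), path)
    return path


def plot_matrix(matrix: DotMatrix, path: str | Path, len_a: int, len_b: int) -> Path:
    """Render the dot matrix as a greyscale PNG (intensity = identity)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for orient, marker in ((ORIENT_DIRECT, "."), (ORIENT_REVCOMP, "x")):
        pts = [(m[0], m[1], m[2]) for m in matrix.matches if m[3] == orient]
        if pts:
            xs, ys, ids = zip(*pts)
            ax.scatter(xs, ys, c=[1 - i for i in ids], cmap="gray", vmin=0, vmax=1,
                       s=4, marker=marker, label=orient)
    ax.set_xlim(0, len_a)
    ax.set_ylim(0, len_b)
    ax.invert_yaxis()
    ax.set_xlabel(matrix.seq_a_name)
    ax.set_ylabel(matrix.seq_b_name)
    ax.set_title(f"window={matrix.window}, min identity={matrix.min_identity}")
    ax.legend(loc="upper right", fontsize=7)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
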
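"""Sampling schedules: golden-angle radial spokes and complementary
cartesian row masks.

In multi-contrast spin-lock imaging the per-contrast images are highly
redundant, so each contrast should sample different k-space locations
("complementary" sampling).  Golden-angle radial acquisition is naturally
complementary — every new spoke takes a different path — while cartesian
row sampling is made complementary by drawing the non-centre rows without
replacement across contrasts.
"""

from __future__ import annotations

import numpy as np

from .containers import SamplingSchedule

__all__ = [
    "GOLDEN_ANGLE",
    "golden_angle_schedule",
    "radial_subsample",
    "cartesian_schedule",
    "nyquist_spoke_count",
]

# Angular increment between consecutive spokes (radians); the golden-ratio
# fraction of the half circle, 180/phi ~ 111.246 degrees.
GOLDEN_ANGLE = np.pi * (np.sqrt(5.0) - 1.0) / 2.0


def nyquist_spoke_count(matrix_size: int) -> int:
    """Spokes needed for full radial sampling of a square matrix (~N*pi/2)."""
    return int(round(matrix_size * np.pi / 2.0))


def golden_angle_angles(indices: np.ndarray) -> np.ndarray:
    """Spoke angles of the golden-angle sequence, folded to [0, pi)."""
    return (np.asarray(indices, dtype=float) * GOLDEN_ANGLE) % np.pi


def golden_angle_schedule(n_spokes: int, n_readout: int) -> SamplingSchedule:
    """Fully sampled golden-angle radial schedule (one block of all spokes).

    Spoke ``k`` lies at angle ``k * GOLDEN_ANGLE mod pi`` as a diametral
    line through the k-space centre; each spoke carries ``n_readout``
    samples spanning the full k-space extent symmetrically.
    """
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    if n_readout < 2:
        raise ValueError("n_readout must be >= 2")
    idx = np.arange(n_spokes)
    return SamplingSchedule(
        scheme="radial",
        matrix_size=n_readout,
        spoke_angles=[golden_angle_angles(idx)],
        spoke_indices=[idx],
        n_readout=n_readout,
    )


def radial_subsample(schedule: SamplingSchedule, af: float,
                     n_contrasts: int) -> SamplingSchedule:
    """Distribute golden-angle spokes over contrasts at an acceleration factor.

    ``spokes_per_contrast = round(n_total / af)`` where ``n_total`` is the
    full-sampling spoke count of the input schedule.  For ``af > 1``
    contrast ``c`` receives the consecutive golden-angle block
    ``[c * spc, (c + 1) * spc)`` — the sequence simply continues past
    ``n_total`` where needed, so blocks are always pairwise disjoint.
    ``af = 1`` gives every contrast the full spoke set.
    """
    if schedule.scheme != "radial":
        raise ValueError("radial_subsample requires a radial schedule")
    if af < 1:
        raise ValueError("acceleration factor must be >= 1")
    n_total = sum(len(b) for b in schedule.spoke_indices)
    if n_total < n_contrasts:
        raise ValueError("need at least one spoke per contrast")
    spc = int(round(n_total / af))
    if spc < 1:
        raise ValueError(
            f"AF {af} too high: fewer than one spoke per contrast")
    if af == 1:
        blocks = [np.arange(n_total) for _ in range(n_contrasts)]
    else:
        blocks = [np.arange(c * spc, (c + 1) * spc)
                  for c in range(n_contrasts)]
    return SamplingSchedule(
        scheme="radial",
        matrix_size=schedule.matrix_size,
        spoke_angles=[golden_angle_angles(b) for b in blocks],
        spoke_indices=blocks,
        n_readout=schedule.n_readout,
    )


def cartesian_schedule(matrix_size: int, af: float, n_contrasts: int,
                       seed: int = 0) -> SamplingSchedule:
    """Complementary cartesian row schedule with a fixed low-frequency block.

    Each contrast samples ``round(matrix_size / af)`` full k-space rows:
    a centred block of one quarter of them (always containing the
    zero-frequency row), the rest split evenly between the top and bottom
    parts.  Top/bottom rows are drawn in random order without replacement
    across contrasts, so every row is used once before any row repeats.
    """
    if af < 1:
        raise ValueError("acceleration factor must be >= 1")
    rows_per_contrast = int(round(matrix_size / af))
    if rows_per_contrast < 2:
        raise ValueError(f"AF {af} too high: fewer than two rows per contrast")
    n_centre = int(round(rows_per_contrast / 4))
    n_centre = max(n_centre, 1)
    centre_row = matrix_size // 2  # zero frequency in the centred DFT
    start = centre_row - n_centre // 2
    centre_block = np.arange(start, start + n_centre)
    n_rest = rows_per_contrast - n_centre
    # even top/bottom split; an odd row goes to the top part, whose pool is
    # at least as large as the bottom one
    n_top = (n_rest + 1) // 2
    n_bottom = n_rest - n_top

    top_pool = np.arange(0, start)
    bottom_pool = np.arange(start + n_centre, matrix_size)
    rng = np.random.default_rng(seed)

    def drawer(pool: np.ndarray):
        order: list[int] = []

        def draw(k: int) -> np.ndarray:
            nonlocal order
            if k > pool.size:
                raise ValueError("more rows requested than the pool holds")
            out: list[int] = []
            for _ in range(k):
                if not order:
                    # exhaustion: reshuffle, deferring rows already drawn for
                    # the current contrast so no contrast repeats a row
                    perm = list(rng.permutation(pool))
                    order = ([r for r in perm if r not in out]
                             + [r for r in perm if r in out])
                out.append(order.pop(0))
            return np.asarray(out, dtype=int)

        return draw

    draw_top, draw_bottom = drawer(top_pool), drawer(bottom_pool)
    rows = []
    for _ in range(n_contrasts):
        sel = np.concatenate([centre_block, draw_top(n_top),
                              draw_bottom(n_bottom)])
        rows.append(np.sort(np.unique(sel)))
        if rows[-1].size != rows_per_contrast:
            raise RuntimeError("row draw produced duplicates")  # pragma: no cover
    return SamplingSchedule(scheme="cartesian", matrix_size=matrix_size,
                            rows=rows, seed=seed)
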
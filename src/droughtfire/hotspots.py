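"""Processing of 1-km active-fire hotspot grids into analysis labels.

Hotspot products register single-pixel thermal anomalies that are often
geolocation noise; the analysis therefore drops any detection without a
companion detection in its 3x3 km neighborhood and pairs the surviving fire
pixels with an equal number of randomly drawn forest pixels that never burned
in the reference years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["LabelGrid", "filter_isolated", "sample_background"]


@dataclass(frozen=True)
class LabelGrid:
    """Binary fire/no-fire values on a 1-km lattice, with a forest mask."""

    values: np.ndarray  # uint8/bool, 1 = fire detection
    mask: np.ndarray  # bool, True = forested pixel
    year: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        mask = np.asarray(self.mask, dtype=bool)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        if values.shape != mask.shape:
            raise ValueError(
                f"values shape {values.shape} != mask shape {mask.shape}"
            )
        object.__setattr__(self, "values", values.astype(np.uint8))
        object.__setattr__(self, "mask", mask)

    @property
    def n_fire(self) -> int:
        return int(self.values.sum())


def filter_isolated(grid: LabelGrid) -> LabelGrid:
    """Drop fire pixels with no companion detection in their 3x3 km window.

    A fire pixel survives iff its centered 3x3 window (cropped at grid edges,
    itself included) contains at least two fire pixels.  Non-fire pixels are
    untouched and no fire pixel is ever created.  Note the operation is not
    idempotent: removing a pixel can isolate a former companion, so a second
    pass may remove more.
    """
    fire = grid.values.astype(np.uint8)
    neighbors = ndimage.convolve(fire, np.ones((3, 3), dtype=np.uint8), mode="constant", cval=0)
    survivors = (fire == 1) & (neighbors >= 2)
    return LabelGrid(values=survivors.astype(np.uint8), mask=grid.mask, year=grid.year)


def sample_background(
    grid: LabelGrid,
    n_fire: int,
    seed: int,
    exclude_years: list[LabelGrid] | None = None,
) -> pd.DataFrame:
    """Draw a balanced fire / fire-free sample from a hotspot grid.

    Takes ``n_fire`` fire pixels (all of them when ``n_fire`` equals the fire
    count, a uniform subsample otherwise) and an equal number of background
    pixels drawn uniformly without replacement from forested pixels that are
    fire-free in this grid and in every grid of ``exclude_years`` (the other
    reference years).  Reproducible for a fixed ``seed``.

    Returns a DataFrame with columns ``row, col, year, label`` (label 1 =
    fire).  Raises ``ValueError`` when either class has too few eligible
    pixels.
    """
    rng = np.random.default_rng(seed)
    fire_mask = grid.values == 1
    burnt_any = fire_mask.copy()
    for other in exclude_years or []:
        if other.values.shape != grid.values.shape:
            raise ValueError("exclude_years grids must share the grid shape")
        burnt_any |= other.values == 1

    fire_rc = np.argwhere(fire_mask)
    if n_fire > len(fire_rc):
        raise ValueError(f"requested {n_fire} fire pixels but only {len(fire_rc)} available")
    bg_rc = np.argwhere(grid.mask & ~burnt_any)
    if n_fire > len(bg_rc):
        raise ValueError(
            f"requested {n_fire} background pixels but only {len(bg_rc)} eligible"
        )

    fire_sel = fire_rc[rng.choice(len(fire_rc), size=n_fire, replace=False)]
    bg_sel = bg_rc[rng.choice(len(bg_rc), size=n_fire, replace=False)]
    frames = pd.DataFrame(
        {
            "row": np.concatenate([fire_sel[:, 0], bg_sel[:, 0]]),
            "col": np.concatenate([fire_sel[:, 1], bg_sel[:, 1]]),
            "year": grid.year,
            "label": np.concatenate([np.ones(n_fire, int), np.zeros(n_fire, int)]),
        }
    )
    return frames
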
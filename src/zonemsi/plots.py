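"""Minimal plotting helpers: ion images and zonal violin plots.

Requires matplotlib (optional dependency); imported lazily.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import FeatureMatrix


def ion_image(fm: FeatureMatrix, feature_index: int, mouse: str,
              grid_shape: tuple[int, int], ax=None):
    """Render one feature's intensity over the pixel grid of one mouse."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    img = np.full(grid_shape, np.nan)
    sel = fm.pixels["mouse"] == mouse
    rows = fm.pixels.loc[sel, "row"].to_numpy()
    cols = fm.pixels.loc[sel, "col"].to_numpy()
    img[rows, cols] = fm.values[sel.to_numpy(), feature_index]
    im = ax.imshow(img, interpolation="nearest")
    ax.set_title(f"m/z {fm.feature_mz[feature_index]:.4f} ({fm.mode})")
    ax.figure.colorbar(im, ax=ax, label="intensity")
    return ax


def zonal_violin(table: pd.DataFrame, lipid_id: str, ax=None):
    """Violin plot of one lipid's ROI median intensities per zone."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = table[table["lipid_id"] == lipid_id]
    if sub.empty:
        raise KeyError(f"lipid {lipid_id!r} not in zonal table")
    zones = ["Z1", "Z2", "Z3"]
    data = [sub.loc[sub["zone"] == z, "median_intensity"].to_numpy()
            for z in zones]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks([1, 2, 3], zones)
    ax.set_ylabel("ROI median intensity")
    ax.set_title(lipid_id)
    return ax
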
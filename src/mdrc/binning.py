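"""Manual binning of evaluated components in the D_iso-D_delta^2 plane.

The classical way to separate tissue water populations: rectangular "bins"
are drawn in the (D_iso, D_delta^2) space — an anisotropic low-diffusivity
bin (white-matter-like), an isotropic low-diffusivity bin (gray-matter-like)
and a fast isotropic bin (free-water-like) — and per voxel one reports the
signal fraction falling in each bin,

    f_bin = (1 / S0) * sum_{i in bin} w_i

and the weighted means of any parameter X over the bin,

    E_bin[X] = sum_{i in bin} w_i X_i / (S0 * f_bin).

The bin limits are a modeling choice, not printed constants; the defaults
below place the free-water threshold per experimental preset and split
tissue at D_delta^2 = 0.25, and every limit is overridable.
Intervals are half-open, [min, max), so shared edges are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: free-water D_iso threshold per experimental preset, m^2/s
FW_THRESHOLDS = {"exvivo_rat": 1.0e-9, "invivo_rat": 1.5e-9,
                 "invivo_human": 2.5e-9}


@dataclass(frozen=True)
class BinDefinition:
    """Rectangle in the (D_iso, D_delta^2) plane; half-open on both axes."""

    name: str
    d_iso_range: tuple[float, float]
    d_delta_sq_range: tuple[float, float] = (0.0, 1.0 + 1e-9)

    def __post_init__(self):
        if not (self.d_iso_range[0] < self.d_iso_range[1]
                and self.d_delta_sq_range[0] < self.d_delta_sq_range[1]):
            raise ValueError(f"bin {self.name!r}: ranges must be well-ordered")

    def contains(self, d_iso, d_delta_sq) -> np.ndarray:
        return ((d_iso >= self.d_iso_range[0])
                & (d_iso < self.d_iso_range[1])
                & (d_delta_sq >= self.d_delta_sq_range[0])
                & (d_delta_sq < self.d_delta_sq_range[1]))

    def overlaps(self, other: "BinDefinition") -> bool:
        a = (max(self.d_iso_range[0], other.d_iso_range[0])
             < min(self.d_iso_range[1], other.d_iso_range[1]))
        b = (max(self.d_delta_sq_range[0], other.d_delta_sq_range[0])
             < min(self.d_delta_sq_range[1], other.d_delta_sq_range[1]))
        return a and b


def default_bins(preset: str = "exvivo_rat", d_max: float = 5e-9,
                 fw_threshold: float | None = None) -> list[BinDefinition]:
    """Three-bin WM-like / GM-like / FW-like partition of the plane."""
    if fw_threshold is None:
        try:
            fw_threshold = FW_THRESHOLDS[preset]
        except KeyError:
            raise ValueError(f"unknown bin preset {preset!r}") from None
    return [
        BinDefinition("wm_like", (0.0, fw_threshold), (0.25, 1.0 + 1e-9)),
        BinDefinition("gm_like", (0.0, fw_threshold), (0.0, 0.25)),
        BinDefinition("fw_like", (fw_threshold, d_max * (1 + 1e-9))),
    ]


def assign_bins(df: pd.DataFrame, bins: list[BinDefinition]) -> pd.Series:
    """Per-component bin label (or None) by rectangle membership.

    ``df`` must carry ``D_iso`` and ``D_delta_sq`` columns.
    """
    for a in range(len(bins)):
        for b in range(a + 1, len(bins)):
            if bins[a].overlaps(bins[b]):
                raise ValueError(f"bins {bins[a].name!r} and {bins[b].name!r} "
                                 "overlap")
    labels = pd.Series([None] * len(df), index=df.index, dtype=object)
    for bn in bins:
        inside = bn.contains(df["D_iso"].to_numpy(),
                             df["D_delta_sq"].to_numpy())
        labels[inside] = bn.name
    return labels


def group_maps(df: pd.DataFrame, labels: pd.Series, group_names: list,
               shape: tuple[int, int, int],
               statistics: tuple = ("D_iso", "D_delta_sq", "R1", "R2",
                                    "delta_diso")) -> dict:
    """Per-voxel signal fractions and weighted means for arbitrary groups.

    Shared by binning and clustering: ``f = sum_in_group w / (n_solutions *
    S0)`` (the pooled-ensemble extension of the per-solution normalization)
    and ``E[X] = weighted mean of X within the group``; voxels where a group
    carries no weight get NaN means.

    Returns ``{"fractions": {name: 3D array}, "means": {(name, stat): 3D
    array}, "group_labels": [...]}``.
    """
    fractions = {g: np.zeros(shape) for g in group_names}
    means = {(g, s): np.full(shape, np.nan) for g in group_names
             for s in statistics}
    lab = np.asarray(labels, dtype=object)
    w = df["w"].to_numpy()
    denom_per_row = (df["n_solutions"] * df["S0"]).to_numpy()
    vox = df[["i", "j", "k"]].to_numpy()
    for g in group_names:
        in_g = lab == g
        if not in_g.any():
            continue
        sub = df.loc[in_g]
        key = [tuple(v) for v in vox[in_g]]
        grouped = sub.assign(_key=key).groupby("_key")
        for ix, chunk in grouped:
            wsum = chunk["w"].sum()
            denom = chunk["n_solutions"].iloc[0] * chunk["S0"].iloc[0]
            fractions[g][ix] = wsum / denom
            for s in statistics:
                means[(g, s)][ix] = float(
                    np.average(chunk[s], weights=chunk["w"]))
    return {"fractions": fractions, "means": means,
            "group_labels": list(group_names)}


def bin_maps(df: pd.DataFrame, bins: list[BinDefinition],
             shape: tuple[int, int, int], **kwargs) -> dict:
    """Bin-resolved fraction and mean maps over an evaluated-component
    table (as produced by :func:`mdrc.metrics.evaluate_collection`)."""
    labels = assign_bins(df, bins)
    return group_maps(df, labels, [b.name for b in bins], shape, **kwargs)
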
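"""Semiquantification of (ox)PCs against a deuterated internal standard.

Quant tables are pandas DataFrames with compounds as rows and samples as
columns.  Semiquantified values are dimensionless area ratios against
PC15:0/18:1-d7 (or any per-sample internal-standard areas), which makes
them invariant to per-sample instrument response.  Heat-map normalization
follows the metabolomics convention: log10 transform, then per-compound
autoscaling with the population standard deviation.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "QuantError",
    "internal_standard_mz",
    "semiquantify",
    "oxpc_fraction",
    "normalize_matrix",
    "apply_lod_floor",
]


class QuantError(ValueError):
    pass


def internal_standard_mz() -> float:
    """[M+H]+ of the PC15:0/18:1-d7 internal standard, from composition."""
    from .chem import AdductKind, adduct_mz, mass_of

    neutral = mass_of("C41H73D7NO8P")
    return adduct_mz(neutral, AdductKind.PROTONATED_POS).value


def semiquantify(
    areas: pd.DataFrame,
    is_area: Mapping[str, float] | pd.Series,
    tissue_weight: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-sample area ratio of each compound to the internal standard.

    ``tissue_weight`` optionally divides each sample by its wet weight
    (for tissue-level comparisons); it does not affect the ratio property.
    """
    is_area = pd.Series(dict(is_area), dtype=float)
    for sample in areas.columns:
        if sample not in is_area.index:
            raise QuantError(f"no internal-standard area for sample {sample!r}")
        if not is_area[sample] > 0:
            raise QuantError(f"internal-standard area must be > 0 in sample {sample!r}")
    if (areas.to_numpy() < 0).any():
        raise QuantError("negative peak areas")
    out = areas.div(is_area[areas.columns], axis=1)
    if tissue_weight is not None:
        w = pd.Series(dict(tissue_weight), dtype=float)
        missing = [s for s in areas.columns if s not in w.index]
        if missing:
            raise QuantError(f"no tissue weight for samples {missing}")
        out = out.div(w[areas.columns], axis=1)
    return out


def oxpc_fraction(oxpc_ratios: pd.DataFrame, pc_ratios: pd.DataFrame) -> pd.Series:
    """Percent of total PC signal carried by oxPCs, per sample.

    100 * sum(oxPC) / (sum(oxPC) + sum(PC)); compound sets must not overlap.
    """
    shared = set(oxpc_ratios.index) & set(pc_ratios.index)
    if shared:
        raise QuantError(f"compound sets overlap: {sorted(shared)[:5]}")
    samples = [s for s in oxpc_ratios.columns if s in pc_ratios.columns]
    if not samples:
        raise QuantError("no shared samples between tables")
    ox = oxpc_ratios[samples].sum(axis=0)
    pc = pc_ratios[samples].sum(axis=0)
    total = ox + pc
    if (total == 0).any():
        bad = total.index[total == 0].tolist()
        raise QuantError(f"both sums are zero in samples {bad}")
    return 100.0 * ox / total


def apply_lod_floor(table: pd.DataFrame, floor: float) -> pd.DataFrame:
    """Report values below the detection floor as missing (not zero)."""
    return table.where(table >= floor)


def normalize_matrix(table: pd.DataFrame, mode: str = "log10_autoscale") -> pd.DataFrame:
    """Per-compound log10 + autoscale: x -> (log10 x - mean) / sd.

    Uses the population standard deviation, so every output row has mean
    0 and sd 1 exactly.  Missing values are ignored in the row statistics.
    """
    if mode != "log10_autoscale":
        raise QuantError(f"unknown normalization mode {mode!r}")
    vals = table.to_numpy(dtype=float)
    bad = np.argwhere(~np.isnan(vals) & (vals <= 0))
    if bad.size:
        r, c = bad[0]
        raise QuantError(
            f"nonpositive value at compound {table.index[r]!r}, sample "
            f"{table.columns[c]!r}: {vals[r, c]}"
        )
    logged = np.log10(vals)
    mean = np.nanmean(logged, axis=1, keepdims=True)
    sd = np.nanstd(logged, axis=1, keepdims=True)  # population sd
    flat = np.where(sd[:, 0] == 0)[0]
    if flat.size:
        raise QuantError(f"constant row (sd = 0): {table.index[flat[0]]!r}")
    return pd.DataFrame((logged - mean) / sd, index=table.index, columns=table.columns)
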
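"""qPCR comparative-Ct quantification and absolute-deviation outlier filtering.

The comparative-Ct (2^-ddCt) method turns raw qPCR cycle thresholds into
fold changes: dCt = Ct(target) - Ct(normalizer) per sample, ddCt = dCt
minus the mean dCt of the reference group, relative quantity
RQ = 2^-ddCt.  Outliers are excluded once, outside center +/- k times the
absolute-deviation dispersion (default k = 3, mean-based, unscaled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["OutlierDecision", "ddct_relative_quantity", "mad_outlier_filter"]


def ddct_relative_quantity(
    table: pd.DataFrame,
    target: str,
    normalizer: str,
    reference_group: str,
    group_col: str = "group",
    sample_col: str = "sample_id",
) -> pd.DataFrame:
    """Per-sample relative quantity by the comparative-Ct (2^-ddCt) method.

    Parameters
    ----------
    table : wide Ct table with one row per sample and one column per assay
        (e.g. sample_id, group, miR-4504, RNU48).
    target, normalizer : assay column names (e.g. a miRNA and RNU48).
    reference_group : label in ``group_col`` whose mean dCt calibrates
        ddCt; its RQ values then have geometric mean exactly 1.

    Returns a copy of (sample, group) with ``delta_ct``, ``ddct`` and
    ``rq`` columns.
    """
    for col in (sample_col, group_col, target, normalizer):
        if col not in table.columns:
            raise ValueError(f"Ct table is missing column {col!r}")
    ct_t = pd.to_numeric(table[target], errors="raise")
    ct_n = pd.to_numeric(table[normalizer], errors="raise")
    if ct_t.isna().any() or ct_n.isna().any():
        bad = table.loc[ct_t.isna() | ct_n.isna(), sample_col].tolist()
        raise ValueError(f"missing Ct values for samples {bad}")
    if (ct_t <= 0).any() or (ct_n <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")

    ref_mask = table[group_col] == reference_group
    if not ref_mask.any():
        raise ValueError(f"reference group {reference_group!r} is empty")

    delta_ct = ct_t - ct_n
    ddct = delta_ct - delta_ct[ref_mask].mean()
    out = table[[sample_col, group_col]].copy()
    out["delta_ct"] = delta_ct
    out["ddct"] = ddct
    out["rq"] = np.exp2(-ddct)
    return out


@dataclass
class OutlierDecision:
    """Result of a single-pass +/- k*MAD exclusion."""

    kept: list[float]
    excluded: list[float]
    center: float
    mad: float
    k: float
    center_mode: str
    degenerate: bool = False

    @property
    def band(self) -> tuple[float, float]:
        return (self.center - self.k * self.mad, self.center + self.k * self.mad)


def mad_outlier_filter(
    values: Sequence[float],
    k: float = 3.0,
    center_mode: str = "mean",
) -> OutlierDecision:
    """Exclude values strictly outside center +/- k * absolute deviation.

    ``center_mode="mean"`` uses the mean and the *mean* absolute
    deviation; ``"median"`` uses the median and the *median* absolute
    deviation.  No robust scale constant is applied, and the pass is not
    iterated.  A zero dispersion (constant data) keeps everything and
    warns.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values to assess outliers")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if center_mode not in ("mean", "median"):
        raise ValueError("center_mode must be 'mean' or 'median'")
    if k <= 0:
        raise ValueError("k must be positive")

    if center_mode == "mean":
        center = float(np.mean(x))
        mad = float(np.mean(np.abs(x - center)))
    else:
        center = float(np.median(x))
        mad = float(np.median(np.abs(x - center)))

    if mad == 0.0:
        warnings.warn("zero absolute deviation; no outliers can be assessed", stacklevel=2)
        return OutlierDecision(
            kept=x.tolist(), excluded=[], center=center, mad=0.0,
            k=k, center_mode=center_mode, degenerate=True,
        )

    lo, hi = center - k * mad, center + k * mad
    outside = (x < lo) | (x > hi)
    return OutlierDecision(
        kept=x[~outside].tolist(),
        excluded=x[outside].tolist(),
        center=center,
        mad=mad,
        k=k,
        center_mode=center_mode,
    )
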
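"""Signature-compound screening by VIP + Gini score fusion.

The two importance measures — OPLS-DA VIP and random-forest Gini — are put
on a common [0, 1] scale by min-max normalization,

    x_nom = (x - min) / (max - min),

and averaged into the fused score X_A = (VIP_nom + Gini_nom) / 2. A
compound is a *signature* differential flavor component when both
VIP >= 1 (the raw VIP, on its own scale) and X_A > 0.5. The VIP cut is
inclusive, the X_A cut exclusive; screening always uses full precision,
2-decimal rounding is display-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FusionTable",
    "minmax_normalize",
    "compute_xa",
    "fuse_importances",
    "screen_signature",
]

VIP_CUT = 1.0
XA_CUT = 0.5


def minmax_normalize(values: pd.Series) -> pd.Series:
    """Affine map of a column onto [0, 1]: min -> 0, max -> 1.

    Order-preserving and idempotent; ties at the extremes all map to 0 or
    1. Raises on a degenerate (all-equal) column, where the map divides by
    zero.
    """
    values = pd.Series(values, dtype=float)
    if values.isna().any():
        raise ValueError("minmax_normalize: missing values in input")
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        raise ValueError("degenerate range: all values equal, min-max undefined")
    return (values - vmin) / (vmax - vmin)


def compute_xa(vip_nom: pd.Series, gini_nom: pd.Series) -> pd.Series:
    """Fused score: arithmetic mean of the two normalized columns."""
    a, b = set(vip_nom.index), set(gini_nom.index)
    if a != b:
        raise ValueError(
            "compound sets differ between VIP and Gini columns: "
            f"only-VIP={sorted(a - b)}, only-Gini={sorted(b - a)}"
        )
    return ((vip_nom + gini_nom.reindex(vip_nom.index)) / 2.0).rename("x_a")


@dataclass
class FusionTable:
    """Fused VIP/Gini record per compound.

    ``table`` columns: vip, gini, x_vnom, x_gnom, x_a, is_signature.
    """

    table: pd.DataFrame
    vip_cut: float = VIP_CUT
    xa_cut: float = XA_CUT

    @property
    def signature(self) -> list[str]:
        """Signature compounds sorted by descending X_A."""
        sub = self.table[self.table["is_signature"]]
        return list(sub.sort_values("x_a", ascending=False, kind="stable").index)

    def report(self, decimals: int = 2) -> pd.DataFrame:
        out = self.table.copy()
        out["x_a"] = out["x_a"].round(decimals)
        return out

    def to_csv(self, path, decimals: int = 2) -> None:
        self.report(decimals).to_csv(path)


def fuse_importances(
    vip: pd.Series,
    gini: pd.Series,
    vip_cut: float = VIP_CUT,
    xa_cut: float = XA_CUT,
) -> FusionTable:
    """Min-max normalize VIP and Gini, average into X_A, flag signatures."""
    vip = pd.Series(vip, dtype=float)
    gini = pd.Series(gini, dtype=float)
    vnom = minmax_normalize(vip)
    gnom = minmax_normalize(gini).reindex(vip.index)
    xa = compute_xa(vnom, gnom)
    tbl = pd.DataFrame(
        {
            "vip": vip,
            "gini": gini,
            "x_vnom": vnom,
            "x_gnom": gnom,
            "x_a": xa,
            "is_signature": (vip >= vip_cut) & (xa > xa_cut),
        }
    )
    tbl.index.name = "compound"
    return FusionTable(table=tbl, vip_cut=vip_cut, xa_cut=xa_cut)


def screen_signature(
    fused: FusionTable | pd.DataFrame,
    vip_cut: float = VIP_CUT,
    xa_cut: float = XA_CUT,
) -> list[str]:
    """Compounds with VIP >= vip_cut and X_A > xa_cut, sorted by X_A desc."""
    tbl = fused.table if isinstance(fused, FusionTable) else fused
    if tbl.empty:
        return []
    hits = tbl[(tbl["vip"] >= vip_cut) & (tbl["x_a"] > xa_cut)]
    return list(hits.sort_values("x_a", ascending=False, kind="stable").index)
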
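"""Packaged reference tables for the two-rose GC-MS study.

Three small tables ship with the package: the published mean ± SD relative
contents of the 61 VOCs detected in *Rosa sterilis* (RS) and *Rosa
roxburghii* (RR) fruit, the water odor thresholds and odor descriptors of
the 12 threshold-annotated compounds, and the published OPLS-DA VIP and
random-forest Gini importances of those 12 key flavor compounds.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .profile import CompoundRecord, GroupProfile, canonical_name
from .roav import ThresholdEntry

__all__ = [
    "load_relative_content",
    "load_group_profiles",
    "load_thresholds",
    "load_vip_gini",
]


def _data_path(name: str):
    return resources.files("flavoromics.data").joinpath(name)


def load_relative_content() -> pd.DataFrame:
    """The published VOC table: compound metadata plus per-group mean ± SD (%)."""
    with resources.as_file(_data_path("relative_content.csv")) as p:
        df = pd.read_csv(p)
    df["compound"] = df["compound"].map(canonical_name)
    return df.set_index("compound")


def load_group_profiles() -> dict[str, GroupProfile]:
    """The published contents as :class:`GroupProfile` objects, keyed RS / RR.

    Printed values are 2-decimal roundings of a 4-replicate mean, so group
    totals close to 100% only within ~0.05; closure is not re-validated here.
    """
    df = load_relative_content()
    compounds = {
        name: CompoundRecord(
            name=name,
            cas=str(row["cas"]),
            formula=str(row["formula"]),
            retention_time=float(row["retention_time_min"]),
            chem_class=str(row["chem_class"]),
        )
        for name, row in df.iterrows()
    }
    out: dict[str, GroupProfile] = {}
    for g in ("RS", "RR"):
        tbl = pd.DataFrame(
            {"mean": df[f"{g}_mean"], "sd": df[f"{g}_sd"], "n": 4}
        )
        out[g] = GroupProfile(group=g, table=tbl, compounds=compounds)
    return out


def load_thresholds() -> list[ThresholdEntry]:
    """Water odor thresholds (mg/kg) and descriptors for the 12 key compounds."""
    from .roav import read_thresholds

    with resources.as_file(_data_path("odor_thresholds.csv")) as p:
        return read_thresholds(p)


def load_vip_gini() -> pd.DataFrame:
    """Published VIP and Gini importances of the 12 key flavor compounds.

    Indexed by canonical compound name; columns ``vip``, ``gini`` and
    ``xa_printed`` (the published fused score, for cross-checks).
    """
    with resources.as_file(_data_path("vip_gini.csv")) as p:
        df = pd.read_csv(p)
    df["compound"] = df["compound"].map(canonical_name)
    return df.set_index("compound")
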
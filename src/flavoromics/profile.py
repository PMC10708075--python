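"""Peak-table data model, relative contents, and group-level VOC accounting.

A GC-MS volatile profile arrives as a replicate-level table of raw peak
areas (one row per injection, one column per identified compound). Relative
content is computed by area normalization: each compound's area as a
percentage of the total area in that injection. Group profiles summarize
replicates as mean ± SD relative content and support simple accounting —
Venn counts of detected compounds, chemical-class composition, and a
rule-based presence-pattern classification of each compound across the two
groups.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHEM_CLASSES",
    "CompoundRecord",
    "PeakTable",
    "GroupProfile",
    "VennCounts",
    "canonical_name",
    "compute_relative_content",
    "aggregate_group_profile",
    "venn_counts",
    "class_composition",
    "presence_pattern",
    "read_peak_table",
    "read_compound_metadata",
    "write_group_profiles",
]

#: The nine structural categories used to bin VOCs.
CHEM_CLASSES = (
    "alcohol",
    "ether",
    "aldehyde",
    "acid",
    "ester",
    "alkane",
    "terpenoid",
    "aromatic",
    "other",
)

VennCounts = namedtuple("VennCounts", "n_group1 n_group2 n_common n_union")


def canonical_name(name: str) -> str:
    """Canonicalize a compound name: trim, collapse whitespace, case-fold."""
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class CompoundRecord:
    """Identity of one volatile organic compound.

    ``name`` is stored canonicalized (trimmed, case-folded); ``chem_class``
    must be one of the nine categories in :data:`CHEM_CLASSES`.
    """

    name: str
    cas: str | None = None
    formula: str | None = None
    retention_time: float | None = None
    chem_class: str = "other"

    def __post_init__(self) -> None:
        cname = canonical_name(self.name)
        if not cname:
            raise ValueError("compound name must be non-empty")
        object.__setattr__(self, "name", cname)
        if self.chem_class not in CHEM_CLASSES:
            raise ValueError(
                f"chem_class {self.chem_class!r} for {cname!r} is not one of "
                f"{sorted(CHEM_CLASSES)}"
            )
        if self.retention_time is not None and not self.retention_time >= 0:
            raise ValueError(f"retention_time must be >= 0 for {cname!r}")


def _merge_records(a: CompoundRecord, b: CompoundRecord) -> CompoundRecord:
    """Merge two records with the same canonical name; conflicting CAS is an error."""
    if a.cas and b.cas and a.cas != b.cas:
        raise ValueError(
            f"CAS conflict for compound {a.name!r}: {a.cas} vs {b.cas}"
        )
    return CompoundRecord(
        name=a.name,
        cas=a.cas or b.cas,
        formula=a.formula or b.formula,
        retention_time=a.retention_time if a.retention_time is not None else b.retention_time,
        chem_class=a.chem_class if a.chem_class != "other" else b.chem_class,
    )


@dataclass
class PeakTable:
    """Replicate-level sample x compound raw peak areas with group labels.

    areas : DataFrame indexed by sample_id, columns = canonical compound names,
        finite non-negative raw peak areas (0 = compound absent from sample).
    groups : Series mapping sample_id -> group label, aligned with ``areas``.
    compounds : canonical name -> :class:`CompoundRecord` metadata.
    """

    areas: pd.DataFrame
    groups: pd.Series
    compounds: dict[str, CompoundRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.areas = self.areas.copy()
        self.areas.columns = [canonical_name(c) for c in self.areas.columns]
        if len(set(self.areas.columns)) != len(self.areas.columns):
            dupes = self.areas.columns[self.areas.columns.duplicated()]
            raise ValueError(f"duplicate compound columns after canonicalization: {list(dupes)}")
        self.groups = self.groups.reindex(self.areas.index)
        self.compounds = {canonical_name(k): v for k, v in self.compounds.items()}
        for name in self.areas.columns:
            if name not in self.compounds:
                self.compounds[name] = CompoundRecord(name=name)
        self.validate()

    def validate(self) -> None:
        vals = self.areas.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("peak areas must be finite")
        if (vals < 0).any():
            raise ValueError("peak areas must be >= 0")
        zero_rows = self.areas.index[vals.sum(axis=1) <= 0]
        if len(zero_rows):
            raise ValueError(
                f"sample(s) with zero total peak area: {list(zero_rows)}"
            )
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()]
            raise ValueError(f"sample(s) without group label: {list(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def group_names(self) -> list[str]:
        # stable order of first appearance
        return list(dict.fromkeys(self.groups))

    def require_two_groups(self) -> None:
        counts = self.groups.value_counts()
        if len(counts) < 2 or (counts < 1).any():
            raise ValueError(
                "discriminant operations need >= 2 non-empty groups; "
                f"found {counts.to_dict()}"
            )


@dataclass
class GroupProfile:
    """Per-group mean ± SD relative content (%) per compound.

    ``table`` is indexed by canonical compound name with columns
    ``mean`` (percent), ``sd`` (percent), ``n`` (replicates). A compound is
    *detected* in the group iff its mean content is > 0.
    """

    group: str
    table: pd.DataFrame
    compounds: dict[str, CompoundRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"mean", "sd", "n"}
        if not required <= set(self.table.columns):
            raise ValueError(f"profile table needs columns {sorted(required)}")
        if (self.table["sd"] < 0).any():
            raise ValueError("sd must be >= 0")
        if (self.table["n"] < 1).any():
            raise ValueError("replicate count n must be >= 1")

    def validate_closure(self, atol: float = 0.01) -> None:
        """Check that mean contents sum to 100% (within ``atol``)."""
        total = float(self.table["mean"].sum())
        if abs(total - 100.0) > atol:
            raise ValueError(
                f"group {self.group!r}: mean contents sum to {total:.4f}, not 100"
            )

    @property
    def mean(self) -> pd.Series:
        return self.table["mean"]

    @property
    def detected(self) -> pd.Index:
        return self.table.index[self.table["mean"] > 0]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_relative_content(table: PeakTable) -> pd.DataFrame:
    """Area-normalize a peak table: percent of total area per sample.

    Entry (s, c) = 100 * area(s, c) / sum_c' area(s, c'); every row sums
    to exactly 100%.
    """
    totals = table.areas.sum(axis=1)
    bad = totals.index[totals <= 0]
    if len(bad):
        raise ValueError(f"sample(s) with zero total peak area: {list(bad)}")
    return table.areas.div(totals, axis=0) * 100.0


def aggregate_group_profile(
    content: pd.DataFrame,
    groups: pd.Series,
    compounds: Mapping[str, CompoundRecord] | None = None,
    ddof: int = 1,
) -> dict[str, GroupProfile]:
    """Aggregate per-replicate contents into per-group mean ± SD profiles.

    Uses the sample standard deviation (``ddof=1``) by default, the usual
    convention for n=4 analytical replicates. A group with a single
    replicate gets sd 0 with a warning.
    """
    groups = groups.reindex(content.index)
    profiles: dict[str, GroupProfile] = {}
    for g in dict.fromkeys(groups):
        sub = content.loc[groups == g]
        n = len(sub)
        mean = sub.mean(axis=0)
        if n <= ddof:
            warnings.warn(
                f"group {g!r} has {n} replicate(s); reporting sd=0",
                UserWarning,
                stacklevel=2,
            )
            sd = pd.Series(0.0, index=content.columns)
        else:
            sd = sub.std(axis=0, ddof=ddof)
        tbl = pd.DataFrame({"mean": mean, "sd": sd, "n": n})
        prof = GroupProfile(group=str(g), table=tbl, compounds=dict(compounds or {}))
        prof.validate_closure(atol=1e-6)
        profiles[str(g)] = prof
    return profiles


def venn_counts(profile1: GroupProfile, profile2: GroupProfile) -> VennCounts:
    """Counts of compounds detected (mean > 0) in each group, both, either."""
    d1 = set(profile1.detected)
    d2 = set(profile2.detected)
    return VennCounts(len(d1), len(d2), len(d1 & d2), len(d1 | d2))


def class_composition(profile: GroupProfile) -> pd.Series:
    """Sum of mean relative contents by chemical class.

    The sums over classes conserve the profile total (partition of the
    compound set).
    """
    classes = pd.Series(
        {
            name: (profile.compounds.get(name) or CompoundRecord(name)).chem_class
            for name in profile.table.index
        }
    )
    out = profile.mean.groupby(classes).sum()
    out.index.name = "chem_class"
    return out.sort_values(ascending=False)


def presence_pattern(
    profile1: GroupProfile,
    profile2: GroupProfile,
    high_threshold: float = 3.0,
) -> pd.Series:
    """Rule-based presence-pattern label per compound.

    A convenience classifier (non-normative): a compound is "high" in a
    group when its mean content exceeds ``high_threshold`` percent.
    Labels: I = high in group 1 only, II = low in both, III = high in
    group 2 only, IV = high in both.
    """
    if not high_threshold > 0:
        raise ValueError("high_threshold must be > 0")
    idx = profile1.table.index.union(profile2.table.index)
    m1 = profile1.mean.reindex(idx, fill_value=0.0)
    m2 = profile2.mean.reindex(idx, fill_value=0.0)
    hi1, hi2 = m1 > high_threshold, m2 > high_threshold
    labels = np.select(
        [hi1 & ~hi2, ~hi1 & hi2, hi1 & hi2], ["I", "III", "IV"], default="II"
    )
    return pd.Series(labels, index=idx, name="presence_pattern")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_LONG_REQUIRED = {"sample_id", "group", "compound", "area"}


def read_compound_metadata(path: str | Path) -> dict[str, CompoundRecord]:
    """Read a compound metadata sidecar CSV.

    Columns: name (or compound), cas, formula, retention_time_min, chem_class.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    name_col = "name" if "name" in df.columns else "compound"
    records: dict[str, CompoundRecord] = {}
    for _, row in df.iterrows():
        rec = CompoundRecord(
            name=row[name_col],
            cas=_opt(row.get("cas")),
            formula=_opt(row.get("formula")),
            retention_time=_optf(row.get("retention_time_min")),
            chem_class=_opt(row.get("chem_class")) or "other",
        )
        if rec.name in records:
            rec = _merge_records(records[rec.name], rec)
        records[rec.name] = rec
    return records


def _opt(v) -> str | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    s = str(v).strip()
    return s or None


def _optf(v) -> float | None:
    s = _opt(v)
    return float(s) if s is not None else None


def read_peak_table(
    path: str | Path,
    metadata: str | Path | Mapping[str, CompoundRecord] | None = None,
    sep: str | None = None,
) -> PeakTable:
    """Read a peak table from CSV/TSV, auto-detecting wide vs long layout.

    Long layout has columns ``sample_id, group, compound, [cas,] area``;
    wide layout has ``sample_id, group`` plus one column per compound.
    The delimiter is sniffed from the header when ``sep`` is None.
    """
    path = Path(path)
    if sep is None:
        header = path.open(encoding="utf-8").readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    if not {"sample_id", "group"} <= set(lower):
        raise ValueError("peak table needs 'sample_id' and 'group' columns")

    if _LONG_REQUIRED <= set(lower):
        wide = df.pivot_table(
            index=[lower["sample_id"], lower["group"]],
            columns=lower["compound"],
            values=lower["area"],
            aggfunc="sum",
            fill_value=0.0,
        )
        wide.index.names = ["sample_id", "group"]
        areas = wide.reset_index().set_index("sample_id")
        groups = areas.pop("group")
        records: dict[str, CompoundRecord] = {}
        if "cas" in lower:
            for comp, cas in df[[lower["compound"], lower["cas"]]].drop_duplicates().itertuples(index=False):
                rec = CompoundRecord(name=comp, cas=_opt(cas))
                if rec.name in records:
                    rec = _merge_records(records[rec.name], rec)
                records[rec.name] = rec
    else:
        df = df.set_index(lower["sample_id"])
        groups = df.pop(lower["group"]).astype(str)
        areas = df.astype(float)
        records = {}

    if metadata is not None:
        meta = (
            dict(metadata)
            if isinstance(metadata, Mapping)
            else read_compound_metadata(metadata)
        )
        for name, rec in meta.items():
            records[name] = _merge_records(records[name], rec) if name in records else rec
    return PeakTable(areas=areas.astype(float), groups=groups.astype(str), compounds=records)


def write_group_profiles(
    profiles: Sequence[GroupProfile] | Mapping[str, GroupProfile],
    path: str | Path,
    decimals: int = 2,
) -> pd.DataFrame:
    """Export group profiles as a CSV mirroring a mean ± SD content table.

    One row per compound (compound, formula, retention time, CAS, chemical
    class, then ``<group>_mean``/``<group>_sd`` per group, rounded to
    ``decimals`` for display). Returns the exported frame.
    """
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    idx = profiles[0].table.index
    for p in profiles[1:]:
        idx = idx.union(p.table.index)
    meta: dict[str, CompoundRecord] = {}
    for p in profiles:
        meta.update(p.compounds)
    out = pd.DataFrame(index=idx)
    out.index.name = "compound"
    out["formula"] = [getattr(meta.get(c), "formula", None) for c in idx]
    out["retention_time_min"] = [getattr(meta.get(c), "retention_time", None) for c in idx]
    out["cas"] = [getattr(meta.get(c), "cas", None) for c in idx]
    out["chem_class"] = [
        getattr(meta.get(c), "chem_class", "other") or "other" for c in idx
    ]
    for p in profiles:
        out[f"{p.group}_mean"] = p.table["mean"].reindex(idx, fill_value=0.0).round(decimals)
        out[f"{p.group}_sd"] = p.table["sd"].reindex(idx, fill_value=0.0).round(decimals)
    out.to_csv(path)
    return out
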
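"""Odor activity values, ROAV key-flavor classification, and flavor networks.

A compound contributes to perceived flavor only above its odor threshold.
The odor activity value is the ratio of the compound's relative content C
(percent of total peak area) to its water odor threshold T (mg/kg):
OAV = C / T. Within a sample group, the relative odor activity value
rescales this to the group's most odor-active compound,
ROAV_i = 100 * OAV_i / OAV_max, so ROAV lies in [0, 100]. Compounds with
ROAV >= 1 are key flavor contributors; 0 < ROAV < 1 marks flavor modifiers.

Key compounds and their odor descriptors form a bipartite flavor network:
one edge per (compound, descriptor) with weight equal to the compound's
ROAV; a descriptor node's weight is the sum of incident ROAVs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .profile import GroupProfile, canonical_name

__all__ = [
    "ThresholdEntry",
    "ROAVResult",
    "read_thresholds",
    "write_thresholds",
    "compute_oav",
    "compute_roav",
    "classify_roav",
    "build_flavor_network",
    "network_to_edge_list",
    "descriptor_weights",
    "format_roav",
    "roav_report",
]

KEY_CUTOFF = 1.0  # ROAV >= 1 -> key flavor contributor
DISPLAY_CUTOFF = 0.1  # printed as "<0.1" below this


@dataclass(frozen=True)
class ThresholdEntry:
    """Water odor threshold and descriptors for one compound.

    threshold is in mg/kg (water) and must be strictly positive; an empty
    descriptor list simply contributes no network edges.
    """

    compound: str
    threshold: float
    cas: str | None = None
    odor_descriptors: tuple[str, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "compound", canonical_name(self.compound))
        if not (np.isfinite(self.threshold) and self.threshold > 0):
            raise ValueError(
                f"odor threshold for {self.compound!r} must be finite and > 0, "
                f"got {self.threshold}"
            )
        descs = tuple(
            dict.fromkeys(canonical_name(d) for d in self.odor_descriptors if str(d).strip())
        )
        object.__setattr__(self, "odor_descriptors", descs)


@dataclass
class ROAVResult:
    """Per-group OAV/ROAV table with key/modifier categories.

    ``table`` is indexed by canonical compound name, with columns
    ``content`` (%), ``threshold``, ``oav``, ``roav`` and ``category`` in
    {key, modifier, negligible, no_threshold}. Exactly one compound has
    roav == 100 (the group's OAV maximum) unless several tie.
    """

    group: str
    table: pd.DataFrame

    @property
    def key_compounds(self) -> pd.DataFrame:
        """Key flavor contributors (ROAV >= 1), sorted by descending ROAV."""
        sub = self.table[self.table["category"] == "key"]
        return sub.sort_values(["roav", "content"], ascending=False, kind="stable")

    @property
    def modifiers(self) -> pd.DataFrame:
        sub = self.table[self.table["category"] == "modifier"]
        return sub.sort_values("roav", ascending=False, kind="stable")


def read_thresholds(path: str | Path) -> list[ThresholdEntry]:
    """Read a threshold table CSV (descriptors semicolon-separated)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    entries = []
    for _, row in df.iterrows():
        descs = str(row.get("odor_descriptors", "") or "")
        cas = row.get("cas")
        entries.append(
            ThresholdEntry(
                compound=row["compound"],
                threshold=float(row["threshold_mg_per_kg"]),
                cas=None if pd.isna(cas) else str(cas),
                odor_descriptors=tuple(d for d in descs.split(";") if d.strip()),
                source=str(row.get("source", "") or ""),
            )
        )
    return entries


def write_thresholds(entries: Iterable[ThresholdEntry], path: str | Path) -> None:
    pd.DataFrame(
        {
            "compound": [e.compound for e in entries],
            "cas": [e.cas for e in entries],
            "threshold_mg_per_kg": [e.threshold for e in entries],
            "odor_descriptors": [";".join(e.odor_descriptors) for e in entries],
            "source": [e.source for e in entries],
        }
    ).to_csv(path, index=False)


def _threshold_index(thresholds: Iterable[ThresholdEntry]) -> dict[str, ThresholdEntry]:
    idx: dict[str, ThresholdEntry] = {}
    for e in thresholds:
        if e.compound in idx:
            prev = idx[e.compound]
            if prev.cas and e.cas and prev.cas != e.cas:
                raise ValueError(
                    f"CAS conflict for threshold entry {e.compound!r}: "
                    f"{prev.cas} vs {e.cas}"
                )
        idx[e.compound] = e
    return idx


def compute_oav(
    profile: GroupProfile, thresholds: Iterable[ThresholdEntry]
) -> pd.DataFrame:
    """OAV = mean relative content (%) / odor threshold (mg/kg) per compound.

    Compounds without a threshold entry are kept with oav = NaN and flagged
    ``no_threshold`` downstream rather than silently dropped. An absent
    compound (content 0) gets oav 0.
    """
    tidx = _threshold_index(thresholds)
    rows = []
    for name in profile.table.index:
        content = float(profile.mean[name])
        entry = tidx.get(name)
        if entry is None:
            oav, thr = np.nan, np.nan
        else:
            thr = entry.threshold
            oav = content / thr
        rows.append((name, content, thr, oav))
    return pd.DataFrame(
        rows, columns=["compound", "content", "threshold", "oav"]
    ).set_index("compound")


def compute_roav(
    oav: pd.DataFrame, group: str = "", key_cutoff: float = KEY_CUTOFF
) -> ROAVResult:
    """Rescale OAVs to the group maximum: ROAV_i = 100 * OAV_i / OAV_max.

    The max-OAV compound gets exactly 100. Raises if no compound in the
    group has a positive OAV.
    """
    oavs = oav["oav"]
    finite = oavs.dropna()
    if finite.empty or not (finite > 0).any():
        raise ValueError(f"no odor-active compounds in group {group!r}")
    oav_max = float(finite.max())
    table = oav.copy()
    table["roav"] = oavs / oav_max * 100.0
    cat = pd.Series("negligible", index=table.index, dtype=object)
    cat[table["roav"] >= key_cutoff] = "key"
    cat[(table["roav"] > 0) & (table["roav"] < key_cutoff)] = "modifier"
    cat[table["oav"].isna()] = "no_threshold"
    table["category"] = cat
    return ROAVResult(group=group, table=table)


def classify_roav(result: ROAVResult) -> dict[str, list[str]]:
    """Sorted key / modifier compound lists with counts, per group."""
    keys = list(result.key_compounds.index)
    mods = list(result.modifiers.index)
    return {
        "group": result.group,
        "key": keys,
        "n_key": len(keys),
        "modifier": mods,
        "n_modifier": len(mods),
    }


def build_flavor_network(
    result: ROAVResult, thresholds: Iterable[ThresholdEntry]
) -> nx.Graph:
    """Bipartite flavor network of key compounds and their odor descriptors.

    Nodes carry ``kind`` ("compound" with ``roav``, or "descriptor" with
    ``summed_roav``); each edge weight is the compound's ROAV, and a
    descriptor's summed_roav is the sum over its incident edges. Only key
    compounds (ROAV >= 1) enter; a key compound without descriptors stays
    as an isolated node with a warning.
    """
    tidx = _threshold_index(thresholds)
    g = nx.Graph()
    for name, row in result.key_compounds.iterrows():
        roav = float(row["roav"])
        g.add_node(name, kind="compound", roav=roav, bipartite=0)
        entry = tidx.get(name)
        descs = entry.odor_descriptors if entry else ()
        if not descs:
            warnings.warn(
                f"key compound {name!r} has no odor descriptors; kept as an "
                "isolated node",
                UserWarning,
                stacklevel=2,
            )
            continue
        for d in descs:  # already canonical + deduplicated
            if not g.has_node(d):
                g.add_node(d, kind="descriptor", summed_roav=0.0, bipartite=1)
            g.add_edge(name, d, weight=roav)
            g.nodes[d]["summed_roav"] += roav
    for d in [n for n, a in g.nodes(data=True) if a["kind"] == "descriptor"]:
        g.nodes[d]["degree"] = g.degree(d)
    return g


def descriptor_weights(g: nx.Graph) -> pd.Series:
    """Summed ROAV per descriptor node, sorted descending."""
    w = {
        n: a["summed_roav"] for n, a in g.nodes(data=True) if a["kind"] == "descriptor"
    }
    return pd.Series(w, name="summed_roav").sort_values(ascending=False)


def network_to_edge_list(g: nx.Graph) -> pd.DataFrame:
    """Edge list (compound, descriptor, weight) for export."""
    rows = []
    for u, v, a in g.edges(data=True):
        if g.nodes[u]["kind"] == "descriptor":
            u, v = v, u
        rows.append((u, v, a["weight"]))
    return pd.DataFrame(rows, columns=["compound", "descriptor", "weight"]).sort_values(
        ["compound", "descriptor"], ignore_index=True
    )


def format_roav(value: float) -> str:
    """Display convention: values below 0.1 (incl. absent = 0) print as '<0.1'."""
    if np.isnan(value):
        return "-"
    if value < DISPLAY_CUTOFF:
        return "<0.1"
    return f"{value:.2f}"


def roav_report(results: Sequence[ROAVResult], thresholds: Iterable[ThresholdEntry]) -> pd.DataFrame:
    """CSV-ready report: compound, threshold, descriptors, formatted ROAV per group.

    Restricted to compounds with a threshold entry, mirroring the usual
    key-flavor table layout; ROAVs below 0.1 display as '<0.1' while full
    precision stays in the underlying :class:`ROAVResult`.
    """
    tidx = _threshold_index(thresholds)
    compounds = [c for c in results[0].table.index if c in tidx]
    out = pd.DataFrame(index=pd.Index(compounds, name="compound"))
    out["threshold_mg_per_kg"] = [tidx[c].threshold for c in compounds]
    out["odor_descriptors"] = ["; ".join(tidx[c].odor_descriptors) for c in compounds]
    for res in results:
        out[f"ROAV_{res.group}"] = [
            format_roav(float(res.table.loc[c, "roav"])) for c in compounds
        ]
    return out
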
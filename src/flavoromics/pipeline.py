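"""End-to-end orchestration: profile -> ROAV -> network -> OPLS-DA/RF -> screen.

Each stage writes its tabular outputs under one run directory and
contributes to a machine-readable :class:`PipelineReport`; a failure
aborts with a stage-tagged :class:`StageError`, leaving earlier outputs in
place. Deterministic fields of the report reproduce bit-identically when
re-run with the recorded config and inputs.

When VIP and Gini are fitted from replicate data (rather than supplied as
a printed table), the signature screen is gated on the cross-validated
Q² of the OPLS-DA model: min-max normalization always pushes some compound
over the X_A cut even on pure noise, so screening without a validated
model would report false signatures on signal-free data.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .fusion import fuse_importances
from .oplsda import OPLSDA, cross_val_q2, fit_pca, permutation_test
from .profile import (
    GroupProfile,
    PeakTable,
    aggregate_group_profile,
    class_composition,
    compute_relative_content,
    presence_pattern,
    read_peak_table,
    venn_counts,
    write_group_profiles,
)
from .rf import fit_rf_importance
from .roav import (
    ROAVResult,
    ThresholdEntry,
    build_flavor_network,
    classify_roav,
    compute_oav,
    compute_roav,
    network_to_edge_list,
    read_thresholds,
    roav_report,
)

__all__ = ["PipelineConfig", "PipelineReport", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the culprit."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Tunable knobs of the pipeline; defaults follow the methods note."""

    scaling: str = "uv"
    n_ortho: int = 1
    n_folds: int = 7
    n_permutations: int = 0  # 0 = skip the permutation test
    n_trees: int = 500
    seed: int = 0
    screen_scope: str = "keys"  # "keys": union of per-group key compounds; or "all"
    vip_cut: float = 1.0
    xa_cut: float = 0.5
    min_q2: float = 0.0  # screen gate when VIP/Gini are fitted
    high_threshold: float = 3.0  # presence-pattern "high" cut (percent)
    key_cutoff: float = 1.0  # ROAV >= cutoff -> key compound
    vip_gini_table: str | None = None  # external printed VIP/Gini CSV

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineReport:
    provenance: dict[str, Any]
    profile: dict[str, Any] = field(default_factory=dict)
    roav: dict[str, Any] = field(default_factory=dict)
    network: dict[str, Any] = field(default_factory=dict)
    discriminant: dict[str, Any] = field(default_factory=dict)
    screen: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, default=_jsonify, ensure_ascii=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _load_table(peak_table) -> PeakTable:
    if isinstance(peak_table, PeakTable):
        return peak_table
    try:
        return read_peak_table(peak_table)
    except FileNotFoundError as e:
        raise StageError("profile", f"peak table not readable: {e}") from e
    except ValueError as e:
        raise StageError("profile", str(e)) from e


def _load_thresholds(thresholds) -> list[ThresholdEntry]:
    if isinstance(thresholds, (str, Path)):
        try:
            return read_thresholds(thresholds)
        except FileNotFoundError as e:
            raise StageError("roav", f"threshold table not readable: {e}") from e
        except (ValueError, KeyError) as e:
            raise StageError("roav", str(e)) from e
    return list(thresholds)


def run_pipeline(
    peak_table: PeakTable | str | Path,
    thresholds: Iterable[ThresholdEntry] | str | Path,
    config: PipelineConfig | Mapping[str, Any] | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> PipelineReport:
    """Run all stages in order; see the module docstring for the contract."""
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, Mapping):
        config = PipelineConfig(**dict(config))
    if seed is not None:
        config.seed = seed
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report = PipelineReport(
        provenance={
            "peak_table": str(peak_table) if not isinstance(peak_table, PeakTable) else "<in-memory>",
            "thresholds": str(thresholds) if isinstance(thresholds, (str, Path)) else "<in-memory>",
            "config": config.as_dict(),
            "config_digest": config.digest(),
            "seed": config.seed,
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
    )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # ----- stage: profile -------------------------------------------
        table = _load_table(peak_table)
        try:
            content = compute_relative_content(table)
            profiles = aggregate_group_profile(content, table.groups, table.compounds)
        except ValueError as e:
            raise StageError("profile", str(e)) from e
        plist = list(profiles.values())
        report.profile = {
            "groups": {g: int(p.table["n"].iloc[0]) for g, p in profiles.items()},
            "n_compounds": int(content.shape[1]),
            "class_composition": {
                g: class_composition(p).round(6).to_dict() for g, p in profiles.items()
            },
        }
        if len(plist) == 2:
            v = venn_counts(plist[0], plist[1])
            report.profile["venn"] = dict(v._asdict())
            report.profile["presence_pattern"] = presence_pattern(
                plist[0], plist[1], config.high_threshold
            ).to_dict()
        if out is not None:
            write_group_profiles(plist, out / "group_profiles.csv")

        # ----- stage: roav ------------------------------------------------
        entries = _load_thresholds(thresholds)
        roav_results: dict[str, ROAVResult] = {}
        for g, prof in profiles.items():
            try:
                oav = compute_oav(prof, entries)
                roav_results[g] = compute_roav(oav, group=g, key_cutoff=config.key_cutoff)
            except ValueError as e:
                raise StageError("roav", str(e)) from e
        report.roav = {g: classify_roav(r) for g, r in roav_results.items()}
        if out is not None:
            roav_report(list(roav_results.values()), entries).to_csv(out / "roav.csv")

        # ----- stage: network ---------------------------------------------
        nets = {}
        for g, r in roav_results.items():
            gnet = build_flavor_network(r, entries)
            nets[g] = gnet
            report.network[g] = {
                "n_compounds": sum(1 for _, a in gnet.nodes(data=True) if a["kind"] == "compound"),
                "n_descriptors": sum(1 for _, a in gnet.nodes(data=True) if a["kind"] == "descriptor"),
                "n_edges": gnet.number_of_edges(),
                "descriptor_weights": {
                    n: round(a["summed_roav"], 6)
                    for n, a in gnet.nodes(data=True)
                    if a["kind"] == "descriptor"
                },
            }
            if out is not None:
                network_to_edge_list(gnet).to_csv(out / f"network_{g}.csv", index=False)
                nx.write_graphml(gnet, out / f"network_{g}.graphml")

        # ----- stage: discriminant (OPLS-DA VIP + RF Gini) ----------------
        fitted_route = config.vip_gini_table is None
        if config.screen_scope == "keys":
            scope = sorted(
                set().union(*(set(r.key_compounds.index) for r in roav_results.values()))
            )
        else:
            scope = list(content.columns)
        if not fitted_route:
            tbl = pd.read_csv(config.vip_gini_table)
            tbl.columns = [c.strip().lower() for c in tbl.columns]
            from .profile import canonical_name

            tbl["compound"] = tbl["compound"].map(canonical_name)
            tbl = tbl.set_index("compound")
            vip = tbl["vip"].astype(float)
            gini = tbl["gini"].astype(float)
            report.discriminant = {
                "source": str(config.vip_gini_table),
                "n_compounds": int(len(vip)),
            }
            q2 = None
        else:
            try:
                table.require_two_groups()
            except ValueError as e:
                raise StageError("discriminant", str(e)) from e
            if len(scope) < 2:
                raise StageError(
                    "discriminant", f"need >= 2 compounds to screen, got {scope}"
                )
            X = content[scope]
            y = table.groups.to_numpy()
            try:
                model = OPLSDA(n_ortho=config.n_ortho, scaling=config.scaling).fit(X, y)
                q2 = cross_val_q2(
                    X, y, n_ortho=config.n_ortho, n_folds=min(config.n_folds, len(y)),
                    scaling=config.scaling,
                )
            except ValueError as e:
                raise StageError("discriminant", str(e)) from e
            vip = pd.Series(model.vip_, index=scope, name="vip")
            imp = fit_rf_importance(X, y, n_trees=config.n_trees, seed=config.seed)
            gini = imp.gini
            pca = fit_pca(content, n_components=min(2, len(y) - 1), scaling=config.scaling)
            report.discriminant = {
                "source": "fitted",
                "n_compounds": len(scope),
                "r2x": round(float(model.r2x_), 6),
                "r2y": round(float(model.r2y_), 6),
                "q2": round(float(q2), 6),
                "n_ortho": int(model.n_ortho_fitted_),
                "vip": {c: round(float(v), 6) for c, v in vip.items()},
                "gini_raw": {c: round(float(v), 6) for c, v in gini.items()},
                "pca_explained_variance_ratio": [
                    round(float(v), 6) for v in pca.explained_variance_ratio
                ],
            }
            if config.n_permutations > 0:
                perm = permutation_test(
                    X,
                    y,
                    n_permutations=config.n_permutations,
                    seed=config.seed,
                    n_ortho=config.n_ortho,
                    n_folds=min(config.n_folds, len(y)),
                    scaling=config.scaling,
                )
                report.discriminant["permutation"] = {
                    "n_permutations": perm.n_permutations,
                    "r2_intercept": round(perm.r2_intercept, 6),
                    "q2_intercept": round(perm.q2_intercept, 6),
                    "p_value_q2": round(perm.p_value_q2, 6),
                }
            if out is not None:
                imp.to_csv(out / "rf_importance.csv")
                pd.DataFrame(
                    {"sample_id": content.index, "group": table.groups.values,
                     "t_predictive": model.scores_},
                ).to_csv(out / "oplsda_scores.csv", index=False)

        # ----- stage: screen ----------------------------------------------
        try:
            fused = fuse_importances(
                vip, gini.reindex(vip.index), vip_cut=config.vip_cut, xa_cut=config.xa_cut
            )
        except ValueError as e:
            raise StageError("screen", str(e)) from e
        gated = fitted_route and q2 is not None and q2 <= config.min_q2
        signature = [] if gated else fused.signature
        if gated:
            warnings.warn(
                f"OPLS-DA Q2 = {q2:.3f} <= {config.min_q2}: model not validated, "
                "signature list suppressed",
                UserWarning,
                stacklevel=2,
            )
        report.screen = {
            "signature": signature,
            "gated_on_q2": bool(gated),
            "x_a": {c: round(float(v), 6) for c, v in fused.table["x_a"].items()},
            "vip_cut": config.vip_cut,
            "xa_cut": config.xa_cut,
        }
        if out is not None:
            fused.to_csv(out / "fusion.csv")

        report.warnings = [str(w.message) for w in caught]

    if out is not None:
        report.to_json(out / "report.json")
    return report
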
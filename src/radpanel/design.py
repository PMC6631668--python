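"""Genome-evenly-spaced panel selection on a linkage map.

The selector is a deterministic greedy scan: within each linkage group,
candidates are walked in map order and a candidate is kept whenever it
lies at least ``min_spacing_cM`` beyond the last kept one.  Co-located
candidates (identical cM, common on dense maps) are ordered by
decreasing MAF then id, so the most informative marker wins the slot.
Greedy left-to-right attains the spacing constraint and never skips a
feasible marker; optimal (max-count or min-variance) placement is out of
scope.

Down-sampling to a plate-friendly size, appending fixed
ancestry-informative / mitochondrial markers, spacing summaries and
failed-assay replacement complete the design workflow.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    ConfigurationError,
    LinkageMap,
    PanelSelection,
    RadPanelError,
    ValidationError,
)

_CAND_COLS = ("marker_id", "linkage_group", "position_cM")


class SizeError(RadPanelError):
    pass


def _as_candidates(candidates) -> pd.DataFrame:
    df = pd.DataFrame(candidates)
    missing = set(_CAND_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"candidate table missing columns {sorted(missing)}")
    if df[["linkage_group", "position_cM"]].isna().any().any():
        bad = df.loc[df[["linkage_group", "position_cM"]].isna().any(axis=1),
                     "marker_id"].iloc[0]
        raise ValidationError(f"unmapped candidate: {bad}")
    if "maf" not in df.columns:
        df = df.assign(maf=np.nan)
    return df


def select_spaced_markers(candidates, min_spacing_cM: float = 3.5) -> PanelSelection:
    """Greedy per-LG selection of markers spaced >= ``min_spacing_cM`` apart.

    ``candidates`` is a DataFrame (or records) with columns marker_id,
    linkage_group, position_cM and optionally maf.
    """
    if min_spacing_cM <= 0:
        raise ConfigurationError("min_spacing_cM must be positive")
    df = _as_candidates(candidates)
    chosen: list[pd.Series] = []
    for lg, grp in df.groupby("linkage_group", sort=True):
        grp = grp.sort_values(["position_cM", "maf", "marker_id"],
                              ascending=[True, False, True],
                              na_position="last", kind="mergesort")
        last = -math.inf
        for _, row in grp.iterrows():
            if row["position_cM"] - last >= min_spacing_cM - 1e-12 or last == -math.inf:
                chosen.append(row)
                last = row["position_cM"]
    table = pd.DataFrame(chosen).reset_index(drop=True)
    table = table[["marker_id", "linkage_group", "position_cM"]
                  + (["maf"] if "maf" in table.columns else [])]
    return PanelSelection(table=table, min_spacing_cM=min_spacing_cM,
                          provenance={"selector": "greedy-left-to-right"})


def downsample_panel(panel: PanelSelection, target_size: int,
                     seed: int) -> PanelSelection:
    """Uniform random subset without replacement, reproducible by seed."""
    if target_size > panel.size:
        raise SizeError(f"target size {target_size} exceeds panel size {panel.size}")
    if target_size == panel.size:
        return PanelSelection(panel.table.copy(), panel.min_spacing_cM,
                              {**panel.provenance, "downsample": "identity"})
    rng = np.random.default_rng(seed)
    keep_idx = np.sort(rng.choice(panel.size, size=target_size, replace=False))
    removed = panel.table.drop(index=panel.table.index[keep_idx])
    table = panel.table.iloc[keep_idx].reset_index(drop=True)
    prov = {**panel.provenance, "downsample_seed": seed,
            "removed_ids": sorted(removed["marker_id"])}
    return PanelSelection(table=table, min_spacing_cM=panel.min_spacing_cM,
                          provenance=prov)


def append_fixed_markers(panel: PanelSelection,
                         nuclear_aims: Sequence[str] = (),
                         mito_markers: Sequence[str] = ()) -> PanelSelection:
    """Append fixed ancestry-informative and mitochondrial markers (unmapped rows)."""
    addons = list(nuclear_aims) + list(mito_markers)
    if len(set(addons)) != len(addons):
        raise ValidationError("duplicate ids among added markers")
    clash = set(addons) & set(panel.marker_ids)
    if clash:
        raise ValidationError(f"added markers already in panel: {sorted(clash)}")
    rows = pd.DataFrame({
        "marker_id": addons,
        "linkage_group": np.nan,
        "position_cM": np.nan,
        "marker_class": (["snp"] * len(nuclear_aims)
                         + ["mitochondrial"] * len(mito_markers)),
    })
    base = panel.table.copy()
    if "marker_class" not in base.columns:
        base = base.assign(marker_class="snp")
    table = pd.concat([base, rows], ignore_index=True)
    prov = {**panel.provenance, "added_nuclear": list(nuclear_aims),
            "added_mito": list(mito_markers)}
    return PanelSelection(table=table, min_spacing_cM=panel.min_spacing_cM,
                          provenance=prov)


def panel_spacing_stats(panel: PanelSelection,
                        lmap: LinkageMap | None = None) -> dict:
    """Spacing summary: per-LG and global mean/SD of gaps, max gap, density.

    Density is total map length divided by the number of panel markers
    (coarse cM-per-marker figure).  Unmapped add-ons are excluded from
    gap statistics but counted in the panel size only when no map is
    given; with a map, density uses the mapped marker count.
    """
    mapped = panel.table.dropna(subset=["linkage_group", "position_cM"])
    per_lg: dict[int, dict] = {}
    gaps_all: list[float] = []
    for lg, grp in mapped.groupby("linkage_group"):
        pos = np.sort(grp["position_cM"].to_numpy(dtype=float))
        gaps = np.diff(pos)
        per_lg[int(lg)] = {
            "n_markers": len(pos),
            "mean_gap_cM": float(np.mean(gaps)) if gaps.size else math.nan,
            "max_gap_cM": float(np.max(gaps)) if gaps.size else math.nan,
        }
        gaps_all.extend(gaps.tolist())
    total_length = lmap.total_length_cM if lmap is not None else \
        float(mapped.groupby("linkage_group")["position_cM"].max().sum())
    n_for_density = len(mapped)
    return {
        "per_lg": per_lg,
        "mean_gap_cM": float(np.mean(gaps_all)) if gaps_all else math.nan,
        "sd_gap_cM": float(np.std(gaps_all, ddof=0)) if gaps_all else math.nan,
        "max_gap_cM": float(np.max(gaps_all)) if gaps_all else math.nan,
        "n_markers": panel.size,
        "density_cM_per_marker": total_length / n_for_density if n_for_density else math.nan,
        "total_length_cM": total_length,
    }


def replace_failed_markers(panel: PanelSelection, failed_ids: Sequence[str],
                           reserves, min_spacing_cM: float | None = None,
                           seed: int = 0) -> PanelSelection:
    """Swap failed assays for reserve candidates, preferring same-LG nearest-cM.

    Spacing is re-checked after replacement; violations are recorded in
    provenance (``spacing_violations``), not silently dropped.  If the
    reserves run out, the shortfall is recorded (``unreplaced``).
    """
    min_spacing = panel.min_spacing_cM if min_spacing_cM is None else min_spacing_cM
    res = _as_candidates(reserves).copy()
    failed = [f for f in failed_ids if f in set(panel.marker_ids)]
    table = panel.table[~panel.table["marker_id"].isin(failed)].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    replacements: dict[str, str] = {}
    unreplaced: list[str] = []
    pos_of = panel.table.set_index("marker_id")[["linkage_group", "position_cM"]]
    for f in failed:
        if res.empty:
            unreplaced.append(f)
            continue
        lg, pos = pos_of.loc[f] if f in pos_of.index else (np.nan, np.nan)
        if not np.isnan(lg):
            same = res[res["linkage_group"] == lg]
            pool = same if len(same) else res
            dist = (pool["position_cM"] - (pos if not np.isnan(pos) else 0.0)).abs()
            pick = pool.loc[dist.sort_values(kind="mergesort").index[0]]
        else:
            pick = res.iloc[rng.integers(len(res))]
        replacements[f] = pick["marker_id"]
        res = res[res["marker_id"] != pick["marker_id"]]
        row = {"marker_id": pick["marker_id"],
               "linkage_group": pick["linkage_group"],
               "position_cM": pick["position_cM"]}
        if "maf" in table.columns:
            row["maf"] = pick.get("maf", np.nan)
        if "marker_class" in table.columns:
            row["marker_class"] = "snp"
        table = pd.concat([table, pd.DataFrame([row])], ignore_index=True)
    out = PanelSelection(table=table, min_spacing_cM=min_spacing,
                         provenance={**panel.provenance,
                                     "replacements": replacements,
                                     "unreplaced": unreplaced,
                                     "replacement_seed": seed})
    out.provenance["spacing_violations"] = out.check_spacing()
    return out
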
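"""Hydrogenase directionality classes and per-class expression aggregation.

Hydrogenase genes arrive with a family ([NiFe], [FeFe], [Fe]) and a group
label (e.g. 1a, 3c, A3) assigned upstream by phylogenetic placement.  A
shipped directionality map translates (family, group) into one of four
activity classes — h2_uptake, h2_evolving, bidirectional, bifurcating —
following the activity annotations of the hydrogenase reference database;
each shipped entry carries a provenance note and the map is plain config.
Unmapped groups are flagged, never dropped.

Per-class expression totals (optionally excluding methanogen MAGs, the
comparison shown for the non-methanogen community) are compared between
treatments with a one-way ANOVA on log10(geTMM + 1), Benjamini-Hochberg
adjusted across the family of (class, day) tests.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "load_directionality_map",
    "assign_directionality",
    "class_expression",
    "compare_classes",
    "ACTIVITY_CLASSES",
]

ACTIVITY_CLASSES = ("h2_uptake", "h2_evolving", "bidirectional", "bifurcating")


def load_directionality_map(path=None) -> pd.DataFrame:
    """The (family, group) -> activity_class table with provenance notes."""
    if path is None:
        ref = resources.files("mireomics.data").joinpath("hydrogenase_directionality.tsv")
        with ref.open() as fh:
            return pd.read_csv(fh, sep="\t")
    return pd.read_csv(path, sep="\t")


def assign_directionality(
    genes: pd.DataFrame,
    directionality: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach an activity class to every hydrogenase gene.

    Unknown (family, group) combinations receive ``activity_class="unmapped"``
    and ``mapped=False``.  A bare [FeFe] group "A" maps to bifurcating but
    triggers a warning, since the subgroups differ in directionality.
    """
    directionality = directionality if directionality is not None else load_directionality_map()
    merged = genes.merge(
        directionality[["family", "group", "activity_class"]],
        on=["family", "group"],
        how="left",
    )
    merged["mapped"] = merged["activity_class"].notna()
    merged["activity_class"] = merged["activity_class"].fillna("unmapped")
    if ((merged["family"] == "[FeFe]") & (merged["group"] == "A")).any():
        warnings.warn(
            "[FeFe] Group A left unrefined; mapped to bifurcating — "
            "provide subgroups A1-A4 for per-subgroup directionality",
            stacklevel=2,
        )
    return merged


def class_expression(
    expr: pd.DataFrame,
    genes: pd.DataFrame,
    exclude_mags: set[str] | None = None,
) -> pd.DataFrame:
    """Summed expression per activity class (rows) per sample (columns).

    ``genes`` must carry gene_id, mag_id and activity_class (see
    :func:`assign_directionality`).  Classes with no genes appear as zero
    rows, and unmapped genes are summed under ``"unmapped"`` so the class
    totals always partition total hydrogenase expression.
    """
    keep = genes if not exclude_mags else genes[~genes["mag_id"].isin(exclude_mags)]
    classes = list(ACTIVITY_CLASSES) + ["unmapped"]
    totals = pd.DataFrame(0.0, index=classes, columns=expr.columns)
    present = keep[keep["gene_id"].isin(expr.index)]
    for cls, block in present.groupby("activity_class"):
        totals.loc[cls] = expr.loc[block["gene_id"]].sum(axis=0)
    return totals.rename_axis(index="activity_class", columns="sample_id")


def compare_classes(
    totals: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Treatment effect per (activity class, day) by ANOVA on log totals.

    Values are log10(total + pseudocount).  P values are Benjamini-Hochberg
    adjusted across all performed tests; significance tiers at adjusted
    p < 0.10 ("*") and < 0.05 ("**").  (class, day) cells with fewer than two
    replicates in any treatment are skipped with a notice row.
    """
    meta = samples.set_index("sample_id")
    records = []
    for cls in totals.index:
        for day in sorted(meta["day"].unique()):
            groups = []
            ok = True
            for trt in sorted(meta["treatment"].unique()):
                cols = meta[(meta["day"] == day) & (meta["treatment"] == trt)].index
                cols = [c for c in cols if c in totals.columns]
                if len(cols) < 2:
                    ok = False
                    break
                groups.append(np.log10(totals.loc[cls, cols].to_numpy(dtype=float) + pseudocount))
            if not ok or len(groups) < 2:
                records.append({"activity_class": cls, "day": day, "f_stat": np.nan,
                                "p_value": np.nan, "note": "insufficient replication"})
                continue
            if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
                f, p = 0.0, 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    f, p = sps.f_oneway(*groups)
                if np.isnan(p):
                    f, p = 0.0, 1.0
            records.append({"activity_class": cls, "day": day, "f_stat": float(f),
                            "p_value": float(p), "note": ""})
    table = pd.DataFrame.from_records(records)
    tested = table["p_value"].notna()
    table["p_adjusted"] = np.nan
    if tested.any():
        table.loc[tested, "p_adjusted"] = multipletests(
            table.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    table["significance"] = np.select(
        [table["p_adjusted"] < 0.05, table["p_adjusted"] < 0.10],
        ["**", "*"],
        default="",
    )
    return table
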
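"""Six-way classification of MAG gene-expression responses to catechin.

At each timepoint a transcriptionally active MAG is summarized by two
metrics computed on the zero/nonzero pattern of its genes across the two
treatments:

* ``%both`` — percentage of the MAG's expressed genes detected in *both*
  unamended and catechin-amended microcosms;
* ``∆unique`` — percentage expressed only in unamended minus percentage
  expressed only in catechin-amended microcosms.

With thresholds ``b`` (default 26) and ``u`` (default 25) the plane splits
into six categories: resistant (%both >= b, |∆unique| <= u), responsive
(%both < b, |∆unique| <= u), sensitive (%both < b, ∆unique >= u),
stimulated (%both < b, ∆unique <= -u), lost_function (%both >= b,
∆unique >= u) and gained_function (%both >= b, ∆unique <= -u).  On the
boundary |∆unique| == u the extreme categories win, so the six regions tile
the plane exactly once.

A gene counts as expressed in a treatment at a day if its normalized
expression is nonzero in at least one replicate (the replicate-union rule;
``all-replicates`` is available for stricter presence).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CATEGORIES",
    "PresencePattern",
    "ClassifierConfig",
    "presence_pattern",
    "response_metrics",
    "classify",
    "classify_all",
]

CATEGORIES = (
    "resistant",
    "responsive",
    "sensitive",
    "stimulated",
    "lost_function",
    "gained_function",
)


@dataclass(frozen=True)
class PresencePattern:
    mag_id: str
    day: int
    n_both: int
    n_unamended_only: int
    n_catechin_only: int

    @property
    def n_total(self) -> int:
        return self.n_both + self.n_unamended_only + self.n_catechin_only


@dataclass
class ClassifierConfig:
    both_threshold: float = 26.0
    unique_threshold: float = 25.0
    presence_rule: str = "replicate-union"  # or "all-replicates"

    def __post_init__(self) -> None:
        if not (0 < self.both_threshold < 100 and 0 < self.unique_threshold < 100):
            raise ValueError("thresholds must lie in (0, 100)")
        if self.presence_rule not in ("replicate-union", "all-replicates"):
            raise ValueError(f"unknown presence rule {self.presence_rule!r}")


def _presence_by_treatment(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    day: int,
    presence_rule: str,
) -> dict[str, pd.Series]:
    """Boolean per-gene presence for each treatment at one day."""
    at_day = samples[samples["day"] == day]
    treatments = sorted(at_day["treatment"].unique())
    if len(treatments) < 2:
        raise ValueError(
            f"day {day}: both treatments are required, found {treatments}"
        )
    presence = {}
    for trt in treatments:
        cols = at_day.loc[at_day["treatment"] == trt, "sample_id"]
        block = expr[list(cols)] > 0
        presence[trt] = block.all(axis=1) if presence_rule == "all-replicates" else block.any(axis=1)
    return presence


def presence_pattern(
    expr: pd.DataFrame,
    catalog: pd.DataFrame,
    samples: pd.DataFrame,
    mag_id: str,
    day: int,
    presence_rule: str = "replicate-union",
) -> PresencePattern:
    genes = catalog.loc[catalog["mag_id"] == mag_id, "gene_id"]
    sub = expr.loc[expr.index.intersection(genes)]
    presence = _presence_by_treatment(sub, samples, day, presence_rule)
    un = presence["unamended"]
    cat = presence["catechin"]
    return PresencePattern(
        mag_id=mag_id,
        day=int(day),
        n_both=int((un & cat).sum()),
        n_unamended_only=int((un & ~cat).sum()),
        n_catechin_only=int((~un & cat).sum()),
    )


def response_metrics(p: PresencePattern) -> tuple[float, float]:
    """(%both, ∆unique) of a presence pattern; requires at least one gene."""
    if p.n_total == 0:
        raise ValueError(f"MAG {p.mag_id!r} at day {p.day}: no expressed genes")
    pct_both = 100.0 * p.n_both / p.n_total
    delta_unique = 100.0 * (p.n_unamended_only - p.n_catechin_only) / p.n_total
    return pct_both, delta_unique


def classify(
    pct_both: float,
    delta_unique: float,
    config: ClassifierConfig | None = None,
) -> str:
    """Assign the unique six-way category; extreme categories win boundaries."""
    config = config or ClassifierConfig()
    b, u = config.both_threshold, config.unique_threshold
    core = pct_both >= b
    if delta_unique >= u:
        return "lost_function" if core else "sensitive"
    if delta_unique <= -u:
        return "gained_function" if core else "stimulated"
    return "resistant" if core else "responsive"


def classify_all(
    expr: pd.DataFrame,
    catalog: pd.DataFrame,
    samples: pd.DataFrame,
    config: ClassifierConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every active MAG at every day.

    Returns the per-(MAG, day) record table and per-day category proportions
    over classified MAGs (proportions sum to one per day).  MAGs with no
    expressed genes at a day are reported ``inactive`` and excluded from the
    proportions.
    """
    config = config or ClassifierConfig()
    mags = catalog.set_index("gene_id")["mag_id"]
    records = []
    for day in sorted(samples["day"].unique()):
        presence = _presence_by_treatment(expr, samples, day, config.presence_rule)
        un, cat = presence["unamended"], presence["catechin"]
        frame = pd.DataFrame(
            {
                "mag_id": mags.loc[expr.index].to_numpy(),
                "both": (un & cat).to_numpy(),
                "un_only": (un & ~cat).to_numpy(),
                "cat_only": (~un & cat).to_numpy(),
            }
        )
        grouped = frame.groupby("mag_id").sum()
        for mag_id, row in grouped.iterrows():
            p = PresencePattern(mag_id, int(day), int(row["both"]),
                                int(row["un_only"]), int(row["cat_only"]))
            if p.n_total == 0:
                records.append(
                    {"mag_id": mag_id, "day": int(day), "n_both": 0,
                     "n_unamended_only": 0, "n_catechin_only": 0,
                     "pct_both": float("nan"), "delta_unique": float("nan"),
                     "category": "inactive"}
                )
                continue
            pct_both, delta = response_metrics(p)
            records.append(
                {"mag_id": mag_id, "day": p.day, "n_both": p.n_both,
                 "n_unamended_only": p.n_unamended_only,
                 "n_catechin_only": p.n_catechin_only,
                 "pct_both": pct_both, "delta_unique": delta,
                 "category": classify(pct_both, delta, config)}
            )
    table = pd.DataFrame.from_records(records)
    classified = table[table["category"] != "inactive"]
    proportions = (
        classified.groupby("day")["category"]
        .value_counts(normalize=True)
        .rename("proportion")
        .reset_index()
    )
    return table, proportions
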
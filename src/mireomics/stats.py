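"""Multi-level beta-diversity and hypothesis testing for microcosm omics.

Gene-level expression is summed to genome (MAG) and to functional-annotation
abundance tables; Bray-Curtis dissimilarities at each level quantify how much
of community restructuring happens at the gene, organism, and function scale.
Treatment and time effects on a distance matrix are assessed with a
permutational multivariate ANOVA (sequential sums of squares, the behavior of
vegan's adonis2), and univariate group contrasts use Kruskal-Wallis with
Dunn's post-hoc z tests and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "level_summaries",
    "bray_curtis",
    "between_treatment_distances",
    "kruskal_dunn_bh",
    "dunn_posthoc",
    "permanova",
]

ANNOTATION_COLUMNS = ("ko_id", "cazy_best_hit", "camper_id")


def level_summaries(
    expr: pd.DataFrame,
    catalog: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene-, MAG- and annotation-level abundance tables.

    Returns (gene, mag, annotation, coverage).  Column sums are conserved
    between the gene and MAG levels.  A gene contributes to the annotation
    level once per non-null annotation column; genes with no annotation are
    listed in the coverage report.
    """
    cat = catalog.set_index("gene_id").loc[expr.index]
    mag = expr.groupby(cat["mag_id"].to_numpy()).sum().rename_axis(index="mag_id")
    pieces = []
    annotated = pd.Series(False, index=expr.index)
    for col in ANNOTATION_COLUMNS:
        if col not in cat.columns:
            continue
        ids = cat[col]
        has = ids.notna() & (ids.astype(str) != "")
        annotated |= has.to_numpy()
        if has.any():
            pieces.append(expr[has.to_numpy()].groupby(ids[has].astype(str).to_numpy()).sum())
    annotation = (
        pd.concat(pieces).groupby(level=0).sum().rename_axis(index="annotation_id")
        if pieces
        else pd.DataFrame(columns=expr.columns)
    )
    coverage = pd.DataFrame(
        {"gene_id": expr.index, "annotated": annotated.to_numpy()}
    )
    return expr.copy(), mag, annotation, coverage


def bray_curtis(abundance: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between sample columns.

    BC(x, y) = 1 - 2 sum(min(x_i, y_i)) / (sum x + sum y), in [0, 1] for
    nonnegative data.  A pair of all-zero samples has no defined distance and
    raises.
    """
    if abundance.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = abundance.to_numpy(dtype=float).T
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = list(abundance.columns[zero][:2])
        raise ValueError(f"all-zero samples have undefined pairwise distance: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=abundance.columns, columns=abundance.columns)


def between_treatment_distances(
    dist: pd.DataFrame,
    samples: pd.DataFrame,
    day: int,
) -> list[float]:
    """All cross-treatment pairwise distances at one day."""
    at_day = samples[samples["day"] == day]
    groups = {
        trt: [s for s in block["sample_id"] if s in dist.index]
        for trt, block in at_day.groupby("treatment")
    }
    present = [trt for trt, cols in groups.items() if cols]
    if len(present) < 2:
        raise ValueError(f"day {day}: both treatments needed, found {present}")
    a, b = (groups[t] for t in sorted(present)[:2])
    return [float(dist.at[i, j]) for i in a for j in b]


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided p values.
    """
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in labels])
    n = {k: len(groups[k]) for k in labels}
    ranks = sps.rankdata(pooled)
    idx = 0
    mean_rank = {}
    for k in labels:
        mean_rank[k] = ranks[idx: idx + n[k]].mean()
        idx += n[k]
    big_n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (big_n - 1))
    records = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt((big_n * (big_n + 1) / 12.0 - tie_term) * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        records.append({"group_a": a, "group_b": b, "z": z, "p_value": min(p, 1.0)})
    return pd.DataFrame.from_records(records)


def kruskal_dunn_bh(groups: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis omnibus + Dunn's post-hoc with BH adjustment.

    Returns {"kw_h", "kw_p", "pairwise": DataFrame with p_adjusted}.
    """
    if len(groups) < 2 or any(len(v) == 0 for v in groups.values()):
        raise ValueError("need >= 2 nonempty groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
        pairwise = dunn_posthoc(groups)
        pairwise["z"] = 0.0
        pairwise["p_value"] = 1.0
    else:
        h, p = sps.kruskal(*arrays)
        pairwise = dunn_posthoc(groups)
    pairwise["p_adjusted"] = multipletests(pairwise["p_value"], method="fdr_bh")[1]
    return {"kw_h": float(h), "kw_p": float(p), "pairwise": pairwise}


def _hat_matrix(design: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(design)
    return q @ q.T


def permanova(
    dist: pd.DataFrame,
    samples: pd.DataFrame,
    factors: list[str] = ("treatment", "day"),
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA with sequential (type-I) terms.

    Distances are Gower-centered (G = -1/2 J D^2 J); each factor's sum of
    squares is the extra variance explained when it is added after the
    preceding factors, and its pseudo-F uses the residual of the full model.
    Sample labels are permuted freely; p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm).
    """
    factors = list(factors)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    meta = samples.set_index("sample_id").loc[dist.index]
    n = len(dist)
    d2 = dist.to_numpy(dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    ss_total = float(np.trace(g))

    designs = [np.ones((n, 1))]
    dfs = []
    for f in factors:
        levels = pd.get_dummies(meta[f].astype("category"), drop_first=True).to_numpy(dtype=float)
        if levels.shape[1] == 0:
            raise ValueError(f"factor {f!r} has a single level")
        if (meta[f].value_counts() < 2).any():
            raise ValueError(f"factor {f!r} has a level with a single sample")
        designs.append(np.hstack([designs[-1], levels]))
        dfs.append(levels.shape[1])
    hats = [_hat_matrix(x) for x in designs]
    df_resid = n - designs[-1].shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_seq = np.array([float(np.sum(hats[k + 1] * gmat)) - float(np.sum(hats[k] * gmat))
                           for k in range(len(factors))])
        ss_res = float(np.trace(gmat)) - float(np.sum(hats[-1] * gmat))
        return ss_seq, ss_res

    ss_obs, ss_res_obs = term_stats(g)
    f_obs = (ss_obs / np.asarray(dfs)) / (ss_res_obs / df_resid)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(factors))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = term_stats(gp)
        f_p = (ss_p / np.asarray(dfs)) / (ss_res_p / df_resid)
        exceed += f_p >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = [
        {"term": f, "df": dfs[k], "sum_sq": ss_obs[k],
         "r2": ss_obs[k] / ss_total, "pseudo_f": f_obs[k], "p_value": pvals[k]}
        for k, f in enumerate(factors)
    ]
    rows.append({"term": "residual", "df": df_resid, "sum_sq": ss_res_obs,
                 "r2": ss_res_obs / ss_total, "pseudo_f": np.nan, "p_value": np.nan})
    rows.append({"term": "total", "df": n - 1, "sum_sq": ss_total,
                 "r2": 1.0, "pseudo_f": np.nan, "p_value": np.nan})
    return pd.DataFrame(rows).set_index("term")
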
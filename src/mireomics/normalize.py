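"""Metatranscriptome count filtering and geTMM normalization.

The post-mapping procedure is: (1) zero out cells with fewer than ``min_count``
mapped reads, (2) convert counts to reads-per-kilobase (RPK) using gene
lengths, (3) compute trimmed-mean-of-M-values (TMM) scaling factors on the RPK
matrix and express each sample per million effective RPK (this combination is
geTMM: gene-length-corrected TMM), and (4) silence genes of genomes that are
not convincingly transcriptionally active in a sample — a MAG needs at least
``mag_on_threshold`` genes with nonzero geTMM in a sample for its genes to be
kept there (the study's threshold of 22 was the dataset-wide median; ``"auto"``
recomputes that median).

The TMM factor of a sample is the precision-weighted mean of log2 expression
ratios against a reference sample after trimming the most extreme 30% of
log-ratios (M) on each side and the most extreme 5% of average log intensities
(A) on each side; genes unexpressed in either member of the pair are excluded.
Factors are rescaled so their geometric mean is one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NormConfig",
    "filter_low_counts",
    "rpk",
    "tmm_factors",
    "getmm",
    "mag_on_filter",
]


@dataclass
class NormConfig:
    min_count: int = 5
    mag_on_threshold: int | str = 22  # the study's median; "auto" recomputes it
    tmm_trim_m: float = 0.30
    tmm_trim_a: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.tmm_trim_m < 0.5 and 0 <= self.tmm_trim_a < 0.5):
            raise ValueError("trim fractions must lie in [0, 0.5)")


def filter_low_counts(counts: pd.DataFrame, min_count: int = 5) -> pd.DataFrame:
    """Zero every cell with ``0 < value < min_count``; dimensions unchanged."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    out = counts.copy()
    out[out < min_count] = 0
    return out


def rpk(counts: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Reads per kilobase: count / (length_bp / 1000), per gene."""
    lengths = catalog.set_index("gene_id")["length_bp"]
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"genes without a catalog length: {list(missing[:5])}")
    lengths = lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive gene length for {bad!r}")
    return counts.div(lengths / 1000.0, axis=0)


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
    weighted: bool = True,
) -> float:
    """log2 TMM factor of ``obs`` against ``ref`` (library-size-scaled)."""
    n_obs = obs.sum()
    n_ref = ref.sum()
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("no co-expressed genes between sample and reference")
    p_obs = obs[both] / n_obs
    p_ref = ref[both] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) precision weights of each M value
    w = (n_obs - obs[both]) / (n_obs * obs[both]) + (n_ref - ref[both]) / (n_ref * ref[both])
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    # rank-based double trim, as in the canonical TMM description
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    if not weighted:
        return float(np.mean(m[keep]))
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def tmm_factors(
    rpk_matrix: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
    weighted: bool = True,
) -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean one.

    ``reference`` selects the reference column; by default the sample whose
    upper quartile of relative expression is closest to the mean upper
    quartile is used.  ``weighted=False`` replaces the precision-weighted
    trimmed mean by a plain trimmed mean; the M/A values and the trim set
    depend only on relative expression, so unweighted factors are exactly
    invariant to per-sample depth scaling (the precision weights carry a
    weak dependence on absolute depth).
    """
    if rpk_matrix.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    x = rpk_matrix.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        empty = rpk_matrix.columns[lib <= 0][0]
        raise ValueError(f"sample {empty!r} has zero total expression")
    if reference is None:
        uq = np.quantile(x / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = rpk_matrix.columns.get_loc(reference)
    log_factors = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_idx:
            continue
        try:
            log_factors[j] = _tmm_pair_factor(x[:, j], x[:, ref_idx], trim_m, trim_a, weighted)
        except ValueError as e:
            raise ValueError(
                f"{e} (sample {rpk_matrix.columns[j]!r} vs reference "
                f"{rpk_matrix.columns[ref_idx]!r})"
            ) from None
    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=rpk_matrix.columns, name="tmm_factor")


def getmm(
    counts: pd.DataFrame,
    catalog: pd.DataFrame,
    config: NormConfig | None = None,
) -> pd.DataFrame:
    """Counts -> geTMM: filter, RPK, TMM scaling, per-million.

    With a single sample the TMM factor is defined as 1, so geTMM reduces to
    RPK per million.
    """
    config = config or NormConfig()
    filtered = filter_low_counts(counts, config.min_count)
    if (filtered.to_numpy() == 0).all():
        raise ValueError("count matrix is empty after low-count filtering")
    r = rpk(filtered, catalog)
    if r.shape[1] == 1:
        factors = pd.Series([1.0], index=r.columns)
    else:
        factors = tmm_factors(r, config.tmm_trim_m, config.tmm_trim_a)
    eff_lib = r.sum(axis=0) * factors
    return r.div(eff_lib, axis=1) * 1e6


def mag_on_filter(
    expr: pd.DataFrame,
    catalog: pd.DataFrame,
    threshold: int | str = 22,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Zero genes of MAGs with too few active genes in a sample.

    Returns the filtered matrix and an activity table with one row per
    (MAG, sample): number of genes with nonzero expression and whether the
    block passed.  ``threshold="auto"`` uses the median gene-on count over all
    (MAG, sample) pairs with at least one active gene.
    """
    if expr.empty:
        raise ValueError("expression matrix is empty")
    mags = catalog.set_index("gene_id")["mag_id"].loc[expr.index]
    on_counts = (expr > 0).groupby(mags.to_numpy()).sum()  # MAG x sample
    if threshold == "auto":
        pooled = on_counts.to_numpy().ravel()
        pooled = pooled[pooled > 0]
        if pooled.size == 0:
            raise ValueError("no active (MAG, sample) pairs to derive a threshold from")
        threshold = int(np.median(pooled))
    threshold = int(threshold)
    if threshold <= 0:
        raise ValueError("mag-on threshold must be positive")
    passed = on_counts >= threshold  # MAG x sample booleans
    mask = passed.loc[mags.to_numpy()].to_numpy()
    out = expr.where(mask, 0.0)
    activity = (
        on_counts.rename_axis(index="mag_id", columns="sample_id")
        .stack()
        .rename("genes_on")
        .reset_index()
    )
    activity["passed"] = activity["genes_on"] >= threshold
    activity["threshold"] = threshold
    return out, activity
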
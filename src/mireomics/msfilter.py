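"""In-source fragment / neutral-loss removal for untargeted LC-MS features.

Electrospray sources fragment some analytes before the mass analyzer, so an
untargeted feature table contains spurious "compounds" that are really pieces
of a co-eluting parent ion.  The filter identifies them in three steps:

1. features are binned by retention time with single-linkage chaining
   (consecutive features closer than the RT tolerance share a bin);
2. within a bin, pairs whose raw cross-sample intensities correlate above a
   threshold (default Pearson r > 0.98) become (parent, fragment) candidates,
   the heavier m/z being the parent;
3. a candidate is confirmed only if its m/z occurs in the parent's MS2
   spectrum within a ppm tolerance (default 5 ppm).

Confirmed fragments are removed; every removal is logged (bin, r, ppm,
parent) for manual review.  Separately, features whose predicted elemental
composition contains a halogen are dropped: halogenated compounds are
unlikely to occur naturally in peat and mark annotation artifacts.

Note the RT tolerance default is 0.005 *seconds*, as the originating
procedure specifies; exports scaled in minutes need a converted tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ledger import LedgerError, parse_formula

__all__ = [
    "FilterConfig",
    "bin_by_rt",
    "correlated_pairs",
    "confirm_in_ms2",
    "remove_artifacts",
    "drop_halogens",
]

HALOGENS = frozenset({"F", "Cl", "Br", "I"})


@dataclass
class FilterConfig:
    rt_tolerance: float = 0.005       # seconds
    min_correlation: float = 0.98
    ppm_tolerance: float = 5.0
    halogens: frozenset[str] = HALOGENS

    def __post_init__(self) -> None:
        if min(self.rt_tolerance, self.ppm_tolerance) <= 0 or not (0 < self.min_correlation <= 1):
            raise ValueError("filter tolerances must be positive")


@dataclass
class RemovalRecord:
    feature_id: str
    parent_id: str
    bin_index: int
    correlation: float
    ppm_error: float


def bin_by_rt(features: pd.DataFrame, rt_tolerance: float = 0.005) -> list[list[str]]:
    """Single-linkage co-elution bins: sort by RT, chain gaps <= tolerance."""
    if features.empty:
        return []
    order = features.sort_values("rt")
    bins: list[list[str]] = []
    last_rt = None
    for fid, rt in zip(order["feature_id"], order["rt"]):
        if last_rt is None or rt - last_rt > rt_tolerance:
            bins.append([])
        bins[-1].append(fid)
        last_rt = rt
    return bins


def _pairwise_pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson r over samples where both intensities are recorded."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return None
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None  # zero variance: correlation undefined
    return float(np.corrcoef(x, y)[0, 1])


def correlated_pairs(
    bin_features: pd.DataFrame,
    intensity_columns: list[str],
    min_correlation: float = 0.98,
) -> list[tuple[str, str, float]]:
    """(parent, fragment, r) candidates within one co-elution bin.

    The heavier ion of each correlated pair is the parent.  Pairs with an
    undefined correlation (zero-variance vector) are skipped with a warning.
    """
    rows = list(bin_features.itertuples())
    out = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            x = np.asarray([getattr(a, c) for c in intensity_columns], dtype=float)
            y = np.asarray([getattr(b, c) for c in intensity_columns], dtype=float)
            r = _pairwise_pearson(x, y)
            if r is None:
                warnings.warn(
                    f"correlation undefined for pair ({a.feature_id}, {b.feature_id}); skipped",
                    stacklevel=2,
                )
                continue
            if r > min_correlation:
                parent, fragment = (a, b) if a.mz >= b.mz else (b, a)
                out.append((parent.feature_id, fragment.feature_id, r))
    return out


def confirm_in_ms2(
    candidate_mz: float,
    parent_spectrum: list[tuple[float, float]] | None,
    ppm_tolerance: float = 5.0,
) -> tuple[bool, float]:
    """Does the parent's MS2 contain the candidate m/z within tolerance?

    Returns (confirmed, best ppm error); a parent without MS2 is unconfirmed.
    """
    if not parent_spectrum:
        return False, math.inf
    best = min(abs(mz - candidate_mz) / candidate_mz * 1e6 for mz, _ in parent_spectrum)
    return best < ppm_tolerance, best


def remove_artifacts(
    features: pd.DataFrame,
    spectra: dict[str, list[tuple[float, float]]],
    config: FilterConfig | None = None,
    intensity_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop confirmed in-source fragments; keep parents; log every removal.

    ``spectra`` maps feature_id -> MS2 peak list of that precursor.  The
    operation is idempotent: re-running on its own output removes nothing.
    """
    config = config or FilterConfig()
    log_cols = ["feature_id", "parent_id", "bin_index", "correlation", "ppm_error"]
    if features.empty:
        return features.copy(), pd.DataFrame(columns=log_cols)
    if intensity_columns is None:
        reserved = {"feature_id", "mz", "rt", "formula", "annotation_level"}
        intensity_columns = [c for c in features.columns if c not in reserved]
    removals: dict[str, RemovalRecord] = {}
    indexed = features.set_index("feature_id", drop=False)
    for bin_idx, members in enumerate(bin_by_rt(features, config.rt_tolerance)):
        if len(members) < 2:
            continue
        pairs = correlated_pairs(indexed.loc[members], intensity_columns, config.min_correlation)
        for parent_id, fragment_id, r in pairs:
            confirmed, ppm = confirm_in_ms2(
                float(indexed.at[fragment_id, "mz"]),
                spectra.get(parent_id),
                config.ppm_tolerance,
            )
            if confirmed and fragment_id not in removals:
                removals[fragment_id] = RemovalRecord(fragment_id, parent_id, bin_idx, r, ppm)
    kept = features[~features["feature_id"].isin(removals)].copy()
    log = pd.DataFrame(
        [
            {"feature_id": r.feature_id, "parent_id": r.parent_id, "bin_index": r.bin_index,
             "correlation": r.correlation, "ppm_error": r.ppm_error}
            for r in removals.values()
        ],
        columns=log_cols,
    )
    return kept, log


def drop_halogens(
    features: pd.DataFrame,
    halogens: frozenset[str] = HALOGENS,
) -> pd.DataFrame:
    """Remove features whose predicted composition contains a halogen.

    Features without a formula are kept (the rule applies to predicted
    compositions only); unparseable formulas are kept with a warning.
    """
    if "formula" not in features.columns or features.empty:
        return features.copy()
    keep = []
    for fid, formula in zip(features["feature_id"], features["formula"]):
        if formula is None or (isinstance(formula, float) and math.isnan(formula)) or formula == "":
            keep.append(True)
            continue
        try:
            counts = parse_formula(str(formula))
        except LedgerError:
            warnings.warn(f"unparseable formula {formula!r} for {fid}; kept", stacklevel=2)
            keep.append(True)
            continue
        keep.append(not any(counts.get(h, 0) > 0 for h in halogens))
    return features[np.asarray(keep)].copy()
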
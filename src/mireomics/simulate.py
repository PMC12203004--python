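"""Synthetic multi-omic inputs with planted ground truth.

Three generators produce everything the pipeline consumes, so every stage is
testable end-to-end without downloads:

* :func:`gen_expression_dataset` — a genes x samples count matrix over a
  two-treatment (unamended / catechin), multi-day, replicated microcosm
  design.  Each MAG is planted into one of the six response categories per
  day by drawing a (%both, ∆unique) target from an interior box of that
  category's region (>= 5 percentage points from every threshold after
  integer rounding) and splitting its genes into both / unamended-only /
  catechin-only presence sets.  Genes "on" in a treatment receive negative
  binomial counts with a floor at the low-count filter threshold so planted
  presence survives normalization; "off" cells occasionally carry
  sub-threshold noise counts (1-4) that the filter must erase.
* :func:`gen_methanogen_fixture` — a small annotation catalog + expression
  matrix containing one MAG per methanogen calling rule (hydrogenotrophic,
  methylotrophic, acetoclastic, obligate-acetoclast Methanotrichales,
  multifunctional, active-but-unclassifiable, and a non-methanogen).
* :func:`gen_lcms_dataset` — an LC-MS feature table with planted
  parent/in-source-fragment pairs (co-eluting, intensity correlation > 0.99,
  fragment m/z present in the parent MS2 within 1 ppm), independent
  co-eluting features that violate correlation or lack MS2 confirmation, and
  halogen-formula features.

All generators are deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .response import CATEGORIES

__all__ = [
    "SimulationDesign",
    "gen_expression_dataset",
    "gen_methanogen_fixture",
    "gen_lcms_dataset",
]


class DesignError(ValueError):
    """Infeasible simulation design (e.g. too few genes for a margin)."""


@dataclass
class SimulationDesign:
    n_mags: int = 60
    genes_per_mag: tuple[int, int] = (120, 200)
    days: tuple[int, ...] = (0, 7, 14, 21, 35)
    replicates_per_cell: int = 3
    treatments: tuple[str, str] = ("unamended", "catechin")
    planted_categories: dict[str, dict[int, str]] | None = None
    dispersion: float = 0.3          # NB overdispersion: var = mu + dispersion * mu^2
    mean_expression: float = 40.0    # median of the lognormal gene-mean profile
    depth_range: tuple[float, float] = (0.7, 1.3)
    noise_rate: float = 0.02         # chance of a sub-threshold count in an off cell
    dropout_rate: float = 0.0        # per-replicate presence dropout
    length_range: tuple[int, int] = (300, 3000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 1:
            raise DesignError("replicates_per_cell must be >= 1")
        if self.planted_categories:
            for mag, per_day in self.planted_categories.items():
                for cat in per_day.values():
                    if cat not in CATEGORIES:
                        raise DesignError(f"MAG {mag!r}: unknown category {cat!r}")


# Interior sampling boxes for (pct_both, delta_unique): every point is at
# least 6 points from the 26/25 thresholds (>= 5 after integer rounding) and
# keeps each treatment's on-fraction above ~25% so MAGs pass the 22-gene
# activity filter under the default design.
_CATEGORY_BOXES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "resistant": ((40.0, 85.0), (-15.0, 15.0)),
    "responsive": ((6.0, 19.0), (-15.0, 15.0)),
    "sensitive": ((8.0, 19.0), (32.0, 55.0)),
    "stimulated": ((8.0, 19.0), (-55.0, -32.0)),
    "lost_function": ((32.0, 55.0), (32.0, 50.0)),
    "gained_function": ((32.0, 55.0), (-50.0, -32.0)),
}
_MARGIN = 5.0
_MIN_SIDE_FRACTION = 0.22


def _margin_ok(pct_both: float, delta: float, category: str) -> bool:
    """Is (pct_both, delta) inside `category` with >= _MARGIN from thresholds?"""
    b, u = 26.0, 25.0
    core = pct_both >= b + _MARGIN if category in (
        "resistant", "lost_function", "gained_function") else pct_both <= b - _MARGIN
    if category in ("resistant", "responsive"):
        return core and abs(delta) <= u - _MARGIN
    if category in ("sensitive", "lost_function"):
        return core and delta >= u + _MARGIN
    return core and delta <= -(u + _MARGIN)


def _sample_targets(category: str, rng: np.random.Generator) -> tuple[float, float]:
    (b_lo, b_hi), (d_lo, d_hi) = _CATEGORY_BOXES[category]
    for _ in range(200):
        b = rng.uniform(b_lo, b_hi)
        d = rng.uniform(d_lo, d_hi)
        un = (100.0 - b + d) / 2.0
        ca = (100.0 - b - d) / 2.0
        if un < 0 or ca < 0:
            continue
        if (b + un) < 100 * _MIN_SIDE_FRACTION or (b + ca) < 100 * _MIN_SIDE_FRACTION:
            continue
        return b, d
    raise DesignError(f"could not sample a target for category {category!r}")


def _integer_partition(n_genes: int, b: float, d: float) -> tuple[int, int, int]:
    n_both = round(n_genes * b / 100.0)
    n_un = round(n_genes * (100.0 - b + d) / 200.0)
    n_cat = n_genes - n_both - n_un
    return n_both, n_un, n_cat


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def gen_expression_dataset(
    design: SimulationDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts, gene catalog, sample table and planted-truth table.

    The truth table has one row per (MAG, day) with the planted category and
    the realized noiseless (%both, ∆unique); per-gene presence sets are in
    the companion columns of the catalog-truth (see ``gene_truth`` attribute
    of the returned truth table, stored as a DataFrame in ``truth.attrs``).
    """
    rng = np.random.default_rng(design.seed)
    mags = [f"MAG{m:03d}" for m in range(design.n_mags)]
    planted = design.planted_categories or {
        mag: {day: CATEGORIES[(i + j) % len(CATEGORIES)] for j, day in enumerate(design.days)}
        for i, mag in enumerate(mags)
    }

    genes, lengths, gene_mag = [], [], []
    gene_means = []
    for mag in mags:
        n_genes = int(rng.integers(design.genes_per_mag[0], design.genes_per_mag[1] + 1))
        if n_genes < 50:
            raise DesignError(
                f"MAG {mag!r}: {n_genes} genes cannot guarantee a "
                f"{_MARGIN}-point margin after rounding"
            )
        for g in range(n_genes):
            genes.append(f"{mag}_g{g:04d}")
            gene_mag.append(mag)
        lengths.extend(rng.integers(design.length_range[0], design.length_range[1] + 1,
                                    size=n_genes))
        gene_means.extend(
            design.mean_expression * rng.lognormal(0.0, 0.6, size=n_genes)
        )
    catalog = pd.DataFrame(
        {"gene_id": genes, "mag_id": gene_mag, "length_bp": np.asarray(lengths, dtype=int)}
    )
    catalog["ko_id"] = [f"K{10000 + (i % 500):05d}" for i in range(len(genes))]
    catalog["cazy_best_hit"] = pd.NA
    catalog["camper_id"] = pd.NA
    gene_means = np.asarray(gene_means)

    samples = []
    for day in design.days:
        for trt in design.treatments:
            for rep in range(1, design.replicates_per_cell + 1):
                samples.append(
                    {"sample_id": f"{trt[:2]}_d{day:02d}_r{rep}", "treatment": trt,
                     "day": int(day), "replicate": f"r{rep}"}
                )
    sample_table = pd.DataFrame(samples)
    depth = {
        s: rng.uniform(*design.depth_range) for s in sample_table["sample_id"]
    }

    gene_index = pd.Index(genes, name="gene_id")
    counts = pd.DataFrame(0, index=gene_index, columns=sample_table["sample_id"], dtype=int)
    truth_rows = []
    gene_truth_rows = []
    mag_slices = {mag: np.flatnonzero(catalog["mag_id"].to_numpy() == mag) for mag in mags}

    for mag in mags:
        idx = mag_slices[mag]
        n_genes = idx.size
        for day in design.days:
            category = planted[mag][day]
            n_both = n_un = n_cat = 0
            for _ in range(50):
                b, d = _sample_targets(category, rng)
                n_both, n_un, n_cat = _integer_partition(n_genes, b, d)
                realized_b = 100.0 * n_both / n_genes
                realized_d = 100.0 * (n_un - n_cat) / n_genes
                if _margin_ok(realized_b, realized_d, category):
                    break
            else:
                raise DesignError(
                    f"MAG {mag!r}, day {day}: cannot realize {category!r} with margin "
                    f">= {_MARGIN} at {n_genes} genes"
                )
            perm = rng.permutation(idx)
            both_set = perm[:n_both]
            un_set = perm[n_both:n_both + n_un]
            cat_set = perm[n_both + n_un:]
            presence = {
                design.treatments[0]: np.concatenate([both_set, un_set]),
                design.treatments[1]: np.concatenate([both_set, cat_set]),
            }
            day_samples = sample_table[sample_table["day"] == day]
            for _, srow in day_samples.iterrows():
                on = presence[srow["treatment"]]
                if design.dropout_rate > 0:
                    keep = rng.random(on.size) >= design.dropout_rate
                    on = on[keep]
                mu = gene_means[on] * depth[srow["sample_id"]]
                vals = 5 + _nb_counts(rng, mu, design.dispersion)
                counts.loc[gene_index[on], srow["sample_id"]] = vals
                off = np.setdiff1d(idx, on, assume_unique=False)
                noisy = off[rng.random(off.size) < design.noise_rate]
                if noisy.size:
                    counts.loc[gene_index[noisy], srow["sample_id"]] = rng.integers(
                        1, 5, size=noisy.size
                    )
            truth_rows.append(
                {"mag_id": mag, "day": int(day), "category": category,
                 "pct_both": 100.0 * n_both / n_genes,
                 "delta_unique": 100.0 * (n_un - n_cat) / n_genes,
                 "n_both": n_both, "n_unamended_only": n_un, "n_catechin_only": n_cat}
            )
            gene_truth_rows.extend(
                [{"gene_id": genes[g], "day": int(day), "presence": "both"} for g in both_set]
                + [{"gene_id": genes[g], "day": int(day), "presence": "unamended_only"}
                   for g in un_set]
                + [{"gene_id": genes[g], "day": int(day), "presence": "catechin_only"}
                   for g in cat_set]
            )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["gene_truth"] = pd.DataFrame(gene_truth_rows)
    return counts, catalog, sample_table, truth


def gen_methanogen_fixture(
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Catalog, expression matrix and expected calls exercising every rule."""
    rng = np.random.default_rng(seed)
    rows = []

    def add(mag, kos, tax_class="", tax_order=""):
        for i, ko in enumerate(kos):
            rows.append(
                {"gene_id": f"{mag}_g{i}", "mag_id": mag, "length_bp": int(rng.integers(600, 2400)),
                 "ko_id": ko, "cazy_best_hit": pd.NA, "camper_id": pd.NA,
                 "tax_class": tax_class, "tax_order": tax_order}
            )

    confirm = ["K00399", "K03388"]  # mcrA + hdrA
    # hydrogenotroph: WL (fwdA) + Mtr (mtrA) + hydrogenase (frhA)
    add("hydro", confirm + ["K00200", "K00577", "K00440"])
    # methylotroph: mtaB
    add("methylo", confirm + ["K04480"])
    # acetoclast: Methanosarcinia, cdhA + ack + pta
    add("aceto", confirm + ["K00192", "K00925", "K00625"],
        tax_class="Methanosarcinia", tax_order="Methanosarcinales")
    # Methanotrichales obligate acetoclast: encodes WL+Mtr+hyd AND acs
    add("methanotrix", confirm + ["K00200", "K00577", "K00440", "K00192", "K01895"],
        tax_class="Methanosarcinia", tax_order="Methanotrichales")
    # multifunctional: WL+Mtr+hyd AND mtxB
    add("multi", confirm + ["K00200", "K00577", "K00440", "K16178"])
    # active but not classifiable: only mcr/hdr expressed
    add("unclassified", confirm)
    # not a methanogen (no Mcr/Hdr)
    add("notmeth", ["K00001", "K00002"])

    catalog = pd.DataFrame(rows)
    expr = pd.DataFrame(
        0.0, index=pd.Index(catalog["gene_id"], name="gene_id"), columns=["S1", "S2"]
    )
    # every gene expressed in S1; S2 left sparse for per-sample tests
    expr["S1"] = rng.uniform(1.0, 20.0, size=len(catalog))
    expr.loc[catalog.loc[catalog["mag_id"] == "hydro", "gene_id"], "S2"] = 3.0

    expected = pd.DataFrame(
        [
            {"mag_id": "hydro", "is_methanogen": True,
             "potential": "hydrogenotrophic", "active_s1": "hydrogenotrophic"},
            {"mag_id": "methylo", "is_methanogen": True,
             "potential": "methylotrophic", "active_s1": "methylotrophic"},
            {"mag_id": "aceto", "is_methanogen": True,
             "potential": "acetoclastic", "active_s1": "acetoclastic"},
            {"mag_id": "methanotrix", "is_methanogen": True,
             "potential": "acetoclastic,hydrogenotrophic", "active_s1": "acetoclastic"},
            {"mag_id": "multi", "is_methanogen": True,
             "potential": "hydrogenotrophic,methylotrophic",
             "active_s1": "hydrogenotrophic,methylotrophic"},
            {"mag_id": "unclassified", "is_methanogen": True,
             "potential": "", "active_s1": "ignored"},
            {"mag_id": "notmeth", "is_methanogen": False,
             "potential": "", "active_s1": "ignored"},
        ]
    )
    return catalog, expr, expected


def gen_lcms_dataset(
    n_parents: int = 50,
    n_fragments_per_parent: int = 2,
    n_independents: int = 100,
    n_halogen: int = 10,
    n_samples: int = 12,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[tuple[float, float]]], pd.DataFrame]:
    """Feature table, MS2 spectra and truth labels with planted artifacts."""
    if min(n_parents, n_fragments_per_parent, n_independents, n_halogen) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    sample_cols = [f"S{i + 1:02d}" for i in range(n_samples)]
    features = []
    spectra: dict[str, list[tuple[float, float]]] = {}
    truth = []
    rt_tol = 0.005

    def intensities(base: float) -> np.ndarray:
        return base * rng.lognormal(0.0, 0.8, size=n_samples)

    parent_rts = 60.0 + np.arange(n_parents) * 1.0  # seconds; far apart vs 5 ms tolerance
    parent_mzs = rng.uniform(300.0, 800.0, size=n_parents)
    parent_int = {}
    halogen_formulas = ["C6H5Cl", "C7H5BrO2", "C6H4F2", "C8H6ClNO", "C5H4IN"]
    clean_formulas = ["C6H6O3", "C15H14O6", "C9H10O4", "C7H6O5", "C8H8O3"]

    for p in range(n_parents):
        fid = f"P{p:03d}"
        vec = intensities(rng.uniform(1e5, 1e6))
        parent_int[fid] = vec
        features.append(
            {"feature_id": fid, "mz": parent_mzs[p], "rt": parent_rts[p],
             "formula": clean_formulas[p % len(clean_formulas)],
             **dict(zip(sample_cols, vec))}
        )
        truth.append({"feature_id": fid, "label": "parent", "parent_id": ""})
        peaks = []
        for f in range(n_fragments_per_parent):
            frag_id = f"P{p:03d}F{f}"
            frag_mz = parent_mzs[p] * rng.uniform(0.3, 0.9)
            frag_rt = parent_rts[p] + rng.uniform(-rt_tol / 2, rt_tol / 2)
            scale = rng.uniform(0.2, 0.8)
            frag_vec = scale * vec * (1.0 + rng.normal(0.0, 0.002, size=n_samples))
            features.append(
                {"feature_id": frag_id, "mz": frag_mz, "rt": frag_rt, "formula": "",
                 **dict(zip(sample_cols, frag_vec))}
            )
            truth.append({"feature_id": frag_id, "label": "fragment", "parent_id": fid})
            peaks.append((frag_mz * (1.0 + rng.uniform(-0.5e-6, 0.5e-6)),
                          float(frag_vec.mean())))
        # decoy MS2 peaks far from every feature m/z
        peaks.extend((rng.uniform(50.0, 250.0), rng.uniform(1e3, 1e4)) for _ in range(3))
        spectra[fid] = peaks

    for i in range(n_independents):
        fid = f"I{i:03d}"
        kind = i % 4
        if kind in (0, 1) or n_parents == 0:  # isolated, uncorrelated by construction
            rt = 200.0 + n_parents + i * 1.0
            mz = rng.uniform(100.0, 900.0)
            vec = intensities(rng.uniform(1e4, 1e6))
        elif kind == 2:  # co-eluting with a parent but uncorrelated
            p = int(rng.integers(n_parents))
            rt = parent_rts[p] + rng.uniform(-rt_tol / 2, rt_tol / 2)
            mz = parent_mzs[p] * rng.uniform(0.3, 0.9)
            for _ in range(100):
                vec = intensities(rng.uniform(1e4, 1e6))
                r = np.corrcoef(vec, parent_int[f"P{p:03d}"])[0, 1]
                if abs(r) < 0.8:
                    break
        else:  # kind == 3: co-eluting and correlated, but absent from parent MS2
            p = int(rng.integers(n_parents))
            rt = parent_rts[p] + rng.uniform(-rt_tol / 2, rt_tol / 2)
            mz = parent_mzs[p] * rng.uniform(0.3, 0.9)
            # keep >= 50 ppm away from every MS2 peak of that parent
            while any(abs(mz - pk) / mz * 1e6 < 50 for pk, _ in spectra[f"P{p:03d}"]):
                mz = parent_mzs[p] * rng.uniform(0.3, 0.9)
            vec = 0.5 * parent_int[f"P{p:03d}"] * (1.0 + rng.normal(0.0, 0.002, size=n_samples))
        features.append(
            {"feature_id": fid, "mz": mz, "rt": rt, "formula": "",
             **dict(zip(sample_cols, vec))}
        )
        truth.append({"feature_id": fid, "label": "independent", "parent_id": ""})

    for h in range(n_halogen):
        fid = f"H{h:03d}"
        features.append(
            {"feature_id": fid, "mz": rng.uniform(100.0, 600.0),
             "rt": 500.0 + n_parents + n_independents + h,
             "formula": halogen_formulas[h % len(halogen_formulas)],
             **dict(zip(sample_cols, intensities(1e4)))}
        )
        truth.append({"feature_id": fid, "label": "halogen", "parent_id": ""})

    feature_table = pd.DataFrame(features)
    return feature_table, spectra, pd.DataFrame(truth)
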
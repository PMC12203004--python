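"""Readers and writers for the pipeline's plain-text exchange formats.

Counts / expression matrices are TSV with gene_id in the first column and one
column per sample; gene catalogs and sample tables are TSV with documented
columns; LC-MS feature tables are CSV in the style of an untargeted
metabolomics export (feature_id, formula, rt, mz, per-sample areas); MS2
spectra travel as MGF via pyteomics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pyteomics import mgf

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
    "read_features",
    "write_features",
    "read_ms2_mgf",
    "write_ms2_mgf",
]


def read_matrix(path) -> pd.DataFrame:
    """Genes x samples TSV -> DataFrame indexed by gene_id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis(index="gene_id").to_csv(path, sep="\t")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False)


def write_ms2_mgf(spectra: dict[str, list[tuple[float, float]]], path,
                  precursor_mz: dict[str, float] | None = None) -> None:
    """Write precursor-id -> peak-list spectra as MGF (TITLE = feature id)."""
    entries = []
    for fid, peaks in spectra.items():
        peaks = sorted(peaks)
        entries.append(
            {
                "m/z array": np.asarray([p[0] for p in peaks]),
                "intensity array": np.asarray([p[1] for p in peaks]),
                "params": {
                    "title": fid,
                    "pepmass": (precursor_mz or {}).get(fid, 0.0) or 0.0,
                },
            }
        )
    mgf.write(entries, str(path), file_mode="w")


def read_ms2_mgf(path) -> dict[str, list[tuple[float, float]]]:
    """MGF -> precursor-id (TITLE) -> [(fragment mz, intensity), ...]."""
    spectra: dict[str, list[tuple[float, float]]] = {}
    with mgf.MGF(str(path)) as reader:
        for entry in reader:
            title = str(entry["params"]["title"])
            spectra[title] = list(
                zip(map(float, entry["m/z array"]), map(float, entry["intensity array"]))
            )
    return spectra
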
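"""Readers and writers for the plain-text formats used by the pipeline.

Feature tables use the MZmine aligned-export CSV dialect ("row ID",
"row m/z", "row retention time", then one "<sample> Peak area" column per
sample). MS/MS spectra use MGF via pyteomics. Metadata and ground-truth
tables are TSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .containers import FeatureTable, IncidenceMatrix
from .errors import MalformedMGFError, MalformedTableError

_PEAK_AREA_SUFFIX = " Peak area"

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_incidence",
    "write_incidence",
    "read_mgf",
    "write_mgf",
]


def read_feature_table(path) -> FeatureTable:
    """Read an MZmine-style aligned feature table CSV.

    Sample columns are recognized by the `` Peak area`` suffix; missing
    areas are read as zero. Duplicate (m/z, rt) rows or non-numeric areas
    raise :class:`~npdiv.errors.MalformedTableError`.
    """
    raw = pd.read_csv(path)
    for col in ("row m/z", "row retention time"):
        if col not in raw.columns:
            raise MalformedTableError(f"missing required column {col!r}")
    sample_cols = [c for c in raw.columns if c.endswith(_PEAK_AREA_SUFFIX)]
    if not sample_cols:
        raise MalformedTableError("no '<sample> Peak area' columns found")
    if "row ID" in raw.columns:
        index = pd.Index(raw["row ID"].astype(str), name="feature_id")
    else:
        index = pd.Index([f"F{i + 1:05d}" for i in range(len(raw))], name="feature_id")
    try:
        areas = raw[sample_cols].apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise MalformedTableError(f"non-numeric peak area: {exc}") from exc
    areas = areas.fillna(0.0).astype(float)
    areas.index = index
    areas.columns = [c[: -len(_PEAK_AREA_SUFFIX)] for c in sample_cols]
    mz = pd.Series(raw["row m/z"].to_numpy(float), index=index, name="mz")
    rt = pd.Series(raw["row retention time"].to_numpy(float), index=index, name="rt")
    return FeatureTable(areas, mz, rt)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table in the MZmine aligned-export CSV dialect."""
    meta = pd.DataFrame(
        {
            "row ID": table.feature_ids,
            "row m/z": table.mz.to_numpy(),
            "row retention time": table.rt.to_numpy(),
        }
    )
    areas = table.abundances.rename(
        columns={s: f"{s}{_PEAK_AREA_SUFFIX}" for s in table.samples}
    ).reset_index(drop=True)
    pd.concat([meta, areas], axis=1).to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV indexed by sample_id.

    Expected columns: sample_id, isolate_id, clade, replicate, is_blank,
    and optional lon/lat.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "isolate_id": str})
    required = {"sample_id", "isolate_id", "is_blank"}
    missing = required - set(meta.columns)
    if missing:
        raise MalformedTableError(f"metadata missing columns: {sorted(missing)}")
    meta["is_blank"] = meta["is_blank"].astype(bool)
    if "clade" in meta.columns:
        meta["clade"] = meta["clade"].fillna("")
    return meta.set_index("sample_id", drop=False)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def check_samples_covered(table: FeatureTable, metadata: pd.DataFrame) -> None:
    """Every feature-table column must have exactly one metadata row."""
    missing = table.samples.difference(metadata.index)
    if len(missing):
        raise MalformedTableError(f"samples absent from metadata: {sorted(missing)[:5]}")


def read_incidence(path, groups: pd.Series | None = None) -> IncidenceMatrix:
    presence = pd.read_csv(path, index_col=0)
    return IncidenceMatrix(presence, groups)


def write_incidence(incidence: IncidenceMatrix, path) -> None:
    incidence.presence.to_csv(path)


def read_mgf(path) -> list:
    """Read MS/MS spectra from an MGF file.

    Each block must carry PEPMASS and a FEATURE_ID; peaks are returned
    sorted by fragment m/z. Returns a list of
    :class:`~npdiv.scaffolds.Spectrum`.
    """
    from .scaffolds import Spectrum  # deferred to avoid an import cycle

    spectra = []
    path = Path(path)
    if path.stat().st_size == 0:
        return spectra
    with _mgf.MGF(str(path)) as reader:
        for block in reader:
            params = block["params"]
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise MalformedMGFError("MGF block without PEPMASS")
            feature_id = str(
                params.get("feature_id") or params.get("title") or len(spectra) + 1
            )
            spectra.append(
                Spectrum(
                    feature_id=feature_id,
                    precursor_mz=float(params["pepmass"][0]),
                    mz=np.asarray(block["m/z array"], dtype=float),
                    intensity=np.asarray(block["intensity array"], dtype=float),
                )
            )
    return spectra


def write_mgf(spectra: Sequence, path) -> None:
    """Write spectra to MGF with PEPMASS and FEATURE_ID per block."""
    entries = []
    for spectrum in spectra:
        entries.append(
            {
                "m/z array": spectrum.mz,
                "intensity array": spectrum.intensity,
                "params": {
                    "feature_id": spectrum.feature_id,
                    "pepmass": spectrum.precursor_mz,
                    "title": spectrum.feature_id,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def match_spectra_to_table(spectra: Iterable, table: FeatureTable) -> list:
    """Warn about spectra whose FEATURE_ID is absent from the table.

    Unmatched spectra are kept as orphans (they become singleton
    scaffolds downstream)."""
    known = set(map(str, table.feature_ids))
    orphans = [s.feature_id for s in spectra if s.feature_id not in known]
    if orphans:
        warnings.warn(
            f"{len(orphans)} spectra have feature IDs absent from the table "
            f"(kept as orphans): {orphans[:5]}",
            stacklevel=2,
        )
    return list(spectra)
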
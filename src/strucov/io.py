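"""Tabular input/output: volume tables, phenotype tables, FreeSurfer stats.

Canonical interchange format is tab-delimited UTF-8 text with ``.`` decimals.
A volume table has a ``subject_id`` column followed by one column per ROI
(gray-matter volume, mm^3); a phenotype table has ``subject_id``, ``age``,
``iq``, ``icv`` and the five RBS-R subscale raw scores.  Missing values are
not supported: the analyses assume a complete-case sample, so any blank or
non-finite cell is an error, never imputed.

A convenience importer for single-subject FreeSurfer outputs (aseg.stats and
the two aparc.stats files) is provided; it is not the canonical path.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, SchemaError, ValidationError
from .roi import ROIScheme, SchemeMode, freesurfer_label_map, load_scheme

#: RBS-R subscale column names, fixed order.
SUBSCALES = (
    "insistence_on_sameness",
    "stereotyped",
    "self_injury",
    "compulsive",
    "ritualistic",
)

PHENOTYPE_COLUMNS = ("age", "iq", "icv") + SUBSCALES


@dataclass
class CohortTable:
    """Per-subject phenotypes: age (years), full-scale IQ, ICV (mm^3) and the
    five RBS-R subscale raw scores.

    ``data`` is indexed by subject id with columns in ``PHENOTYPE_COLUMNS``
    order.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"phenotype table missing columns: {missing}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate subject ids: {dupes}")
        self.data = self.data.loc[:, list(PHENOTYPE_COLUMNS)]
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("phenotype table contains missing/non-finite cells")
        for col in ("age", "iq", "icv"):
            if (self.data[col] <= 0).any():
                bad = self.data.index[self.data[col] <= 0][0]
                raise ValidationError(f"non-positive {col} for subject {bad!r}")
        for col in SUBSCALES:
            s = self.data[col]
            if (s < 0).any():
                bad = self.data.index[s < 0][0]
                raise ValidationError(f"negative {col} score for subject {bad!r}")
            if not np.allclose(s, np.round(s)):
                bad = self.data.index[~np.isclose(s, np.round(s))][0]
                raise ValidationError(
                    f"{col} score for subject {bad!r} is not an integer raw score"
                )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    def subscale(self, name: str) -> np.ndarray:
        if name not in SUBSCALES:
            raise SchemaError(f"unknown RBS-R subscale {name!r}")
        return self.data[name].to_numpy(dtype=float)

    def covariates(self) -> np.ndarray:
        """The nuisance covariate matrix (age, IQ, ICV), subjects x 3."""
        return self.data[["age", "iq", "icv"]].to_numpy(dtype=float)


@dataclass
class VolumeTable:
    """Subjects x ROI gray-matter volumes (mm^3) with their ROI scheme.

    ``data`` is indexed by subject id; columns follow canonical scheme order.
    """

    data: pd.DataFrame
    scheme: ROIScheme = field(default_factory=load_scheme)

    def __post_init__(self) -> None:
        want = self.scheme.names
        missing = [c for c in want if c not in self.data.columns]
        if missing:
            raise SchemaError(f"volume table missing ROI columns: {missing}")
        extra = [c for c in self.data.columns if c not in want]
        if extra:
            raise SchemaError(f"volume table has unknown ROI columns: {extra}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate subject ids: {dupes}")
        self.data = self.data.loc[:, want]
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite volume at subject {self.data.index[r]!r}, ROI {want[c]!r}"
            )
        if (vals <= 0).any():
            r, c = np.argwhere(vals <= 0)[0]
            raise ValidationError(
                f"non-positive volume at subject {self.data.index[r]!r}, ROI {want[c]!r}"
            )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    def matrix(self, rois: list[str] | None = None) -> np.ndarray:
        """Volumes as a float array, optionally restricted to ``rois``."""
        df = self.data if rois is None else self.data.loc[:, list(rois)]
        return df.to_numpy(dtype=float)

    def subset_subjects(self, subject_ids: list[str]) -> "VolumeTable":
        return VolumeTable(self.data.loc[list(subject_ids)].copy(), self.scheme)


def lateralized_to_bilateral(table: VolumeTable) -> VolumeTable:
    """Average left/right subcortical volumes into bilateral structures.

    Cortical parcels stay lateralized; only the 14 subcortical columns
    collapse to 7.
    """
    if table.scheme.mode != "lateralized14":
        raise SchemaError("bilateral derivation requires a lateralized14 table")
    target = load_scheme("bilateral7")
    out = pd.DataFrame(index=table.data.index)
    for name in target.subcortical_names:
        out[name] = table.data[[f"{name}_left", f"{name}_right"]].mean(axis=1)
    for name in target.cortical_names:
        out[name] = table.data[name]
    return VolumeTable(out, target)


def read_volume_table(path: str | Path, scheme_mode: SchemeMode = "bilateral7") -> VolumeTable:
    """Read a TSV volume table, reordering columns to canonical scheme order.

    A ``bilateral7`` table may be derived from a lateralized file: if the file
    carries the 14 per-hemisphere subcortical columns, left/right volumes are
    averaged per structure.
    """
    df = _read_tsv(path)
    scheme = load_scheme(scheme_mode)
    if scheme_mode == "bilateral7" and not set(scheme.subcortical_names) <= set(df.columns):
        lat = load_scheme("lateralized14")
        if set(lat.names) <= set(df.columns):
            return lateralized_to_bilateral(VolumeTable(df, lat))
    return VolumeTable(df, scheme)


def write_volume_table(table: VolumeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="subject_id")


def read_phenotypes(path: str | Path) -> CohortTable:
    """Read a TSV phenotype table into a validated :class:`CohortTable`."""
    return CohortTable(_read_tsv(path))


def write_phenotypes(cohort: CohortTable, path: str | Path) -> None:
    cohort.data.to_csv(path, sep="\t", index_label="subject_id")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps write->read->write byte-identical
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str}, float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise SchemaError(f"{path}: first column must be 'subject_id'")
    df = df.set_index("subject_id")
    if df.isna().any().any():
        raise ValidationError(f"{path}: blank cells are not supported")
    return df


# ---------------------------------------------------------------------------
# FreeSurfer stats dialect (single-subject convenience importer)
# ---------------------------------------------------------------------------

_ETIV_RE = re.compile(
    r"^#\s*Measure\s+EstimatedTotalIntraCranialVol\s*,.*,\s*([0-9.eE+-]+)\s*,\s*mm"
)


def _parse_stats_body(path: Path, value_col: str) -> dict[str, float]:
    """Parse the whitespace-delimited body of a FreeSurfer stats file.

    Column positions come from the ``# ColHeaders`` line; comment lines start
    with ``#``.  Returns StructName -> value of ``value_col``.
    """
    headers: list[str] | None = None
    rows: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "ColHeaders" in line:
                headers = line.split()[2:]
            continue
        if not line.strip():
            continue
        if headers is None:
            raise FormatError(f"{path}: data row before ColHeaders line")
        parts = line.split()
        if len(parts) != len(headers):
            raise FormatError(f"{path}: row has {len(parts)} fields, expected {len(headers)}")
        rec = dict(zip(headers, parts))
        if value_col not in rec or "StructName" not in rec:
            raise FormatError(f"{path}: missing {value_col} or StructName column")
        try:
            rows[rec["StructName"]] = float(rec[value_col])
        except ValueError as exc:
            raise FormatError(f"{path}: unparsable {value_col} in row {line!r}") from exc
    return rows


def _parse_etiv(path: Path) -> float:
    for line in Path(path).read_text().splitlines():
        m = _ETIV_RE.match(line)
        if m:
            try:
                return float(m.group(1))
            except ValueError as exc:
                raise FormatError(f"{path}: unparsable eTIV measure line") from exc
    raise FormatError(f"{path}: no EstimatedTotalIntraCranialVol measure line")


def read_freesurfer_stats(
    aseg_path: str | Path,
    aparc_lh_path: str | Path,
    aparc_rh_path: str | Path,
) -> dict[str, float]:
    """Read one subject's ROI volumes from FreeSurfer stats outputs.

    Returns a flat mapping with the 14 lateralized subcortical volumes
    (``Volume_mm3`` from aseg.stats), the 68 cortical parcel volumes
    (``GrayVol`` from the two aparc.stats files) and the ICV estimate under
    key ``"icv"`` (the eTIV measure header in aseg.stats).
    """
    labels = freesurfer_label_map()
    aseg = _parse_stats_body(Path(aseg_path), "Volume_mm3")
    lh = _parse_stats_body(Path(aparc_lh_path), "GrayVol")
    rh = _parse_stats_body(Path(aparc_rh_path), "GrayVol")
    scheme = load_scheme("lateralized14")
    out: dict[str, float] = {}
    for roi in scheme.rois:
        fs = labels[roi.name]
        if roi.tissue_class == "subcortical":
            source, where = aseg, "aseg"
        elif roi.hemisphere == "left":
            source, where = lh, "lh aparc"
        else:
            source, where = rh, "rh aparc"
        if fs not in source:
            raise FormatError(f"structure {fs!r} absent from {where} stats file")
        out[roi.name] = source[fs]
    out["icv"] = _parse_etiv(Path(aseg_path))
    return out
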
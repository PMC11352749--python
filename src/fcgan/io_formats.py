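"""Readers and writers for the pipeline's on-disk formats.

Three plain-text formats are handled:

* ROI time-series matrices — one file per subject, rows = timepoints,
  columns = regions, whitespace- or comma-delimited (the dialect of the
  ABIDE-preprocessed AAL ``.1D`` extracts), with an optional single header
  row of region labels;
* phenotype tables — CSV with subject ID, acquisition site and diagnosis
  code columns (default code mapping 1 → ASD, 2 → HC);
* feature tables — CSV with columns ``subject_id, site, label, f0001…fNNNN``
  holding one fixed-length connectivity vector per subject.

Site labels are treated as opaque strings and never normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ASD = "ASD"
HC = "HC"
LABELS = (HC, ASD)  # index = integer code used internally (HC=0, ASD=1)
LABEL_TO_INT = {HC: 0, ASD: 1}
SYNTH_SITE = "SYNTH"

DEFAULT_DX_MAP = {1: ASD, 2: HC}


@dataclass(frozen=True)
class PhenotypeRecord:
    subject_id: str
    site_id: str
    dx_label: str  # ASD or HC

    def __post_init__(self):
        if self.dx_label not in LABELS:
            raise ValueError(f"dx_label must be one of {LABELS}, got {self.dx_label!r}")
        if not self.site_id:
            raise ValueError("site_id must be non-empty")


@dataclass
class RoiTimeSeries:
    """One subject's T×R matrix of regional BOLD-like signals."""

    subject_id: str
    values: np.ndarray  # shape (T, R)
    region_labels: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D matrix (timepoints × regions)")
        t, r = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if r < 2:
            raise ValueError(f"need at least 2 regions, got {r}")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite entries")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureTable:
    """Per-subject connectivity feature vectors with site and class labels."""

    subject_ids: list[str]
    sites: list[str]
    labels: list[str | None]
    values: np.ndarray  # shape (n_subjects, D)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        n = len(self.subject_ids)
        if not (len(self.sites) == len(self.labels) == n == self.values.shape[0]):
            raise ValueError("inconsistent row counts in feature table")

    def __len__(self) -> int:
        return len(self.subject_ids)

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (self.subject_ids == other.subject_ids
                and self.sites == other.sites
                and self.labels == other.labels
                and self.values.shape == other.values.shape
                and np.array_equal(self.values, other.values))

    def label_ints(self) -> np.ndarray:
        """Integer class codes (HC=0, ASD=1); raises if any label is absent."""
        if any(lab is None for lab in self.labels):
            raise ValueError("feature table has unlabelled rows")
        return np.array([LABEL_TO_INT[lab] for lab in self.labels], dtype=np.int64)

    def select(self, indices) -> "FeatureTable":
        idx = np.asarray(indices)
        return FeatureTable(
            subject_ids=[self.subject_ids[i] for i in idx],
            sites=[self.sites[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            values=self.values[idx],
        )

    def subset_by_ids(self, ids) -> "FeatureTable":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        return self.select([pos[s] for s in ids])

    @staticmethod
    def concatenate(tables: list["FeatureTable"]) -> "FeatureTable":
        dims = {t.dim for t in tables}
        if len(dims) > 1:
            raise ValueError(f"feature width mismatch across tables: {sorted(dims)}")
        return FeatureTable(
            subject_ids=[s for t in tables for s in t.subject_ids],
            sites=[s for t in tables for s in t.sites],
            labels=[s for t in tables for s in t.labels],
            values=np.vstack([t.values for t in tables]),
        )


# ---------------------------------------------------------------------------
# ROI time series
# ---------------------------------------------------------------------------

def _sniff_delimiter(line: str) -> str | None:
    """Comma if the first data line contains one, otherwise whitespace."""
    return "," if "," in line else None  # None → any whitespace for str.split


def read_roi_timeseries(path, subject_id: str | None = None,
                        delimiter: str | None = "auto") -> RoiTimeSeries:
    """Parse one subject's ROI time-series matrix from a text file.

    Rows are timepoints, columns are regions. A single leading header row of
    region labels is detected by its first token being non-numeric. Ragged
    rows raise rather than truncate.
    """
    path = Path(path)
    raw = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not raw:
        raise ValueError(f"{path}: empty file")
    sep = _sniff_delimiter(raw[0]) if delimiter == "auto" else delimiter
    rows = [ln.split(sep) for ln in raw]
    rows = [[tok.strip() for tok in row if tok.strip() != ""] for row in rows]

    region_labels = None
    try:
        float(rows[0][0])
    except ValueError:
        region_labels = rows[0]
        rows = rows[1:]

    if len(rows) < 3:
        raise ValueError(f"{path}: fewer than 3 timepoint rows")
    width = len(rows[0])
    data = np.empty((len(rows), width))
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged row {i + 1 + (region_labels is not None)} "
                f"has {len(row)} values, expected {width}")
        for j, tok in enumerate(row):
            try:
                data[i, j] = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {tok!r} at row {i + 1}, "
                    f"column {j + 1}") from None
    if region_labels is not None and len(region_labels) != width:
        raise ValueError(f"{path}: header has {len(region_labels)} labels for "
                         f"{width} columns")
    return RoiTimeSeries(subject_id=subject_id or path.stem, values=data,
                         region_labels=region_labels)


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

def read_phenotype(path,
                   subject_col: str = "subject_id",
                   site_col: str = "site_id",
                   dx_col: str = "dx",
                   dx_map: dict | None = None) -> list[PhenotypeRecord]:
    """Load phenotype records, mapping diagnosis codes to {ASD, HC}.

    Rows whose diagnosis code is absent from the mapping are dropped with a
    logged count. Duplicate subject IDs raise.
    """
    dx_map = DEFAULT_DX_MAP if dx_map is None else dx_map
    df = pd.read_csv(path, dtype=str)
    if df.empty and not set(df.columns):
        logger.warning("phenotype file %s is empty", path)
        return []
    missing = [c for c in (subject_col, site_col, dx_col) if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing column(s): {missing}")

    # accept either raw codes (possibly numeric strings) or label strings
    normalized_map = {str(k): v for k, v in dx_map.items()}
    normalized_map.update({ASD: ASD, HC: HC})

    records: list[PhenotypeRecord] = []
    seen: set[str] = set()
    n_unknown = 0
    for _, row in df.iterrows():
        sid = str(row[subject_col])
        code = str(row[dx_col]).strip()
        # "1.0" and "1" both map to code 1
        if code.endswith(".0"):
            code = code[:-2]
        label = normalized_map.get(code)
        if label is None:
            n_unknown += 1
            continue
        if sid in seen:
            raise ValueError(f"duplicate subject_id {sid!r} in phenotype table")
        seen.add(sid)
        records.append(PhenotypeRecord(sid, str(row[site_col]), label))
    if n_unknown:
        logger.warning("excluded %d phenotype row(s) with unmapped diagnosis codes",
                       n_unknown)
    if not records:
        logger.warning("phenotype file %s yielded no records", path)
    return records


# ---------------------------------------------------------------------------
# Feature table CSV
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path) -> None:
    path = Path(path)
    cols = [f"f{i + 1:04d}" for i in range(table.dim)]
    df = pd.DataFrame(table.values, columns=cols)
    df.insert(0, "label", [lab if lab is not None else "" for lab in table.labels])
    df.insert(0, "site", table.sites)
    df.insert(0, "subject_id", table.subject_ids)
    # repr-roundtrip float formatting keeps read(write(t)) bit-exact
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, dtype={"subject_id": str, "site": str, "label": str},
                     keep_default_na=False, float_precision="round_trip")
    meta_cols = ["subject_id", "site", "label"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {missing}")
    feat_cols = [c for c in df.columns if c not in meta_cols]
    expected = [f"f{i + 1:04d}" for i in range(len(feat_cols))]
    if feat_cols != expected:
        raise ValueError("feature columns are not a contiguous f0001…fNNNN block")
    values = df[feat_cols].to_numpy(dtype=np.float64)
    labels = [lab if lab != "" else None for lab in df["label"]]
    return FeatureTable(subject_ids=list(df["subject_id"]), sites=list(df["site"]),
                        labels=labels, values=values)
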
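"""Pearson functional-connectivity features.

Each subject's T×R regional time-series matrix is reduced to the symmetric
R×R matrix of pairwise Pearson correlations, and that matrix to its
strictly-upper-triangle vector of length R(R−1)/2 — 6670 values for the
116-region AAL parcellation. The vectorization makes subjects with
different scan lengths comparable with a single fixed-length feature
vector, which is what the downstream generative and classification models
consume.

Conventions: the diagonal is forced to 1 (including zero-variance regions);
a zero-variance series yields r = 0 with a logged warning, never NaN; the
upper triangle is flattened in row-major (i, j) order with i < j, 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import FeatureTable, PhenotypeRecord, RoiTimeSeries

logger = logging.getLogger(__name__)

DEGENERATE_R = 0.0  # correlation reported for a zero-variance series


@dataclass
class ConnectivityMatrix:
    subject_id: str
    matrix: np.ndarray  # R×R, symmetric, unit diagonal

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("connectivity matrix must be square")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


def pearson_r(x, y, degenerate_value: float = DEGENERATE_R) -> float:
    r"""Pearson product-moment correlation of two equal-length series.

    r = Σ(x_i − x̄)(y_i − ȳ) / sqrt( Σ(x_i − x̄)² · Σ(y_i − ȳ)² )

    Symmetric in its arguments and invariant to positive affine rescaling.
    If either series has zero variance the correlation is undefined; the
    configured degenerate value (default 0, "no linear coupling") is
    returned with a warning instead of NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        logger.warning("zero-variance series in pearson_r; returning %g",
                       degenerate_value)
        return degenerate_value
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def connectivity_matrix(ts: RoiTimeSeries,
                        degenerate_value: float = DEGENERATE_R) -> ConnectivityMatrix:
    """All-pairs Pearson correlation of a subject's regional series.

    Computed vectorized on centered, unit-norm columns; zero-variance
    regions get r = 0 against every other region (diagonal still 1).
    """
    x = ts.values
    xc = x - x.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(xc, axis=0)
    degenerate = norms == 0.0
    if degenerate.any():
        logger.warning("subject %s: %d zero-variance region(s); correlations "
                       "set to %g", ts.subject_id, int(degenerate.sum()),
                       degenerate_value)
    safe = np.where(degenerate, 1.0, norms)
    unit = xc / safe
    cm = unit.T @ unit
    cm = np.clip(cm, -1.0, 1.0)
    cm[degenerate, :] = degenerate_value
    cm[:, degenerate] = degenerate_value
    cm = (cm + cm.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(cm, 1.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, matrix=cm)


def vectorize_upper(cm: ConnectivityMatrix) -> np.ndarray:
    """Strictly-upper-triangle entries in row-major (i<j) order.

    Length R(R−1)/2 — the fixed-length connectivity feature vector.
    """
    r = cm.n_regions
    iu = np.triu_indices(r, k=1)
    return cm.matrix[iu].copy()


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def edge_index(i: int, j: int, n_regions: int) -> int:
    """Position of region pair (i, j), i<j, in the upper-triangle vector."""
    if not 0 <= i < j < n_regions:
        raise ValueError(f"require 0 <= i < j < R, got i={i}, j={j}, R={n_regions}")
    return i * n_regions - i * (i + 1) // 2 + (j - i - 1)


def edge_pair(index: int, n_regions: int) -> tuple[int, int]:
    """Inverse of :func:`edge_index`."""
    if not 0 <= index < n_edges(n_regions):
        raise ValueError(f"edge index {index} out of range for R={n_regions}")
    i = 0
    offset = index
    row_len = n_regions - 1
    while offset >= row_len:
        offset -= row_len
        i += 1
        row_len -= 1
    return i, i + 1 + offset


def extract_features(timeseries: list[RoiTimeSeries],
                     phenotype: list[PhenotypeRecord]) -> FeatureTable:
    """Vectorized FC features for a cohort, joined with phenotype labels.

    Subjects keep the order of `timeseries`; every subject must appear in
    the phenotype table and all subjects must share the same region count.
    """
    pheno = {rec.subject_id: rec for rec in phenotype}
    n_regions = {ts.n_regions for ts in timeseries}
    if len(n_regions) > 1:
        raise ValueError(f"region count differs across subjects: {sorted(n_regions)}")
    rows, sids, sites, labels = [], [], [], []
    for ts in timeseries:
        rec = pheno.get(ts.subject_id)
        if rec is None:
            raise ValueError(f"subject {ts.subject_id!r} missing from phenotype table")
        rows.append(vectorize_upper(connectivity_matrix(ts)))
        sids.append(ts.subject_id)
        sites.append(rec.site_id)
        labels.append(rec.dx_label)
    return FeatureTable(subject_ids=sids, sites=sites, labels=labels,
                        values=np.vstack(rows))
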
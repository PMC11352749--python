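"""Synthetic multi-site cohorts with a planted connectivity difference.

The generator emulates the structural features of a multi-site resting
state cohort that the pipeline must cope with: several acquisition sites
with unequal ASD/HC counts, per-subject scan lengths T that vary within and
across sites, and a between-class signal that lives purely in correlation
structure (not in region means) — which is exactly what Pearson
connectivity features can detect.

Each subject's series is drawn from a zero-mean multivariate normal whose
correlation matrix is the class target: a uniform background correlation
for controls, plus a shift Δr on a configured set of planted region pairs
for the ASD class. Targets that lose positive semi-definiteness are
repaired by eigenvalue clipping with re-normalization to unit diagonal.

It makes no attempt at BOLD realism (no hemodynamics, autocorrelation or
scanner noise), so results on these cohorts demonstrate pipeline
correctness and signal recovery, not clinical performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import edge_index, n_edges
from .io_formats import ASD, HC, FeatureTable, PhenotypeRecord, RoiTimeSeries

logger = logging.getLogger(__name__)

#: default planted region pairs for a 16-region fixture: eight disjoint
#: pairs plus two overlapping ones
DEFAULT_PLANTED_EDGES = ((0, 1), (2, 3), (4, 5), (6, 7), (8, 9), (10, 11),
                         (12, 13), (14, 15), (0, 8), (4, 12))

#: the 17-site cohort composition used for split-protocol testing:
#: (site, n_ASD, n_HC), totalling 408 ASD + 476 HC = 884 subjects
MULTI_SITE_COHORT = (
    ("CALTECH", 19, 18), ("CMU", 3, 2), ("KKU", 12, 27), ("LEUVEN", 27, 34),
    ("MAXMUN", 18, 24), ("NYU", 73, 98), ("OHSU", 12, 11), ("OLIN", 14, 11),
    ("PITT", 22, 23), ("SBL", 14, 12), ("SDSU", 12, 21), ("STANFORD", 17, 19),
    ("TRINITY", 21, 23), ("UCLA", 36, 39), ("UM", 48, 65), ("USM", 38, 23),
    ("YALE", 22, 26),
)


@dataclass(frozen=True)
class FixtureConfig:
    regions: int = 16
    sites: tuple[tuple[str, int, int], ...] = (("A", 80, 80), ("B", 60, 60),
                                               ("C", 40, 40), ("D", 20, 20))
    timepoints: tuple[int, int] = (80, 120)
    planted_edges: tuple[tuple[int, int], ...] = DEFAULT_PLANTED_EDGES
    effect: float = 0.4           # Δr added on planted edges in the ASD class
    base_correlation: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for i, j in self.planted_edges:
            if not 0 <= i < j < self.regions:
                raise ValueError(f"invalid planted edge ({i}, {j}) for "
                                 f"R={self.regions}")
        if not 0.0 <= self.effect < 1.0:
            raise ValueError("effect must be in [0, 1)")
        if self.timepoints[0] > self.timepoints[1] or self.timepoints[0] < 3:
            raise ValueError("timepoints range must satisfy 3 <= T_min <= T_max")

    def n_subjects(self) -> int:
        return sum(a + h for _, a, h in self.sites)


def _nearest_correlation(mat: np.ndarray, min_eig: float = 1e-6,
                         max_shift: float = 0.5) -> np.ndarray:
    """Eigenvalue-clip `mat` to PSD and renormalize to unit diagonal."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() >= min_eig:
        return mat
    if vals.min() < -max_shift:
        raise ValueError(f"target correlation matrix too indefinite "
                         f"(min eigenvalue {vals.min():.3f})")
    logger.warning("repairing non-PSD target correlation (min eigenvalue %.4f)",
                   vals.min())
    repaired = (vecs * np.clip(vals, min_eig, None)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def target_correlations(config: FixtureConfig) -> dict[str, np.ndarray]:
    """Per-class target correlation matrices {HC: base, ASD: base + Δr}."""
    r = config.regions
    base = np.full((r, r), config.base_correlation)
    np.fill_diagonal(base, 1.0)
    shifted = base.copy()
    for i, j in config.planted_edges:
        shifted[i, j] += config.effect
        shifted[j, i] += config.effect
    return {HC: _nearest_correlation(base),
            ASD: _nearest_correlation(np.clip(shifted, -1.0, 1.0))}


def make_dataset(config: FixtureConfig) -> tuple[list[RoiTimeSeries],
                                                 list[PhenotypeRecord]]:
    """Sample a full multi-site cohort of ROI time series plus phenotypes.

    Per subject: T drawn uniformly from the site's timepoint range, then T
    observations from N(0, Σ_class). Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    targets = target_correlations(config)
    chol = {lab: np.linalg.cholesky(m) for lab, m in targets.items()}
    tmin, tmax = config.timepoints
    series, pheno = [], []
    for site, n_asd, n_hc in config.sites:
        for label, count in ((ASD, n_asd), (HC, n_hc)):
            for k in range(count):
                sid = f"{site}_{label}_{k:03d}"
                t = int(rng.integers(tmin, tmax + 1))
                x = rng.standard_normal((t, config.regions)) @ chol[label].T
                series.append(RoiTimeSeries(subject_id=sid, values=x))
                pheno.append(PhenotypeRecord(sid, site, label))
    return series, pheno


def make_feature_fixture(config: FixtureConfig,
                         noise_sigma: float = 0.1) -> FeatureTable:
    """Fast path: plant the class shift directly on feature vectors.

    Skips the time-series stage. Every vector is the background correlation
    level plus Gaussian noise; ASD rows additionally carry +Δr on the
    planted edge coordinates. Entries are clipped to [−1, 1].
    """
    rng = np.random.default_rng(config.seed)
    d = n_edges(config.regions)
    planted_idx = np.array([edge_index(i, j, config.regions)
                            for i, j in config.planted_edges])
    base = np.full(d, config.base_correlation)
    sids, sites, labels, rows = [], [], [], []
    for site, n_asd, n_hc in config.sites:
        for label, count in ((ASD, n_asd), (HC, n_hc)):
            for k in range(count):
                vec = base + rng.normal(0.0, noise_sigma, size=d)
                if label == ASD:
                    vec[planted_idx] += config.effect
                sids.append(f"{site}_{label}_{k:03d}")
                sites.append(site)
                labels.append(label)
                rows.append(np.clip(vec, -1.0, 1.0))
    return FeatureTable(subject_ids=sids, sites=sites, labels=labels,
                        values=np.vstack(rows))


def write_dataset(series: list[RoiTimeSeries], pheno: list[PhenotypeRecord],
                  out_dir) -> None:
    """Write ROI files and a phenotype CSV in the formats the loaders read."""
    from pathlib import Path

    import pandas as pd

    out = Path(out_dir)
    roi_dir = out / "roi"
    roi_dir.mkdir(parents=True, exist_ok=True)
    for ts in series:
        np.savetxt(roi_dir / f"{ts.subject_id}.1D", ts.values, fmt="%.10g")
    pd.DataFrame(
        {"subject_id": [p.subject_id for p in pheno],
         "site_id": [p.site_id for p in pheno],
         "dx": [1 if p.dx_label == ASD else 2 for p in pheno]}
    ).to_csv(out / "phenotype.csv", index=False)
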
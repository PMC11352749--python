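"""Site- and class-stratified partitioning.

Multi-site cohorts have wildly unequal per-site class counts (one site may
hold over a hundred subjects, another fewer than ten), so unstratified
splitting can leave a small site entirely out of training. All partitions
here therefore stratify jointly on the (site, class) pair:

* holdout — per-stratum random split at a given test fraction,
* k-fold — per-stratum round-robin assignment after a seeded shuffle
  (fold sizes within each stratum differ by at most one),
* leave-site-out — train on one site (NYU by default) and test on each
  remaining site separately, with a configurable exclusion list.

Plans are deterministic given the seed and serializable to JSON.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import FeatureTable

logger = logging.getLogger(__name__)

TRAIN = "train"
TEST = "test"


@dataclass
class SplitPlan:
    """Assignment of every subject to a fold ('train'/'test' or an integer)."""

    assignments: dict[str, object]  # subject_id -> TRAIN/TEST, fold int, or site key
    seed: int | None
    kind: str  # holdout | kfold | leave-site
    strata: dict[str, int] = field(default_factory=dict)  # "site|label" -> count

    def members(self, fold) -> list[str]:
        return [sid for sid, f in self.assignments.items() if f == fold]

    def folds(self) -> list:
        seen = []
        for f in self.assignments.values():
            if f not in seen:
                seen.append(f)
        return seen

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"kind": self.kind, "seed": self.seed, "strata": self.strata,
             "assignments": self.assignments}, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(assignments=d["assignments"], seed=d["seed"], kind=d["kind"],
                   strata=d.get("strata", {}))


def _strata(table: FeatureTable) -> dict[tuple[str, str], list[int]]:
    groups: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, (site, label) in enumerate(zip(table.sites, table.labels)):
        if label is None:
            raise ValueError(f"subject {table.subject_ids[i]!r} has no class label")
        groups[(site, label)].append(i)
    return groups


def stratified_split(table: FeatureTable, test_fraction: float,
                     seed: int) -> SplitPlan:
    """Random train/test split preserving every (site, class) stratum.

    Within a stratum of size n the test count is round-half-up of
    n·test_fraction, capped so that at least one subject stays in training
    whenever n ≥ 2; singleton strata go to training with a warning.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    assignments: dict[str, str] = {}
    strata_counts: dict[str, int] = {}
    for (site, label), idx in sorted(_strata(table).items()):
        strata_counts[f"{site}|{label}"] = len(idx)
        n = len(idx)
        if n == 1:
            logger.warning("stratum (%s, %s) has a single subject; kept in train",
                           site, label)
            assignments[table.subject_ids[idx[0]]] = TRAIN
            continue
        n_test = int(np.floor(test_fraction * n + 0.5))
        n_test = min(n_test, n - 1)  # >=1 train member
        order = rng.permutation(n)
        for rank, pos in enumerate(order):
            assignments[table.subject_ids[idx[pos]]] = (
                TEST if rank < n_test else TRAIN)
    return SplitPlan(assignments=assignments, seed=seed, kind="holdout",
                     strata=strata_counts)


def stratified_kfold(table: FeatureTable, k: int = 10,
                     seed: int = 0) -> SplitPlan:
    """k disjoint folds with per-(site, class) counts differing by ≤ 1."""
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    strata_counts: dict[str, int] = {}
    for (site, label), idx in sorted(_strata(table).items()):
        strata_counts[f"{site}|{label}"] = len(idx)
        if len(idx) < k:
            logger.warning("stratum (%s, %s) has %d subject(s) < k=%d; some "
                           "folds will lack it", site, label, len(idx), k)
        order = rng.permutation(len(idx))
        start = int(rng.integers(k))  # rotate so small strata spread across folds
        for rank, pos in enumerate(order):
            assignments[table.subject_ids[idx[pos]]] = (start + rank) % k
    return SplitPlan(assignments=assignments, seed=seed, kind="kfold",
                     strata=strata_counts)


def leave_site_protocol(table: FeatureTable, train_site: str = "NYU",
                        excluded_sites: tuple[str, ...] = ("CMU",)) -> SplitPlan:
    """Train on one site; one test group per remaining non-excluded site."""
    sites = set(table.sites)
    if train_site not in sites:
        raise ValueError(f"train site {train_site!r} not present in table")
    assignments: dict[str, str] = {}
    for sid, site in zip(table.subject_ids, table.sites):
        if site == train_site:
            assignments[sid] = TRAIN
        elif site in excluded_sites:
            assignments[sid] = "excluded"
        else:
            assignments[sid] = f"test:{site}"
    return SplitPlan(assignments=assignments, seed=None, kind="leave-site")


def held_out_sites(plan: SplitPlan) -> list[str]:
    """Site labels of the per-site test groups of a leave-site plan."""
    return sorted({f.split(":", 1)[1] for f in plan.assignments.values()
                   if isinstance(f, str) and f.startswith("test:")})
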
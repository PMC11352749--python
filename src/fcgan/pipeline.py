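"""End-to-end orchestration: features → split → AE → cGAN → classifier → report.

A run is described by a single :class:`RunConfig` (loadable from YAML) and
executed stage by stage into a run directory, every stage reading only
artifacts written by earlier stages. One global seed deterministically
derives a per-stage seed (CRC-32 of the stage name mixed into a numpy
``SeedSequence``), so re-running an identical config reproduces every
artifact checksum in the manifest.

Three evaluation protocols are supported — a stratified holdout split,
stratified 10-fold cross-validation, and leave-site-out (train on one
site, test on each remaining site) — and three model configurations: the
full pipeline (cGAN augmentation + attention classifier), "cgan_only"
(augmentation + plain MLP) and "mha_only" (attention classifier on real
data alone).

The default profile is desk-scale (layer widths at 1% of the full-scale
architecture, 300 epochs per stage) so a run completes in minutes on one
CPU; ``paper_profile`` switches a config to the full-scale settings
(scale 1, 5000 epochs per stage).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ae_fidelity, augment_cgan, classifier_mha, evaluation
from .ae_fidelity import AeSpec
from .augment_cgan import CganSpec
from .classifier_mha import MhaSpec, MlpSpec
from .features import extract_features
from .io_formats import (FeatureTable, read_feature_table, write_feature_table)
from .simulate import FixtureConfig, make_dataset, make_feature_fixture
from .splits import (held_out_sites, leave_site_protocol, stratified_kfold,
                     stratified_split)

logger = logging.getLogger(__name__)

PROTOCOLS = ("holdout", "kfold10", "leave-site")
ABLATIONS = ("full", "cgan_only", "mha_only")


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived deterministically from the global seed."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    out_dir: str = "run"
    fixture: FixtureConfig = field(default_factory=FixtureConfig)
    features_csv: str | None = None   # skip simulation, load features instead
    simulate_timeseries: bool = True  # False → plant shift on features directly
    protocol: str = "holdout"
    ablation: str = "full"
    test_fraction: float = 0.3
    kfolds: int = 10
    train_site: str = "NYU"
    excluded_sites: tuple[str, ...] = ("CMU",)
    n_synth_per_class: int = 1000
    ae_subset_fraction: float = 0.25
    heads: int = 10
    tokens: int = 1
    scale: float = 0.01
    ae_epochs: int = 300
    cgan_epochs: int = 300
    clf_epochs: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fixture_raw = raw.pop("fixture", {})
        if fixture_raw:
            fixture_raw["sites"] = tuple(tuple(s) for s in fixture_raw.get(
                "sites", FixtureConfig().sites))
            fixture_raw["planted_edges"] = tuple(tuple(e) for e in fixture_raw.get(
                "planted_edges", FixtureConfig().planted_edges))
            if "timepoints" in fixture_raw:
                fixture_raw["timepoints"] = tuple(fixture_raw["timepoints"])
        if "excluded_sites" in raw:
            raw["excluded_sites"] = tuple(raw["excluded_sites"])
        return cls(fixture=FixtureConfig(**fixture_raw), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def paper_profile(config: RunConfig) -> RunConfig:
    """Full-scale settings: widths at scale 1, 5000 epochs per stage."""
    return dataclasses.replace(config, scale=1.0, ae_epochs=5000,
                               cgan_epochs=5000, clf_epochs=5000)


@dataclass
class RunResult:
    out_dir: Path
    reports: list[evaluation.EvalReport]
    table: "object"  # pandas DataFrame
    manifest: dict

    @property
    def pooled(self) -> dict:
        return self.table.iloc[-1].to_dict()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stratified_subset(table: FeatureTable, fraction: float,
                       seed: int) -> FeatureTable:
    """Per-class random subset used to train the fidelity autoencoder."""
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    labels = np.array([lab or "" for lab in table.labels])
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        k = max(1, round(fraction * len(idx)))
        keep.extend(rng.permutation(idx)[:k].tolist())
    return table.select(sorted(keep))


def _train_models(train: FeatureTable, config: RunConfig, out: Path,
                  tag: str = "") -> tuple:
    """AE + cGAN + synthetic table + classifier for one training set.

    Returns (clf_bundle, synth_table_or_None, cgan_bundle_or_None,
    ae_bundle_or_None). Which parts run depends on the ablation.
    """
    d = train.dim
    synth = cgan_bundle = ae_bundle = None
    if config.ablation in ("full", "cgan_only"):
        ae_spec = AeSpec(feature_dim=d, scale=config.scale,
                         epochs=config.ae_epochs,
                         seed=stage_seed(config.seed, "ae" + tag))
        subset = _stratified_subset(train, config.ae_subset_fraction,
                                    stage_seed(config.seed, "ae-subset" + tag))
        ae_bundle = ae_fidelity.train_autoencoder(subset, ae_spec)
        ae_fidelity.save_bundle(ae_bundle, out / f"ae{tag}.bundle")

        cgan_spec = CganSpec(feature_dim=d, scale=config.scale,
                             epochs=config.cgan_epochs,
                             seed=stage_seed(config.seed, "cgan" + tag))
        cgan_bundle = augment_cgan.train_cgan(train, cgan_spec, ae=ae_bundle)
        augment_cgan.save_bundle(cgan_bundle, out / f"cgan{tag}.bundle")

        synth = augment_cgan.generate_synthetic(
            cgan_bundle, config.n_synth_per_class,
            seed=stage_seed(config.seed, "synth" + tag))
        write_feature_table(synth, out / f"synthetic{tag}.csv")

    clf_seed = stage_seed(config.seed, "clf" + tag)
    if config.ablation == "cgan_only":
        spec: MhaSpec | MlpSpec = MlpSpec(input_dim=d, scale=config.scale,
                                          epochs=config.clf_epochs, seed=clf_seed)
    else:
        spec = MhaSpec(input_dim=d, heads=config.heads, tokens=config.tokens,
                       scale=config.scale, epochs=config.clf_epochs,
                       seed=clf_seed)
    clf = classifier_mha.build_classifier(spec)
    classifier_mha.train_classifier(clf, train, synth)
    classifier_mha.save_bundle(clf, out / f"classifier{tag}.bundle")
    return clf, synth, cgan_bundle, ae_bundle


def _evaluate_group(clf, test: FeatureTable, group: str) -> evaluation.EvalReport:
    probs, pred_labels = classifier_mha.predict(clf, test)
    return evaluation.confusion_metrics(test.labels, pred_labels,
                                        scores=probs, group=group)


def load_or_make_features(config: RunConfig) -> FeatureTable:
    if config.features_csv is not None:
        return read_feature_table(config.features_csv)
    if config.simulate_timeseries:
        series, pheno = make_dataset(config.fixture)
        return extract_features(series, pheno)
    return make_feature_fixture(config.fixture)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the configured protocol end to end into the run directory.

    Artifacts written: ``features.csv``, ``plan.json``, per-training-set
    model bundles and synthetic tables, ``predictions.csv``,
    ``report.json`` / ``report.txt`` and a ``manifest.json`` with the full
    config, derived stage seeds and SHA-256 checksums of every artifact.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    features = load_or_make_features(config)
    write_feature_table(features, out / "features.csv")

    split_seed = stage_seed(config.seed, "split")
    if config.protocol == "holdout":
        plan = stratified_split(features, config.test_fraction, split_seed)
        pairs = [("holdout", plan.members("train"), plan.members("test"))]
    elif config.protocol == "kfold10":
        plan = stratified_kfold(features, config.kfolds, split_seed)
        pairs = []
        for fold in range(config.kfolds):
            test_ids = plan.members(fold)
            train_ids = [s for s in plan.assignments if plan.assignments[s] != fold]
            pairs.append((f"fold{fold}", train_ids, test_ids))
    else:  # leave-site
        plan = leave_site_protocol(features, config.train_site,
                                   config.excluded_sites)
        train_ids = plan.members("train")
        pairs = [(f"site:{site}", train_ids, plan.members(f"test:{site}"))
                 for site in held_out_sites(plan)]
    plan.to_json(out / "plan.json")

    reports: list[evaluation.EvalReport] = []
    pred_rows: list[dict] = []
    trained_train_ids: tuple | None = None
    clf = None
    for group, train_ids, test_ids in pairs:
        if not test_ids:
            logger.warning("group %s has an empty test set; skipped", group)
            continue
        # leave-site shares one training set across all test groups
        if trained_train_ids != tuple(train_ids):
            tag = "" if len(pairs) == 1 or config.protocol == "leave-site" \
                else f"-{group}"
            clf, *_ = _train_models(features.subset_by_ids(train_ids), config,
                                    out, tag=tag)
            trained_train_ids = tuple(train_ids)
        test = features.subset_by_ids(test_ids)
        rep = _evaluate_group(clf, test, group)
        reports.append(rep)
        probs, pred_labels = classifier_mha.predict(clf, test)
        for sid, lab, p, pl in zip(test.subject_ids, test.labels, probs,
                                   pred_labels):
            pred_rows.append({"subject_id": sid, "group": group, "label": lab,
                              "score": p, "prediction": pl})

    import pandas as pd
    pd.DataFrame(pred_rows).to_csv(out / "predictions.csv", index=False,
                                   float_format="%.10g")
    table = evaluation.aggregate(reports)
    (out / "report.json").write_text(json.dumps(
        {"groups": [r.to_dict() for r in reports],
         "pooled": table.iloc[-1].drop(["undefined"], errors="ignore").to_dict(),
         "pooling": "metrics recomputed from summed confusion counts"},
        indent=1, default=float))
    (out / "report.txt").write_text(evaluation.format_table(table) + "\n")

    manifest = {
        "config": json.loads(json.dumps(config.to_dict(), default=list)),
        "stage_seeds": {name: stage_seed(config.seed, name)
                        for name in ("split", "ae", "cgan", "synth", "clf")},
        "artifacts": {p.name: _sha256(p) for p in sorted(out.iterdir())
                      if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return RunResult(out_dir=out, reports=reports, table=table,
                     manifest=manifest)


def sweep_synth_counts(config: RunConfig, counts: list[int]):
    """Accuracy (and friends) as a function of synthetic training-set size.

    All counts share the same real-data split, autoencoder and trained
    cGAN; only the sampled synthetic table and the classifier differ. A
    count of 0 means no augmentation (the real-data-only configuration).
    Returns a pandas DataFrame with one row per count.
    """
    import pandas as pd

    if not counts:
        raise ValueError("counts list is empty")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if config.protocol != "holdout":
        raise ValueError("the synthetic-count sweep uses the holdout protocol")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features = load_or_make_features(config)
    plan = stratified_split(features, config.test_fraction,
                            stage_seed(config.seed, "split"))
    train = features.subset_by_ids(plan.members("train"))
    test = features.subset_by_ids(plan.members("test"))

    d = train.dim
    ae_spec = AeSpec(feature_dim=d, scale=config.scale, epochs=config.ae_epochs,
                     seed=stage_seed(config.seed, "ae"))
    ae_bundle = ae_fidelity.train_autoencoder(
        _stratified_subset(train, config.ae_subset_fraction,
                           stage_seed(config.seed, "ae-subset")), ae_spec)
    cgan_spec = CganSpec(feature_dim=d, scale=config.scale,
                         epochs=config.cgan_epochs,
                         seed=stage_seed(config.seed, "cgan"))
    cgan_bundle = augment_cgan.train_cgan(train, cgan_spec, ae=ae_bundle)

    rows = []
    for count in counts:
        synth = None
        if count > 0:
            synth = augment_cgan.generate_synthetic(
                cgan_bundle, max(1, count // 2),
                seed=stage_seed(config.seed, f"synth-{count}"))
        spec = MhaSpec(input_dim=d, heads=config.heads, tokens=config.tokens,
                       scale=config.scale, epochs=config.clf_epochs,
                       seed=stage_seed(config.seed, "clf"))
        clf = classifier_mha.build_classifier(spec)
        classifier_mha.train_classifier(clf, train, synth)
        rep = _evaluate_group(clf, test, group=f"synth={count}")
        rows.append({"n_synthetic": count, **{k: v for k, v in
                                              rep.to_dict().items()
                                              if k not in ("group",)}})
    df = pd.DataFrame(rows)
    df.drop(columns=["undefined"], errors="ignore").to_csv(
        out / "sweep.csv", index=False, float_format="%.10g")
    return df
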
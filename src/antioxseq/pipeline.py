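"""Four-phase pipeline driver: extract -> balance -> select -> classify.

A :class:`RunConfig` (usually loaded from YAML) fixes every stage
parameter and one global seed; the seed fans out deterministically to
stage-local seeds (seed + stage offset) so each stage is independently
reproducible.  ``run_pipeline`` executes the phases in order on a
train/test pair that is split before any rebalancing — test data never
passes through the resampler — and writes all intermediate artifacts
plus a final report into a run directory.  Every text artifact carries a
provenance stamp (config hash + seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import joblib
import yaml

from . import classify, features, imbalance, mrmd, sequence_io, synthetic
from .errors import ConfigError

logger = logging.getLogger(__name__)

_STAGE_OFFSETS = {"simulate": 0, "balance": 1, "select": 2, "train": 3}


@dataclass
class DataConfig:
    source: str = "synthetic"  # "synthetic" | "fasta"
    # synthetic source
    benchmark_shape: bool = True
    n_pos: int = 253
    n_neg: int = 1552
    enrichment: float = 3.0
    length_range: tuple[int, int] = (50, 300)
    test_pos: int = 53
    test_neg: int = 52
    # fasta source
    fasta_pos: Optional[str] = None
    fasta_neg: Optional[str] = None


@dataclass
class ExtractConfig:
    gap: int = 3
    families: tuple[str, ...] = ("cksaap", "ct")
    ct_norm: str = "max"


@dataclass
class BalanceConfig:
    method: str = "smote"  # "smote" | "random_under" | "none"
    k_neighbors: int = 5
    target_ratio: float = 1.0


@dataclass
class SelectConfig:
    enabled: bool = True
    folds: int = 10
    step: int = 1
    trees: int = 100
    scale: str = "minmax"


@dataclass
class TrainConfig:
    trees: int = 100


@dataclass
class RunConfig:
    seed: int = 0
    data: DataConfig = field(default_factory=DataConfig)
    extract: ExtractConfig = field(default_factory=ExtractConfig)
    balance: BalanceConfig = field(default_factory=BalanceConfig)
    select: SelectConfig = field(default_factory=SelectConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def stage_seed(self, stage: str) -> int:
        return self.seed + _STAGE_OFFSETS[stage]

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        """Build and validate; aggregates every problem before raising."""
        problems: list[str] = []
        known = {"seed", "data", "extract", "balance", "select", "train"}
        for key in raw:
            if key not in known:
                problems.append(f"unknown section {key!r}")

        def section(name, klass):
            sub = raw.get(name, {})
            if not isinstance(sub, dict):
                problems.append(f"section {name!r} must be a mapping")
                return klass()
            valid = {f for f in klass.__dataclass_fields__}
            for k in sub:
                if k not in valid:
                    problems.append(f"{name}.{k}: unknown field")
            kwargs = {k: v for k, v in sub.items() if k in valid}
            if "length_range" in kwargs:
                kwargs["length_range"] = tuple(kwargs["length_range"])
            if "families" in kwargs:
                kwargs["families"] = tuple(kwargs["families"])
            try:
                return klass(**kwargs)
            except (TypeError, ValueError) as exc:
                problems.append(f"{name}: {exc}")
                return klass()

        cfg = cls(
            seed=raw.get("seed", 0),
            data=section("data", DataConfig),
            extract=section("extract", ExtractConfig),
            balance=section("balance", BalanceConfig),
            select=section("select", SelectConfig),
            train=section("train", TrainConfig),
        )
        if not isinstance(cfg.seed, int):
            problems.append("seed: must be an integer")
        if cfg.data.source not in ("synthetic", "fasta"):
            problems.append("data.source: must be 'synthetic' or 'fasta'")
        if cfg.data.source == "fasta":
            for fld in ("fasta_pos", "fasta_neg"):
                path = getattr(cfg.data, fld)
                if path is None:
                    problems.append(f"data.{fld}: required for source 'fasta'")
                elif not Path(path).exists():
                    problems.append(f"data.{fld}: file not found: {path}")
        if cfg.balance.method not in ("smote", "random_under", "none"):
            problems.append("balance.method: must be smote, random_under or none")
        if problems:
            raise ConfigError(problems)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(["top level of the config must be a mapping"])
        return cls.from_dict(raw)


def _load_split(cfg: RunConfig):
    d = cfg.data
    if d.source == "synthetic":
        if d.benchmark_shape:
            return synthetic.benchmark_shape_dataset(
                cfg.stage_seed("simulate"), enrichment=d.enrichment, length_range=d.length_range
            )
        ds = synthetic.generate(
            synthetic.SyntheticDatasetSpec(
                n_pos=d.n_pos,
                n_neg=d.n_neg,
                length_range=d.length_range,
                enrichment=d.enrichment,
                seed=cfg.stage_seed("simulate"),
            )
        )
        return sequence_io.stratified_split(ds, d.test_pos, d.test_neg, cfg.stage_seed("simulate"))
    pos = sequence_io.read_fasta(d.fasta_pos, label=1)
    neg = sequence_io.read_fasta(d.fasta_neg, label=0)
    ds = sequence_io.validate_sequences(pos.concat(neg), policy="drop")
    return sequence_io.stratified_split(ds, d.test_pos, d.test_neg, cfg.stage_seed("simulate"))


def _stamp(path: Path, cfg: RunConfig) -> None:
    """Prepend the provenance comment line to a text artifact."""
    text = path.read_text()
    path.write_text(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n" + text)


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the four phases and populate ``outdir``; returns the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp_targets: list[Path] = []

    train_ds, test_ds = _load_split(cfg)
    logger.info(
        "split: train %d+/%d-, test %d+/%d-",
        train_ds.n_positive, train_ds.n_negative, test_ds.n_positive, test_ds.n_negative,
    )

    # phase 1: descriptors
    fm_train = features.extract_features(
        train_ds, gap=cfg.extract.gap, features=cfg.extract.families, ct_norm=cfg.extract.ct_norm
    )
    fm_test = features.extract_features(
        test_ds, gap=cfg.extract.gap, features=cfg.extract.families, ct_norm=cfg.extract.ct_norm
    )
    sequence_io.write_feature_csv(fm_train, outdir / "train_features.csv")
    sequence_io.write_feature_csv(fm_test, outdir / "test_features.csv")
    stamp_targets += [outdir / "train_features.csv", outdir / "test_features.csv"]

    # phase 2: rebalance the training matrix only
    if cfg.balance.method != "none":
        rcfg = imbalance.ResampleConfig(
            method=cfg.balance.method,
            k_neighbors=cfg.balance.k_neighbors,
            target_ratio=cfg.balance.target_ratio,
            seed=cfg.stage_seed("balance"),
        )
        fm_bal = imbalance.resample(fm_train, rcfg)
        sequence_io.write_feature_csv(fm_bal, outdir / "balanced_features.csv")
        stamp_targets.append(outdir / "balanced_features.csv")
    else:
        fm_bal = fm_train

    # phase 3: MRMD ranking + incremental subset search
    table = mrmd.mrmd_rank(fm_bal, scale=cfg.select.scale)
    table.to_dataframe().to_csv(outdir / "ranked.csv", index=False)
    stamp_targets.append(outdir / "ranked.csv")
    if cfg.select.enabled:
        sel = mrmd.incremental_select(
            fm_bal,
            table,
            folds=cfg.select.folds,
            step=cfg.select.step,
            seed=cfg.stage_seed("select"),
            trees=cfg.select.trees,
        )
        subset = sel.chosen_features
        curve = {"sizes": sel.sizes, "accuracies": sel.accuracies}
    else:
        subset = list(fm_bal.feature_names)
        curve = None
    (outdir / "subset.txt").write_text("".join(f"{f}\n" for f in subset))
    stamp_targets.append(outdir / "subset.txt")

    # phase 4: final model on the chosen subset, evaluated on the test set
    bundle = classify.train_forest(
        fm_bal, subset, trees=cfg.train.trees, seed=cfg.stage_seed("train")
    )
    joblib.dump(bundle, outdir / "model.joblib")
    cc, report = classify.evaluate(bundle, fm_test)

    roc = report.roc_points
    with open(outdir / "roc.csv", "w") as fh:
        fh.write("fpr,tpr\n")
        for x, y in roc:
            fh.write(f"{x},{y}\n")
    stamp_targets.append(outdir / "roc.csv")

    out = {
        "provenance": {"config_hash": cfg.config_hash(), "seed": cfg.seed},
        "counts": {
            "train_pos": train_ds.n_positive,
            "train_neg": train_ds.n_negative,
            "balanced_pos": int((fm_bal.labels == 1).sum()),
            "balanced_neg": int((fm_bal.labels == 0).sum()),
            "test_pos": test_ds.n_positive,
            "test_neg": test_ds.n_negative,
        },
        "selection": curve and {**curve, "chosen_size": len(subset)},
        "confusion": {"TP": cc.TP, "FP": cc.FP, "FN": cc.FN, "TN": cc.TN},
        "metrics": report.as_dict(),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(out, fh, indent=2)
    for path in stamp_targets:
        _stamp(path, cfg)
    return out
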
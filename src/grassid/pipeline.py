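"""End-to-end orchestration: images (or a feature CSV) to a classification report.

Stages mirror the processing flow the feature design implies: segmentation →
feature extraction → correlation-based selection → rotated-PCA fit on a
random training split → score descriptives → CI-gap thresholds → pairwise
holdout classification. Every stage writes its artifact to the output
directory; writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import discrimination as disc
from . import features as feat
from . import pca, selection
from .errors import EmptySegmentation, GrassIdError
from .segmentation import SegmentationConfig, load_image, save_mask, segment_plant

log = logging.getLogger("grassid")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips losslessly through JSON."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    selection_threshold: float = 0.7
    selection_priority: list[str] | None = None
    kaiser_tolerance: float = 0.05
    row_normalize: bool = True
    split_fraction: float = 0.2
    seed: int = 0
    pairs: list[tuple[str, str]] | None = None  # None = all species pairs

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        _atomic_write_text(path, json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        seg = SegmentationConfig(**d.pop("segmentation"))
        pairs = d.pop("pairs")
        return cls(
            segmentation=seg,
            pairs=[tuple(p) for p in pairs] if pairs else None,
            **d,
        )


def _atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_csv(df: pd.DataFrame, path: str | Path, **kw) -> None:
    _atomic_write_text(path, df.to_csv(index=False, **kw))


def extract_from_images(
    image_dir: str | Path,
    cfg: SegmentationConfig | None = None,
    mask_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Segment every image in a directory and build the feature table.

    Species labels come from ``manifest.csv`` (columns file, species) when
    present, otherwise from the filename prefix before the first underscore.
    Images where no plant is found are reported and skipped.
    """
    image_dir = Path(image_dir)
    manifest_path = image_dir / "manifest.csv"
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
        entries = list(zip(manifest["file"], manifest["species"]))
    else:
        entries = [
            (p.name, p.stem.split("_")[0])
            for p in sorted(image_dir.glob("*.png"))
            if not p.stem.endswith("_mask")
        ]
    records = []
    t0 = time.perf_counter()
    for fname, species in entries:
        try:
            region = segment_plant(load_image(image_dir / fname), cfg)
        except EmptySegmentation:
            log.warning("no plant found in %s; skipped", fname)
            continue
        if mask_dir is not None:
            save_mask(Path(mask_dir) / f"{Path(fname).stem}_segmask.png", region.mask)
        records.append((Path(fname).stem, species, feat.extract_features(region)))
    log.info(
        "extracted %d/%d feature vectors in %.1f s",
        len(records), len(entries), time.perf_counter() - t0,
    )
    return feat.feature_table(records)


def run_pipeline(
    input_path: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every stage and write all artifacts; returns a summary dict.

    ``input_path`` is either a directory of single-plant images or a feature
    CSV (which skips the image stages).
    """
    config = config or PipelineConfig()
    input_path, outdir = Path(input_path), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    if input_path.is_dir():
        table = extract_from_images(input_path, config.segmentation, mask_dir=outdir)
    else:
        table = feat.read_feature_table(input_path)
    if table.empty:
        raise GrassIdError("no usable plants in input")
    _atomic_write_csv(table, outdir / "features.csv")
    log.info("feature table: %d plants, %d species", len(table), table["species"].nunique())

    corr = selection.correlation_matrix(table)
    _atomic_write_text(outdir / "correlation.csv", corr.to_csv())
    sel = selection.select_features(
        corr, threshold=config.selection_threshold, priority=config.selection_priority
    )
    sel.to_json(outdir / "selection.json")
    log.info("selected %d/%d features: %s", len(sel.kept), corr.shape[0], sel.kept)

    train, test = disc.evaluate_holdout(table, config.split_fraction, config.seed)
    model = pca.fit_model(
        train, sel.kept,
        kaiser_tolerance=config.kaiser_tolerance,
        row_normalize=config.row_normalize,
    )
    model.to_json(outdir / "model.json")
    log.info(
        "PCA: retained %d components explaining %.1f%% of variance",
        model.retained_k, model.explained_pct[: model.retained_k].sum(),
    )

    train_scores = model.score(train)
    test_scores = model.score(test)
    _atomic_write_csv(
        train_scores.assign(plant_id=train["plant_id"].values, species=train["species"].values),
        outdir / "scores_train.csv",
    )
    _atomic_write_csv(
        test_scores.assign(plant_id=test["plant_id"].values, species=test["species"].values),
        outdir / "scores_test.csv",
    )

    labels_train = train["species"].to_numpy()
    anova = {
        comp: asdict(disc.one_way_anova(train_scores[comp].to_numpy(), labels_train))
        for comp in train_scores.columns
    }
    posthoc = {
        comp: [
            asdict(c)
            for c in disc.bonferroni_pairwise(train_scores[comp].to_numpy(), labels_train)
        ]
        for comp in train_scores.columns
    }
    _atomic_write_text(outdir / "anova.json", json.dumps({"anova": anova, "posthoc": posthoc}, indent=2))

    descriptives = disc.describe_scores(train_scores, labels_train)
    _atomic_write_csv(descriptives, outdir / "descriptives.csv")

    species = sorted(table["species"].unique())
    pairs = config.pairs or list(combinations(species, 2))
    plan = disc.suggest_plan(descriptives, pairs)
    thresholds = disc.derive_thresholds(descriptives, plan)
    _atomic_write_text(
        outdir / "thresholds.json", json.dumps([asdict(t) for t in thresholds], indent=2)
    )

    report = disc.classify_pairwise(test_scores, test["species"].to_numpy(), thresholds)
    _atomic_write_text(
        outdir / "classification.json", json.dumps(report["comparisons"], indent=2)
    )
    _atomic_write_csv(pd.DataFrame(report["predictions"]), outdir / "predictions.csv")

    summary = {
        "n_plants": int(len(table)),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "selected_features": sel.kept,
        "retained_components": int(model.retained_k),
        "accuracies": {
            f"{c['pair'][0]}-vs-{c['pair'][1]}": c["accuracy_pct"]
            for c in report["comparisons"]
        },
        "runtime_s": time.perf_counter() - t0,
    }
    _atomic_write_text(outdir / "summary.json", json.dumps(summary, indent=2))
    log.info("pipeline done in %.1f s; accuracies %s", summary["runtime_s"], summary["accuracies"])
    return summary
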
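"""Feature-table I/O, the deep-feature extraction adapter, and the pipeline.

Table dialect
-------------
Delimited text (comma or tab, inferred from the extension): a header
row of feature names, one row per sample, and a final column named
``label`` holding the binary class.  A JSON sidecar (``<stem>.mask.json``)
optionally records the ground-truth informative columns of synthetic
tables.  The binary container is a NumPy ``.npz`` archive (bit-exact
round trip).

Image input follows the LC25000 colon layout: a directory with class
subfolders ``colon_aca`` (adenocarcinoma, the positive class) and
``colon_n`` (benign).  Real CNN backbones need a user-supplied runtime
and weights; the ``stub`` adapter produces deterministic seeded
features from the pixels themselves so the full pipeline is testable
offline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .goa import GoaConfig
from .selection import FitnessSpec, SelectionResult, select_features
from .classify import train_eval, CLASSIFIERS
from .synthetic import FeatureTable, SyntheticSpec, generate

logger = logging.getLogger("goafs")

__all__ = [
    "LABEL_COLUMN",
    "CLASS_FOLDERS",
    "BackboneAdapter",
    "PipelineConfig",
    "read_feature_table",
    "write_feature_table",
    "extract_features",
    "run_pipeline",
]

LABEL_COLUMN = "label"
#: recognized LC25000 colon class folders -> binary label
CLASS_FOLDERS = {"colon_aca": 1, "colon_n": 0}
KNOWN_BACKBONES = ("squeezenet", "resnet50", "alexnet", "googlenet", "stub")


# ---------------------------------------------------------------- tables

def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a table as delimited text or (``.npz``) binary archive."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            values=table.values,
            labels=np.asarray(table.labels),
            feature_names=np.asarray(table.feature_names),
            **(
                {"informative_mask": table.informative_mask}
                if table.informative_mask is not None
                else {}
            ),
        )
        return
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df[LABEL_COLUMN] = np.asarray(table.labels)
    df.to_csv(path, sep=_delimiter_for(path), index=False)
    if table.informative_mask is not None:
        sidecar = path.with_suffix(path.suffix + ".mask.json")
        sidecar.write_text(
            json.dumps({"informative_mask": table.informative_mask.astype(int).tolist()})
        )


def read_feature_table(path) -> FeatureTable:
    """Read a table written by :func:`write_feature_table`.

    Raises ``ValueError`` naming the offending row/column for
    non-numeric cells, and for a missing label column or duplicate
    feature names.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as archive:
            mask = (
                archive["informative_mask"].astype(bool)
                if "informative_mask" in archive
                else None
            )
            return FeatureTable(
                values=archive["values"],
                labels=archive["labels"],
                feature_names=[str(n) for n in archive["feature_names"]],
                informative_mask=mask,
            )
    with open(path) as fh:
        header = fh.readline().strip().split(_delimiter_for(path))
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate feature names {sorted(dupes)}")
    df = pd.read_csv(path, sep=_delimiter_for(path))
    if LABEL_COLUMN not in df.columns:
        raise ValueError(
            f"{path}: missing required {LABEL_COLUMN!r} column "
            f"(found {list(df.columns)})"
        )
    feature_cols = [c for c in df.columns if c != LABEL_COLUMN]
    for col in feature_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric cell at row {row}, column {col!r}: "
                f"{df[col].iloc[row]!r}"
            )
        df[col] = numeric
    if df[feature_cols].isna().any().any():
        raise ValueError(f"{path}: missing values in feature columns")

    mask = None
    sidecar = path.with_suffix(path.suffix + ".mask.json")
    if sidecar.exists():
        mask = np.asarray(
            json.loads(sidecar.read_text())["informative_mask"], dtype=bool
        )
    return FeatureTable(
        values=df[feature_cols].to_numpy(dtype=float),
        labels=df[LABEL_COLUMN].to_numpy(),
        feature_names=feature_cols,
        informative_mask=mask,
    )


# ------------------------------------------------------------- extraction

@dataclass(frozen=True)
class BackboneAdapter:
    """Deep-feature extractor configuration.

    The ``stub`` backbone needs no weights: it resizes each image to
    ``input_size``, flattens the grayscale pixels and applies a seeded
    Gaussian random projection to ``feature_dim`` dimensions —
    deterministic for a given directory and seed.  The named CNN
    backbones are declared for interface completeness; using one
    requires a user-provided runtime and pretrained weights.
    """

    backbone_id: str = "stub"
    layer_tag: str = "penultimate"
    input_size: int = 32
    feature_dim: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone_id not in KNOWN_BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone_id!r}; choose from {KNOWN_BACKBONES}"
            )


def _stub_features(pixels: np.ndarray, adapter: BackboneAdapter) -> np.ndarray:
    rng = np.random.default_rng(adapter.seed)
    proj = rng.standard_normal((pixels.size, adapter.feature_dim))
    return (pixels / 255.0) @ proj / np.sqrt(pixels.size)


def extract_features(image_dir, adapter: BackboneAdapter) -> FeatureTable:
    """One feature row per image; labels from the class subfolders.

    Images are visited in sorted path order for determinism.
    Unreadable files are skipped with a logged warning; an unknown
    subfolder or an empty class folder is an error.
    """
    table, _ = extract_features_with_report(image_dir, adapter)
    return table


def extract_features_with_report(
    image_dir, adapter: BackboneAdapter
) -> tuple[FeatureTable, list[str]]:
    """As :func:`extract_features`, also returning the skipped files."""
    if adapter.backbone_id != "stub":
        raise RuntimeError(
            f"backbone {adapter.backbone_id!r} requires a user-supplied "
            "inference runtime and pretrained weights; install the optional "
            "extractor dependencies and provide a weights path, or use the "
            "'stub' backbone"
        )
    try:
        from PIL import Image
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("image extraction requires pillow") from exc

    image_dir = Path(image_dir)
    subdirs = sorted(p for p in image_dir.iterdir() if p.is_dir())
    unknown = [p.name for p in subdirs if p.name not in CLASS_FOLDERS]
    if unknown:
        raise ValueError(
            f"unknown class folder(s) {unknown}; recognized: {sorted(CLASS_FOLDERS)}"
        )
    if not subdirs:
        raise ValueError(f"{image_dir} contains no class subfolders")

    rows, labels, skipped = [], [], []
    for sub in subdirs:
        files = sorted(p for p in sub.iterdir() if p.is_file())
        n_before = len(rows)
        for f in files:
            try:
                with Image.open(f) as img:
                    img = img.convert("L").resize(
                        (adapter.input_size, adapter.input_size)
                    )
                    pixels = np.asarray(img, dtype=float).ravel()
            except Exception:
                logger.warning("skipping unreadable image %s", f)
                skipped.append(str(f))
                continue
            rows.append(_stub_features(pixels, adapter))
            labels.append(CLASS_FOLDERS[sub.name])
        if len(rows) == n_before:
            raise ValueError(f"class folder {sub} contains no readable images")

    table = FeatureTable(
        values=np.vstack(rows),
        labels=np.asarray(labels),
        feature_names=[f"{adapter.backbone_id}_{i}" for i in range(adapter.feature_dim)],
    )
    return table, skipped


# --------------------------------------------------------------- pipeline

@dataclass
class PipelineConfig:
    """End-to-end run configuration: exactly one input source."""

    table_path: str | None = None
    image_dir: str | None = None
    synthetic_spec: SyntheticSpec | None = None
    adapter: BackboneAdapter = field(default_factory=BackboneAdapter)
    goa: GoaConfig | None = None          # bounds set from the table if None
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    classifiers: tuple[str, ...] = CLASSIFIERS
    output_dir: str = "goafs_out"
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        sources = [
            s for s in (self.table_path, self.image_dir, self.synthetic_spec)
            if s is not None
        ]
        if len(sources) != 1:
            raise ValueError(
                "exactly one input source (table_path | image_dir | "
                "synthetic_spec) must be set"
            )
        for cid in self.classifiers:
            if cid not in CLASSIFIERS:
                raise ValueError(f"unknown classifier {cid!r}")


def _load_input(cfg: PipelineConfig) -> tuple[FeatureTable, list[str]]:
    if cfg.table_path is not None:
        return read_feature_table(cfg.table_path), []
    if cfg.image_dir is not None:
        return extract_features_with_report(cfg.image_dir, cfg.adapter)
    return generate(cfg.synthetic_spec), []


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Load or extract features, select a subset, evaluate classifiers.

    Writes, under ``cfg.output_dir``: the selection result JSON, the
    fitness trace as two-column TSV, the metric panel as JSON and as
    one delimited row per classifier, and a provenance log.  Returns
    the report as a dict.  Any stage failure raises with a
    stage-tagged message.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.verbosity:
        logging.basicConfig(level=logging.INFO)

    try:
        table, skipped = _load_input(cfg)
    except Exception as exc:
        raise RuntimeError(f"[input] {exc}") from exc

    spec = FitnessSpec(
        alpha=cfg.fitness.alpha,
        classifier_id=cfg.fitness.classifier_id,
        n_splits=cfg.fitness.n_splits,
        seed=cfg.seed,
    )
    goa_cfg = cfg.goa or GoaConfig(
        lower_bounds=[0.0] * table.n_features,
        upper_bounds=[1.0] * table.n_features,
        seed=cfg.seed,
    )
    try:
        result = select_features(table, goa_cfg, spec)
    except Exception as exc:
        raise RuntimeError(f"[selection] {exc}") from exc

    metric_rows = {}
    try:
        for cid in cfg.classifiers:
            m, cm = train_eval(
                table, result.mask, classifier_id=cid,
                n_splits=spec.n_splits, seed=cfg.seed,
            )
            metric_rows[cid] = {**m.as_dict(), **asdict(cm)}
    except Exception as exc:
        raise RuntimeError(f"[evaluation] {exc}") from exc

    (out / "selection.json").write_text(result.to_json())
    result.write_trace(out / "trace.tsv")
    report = {
        "schema_version": 1,
        "seed": cfg.seed,
        "n_samples": table.n_samples,
        "n_features": table.n_features,
        "selected_count": result.mask.selected_count,
        "selected_indices": result.mask.selected_indices(),
        "final_fitness": result.final_fitness,
        "skipped_images": skipped,
        "metrics": metric_rows,
    }
    (out / "metrics.json").write_text(json.dumps(report, indent=2))
    header = "method,sensitivity,specificity,accuracy,precision,f1"
    lines = [header] + [
        f"{cid},{m['sensitivity']:.4f},{m['specificity']:.4f},"
        f"{m['accuracy']:.4f},{m['precision']:.4f},{m['f1']:.4f}"
        for cid, m in metric_rows.items()
    ]
    (out / "metrics.csv").write_text("\n".join(lines) + "\n")
    (out / "run.log").write_text(
        f"seed={cfg.seed}\nclassifiers={cfg.classifiers}\n"
        f"goa={asdict(goa_cfg)}\nfitness={asdict(spec)}\n"
    )
    logger.info(
        "pipeline complete: %d/%d features selected, final fitness %.5f",
        result.mask.selected_count, table.n_features, result.final_fitness,
    )
    return report
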
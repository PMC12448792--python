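"""End-to-end workflow orchestration: preprocess -> train -> enhance ->
impute -> evaluate, driven by one :class:`RunConfig`.

Each stage reads the previous stage's artifacts from ``work_dir`` and logs the
configuration hash and seed, so a rerun with an identical configuration is
reproducible bit for bit (timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dnase as dn
from .errors import DependencyError, SplitError, ValidationError
from .hic_io import (
    ContactMatrix,
    Tile,
    TileSet,
    assemble_tiles,
    minmax_normalize,
    read_contact_matrix,
    tile_matrix,
    write_contact_matrix,
)
from .metrics import (
    MetricParams,
    MetricReport,
    compute_mse,
    genomedisco_score,
    hicrep_scc,
    psnr,
    ssim,
    summarize,
)
from .model import (
    ModelConfig,
    NetworkState,
    TrainConfig,
    load_checkpoint,
    model_forward,
    save_checkpoint,
    train_model,
)
from .synthetic import make_fixture_suite

log = logging.getLogger("dicarn")

#: default chromosome split: validation 2, 6, 10, 12; test 4, 14, 16, 20;
#: training = autosomes 1-22 minus both (X and Y excluded).
DEFAULT_VAL = ["chr2", "chr6", "chr10", "chr12"]
DEFAULT_TEST = ["chr4", "chr14", "chr16", "chr20"]
DEFAULT_TRAIN = [
    f"chr{i}" for i in range(1, 23)
    if f"chr{i}" not in DEFAULT_VAL + DEFAULT_TEST
]


@dataclass
class RunConfig:
    """Configuration for one pipeline run (YAML-serializable)."""

    data_dir: str = "."
    work_dir: str = "run"
    train_chroms: list[str] = field(default_factory=lambda: list(DEFAULT_TRAIN))
    val_chroms: list[str] = field(default_factory=lambda: list(DEFAULT_VAL))
    test_chroms: list[str] = field(default_factory=lambda: list(DEFAULT_TEST))
    lr_template: str = "{chrom}_lr.txt"
    hr_template: str = "{chrom}_hr.txt"
    dnase_template: str = "{chrom}_dnase.bedGraph"
    bins_template: str = "{chrom}_bins.bed"
    resolution: int = 10_000
    tile_size: int = 40
    stride: int = 40
    max_diag_distance: int = 400
    clip_quantile: float = 0.99
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    impute_distance_cap: int = 400
    impute_chunk: int = 200
    impute_regress_target: str = "if"
    augment_mode: str = "target"
    augment_pseudo_depth: float = 1e6
    downsample_ratio: float = 1.0 / 16.0
    metric_params: MetricParams = field(default_factory=MetricParams)
    seed: int = 0

    def __post_init__(self) -> None:
        splits = [set(self.train_chroms), set(self.val_chroms), set(self.test_chroms)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = splits[i] & splits[j]
                if overlap:
                    raise SplitError(f"chromosomes {sorted(overlap)} appear in two splits")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.model.to_dict()
        d["train"] = self.train.to_dict()
        d["metric_params"] = {
            k: v for k, v in asdict(self.metric_params).items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "model" in d:
            d["model"] = ModelConfig.from_dict(d["model"])
        if "train" in d:
            d["train"] = TrainConfig(**d["train"])
        if "metric_params" in d:
            d["metric_params"] = MetricParams(**d["metric_params"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def fixture_default(cls, data_dir, work_dir, **kw) -> "RunConfig":
        """Configuration matched to the synthetic fixture suite: one training,
        one validation and one test chromosome, and a small fast network."""
        defaults = dict(
            data_dir=str(data_dir),
            work_dir=str(work_dir),
            train_chroms=["chrS1"],
            val_chroms=["chrS2"],
            test_chroms=["chrS3"],
            model=ModelConfig(n_cascades=1, channels=8, attention_blocks=()),
            train=TrainConfig(learning_rate=3e-3, batch_size=8, epochs=15, seed=0),
        )
        defaults.update(kw)
        return cls(**defaults)


def _log_run(cfg: RunConfig, stage: str) -> None:
    log.info("stage=%s config_hash=%s seed=%d", stage, cfg.config_hash(), cfg.seed)


def _load_normalized(cfg: RunConfig, chrom: str, which: str) -> ContactMatrix:
    tmpl = cfg.lr_template if which == "lr" else cfg.hr_template
    path = Path(cfg.data_dir) / tmpl.format(chrom=chrom)
    if not path.exists():
        raise DependencyError(f"missing {which.upper()} matrix for {chrom}: {path}")
    m = read_contact_matrix(path, "triplet_text", chrom, cfg.resolution)
    return minmax_normalize(m, cfg.clip_quantile)


def _tiles_for(cfg: RunConfig, chrom: str, which: str) -> TileSet:
    return tile_matrix(
        _load_normalized(cfg, chrom, which),
        size=cfg.tile_size,
        stride=cfg.stride,
        max_diag_distance=cfg.max_diag_distance,
    )


def _tile_archive_path(cfg: RunConfig, split: str) -> Path:
    return Path(cfg.work_dir) / f"tiles_{split}.npz"


def expected_tile_count(n_bins: int, size: int, stride: int, max_diag: int) -> int:
    """Closed-form tile count for one chromosome."""
    offs = range(0, n_bins - size + 1, stride)
    return sum(1 for r in offs for c in offs if abs(r - c) <= max_diag)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def cmd_preprocess(cfg: RunConfig) -> dict[str, int]:
    """Tile every split's chromosomes into per-split (LR, HR, offsets) archives."""
    _log_run(cfg, "preprocess")
    Path(cfg.work_dir).mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    for split, chroms in (
        ("train", cfg.train_chroms),
        ("val", cfg.val_chroms),
        ("test", cfg.test_chroms),
    ):
        lr_list, hr_list, offs, labels = [], [], [], []
        for chrom in chroms:
            lr_ts = _tiles_for(cfg, chrom, "lr")
            hr_ts = _tiles_for(cfg, chrom, "hr")
            lr_list.append(lr_ts.arrays())
            hr_list.append(hr_ts.arrays())
            offs.append(np.array([(t.row_offset, t.col_offset) for t in lr_ts.tiles]))
            labels += [chrom] * len(lr_ts)
        lr = np.concatenate(lr_list) if lr_list else np.empty((0, cfg.tile_size, cfg.tile_size))
        hr = np.concatenate(hr_list) if hr_list else np.empty((0, cfg.tile_size, cfg.tile_size))
        off = np.concatenate(offs) if offs else np.empty((0, 2), dtype=int)
        np.savez_compressed(
            _tile_archive_path(cfg, split),
            lr=lr, hr=hr, offsets=off,
            chroms=np.array(labels, dtype="U32"),
            config_hash=np.array(cfg.config_hash(), dtype="U12"),
        )
        counts[split] = int(lr.shape[0])
        log.info("split=%s tiles=%d", split, counts[split])
    return counts


def _load_tiles(cfg: RunConfig, split: str) -> tuple[np.ndarray, np.ndarray]:
    path = _tile_archive_path(cfg, split)
    if not path.exists():
        raise DependencyError(f"missing tile archive for split {split!r}: run preprocess first")
    with np.load(path) as npz:
        return npz["lr"], npz["hr"]


def cmd_train(cfg: RunConfig, extra_pairs=None) -> NetworkState:
    """Train on the preprocessed tile archives; save checkpoint and log.

    ``extra_pairs`` (optional ``(lr, hr)`` array stacks) are appended to the
    training set — the hook used by accessibility-based augmentation.
    """
    _log_run(cfg, "train")
    x_tr, y_tr = _load_tiles(cfg, "train")
    x_va, y_va = _load_tiles(cfg, "val")
    if extra_pairs is not None:
        ex, ey = extra_pairs
        x_tr = np.concatenate([x_tr, ex])
        y_tr = np.concatenate([y_tr, ey])
    train_pairs = list(zip(x_tr, y_tr))
    val_pairs = list(zip(x_va, y_va))
    state = train_model(train_pairs, val_pairs, cfg.model, cfg.train)
    work = Path(cfg.work_dir)
    save_checkpoint(state, work / "checkpoint.npz")
    with open(work / "training_log.tsv", "w") as fh:
        fh.write("epoch\ttrain_mse\tval_ssim\n")
        for epoch, mse_, ssim_ in state.log:
            fh.write(f"{epoch}\t{mse_:.8g}\t{ssim_:.8g}\n")
    log.info("best_epoch=%d best_val_ssim=%.6g", state.epoch, state.best_validation_score)
    return state


def cmd_enhance(cfg: RunConfig, chroms: list[str] | None = None) -> dict[str, ContactMatrix]:
    """Enhance each (test) chromosome's LR matrix with the trained network."""
    _log_run(cfg, "enhance")
    ckpt = Path(cfg.work_dir) / "checkpoint.npz"
    if not ckpt.exists():
        raise DependencyError("missing checkpoint: run train first")
    state = load_checkpoint(ckpt)
    out: dict[str, ContactMatrix] = {}
    for chrom in chroms or cfg.test_chroms:
        tiles = _tiles_for(cfg, chrom, "lr")
        enhanced = model_forward(tiles, state, batch_size=cfg.train.batch_size)
        mat = assemble_tiles(enhanced)
        write_contact_matrix(mat, Path(cfg.work_dir) / f"enhanced_{chrom}.txt")
        out[chrom] = mat
    return out


def _five_metrics(pred: np.ndarray, truth: np.ndarray, p: MetricParams) -> dict[str, float]:
    clipped = np.clip(pred, 0.0, p.L)
    return {
        "ssim": ssim(clipped, truth, p),
        "psnr": psnr(clipped, truth, p),
        "mse": compute_mse(clipped, truth),
        "disco": genomedisco_score(clipped, truth, p),
        "scc": hicrep_scc(clipped, truth, p),
    }


def cmd_evaluate(cfg: RunConfig, chroms: list[str] | None = None) -> dict[str, MetricReport]:
    """Score enhanced matrices against the normalized truth; also score the
    un-enhanced LR input as a baseline.  Writes TSV reports."""
    _log_run(cfg, "evaluate")
    chroms = chroms or cfg.test_chroms
    per: dict[str, dict[str, float]] = {}
    base: dict[str, dict[str, float]] = {}
    p = cfg.metric_params
    for chrom in chroms:
        truth = _load_normalized(cfg, chrom, "hr").values
        lr = _load_normalized(cfg, chrom, "lr").values
        enh_path = Path(cfg.work_dir) / f"enhanced_{chrom}.txt"
        if not enh_path.exists():
            raise DependencyError(f"missing enhanced matrix for {chrom}: run enhance first")
        pred = read_contact_matrix(
            enh_path, "triplet_text", chrom, cfg.resolution, n_bins=truth.shape[0]
        ).values
        per[chrom] = _five_metrics(pred, truth, p)
        base[chrom] = _five_metrics(lr, truth, p)
    report = summarize(per)
    baseline = summarize(base)
    work = Path(cfg.work_dir)
    (work / "report.tsv").write_text(report.to_tsv())
    (work / "report_baseline.tsv").write_text(baseline.to_tsv())
    return {"enhanced": report, "baseline": baseline}


def cmd_impute(cfg: RunConfig, chroms: list[str] | None = None,
               augment: bool = False):
    """Impute IF matrices from accessibility tracks; optionally build the
    augmented training pair stacks."""
    _log_run(cfg, "impute")
    Path(cfg.work_dir).mkdir(parents=True, exist_ok=True)
    chroms = chroms or (cfg.test_chroms if cfg.augment_mode == "target" else cfg.train_chroms)
    imputed: dict[str, ContactMatrix] = {}
    for chrom in chroms:
        data = Path(cfg.data_dir)
        bg = data / cfg.dnase_template.format(chrom=chrom)
        bed = data / cfg.bins_template.format(chrom=chrom)
        hic_path = data / cfg.hr_template.format(chrom=chrom)
        for path, what in ((bg, "DNase track"), (bed, "bin BED"), (hic_path, "Hi-C matrix")):
            if not path.exists():
                raise DependencyError(f"missing {what} for {chrom}: {path}")
        track = dn.aggregate_signal_to_bins(
            dn.read_bedgraph(bg, chrom), dn.read_bed_bins(bed, chrom), chrom=chrom
        )
        hic = read_contact_matrix(hic_path, "triplet_text", chrom, cfg.resolution,
                                  n_bins=track.n_bins)
        mat = dn.impute_chromosome_chunked(
            track, hic, chunk=cfg.impute_chunk,
            distance_cap=cfg.impute_distance_cap,
            regress_target=cfg.impute_regress_target,
        )
        write_contact_matrix(mat, Path(cfg.work_dir) / f"imputed_{chrom}.txt")
        imputed[chrom] = mat
    if not augment:
        return imputed
    dataset_pairs = []
    for ci, chrom in enumerate(sorted(imputed)):
        lr_t, hr_t = dn.imputed_matrix_to_pairs(
            imputed[chrom], cfg.downsample_ratio, seed=cfg.seed + ci,
            pseudo_depth=cfg.augment_pseudo_depth,
            tile_size=cfg.tile_size, stride=cfg.stride,
            max_diag_distance=cfg.max_diag_distance,
            clip_quantile=cfg.clip_quantile,
        )
        dataset_pairs.append((lr_t.arrays(), hr_t.arrays(), chrom))
    lr = np.concatenate([a for a, _, _ in dataset_pairs])
    hr = np.concatenate([b for _, b, _ in dataset_pairs])
    labels = np.concatenate(
        [np.full(len(a), c, dtype="U32") for a, _, c in dataset_pairs]
    )
    np.savez_compressed(Path(cfg.work_dir) / "augmented_pairs.npz",
                        lr=lr, hr=hr, chroms=labels,
                        mode=np.array(cfg.augment_mode, dtype="U8"))
    return imputed


def cmd_make_fixtures(out_dir, n_bins: int = 400, seed: int = 0) -> dict:
    """Generate the synthetic fixture suite."""
    log.info("stage=make-fixtures n_bins=%d seed=%d", n_bins, seed)
    return make_fixture_suite(out_dir, n_bins=n_bins, seed=seed)


def run_full_pipeline(data_dir, work_dir, seed: int = 0, n_bins: int = 400,
                      **cfg_kw) -> dict:
    """Fixture-scale end-to-end run; returns the evaluation reports."""
    cmd_make_fixtures(data_dir, n_bins=n_bins, seed=seed)
    cfg = RunConfig.fixture_default(data_dir, work_dir, seed=seed, **cfg_kw)
    cfg.train.seed = seed
    cmd_preprocess(cfg)
    cmd_train(cfg)
    cmd_enhance(cfg)
    return cmd_evaluate(cfg)
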
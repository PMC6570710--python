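"""End-to-end experiment driver and fixture generation.

Reproduces, at configurable desk scale, the three-model comparison at the
heart of the method: a discriminative L1 regressor, the standard pix2pix
cGAN, and the extended cGAN whose adversarial term also sees unlabeled
domain-shifted frames. All three train on identical data with identical
seeds and are scored on the same held-out synthetic split and on a
held-out domain-shifted split (where the implicit domain adaptation is
expected to show).
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import scene_sim as ss
from .eval_metrics import evaluate_pairs
from .gan_core import (
    DepthCodec,
    DiscriminatorSpec,
    GeneratorSpec,
    Pix2PixTrainer,
    TrainingConfig,
    split_dataset,
)

log = logging.getLogger("colodepth")

ALL_MODES = ("discriminative", "standard", "extended")

__all__ = [
    "ExperimentConfig",
    "render_toy_dataset",
    "compare_modes",
    "run_comparison",
    "make_fixtures",
]


@dataclass
class ExperimentConfig:
    modes: tuple = ALL_MODES
    n_pairs: int = 36  # synthetic RGB/depth pairs (spread over the 9 subsets)
    n_shifted_train: int = 8  # unlabeled domain-shifted pool for extended mode
    n_shifted_test: int = 6  # held-out domain-shifted scoring set
    image_size: int = 32
    epochs: int = 20
    batch_size: int = 10
    seeds: tuple = (0,)
    out_dir: str = "comparison"
    gen_spec: GeneratorSpec = field(default_factory=GeneratorSpec)
    disc_spec: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    scene_seed: int = 0
    ray_step: float = 0.1

    def __post_init__(self):
        if not self.seeds:
            raise ValueError("need at least one seed")
        bad = set(self.modes) - set(ALL_MODES)
        if bad:
            raise ValueError(f"unknown modes: {sorted(bad)}")


def render_toy_dataset(
    n_pairs, n_shifted_train, n_shifted_test, size=32, seed=0, ray_step=0.1
):
    """Deterministic in-memory micro-dataset over the 9-subset grid.

    Returns (pairs, shifted_train_rgb, shifted_test_pairs); pairs cycle
    through the 3x3 light/material grid. Shifted frames reuse the same
    geometry family but the out-of-distribution appearance profile.
    """
    scene = ss.default_scene(seed)
    cam = ss.default_camera(size)
    mats, rigs = ss.material_grid(), ss.light_grid()
    poses = ss.sample_camera_path(scene, n_pairs, 0.2, 0.1, seed=seed)
    pairs = []
    for k, pose in enumerate(poses):
        li, mi = (k // 3) % 3, k % 3
        spec = dataclasses.replace(
            scene, material=mats[mi], lights=rigs[li], seed=seed + k
        )
        pr = ss.render_pair(spec, cam, pose, step=ray_step, subset_id=(li, mi))
        rgb = ss.add_specular_artifacts(pr.rgb, n_blobs=2, seed=seed * 131 + k)
        pairs.append((rgb, pr.depth))
    n_sh = n_shifted_train + n_shifted_test
    shifted_train, shifted_test = [], []
    if n_sh:
        sposes = ss.sample_camera_path(scene, n_sh, 0.2, 0.1, seed=seed + 10007)
        for k, pose in enumerate(sposes):
            pr = ss.render_domain_shifted(scene, cam, pose, step=ray_step)
            if k < n_shifted_train:
                shifted_train.append(pr.rgb)
            else:
                shifted_test.append((pr.rgb, pr.depth))
    return pairs, shifted_train, shifted_test


def compare_modes(cfg: ExperimentConfig, seed: int):
    """Train every requested mode on identical data/seed; return report rows.

    Each row carries the MetricReport on the held-out synthetic test split
    and (when shifted frames exist) on the held-out domain-shifted split.
    """
    pairs, sh_train, sh_test = render_toy_dataset(
        cfg.n_pairs,
        cfg.n_shifted_train,
        cfg.n_shifted_test,
        size=cfg.image_size,
        seed=cfg.scene_seed,
        ray_step=cfg.ray_step,
    )
    idx_rows = split_dataset([{"i": i} for i in range(len(pairs))], seed=seed)
    tr = [pairs[r["i"]] for r in idx_rows if r["split"] == "train"]
    va = [pairs[r["i"]] for r in idx_rows if r["split"] == "val"]
    te = [pairs[r["i"]] for r in idx_rows if r["split"] == "test"]
    codec = DepthCodec()
    rows = []
    for mode in cfg.modes:
        config = TrainingConfig(
            mode=mode,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            seed=seed,
        )
        trainer = Pix2PixTrainer(cfg.gen_spec, cfg.disc_spec, config, codec)
        reals = sh_train if mode == "extended" else []
        report = trainer.fit(tr, reals=reals, val_pairs=va)
        row = {
            "mode": mode,
            "seed": seed,
            "synthetic": evaluate_pairs(
                lambda c: trainer.predict(c, noise_seed=seed), te
            ),
            "train_report": report,
        }
        if sh_test:
            row["shifted"] = evaluate_pairs(
                lambda c: trainer.predict(c, noise_seed=seed), sh_test
            )
        rows.append(row)
        log.info(
            "mode=%s seed=%d test L1=%.3f cm%s",
            mode,
            seed,
            row["synthetic"].mean_l1,
            f" shifted L1={row['shifted'].mean_l1:.3f} cm" if sh_test else "",
        )
    return rows


def run_comparison(cfg: ExperimentConfig):
    """Full comparison over all configured seeds; writes CSV + JSON tables.

    The CSV mirrors the familiar model-comparison layout: one row per mode
    with mean +/- std of L1 (cm), relative L1 (%) and RMSE (cm) over the
    held-out synthetic split, plus the same metrics on the domain-shifted
    split. Deterministic given the seed list.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    log.info("comparison config hash %s seeds %s", cfg_hash, list(cfg.seeds))
    all_rows = []
    for seed in cfg.seeds:
        all_rows.extend(compare_modes(cfg, seed))
    table = []
    for mode in cfg.modes:
        rows = [r for r in all_rows if r["mode"] == mode]
        syn = [r["synthetic"] for r in rows]
        entry = {
            "mode": mode,
            "mean_l1_cm": float(np.mean([m.mean_l1 for m in syn])),
            "std_l1_cm": float(np.mean([m.std_l1 for m in syn])),
            "mean_rel_l1_pct": float(np.mean([m.mean_rel_l1 for m in syn])),
            "std_rel_l1_pct": float(np.mean([m.std_rel_l1 for m in syn])),
            "mean_rmse_cm": float(np.mean([m.mean_rmse for m in syn])),
            "std_rmse_cm": float(np.mean([m.std_rmse for m in syn])),
            "mean_max_l1_cm": float(np.mean([m.mean_max_l1 for m in syn])),
        }
        if "shifted" in rows[0]:
            sh = [r["shifted"] for r in rows]
            entry["shifted_mean_l1_cm"] = float(np.mean([m.mean_l1 for m in sh]))
            entry["shifted_mean_rmse_cm"] = float(np.mean([m.mean_rmse for m in sh]))
        table.append(entry)
    csv_path = os.path.join(cfg.out_dir, "comparison.csv")
    with open(csv_path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(table[0].keys()))
        w.writeheader()
        w.writerows(table)
    with open(os.path.join(cfg.out_dir, "comparison.json"), "w") as fh:
        json.dump({"config_hash": cfg_hash, "table": table}, fh, indent=1)
    return table


# ---------------------------------------------------------------------------
# Canonical desk-scale studies
# ---------------------------------------------------------------------------


def learning_smoke_study(seed):
    """Short standard-pix2pix run: does validation L1 drop below epoch 1?

    40 pairs at 32x32, 30 epochs, published hyper-parameters (lambda=200,
    Adam 2e-4, batch 20). Returns (val_l1_epoch1, val_l1_final) in cm.
    """
    pairs, _, _ = render_toy_dataset(40, 0, 0, size=32, seed=seed)
    idx = split_dataset([{"i": i} for i in range(len(pairs))], seed=seed)
    tr_pairs = [pairs[r["i"]] for r in idx if r["split"] == "train"]
    va_pairs = [pairs[r["i"]] for r in idx if r["split"] == "val"]
    cfg = TrainingConfig(mode="standard", epochs=30, batch_size=20, seed=seed)
    trainer = Pix2PixTrainer(
        GeneratorSpec(n_levels=3, base_channels=8),
        DiscriminatorSpec(n_layers=2, base_channels=8),
        cfg,
        DepthCodec(),
    )
    report = trainer.fit(tr_pairs, val_pairs=va_pairs, epochs=30)
    return report.val_l1_cm[0], report.val_l1_cm[-1]


def domain_adaptation_study(seed, epochs=80, size=64):
    """Paired standard-vs-extended comparison on held-out shifted frames.

    Both models share data, initialization seed and schedule; only the
    extended model's adversarial loss sees the unlabeled domain-shifted
    pool. Predictions are averaged over three dropout draws. Returns
    (standard_shifted_l1_cm, extended_shifted_l1_cm).
    """
    pairs, sh_train, sh_test = render_toy_dataset(30, 16, 10, size=size, seed=0)
    idx = split_dataset([{"i": i} for i in range(len(pairs))], seed=seed)
    tr_pairs = [pairs[r["i"]] for r in idx if r["split"] == "train"]
    va_pairs = [pairs[r["i"]] for r in idx if r["split"] == "val"]
    out = {}
    for mode in ("standard", "extended"):
        cfg = TrainingConfig(mode=mode, epochs=epochs, batch_size=10, seed=seed)
        trainer = Pix2PixTrainer(
            GeneratorSpec(n_levels=4, base_channels=8),
            DiscriminatorSpec(n_layers=3, base_channels=8),
            cfg,
            DepthCodec(),
        )
        trainer.fit(
            tr_pairs,
            reals=sh_train if mode == "extended" else [],
            val_pairs=va_pairs,
            epochs=epochs,
        )
        out[mode] = float(
            np.mean(
                [
                    np.mean(
                        [
                            np.mean(np.abs(trainer.predict(c, noise_seed=s) - d))
                            for s in (seed, seed + 1, seed + 2)
                        ]
                    )
                    for c, d in sh_test
                ]
            )
        )
    return out["standard"], out["extended"]


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def make_fixtures(out_dir, seed=0, size=32):
    """Deterministic micro-dataset + geometry fixtures for the test suites.

    Writes 18 RGB/depth pairs (9 subsets x 2), 6 domain-shifted frames, a
    stereo marker-correspondence CSV generated from a synthetic rig with its
    ground-truth JSON, and expected-value JSONs computed by brute-force
    oracles (codec samples, loop-computed metrics). Byte-identical across
    reruns with the same seed.
    """
    os.makedirs(out_dir, exist_ok=True)
    cam = ss.default_camera(size)
    rows = ss.generate_dataset(
        out_dir, n_per_subset=2, seed=seed, camera=cam, n_domain_shifted=6, step=0.1
    )

    # synthetic stereo rig + markers: project known 3D points into both views
    rig_cam = ss.CameraModel(fx=120.0, fy=120.0, cx=63.5, cy=63.5, width=128, height=128)
    rng = np.random.default_rng(seed)
    n_mark = 6
    world = np.column_stack(
        [rng.uniform(-1.5, 1.5, n_mark), rng.uniform(-1.5, 1.5, n_mark), rng.uniform(4.0, 9.0, n_mark)]
    )
    baseline = np.array([-0.5, 0.0, 0.0])  # right camera at +0.5 cm along x
    lpix = rig_cam.project(world)
    rpix = rig_cam.project(world + baseline)
    with open(os.path.join(out_dir, "markers_stereo.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "lx", "ly", "rx", "ry"])
        for i in range(n_mark):
            w.writerow([i, *(f"{v:.10f}" for v in (*lpix[i], *rpix[i]))])
    # a known similarity transform from world to "virtual" coordinates
    ang = 0.4
    Rv = np.array(
        [
            [np.cos(ang), -np.sin(ang), 0.0],
            [np.sin(ang), np.cos(ang), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    s_true, t_true = 2.0, np.array([1.0, -2.0, 0.5])
    virtual = s_true * world @ Rv.T + t_true
    with open(os.path.join(out_dir, "markers_3d.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "wx", "wy", "wz", "vx", "vy", "vz"])
        for i in range(n_mark):
            w.writerow([i, *(f"{v:.10f}" for v in (*world[i], *virtual[i]))])
    rig_meta = {
        "camera": dataclasses.asdict(rig_cam),
        "baseline_t": list(baseline),
        "transform": {"s": s_true, "R": Rv.tolist(), "t": t_true.tolist()},
        "world_points": world.tolist(),
    }
    with open(os.path.join(out_dir, "rig_truth.json"), "w") as fh:
        json.dump(rig_meta, fh, indent=1, sort_keys=True)

    # expected values from brute-force oracles
    codec_dmax = 20.0
    depths = [0.0, float(np.e - 1.0), 5.0, codec_dmax]
    expected = {
        "codec": {
            "d_max": codec_dmax,
            "depths": depths,
            "encoded": [
                2.0 * float(np.log1p(d)) / float(np.log1p(codec_dmax)) - 1.0
                for d in depths
            ],
        },
        "loss_cgan_half": 2.0 * float(np.log(0.5)),
    }
    x = rng.uniform(0.5, 19.5, (5, 5))
    y = rng.uniform(0.5, 19.5, (5, 5))
    acc_l1 = acc_sq = acc_mx = acc_rel = 0.0
    for i in range(5):
        for j in range(5):
            d = abs(x[i, j] - y[i, j])
            acc_l1 += d
            acc_sq += d * d
            acc_mx = max(acc_mx, d)
            acc_rel += d / x[i, j]
    expected["metrics_5x5"] = {
        "x": x.tolist(),
        "y": y.tolist(),
        "l1": acc_l1 / 25.0,
        "rmse": float(np.sqrt(acc_sq / 25.0)),
        "max": acc_mx,
        "rel_pct": 100.0 * acc_rel / 25.0,
    }
    with open(os.path.join(out_dir, "expected.json"), "w") as fh:
        json.dump(expected, fh, indent=1, sort_keys=True)
    return rows
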
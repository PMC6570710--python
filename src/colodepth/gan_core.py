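"""Conditional-GAN depth prediction: losses, training regimes, codec, splits.

The generator G maps an RGB colonoscopy-like image c (plus dropout noise z)
to a depth map; the discriminator D scores (condition, depth) channel pairs
as real or fake. Training minimizes, over G, the maximum over D of

    L_cGAN(G, D) = E[log(1 - D(c, G(c, z)))] + E[log D(c, x)]

combined with an L1 reconstruction term weighted by lambda (default 200).

Three regimes are supported:

* ``standard``   — plain pix2pix on paired synthetic data (no batchnorm).
* ``extended``   — each batch additionally carries unlabeled real-domain
  images c_r whose predictions y_r = G(c_r, z) join the *fake* set of the
  adversarial loss for both players but are excluded from the L1 term
  (no labels exist for them); loss weights are unchanged. This is the
  implicit domain-adaptation mechanism.
* ``discriminative`` — the generator architecture trained by pure L1
  regression with the adversarial term disabled.

Depth enters the model through a logarithmic codec,
``encode(d) = 2*ln(1+d)/ln(1+d_max) - 1``, mapping [0, d_max] onto [-1, 1];
metrics are always computed on decoded cm-scale maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, PatchDiscriminator, UNetGenerator

_P_EPS = 1e-7  # probability clip for log terms

__all__ = [
    "DepthCodec",
    "GeneratorSpec",
    "DiscriminatorSpec",
    "TrainingConfig",
    "TrainBatch",
    "TrainReport",
    "Pix2PixTrainer",
    "encode_depth",
    "decode_depth",
    "loss_cgan",
    "loss_l1",
    "combined_generator_objective",
    "split_dataset",
    "train",
    "predict_depth",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Depth codec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepthCodec:
    """Invertible log remap between metric depth (cm) and model space [-1,1]."""

    d_max: float = 20.0

    def encode(self, depth):
        d = np.asarray(depth, dtype=float)
        if np.any(d < -1e-9) or np.any(d > self.d_max + 1e-9):
            raise ValueError(f"depth outside [0, {self.d_max}]")
        d = np.clip(d, 0.0, self.d_max)
        return 2.0 * np.log1p(d) / np.log1p(self.d_max) - 1.0

    def decode(self, encoded):
        e = np.asarray(encoded, dtype=float)
        if np.any(e < -1.0 - 1e-9) or np.any(e > 1.0 + 1e-9):
            raise ValueError("encoded depth outside [-1, 1]")
        e = np.clip(e, -1.0, 1.0)
        return np.expm1(0.5 * (e + 1.0) * np.log1p(self.d_max))


def encode_depth(depth, codec: DepthCodec):
    """Metric depth (cm) -> model space [-1, 1]; strictly increasing."""
    return codec.encode(depth)


def decode_depth(encoded, codec: DepthCodec):
    """Exact inverse of :func:`encode_depth`."""
    return codec.decode(encoded)


# ---------------------------------------------------------------------------
# Specs and configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorSpec:
    """U-Net generator contract: L levels, skip i <-> L+1-i, no batchnorm."""

    n_levels: int = 3
    base_channels: int = 8
    max_channels: int = 64
    dropout_p: float = 0.5
    use_dropout_at_inference: bool = True  # dropout realizes the noise input z


@dataclass(frozen=True)
class DiscriminatorSpec:
    n_layers: int = 2
    base_channels: int = 8
    max_channels: int = 64
    aggregation: str = "mean_patch"  # or "global"


@dataclass(frozen=True)
class TrainingConfig:
    lambda_l1: float = 200.0
    lr: float = 2e-4
    epochs: int = 300
    batch_size: int = 20
    reals_per_batch: int = 1
    split_ratios: tuple = (6, 1, 3)
    seed: int = 0
    mode: str = "standard"  # standard | extended | discriminative
    gen_loss_form: str = "non_saturating"  # or "minimax"

    def __post_init__(self):
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")
        if any(r <= 0 for r in self.split_ratios):
            raise ValueError("split ratios must be positive")
        if self.reals_per_batch >= self.batch_size:
            raise ValueError("reals_per_batch must be < batch_size")
        if self.mode not in ("standard", "extended", "discriminative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.gen_loss_form not in ("non_saturating", "minimax"):
            raise ValueError(f"unknown gen_loss_form {self.gen_loss_form!r}")


@dataclass
class TrainBatch:
    """pairs: (rgb HxWx3 in [0,1], depth HxW cm); reals: unlabeled rgb only."""

    pairs: list
    reals: list = field(default_factory=list)


@dataclass
class TrainReport:
    g_loss: list = field(default_factory=list)
    d_loss: list = field(default_factory=list)
    l1_term: list = field(default_factory=list)
    adv_term: list = field(default_factory=list)
    val_l1_cm: list = field(default_factory=list)


@dataclass
class StepLosses:
    d_loss: float
    g_adv: float
    g_l1: float
    g_total: float


# ---------------------------------------------------------------------------
# Loss functions
# ---------------------------------------------------------------------------


def _check_probs(p):
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("discriminator outputs must lie strictly in (0,1)")
    return p


def loss_cgan(d_real, d_fake):
    """E[log(1 - d_fake)] + E[log d_real]: the value the discriminator ascends."""
    d_real = _check_probs(d_real)
    d_fake = _check_probs(d_fake)
    return float(np.mean(np.log1p(-d_fake)) + np.mean(np.log(d_real)))


def loss_l1(y, x_encoded):
    """Mean absolute difference over all pixels (model-space maps)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x_encoded, dtype=float)
    if y.shape != x.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {x.shape}")
    return float(np.mean(np.abs(y - x)))


def combined_generator_objective(adv_term, l1_term, lambda_l1):
    """adv + lambda * L1 — the generator's full objective."""
    if lambda_l1 < 0:
        raise ValueError("lambda_l1 must be >= 0")
    return float(adv_term) + float(lambda_l1) * float(l1_term)


# ---------------------------------------------------------------------------
# Image layout helpers
# ---------------------------------------------------------------------------


def _to_nchw(imgs):
    """List/array of HxWx3 (or HxW) images -> (N,C,H,W) float array."""
    a = np.asarray(imgs, dtype=float)
    if a.ndim == 3 and a.shape[-1] == 3:
        a = a[None]
    if a.ndim == 2:
        a = a[None, None]
    elif a.ndim == 3:  # N x H x W single-channel
        a = a[:, None]
    elif a.ndim == 4 and a.shape[-1] == 3:
        a = np.moveaxis(a, -1, 1)
    return a


# ---------------------------------------------------------------------------
# Trainer
# ---------------------------------------------------------------------------


class Pix2PixTrainer:
    """Owns G, D, their Adam optimizers and the step logic for all regimes."""

    def __init__(
        self,
        gen_spec: GeneratorSpec = GeneratorSpec(),
        disc_spec: DiscriminatorSpec = DiscriminatorSpec(),
        config: TrainingConfig = TrainingConfig(),
        codec: DepthCodec = DepthCodec(),
    ):
        self.gen_spec = gen_spec
        self.disc_spec = disc_spec
        self.config = config
        self.codec = codec
        self.G = UNetGenerator(
            in_channels=3,
            out_channels=1,
            n_levels=gen_spec.n_levels,
            base_channels=gen_spec.base_channels,
            max_channels=gen_spec.max_channels,
            dropout_p=gen_spec.dropout_p,
            seed=config.seed,
        )
        self.D = PatchDiscriminator(
            in_channels=4,
            n_layers=disc_spec.n_layers,
            base_channels=disc_spec.base_channels,
            max_channels=disc_spec.max_channels,
            aggregation=disc_spec.aggregation,
            seed=config.seed + 1,
        )
        self.optG = Adam(self.G.layers(), lr=config.lr)
        self.optD = Adam(self.D.layers(), lr=config.lr)

    # -- forward passes -----------------------------------------------------
    def generator_forward(self, c, noise_seed=0):
        """RGB (HxWx3 or NxHxWx3, [0,1]) -> model-space map(s) in [-1,1]."""
        single = np.asarray(c).ndim == 3
        cn = 2.0 * _to_nchw(c) - 1.0
        y = self.G.forward(cn, np.random.default_rng(noise_seed))
        return y[0, 0] if single else y[:, 0]

    def discriminator_forward(self, c, m):
        """Condition + depth-like map -> probability (scalar or (N,))."""
        single = np.asarray(c).ndim == 3
        cn = 2.0 * _to_nchw(c) - 1.0
        mn = _to_nchw(m)
        p = self.D.forward(cn, mn)
        return float(p[0]) if single else p

    def predict(self, c, noise_seed=0):
        """RGB image -> depth map in cm, clipped to [0, d_max]."""
        y = self.generator_forward(c, noise_seed=noise_seed)
        return np.clip(self.codec.decode(np.clip(y, -1, 1)), 0.0, self.codec.d_max)

    # -- training steps -----------------------------------------------------
    def _step(self, batch: TrainBatch, rng, mode=None):
        cfg = self.config
        mode = mode or cfg.mode
        if not batch.pairs:
            raise ValueError("empty batch")
        for r in batch.reals:
            if not (isinstance(r, np.ndarray) and r.ndim == 3 and r.shape[-1] == 3):
                raise TypeError(
                    "real batch elements must be bare RGB images; "
                    "they carry no ground-truth depth"
                )
        n_p = len(batch.pairs)
        c_pairs = 2.0 * _to_nchw([p[0] for p in batch.pairs]) - 1.0
        x_enc = _to_nchw([self.codec.encode(p[1]) for p in batch.pairs])
        if batch.reals:
            c_reals = 2.0 * _to_nchw(list(batch.reals)) - 1.0
            all_c = np.concatenate([c_pairs, c_reals], axis=0)
        else:
            all_c = c_pairs
        n_f = len(all_c)
        npix = x_enc[0].size

        drop_rng = np.random.default_rng(rng.integers(2**31))
        y_all = self.G.forward(all_c, drop_rng)

        l1 = loss_l1(y_all[:n_p], x_enc)
        if mode == "discriminative":
            # pure regression: adversarial term disabled entirely
            self.G.zero_grad()
            dY = np.zeros_like(y_all)
            dY[:n_p] = np.sign(y_all[:n_p] - x_enc) / (n_p * npix)
            self.G.backward(dY)
            self.optG.step()
            return StepLosses(d_loss=0.0, g_adv=0.0, g_l1=l1, g_total=l1)

        # --- discriminator ascent on L_cGAN ---
        self.D.zero_grad()
        p_real = self.D.forward(c_pairs, x_enc)
        pr = np.clip(p_real, _P_EPS, 1 - _P_EPS)
        self.D.backward(-1.0 / (n_p * pr))  # descend -(mean log p_real)
        p_fake = self.D.forward(all_c, y_all)
        pf = np.clip(p_fake, _P_EPS, 1 - _P_EPS)
        self.D.backward(1.0 / (n_f * (1.0 - pf)))  # descend -(mean log(1-p_fake))
        self.optD.step()
        d_loss = np.mean(np.log1p(-pf)) + np.mean(np.log(pr))

        # --- generator descent on adv + lambda * L1 ---
        self.G.zero_grad()
        self.D.zero_grad()
        p_fake2 = self.D.forward(all_c, y_all)
        pf2 = np.clip(p_fake2, _P_EPS, 1 - _P_EPS)
        if cfg.gen_loss_form == "non_saturating":
            g_adv = -float(np.mean(np.log(pf2)))
            dp = -1.0 / (n_f * pf2)
        else:  # minimax form as printed in the objective
            g_adv = float(np.mean(np.log1p(-pf2)))
            dp = -1.0 / (n_f * (1.0 - pf2))
        _, dY = self.D.backward(dp)
        self.D.zero_grad()  # D parameter gradients from the G pass are discarded
        dY = dY.copy()
        # L1 gradients attach to synthetic pairs only: reals have no labels
        dY[:n_p] += cfg.lambda_l1 * np.sign(y_all[:n_p] - x_enc) / (n_p * npix)
        self.G.backward(dY)
        self.optG.step()
        return StepLosses(
            d_loss=float(d_loss),
            g_adv=g_adv,
            g_l1=l1,
            g_total=combined_generator_objective(g_adv, l1, cfg.lambda_l1),
        )

    def train_step_standard(self, batch: TrainBatch, rng=None):
        """One pix2pix step: D ascends L_cGAN, G descends adv + lambda*L1."""
        if batch.reals:
            raise ValueError("standard step takes no real images")
        rng = rng if rng is not None else np.random.default_rng(self.config.seed)
        return self._step(batch, rng, mode="standard")

    def train_step_extended(self, batch: TrainBatch, rng=None):
        """Standard step + unlabeled reals in the adversarial fake set only.

        For each real image c_r the pair (c_r, G(c_r, z)) is scored by the
        discriminator as a fake for both players; no L1 term is formed for
        reals and the loss weights are unchanged. With ``reals=[]`` this
        degenerates numerically to the standard step.
        """
        rng = rng if rng is not None else np.random.default_rng(self.config.seed)
        return self._step(batch, rng, mode="extended" if batch.reals else "standard")

    # -- full training loop -------------------------------------------------
    def fit(self, pairs, reals=None, val_pairs=None, epochs=None, log=None):
        """Run epochs of the configured step over shuffled batches.

        ``pairs``: list of (rgb, depth_cm); ``reals``: unlabeled rgb pool
        (required in extended mode); ``val_pairs`` drive the per-epoch
        validation mean-L1 (cm) and best-checkpoint selection. Deterministic
        given the config seed. Returns a TrainReport.
        """
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        reals = list(reals or [])
        if cfg.mode == "extended" and not reals:
            raise ValueError("extended mode requires a non-empty real-image pool")
        rng = np.random.default_rng(cfg.seed)
        report = TrainReport()
        best = (np.inf, self.G.state_dict())
        n_syn = (
            cfg.batch_size - cfg.reals_per_batch
            if cfg.mode == "extended"
            else cfg.batch_size
        )
        n_syn = max(1, min(n_syn, len(pairs)))
        for epoch in range(epochs):
            order = rng.permutation(len(pairs))
            ep = {"g": [], "d": [], "l1": [], "adv": []}
            for start in range(0, len(pairs), n_syn):
                idx = order[start : start + n_syn]
                if len(idx) == 0:
                    continue
                bp = [pairs[i] for i in idx]
                br = []
                if cfg.mode == "extended":
                    ridx = rng.integers(0, len(reals), cfg.reals_per_batch)
                    br = [reals[i] for i in ridx]
                losses = self._step(TrainBatch(pairs=bp, reals=br), rng)
                ep["g"].append(losses.g_total)
                ep["d"].append(losses.d_loss)
                ep["l1"].append(losses.g_l1)
                ep["adv"].append(losses.g_adv)
            report.g_loss.append(float(np.mean(ep["g"])))
            report.d_loss.append(float(np.mean(ep["d"])))
            report.l1_term.append(float(np.mean(ep["l1"])))
            report.adv_term.append(float(np.mean(ep["adv"])))
            if val_pairs:
                v = self.validate(val_pairs, noise_seed=cfg.seed)
                report.val_l1_cm.append(v)
                if v < best[0]:
                    best = (v, self.G.state_dict())
            if log:
                log(epoch, report)
        if val_pairs and report.val_l1_cm:
            self.G.load_state_dict(best[1])
        return report

    def validate(self, pairs, noise_seed=0):
        """Mean absolute depth error (cm) of predictions over (rgb, depth) pairs."""
        errs = [
            float(np.mean(np.abs(self.predict(c, noise_seed=noise_seed) - d)))
            for c, d in pairs
        ]
        return float(np.mean(errs))


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------


def split_dataset(rows, ratios=(6, 1, 3), seed=0):
    """Random disjoint train/val/test partition with largest-remainder rounding.

    ``rows`` is a manifest (list of dicts); returns a new list with the
    ``split`` field filled. With 10k items and the default 6:1:3 ratios the
    proportions are exact.
    """
    rows = list(rows)
    n = len(rows)
    if n < 3:
        raise ValueError("need at least 3 items to split")
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("ratios must be positive")
    quota = n * ratios / ratios.sum()
    counts = np.floor(quota).astype(int)
    rem = quota - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    names = ["train", "val", "test"]
    out = [dict(r) for r in rows]
    pos = 0
    for name, cnt in zip(names, counts):
        for i in order[pos : pos + cnt]:
            out[i]["split"] = name
        pos += cnt
    return out


# ---------------------------------------------------------------------------
# Manifest-level train / predict and checkpointing
# ---------------------------------------------------------------------------


def _load_split(manifest_rows, split, domain="synthetic"):
    from .scene_sim import load_pair

    pairs = []
    for row in manifest_rows:
        if row.get("split") == split and row.get("domain", "synthetic") == domain:
            pr = load_pair(row["path_rgb"], row["path_depth"])
            pairs.append((pr.rgb, pr.depth))
    return pairs


def train(
    manifest_rows,
    config: TrainingConfig,
    gen_spec: GeneratorSpec = GeneratorSpec(),
    disc_spec: DiscriminatorSpec = DiscriminatorSpec(),
    codec: DepthCodec = DepthCodec(),
    real_pool=None,
    epochs=None,
    log=None,
):
    """Train from a manifest with a filled split column; returns (trainer, report).

    Synthetic rows with split=train/val feed the paired losses; the real pool
    for extended mode is either ``real_pool`` (list of RGB arrays) or the
    manifest rows with domain="shifted" (RGB only — their depth is never read).
    """
    train_pairs = _load_split(manifest_rows, "train")
    if not train_pairs:
        raise ValueError("manifest has no train split")
    val_pairs = _load_split(manifest_rows, "val")
    reals = list(real_pool or [])
    if config.mode == "extended" and not reals:
        from .scene_sim import load_pair

        for row in manifest_rows:
            if row.get("domain") == "shifted":
                reals.append(load_pair(row["path_rgb"], row["path_depth"]).rgb)
        if not reals:
            raise ValueError("extended mode requires a real/domain-shifted pool")
    trainer = Pix2PixTrainer(gen_spec, disc_spec, config, codec)
    report = trainer.fit(train_pairs, reals=reals, val_pairs=val_pairs, epochs=epochs, log=log)
    return trainer, report


def predict_depth(trainer: Pix2PixTrainer, c, noise_seed=0):
    """decode(G(c, z)): depth map in cm, within [0, d_max]."""
    return trainer.predict(c, noise_seed=noise_seed)


def save_checkpoint(path, trainer: Pix2PixTrainer):
    """Serialize G/D parameters plus the training config and depth codec."""
    import dataclasses as dc

    meta = {
        "config": dc.asdict(trainer.config),
        "gen_spec": dc.asdict(trainer.gen_spec),
        "disc_spec": dc.asdict(trainer.disc_spec),
        "codec": dc.asdict(trainer.codec),
    }
    arrays = {f"G.{k}": v for k, v in trainer.G.state_dict().items()}
    arrays.update({f"D.{k}": v for k, v in trainer.D.state_dict().items()})
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg = TrainingConfig(**{**meta["config"], "split_ratios": tuple(meta["config"]["split_ratios"])})
    trainer = Pix2PixTrainer(
        GeneratorSpec(**meta["gen_spec"]),
        DiscriminatorSpec(**meta["disc_spec"]),
        cfg,
        DepthCodec(**meta["codec"]),
    )
    trainer.G.load_state_dict(
        {k[2:]: data[k] for k in data.files if k.startswith("G.")}
    )
    trainer.D.load_state_dict(
        {k[2:]: data[k] for k in data.files if k.startswith("D.")}
    )
    return trainer
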
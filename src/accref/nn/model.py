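"""Accuracy-prediction network: architecture, loss, toy training.

The network mirrors the published accuracy-estimation design: a shared
3D-convolutional encoder summarizes each residue's local atomic environment;
the resulting per-residue embeddings are concatenated with the other 1D
features, tiled onto the pair grid together with the 2D features, and passed
through a residual 2D trunk of 20 blocks with dilation rates cycling
1, 2, 4, 8.  Two four-block arms emit, per ordered pair, 15 estogram logits
and one contact-mask logit.  Outputs are symmetrized and the per-residue
l-DDT is reconstructed from them, so the l-DDT head costs no extra
parameters.  Channel widths default to CPU-friendly values and are
configurable; training uses ADAM at lr 5e-4 with a 0.98 per-epoch decay and

    loss = estogram cross-entropy + 10 * l-DDT MSE + 0.25 * mask BCE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ..estogram import (AccuracyPrediction, BinSpec, Estogram,
                        LDDT_CUTOFF_CATEGORIES, predicted_lddt)
from ..features import FeatureBundle
from . import autograd as ag
from .autograd import Tensor


@dataclass(frozen=True)
class NetworkConfig:
    trunk_blocks: int = 20
    dilation_cycle: tuple = (1, 2, 4, 8)
    arm_blocks: int = 4
    estogram_categories: int = 15
    trunk_width: int = 32
    encoder_channels: tuple = (8, 16)
    embed_dim: int = 16
    voxel_channels: int = 5
    f1_dim: int = 40
    f2_dim: int = 10
    lr: float = 0.0005
    lr_decay_per_epoch: float = 0.98

    def fingerprint(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass(frozen=True)
class LossWeights:
    estogram: float = 1.0
    lddt: float = 10.0
    mask: float = 0.25

    def __post_init__(self) -> None:
        if min(self.estogram, self.lddt, self.mask) < 0:
            raise ValueError("loss weights must be non-negative")


def _cutoff_matrix(n_cat: int) -> np.ndarray:
    """15 x 4 indicator: category k contributes to |e| <= 0.5/1/2/4 A."""
    m = np.zeros((n_cat, 4))
    for col, cutoff in enumerate((0.5, 1.0, 2.0, 4.0)):
        for cat in LDDT_CUTOFF_CATEGORIES[cutoff]:
            m[cat, col] = 1.0
    return m


def lddt_from_outputs(probs: Tensor, mask: Tensor, n: int,
                      eps: float = 1e-9) -> Tensor:
    """Differentiable per-residue l-DDT from estogram probs and mask."""
    k = Tensor(_cutoff_matrix(probs.shape[-1]))
    within = (probs.reshape(n * n, -1) @ k).reshape(n, n, 4)
    offdiag = Tensor(1.0 - np.eye(n))
    w = mask * offdiag                               # (n, n)
    weighted = within * w.reshape(n, n, 1)
    num = weighted.sum(axis=1).sum(axis=1)           # (n,)
    p4 = w.sum(axis=1)                               # (n,)
    return num * 0.25 / (p4 + Tensor(np.full(n, eps)))


class AccuracyNetwork:
    """Trainable estogram / mask / l-DDT predictor."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        self.config = config or NetworkConfig()
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(seed)
        self._build()

    # -- construction -------------------------------------------------------

    def _param(self, name: str, shape: tuple, fan_in: int,
               gain: float = 1.0) -> Tensor:
        scale = gain * np.sqrt(2.0 / fan_in)
        t = Tensor(self._rng.normal(0.0, scale, size=shape), requires_grad=True)
        self.params[name] = t
        return t

    def _bias(self, name: str, size: int) -> Tensor:
        t = Tensor(np.zeros(size), requires_grad=True)
        self.params[name] = t
        return t

    def _build(self) -> None:
        cfg = self.config
        c_in = cfg.voxel_channels
        c1, c2 = cfg.encoder_channels
        self._param("enc.w1", (3, 3, 3, c_in, c1), 27 * c_in)
        self._bias("enc.b1", c1)
        self._param("enc.w2", (3, 3, 3, c1, c2), 27 * c1)
        self._bias("enc.b2", c2)
        self._param("enc.wd", (c2, cfg.embed_dim), c2)
        self._bias("enc.bd", cfg.embed_dim)

        width = cfg.trunk_width
        pair_in = 2 * (cfg.f1_dim + cfg.embed_dim) + cfg.f2_dim
        self._param("proj.w", (pair_in, width), pair_in)
        self._bias("proj.b", width)
        # residual branches start small so the deep trunk is near-identity
        # at initialization and the heads emit moderate logits
        res_gain = 1.0 / np.sqrt(cfg.trunk_blocks + cfg.arm_blocks)
        for blk in range(cfg.trunk_blocks):
            self._param(f"trunk.{blk}.w", (3, 3, width, width), 9 * width,
                        gain=res_gain)
            self._bias(f"trunk.{blk}.b", width)
        for arm in ("esto", "mask"):
            for blk in range(cfg.arm_blocks):
                self._param(f"{arm}.{blk}.w", (3, 3, width, width), 9 * width,
                            gain=res_gain)
                self._bias(f"{arm}.{blk}.b", width)
        self._param("esto.out.w", (width, cfg.estogram_categories), width,
                    gain=0.1)
        self._bias("esto.out.b", cfg.estogram_categories)
        self._param("mask.out.w", (width, 1), width, gain=0.1)
        self._bias("mask.out.b", 1)

    # -- introspection ------------------------------------------------------

    @property
    def n_trunk_blocks(self) -> int:
        return self.config.trunk_blocks

    @property
    def trunk_dilations(self) -> list[int]:
        cyc = self.config.dilation_cycle
        return [cyc[i % len(cyc)] for i in range(self.config.trunk_blocks)]

    # -- forward ------------------------------------------------------------

    def _residual_stack(self, x: Tensor, prefix: str, n_blocks: int,
                        dilated: bool) -> Tensor:
        cyc = self.config.dilation_cycle
        for blk in range(n_blocks):
            dil = cyc[blk % len(cyc)] if dilated else 1
            h = ag.conv2d(x.elu(), self.params[f"{prefix}.{blk}.w"],
                          self.params[f"{prefix}.{blk}.b"], dilation=dil)
            x = x + h
        return x

    def _forward_graph(self, bundle: FeatureBundle) -> tuple[Tensor, Tensor]:
        cfg = self.config
        n = bundle.n
        vox = Tensor(bundle.voxels)
        h = ag.conv3d(vox, self.params["enc.w1"], self.params["enc.b1"]).elu()
        h = ag.avgpool3d(h, 2)
        h = ag.conv3d(h, self.params["enc.w2"], self.params["enc.b2"]).elu()
        pooled = h.mean(axis=(1, 2, 3))                       # (n, c2)
        emb = (pooled @ self.params["enc.wd"] + self.params["enc.bd"]).elu()

        f1 = ag.concat([Tensor(bundle.f1), emb], axis=1)      # (n, F1+E)
        fdim = f1.shape[1]
        ones_j = Tensor(np.ones((1, n, 1)))
        ones_i = Tensor(np.ones((n, 1, 1)))
        row_i = f1.reshape(n, 1, fdim) * ones_j
        row_j = f1.reshape(1, n, fdim) * ones_i
        paired = ag.concat([row_i, row_j, Tensor(bundle.f2)], axis=2)

        width = cfg.trunk_width
        x = (paired.reshape(n * n, -1) @ self.params["proj.w"]
             + self.params["proj.b"]).elu().reshape(n, n, width)
        x = self._residual_stack(x, "trunk", cfg.trunk_blocks, dilated=True)

        xe = self._residual_stack(x, "esto", cfg.arm_blocks, dilated=False)
        esto_logits = (xe.elu().reshape(n * n, width) @ self.params["esto.out.w"]
                       + self.params["esto.out.b"]).reshape(n, n, cfg.estogram_categories)
        xm = self._residual_stack(x, "mask", cfg.arm_blocks, dilated=False)
        mask_logits = (xm.elu().reshape(n * n, width) @ self.params["mask.out.w"]
                       + self.params["mask.out.b"]).reshape(n, n)

        probs = esto_logits.softmax(axis=-1)
        mask = mask_logits.sigmoid()
        # symmetrize ordered-pair outputs by averaging
        probs = (probs + probs.transpose((1, 0, 2))) * 0.5
        mask = (mask + mask.transpose((1, 0))) * 0.5
        return probs, mask

    def forward(self, bundle: FeatureBundle) -> AccuracyPrediction:
        """Deterministic inference; returns the standard prediction bundle."""
        probs, mask = self._forward_graph(bundle)
        est = Estogram(probs.data.copy())
        per_res, glob = predicted_lddt(est, mask.data)
        return AccuracyPrediction(est, mask.data.copy(), per_res, glob,
                                  provenance="network")

    # -- loss ---------------------------------------------------------------

    def loss_graph(self, bundle: FeatureBundle, truth: AccuracyPrediction,
                   weights: LossWeights = LossWeights()) -> tuple[Tensor, dict]:
        n = bundle.n
        probs, mask = self._forward_graph(bundle)
        t_est = Tensor(truth.estogram.probs)
        t_mask = Tensor(truth.mask)
        ce = -(t_est * probs.log()).sum(axis=2).mean()
        bce = -(t_mask * mask.log()
                + (1.0 - t_mask) * (1.0 - mask).log()).mean()
        lddt = lddt_from_outputs(probs, mask, n)
        t_lddt = np.nan_to_num(truth.per_residue_lddt, nan=0.0)
        defined = Tensor((~np.isnan(truth.per_residue_lddt)).astype(float))
        n_def = max(1.0, float(defined.data.sum()))
        mse = (((lddt - Tensor(t_lddt)) * defined) ** 2).sum() * (1.0 / n_def)
        total = (ce * weights.estogram + mse * weights.lddt + bce * weights.mask)
        comps = {"estogram": float(ce.data), "lddt": float(mse.data),
                 "mask": float(bce.data)}
        return total, comps

    def loss(self, bundle: FeatureBundle, truth: AccuracyPrediction,
             weights: LossWeights = LossWeights()) -> tuple[float, dict]:
        total, comps = self.loss_graph(bundle, truth, weights)
        return float(total.data), comps

    # -- training -----------------------------------------------------------

    def train_toy(self, dataset: list[tuple[FeatureBundle, AccuracyPrediction]],
                  epochs: int = 100, seed: int = 0,
                  weights: LossWeights = LossWeights(),
                  verbose: bool = False) -> dict:
        """Seeded small-scale training; returns the per-epoch loss log."""
        if not dataset:
            raise ValueError("empty dataset")
        rng = np.random.default_rng(seed)
        opt = ag.Adam(self.params, lr=self.config.lr)
        log = {"epoch_loss": [], "lr": [], "components": []}
        for epoch in range(epochs):
            opt.lr = self.config.lr * self.config.lr_decay_per_epoch ** epoch
            order = rng.permutation(len(dataset))
            losses, comps_acc = [], {"estogram": 0.0, "lddt": 0.0, "mask": 0.0}
            for idx in order:
                bundle, truth = dataset[idx]
                opt.zero_grad()
                total, comps = self.loss_graph(bundle, truth, weights)
                total.backward()
                opt.step()
                losses.append(float(total.data))
                for k in comps_acc:
                    comps_acc[k] += comps[k] / len(dataset)
            log["epoch_loss"].append(float(np.mean(losses)))
            log["lr"].append(opt.lr)
            log["components"].append(comps_acc)
            if verbose:
                print(f"epoch {epoch}: loss {log['epoch_loss'][-1]:.4f}")
        return log

    # -- serialization --------------------------------------------------------

    def save_weights(self, path: str) -> None:
        arrays = {k: p.data for k, p in self.params.items()}
        arrays["__fingerprint__"] = np.frombuffer(
            self.config.fingerprint().encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    def load_weights(self, path: str) -> None:
        with np.load(path) as data:
            fp = bytes(data["__fingerprint__"]).decode()
            if fp != self.config.fingerprint():
                raise ValueError("weight file does not match network configuration")
            for k, p in self.params.items():
                p.data = data[k].copy()


def ensemble_predict(networks: list[AccuracyNetwork],
                     bundle: FeatureBundle) -> AccuracyPrediction:
    """Average estogram and mask probabilities over an ensemble."""
    if not networks:
        raise ValueError("empty ensemble")
    preds = [net.forward(bundle) for net in networks]
    probs = np.mean([p.estogram.probs for p in preds], axis=0)
    mask = np.mean([p.mask for p in preds], axis=0)
    est = Estogram(probs, preds[0].estogram.bin_spec)
    return AccuracyPrediction.from_estogram_mask(est, mask, provenance="network")
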
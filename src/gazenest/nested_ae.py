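"""The nested-autoencoder multi-view classifier.

Architecture, trained jointly end to end on a subject's V = 12 heatmap
pairs:

* **Inner autoencoder** (shared across images): a shallow convolutional
  encoder takes the two viewings of one image stacked as 2 channels of a
  24x32 input and compresses them to an image-dependent latent z (d_z = 64);
  a mirrored transposed-convolution decoder with a sigmoid output
  reconstructs both heatmaps, contributing the reconstruction loss
  ``L_inner = 1/2 * sum_v ||x_v - xhat_v||_F^2``.
* **Outer autoencoder** (shared across views): a fully connected encoder
  maps each z^v to a low-dimensional z~^v (d = 32); a weight-adaptive fusion
  layer forms the subject-level common representation
  ``Z = sum_v softmax(beta_m)_v * z~^v``; a fully connected decoder maps Z
  back to one reconstruction zhat^v per view, contributing
  ``L_outer = 1/2 * (sum_v ||z^v - zhat^v||_F^2 + ||Z - sum_v w_v z~^v||_F^2)``
  (the consistency term vanishes identically when Z is defined as the fused
  sum, as here).
* **Classifier**: a 3-layer fully connected head on Z ending in a sigmoid,
  trained with binary cross-entropy ``L_cls`` (PwAD = 1 positive).

Total loss ``L = L_cls + L_inner + L_outer`` (per-term weights
configurable). Ablation switches reproduce the reduced variants: encoders
only, either decoder alone, difference maps (x2 - x1 replacing the inner
autoencoder) and a shallow CNN replacing the outer autoencoder.

Training is plain-numpy Adam via :mod:`gazenest.autodiff`, so identical
data + config + seed yields bitwise-identical parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .heatmap import GRID_COLS, GRID_ROWS, SubjectViews

__all__ = [
    "TrainConfig",
    "NestedAutoencoderClassifier",
    "train",
    "predict",
    "inner_loss",
    "outer_loss",
    "classification_loss",
    "total_loss",
]

PROB_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings and the ablation switch set."""

    epochs: int = 200
    lr: float = 1e-3
    batch_size: int = 8  # subjects per step
    seed: int = 0
    w_cls: float = 1.0
    w_inner: float = 1.0
    w_outer: float = 1.0
    use_inner_decoder: bool = True
    use_outer_decoder: bool = True
    use_fusion_layer: bool = True
    inner_mode: str = "autoencoder"  # or "difference_map"
    outer_mode: str = "autoencoder"  # or "shallow_cnn"
    d_z: int = 64
    d_z_tilde: int = 32
    n_views: int = 12
    dtype: str = "float32"  # single precision is ample for these magnitudes

    def __post_init__(self) -> None:
        if self.dtype not in ("float32", "float64"):
            raise ValueError(f"unknown dtype {self.dtype!r}")
        if self.inner_mode not in ("autoencoder", "difference_map"):
            raise ValueError(f"unknown inner_mode {self.inner_mode!r}")
        if self.outer_mode not in ("autoencoder", "shallow_cnn"):
            raise ValueError(f"unknown outer_mode {self.outer_mode!r}")


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class NestedAutoencoderClassifier:
    """Jointly trained inner/outer autoencoders plus classifier head."""

    def __init__(self, config: TrainConfig):
        self.config = config
        self._dtype = np.float32 if config.dtype == "float32" else np.float64
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(config.seed))

    # -- parameters --------------------------------------------------------

    def _add(self, name: str, data: np.ndarray) -> None:
        self.params[name] = Tensor(data.astype(self._dtype), requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        if cfg.inner_mode == "autoencoder":
            # inner encoder: conv(2->8,s2) conv(8->16,s2) conv(16->32,s1) dense->d_z
            self._add("ie_c1_w", _he(rng, (8, 2, 3, 3), 2 * 9))
            self._add("ie_c1_b", np.zeros(8))
            self._add("ie_c2_w", _he(rng, (16, 8, 3, 3), 8 * 9))
            self._add("ie_c2_b", np.zeros(16))
            self._add("ie_c3_w", _he(rng, (32, 16, 3, 3), 16 * 9))
            self._add("ie_c3_b", np.zeros(32))
            flat = 32 * (GRID_ROWS // 4) * (GRID_COLS // 4)  # 32*6*8 = 1536
            self._add("ie_fc_w", _he(rng, (flat, cfg.d_z), flat))
            self._add("ie_fc_b", np.zeros(cfg.d_z))
            self._z_dim = cfg.d_z
            if cfg.use_inner_decoder:
                self._add("id_fc_w", _he(rng, (cfg.d_z, flat), cfg.d_z))
                self._add("id_fc_b", np.zeros(flat))
                self._add("id_c3_w", _he(rng, (32, 16, 3, 3), 32 * 9))
                self._add("id_c3_b", np.zeros(16))
                self._add("id_c2_w", _he(rng, (16, 8, 3, 3), 16 * 9))
                self._add("id_c2_b", np.zeros(8))
                self._add("id_c1_w", _he(rng, (8, 2, 3, 3), 8 * 9))
                self._add("id_c1_b", np.zeros(2))
        else:  # difference_map: z is the flattened x2 - x1
            self._z_dim = GRID_ROWS * GRID_COLS

        if cfg.outer_mode == "autoencoder":
            self._add("oe_w", _he(rng, (self._z_dim, cfg.d_z_tilde), self._z_dim))
            self._add("oe_b", np.zeros(cfg.d_z_tilde))
            if cfg.use_fusion_layer:
                self._add("fusion_logits", np.zeros(cfg.n_views))
            if cfg.use_outer_decoder:
                self._add("od_w1", _he(rng, (cfg.d_z_tilde, 128), cfg.d_z_tilde))
                self._add("od_b1", np.zeros(128))
                self._add("od_w2", _he(rng, (128, cfg.n_views * self._z_dim), 128))
                self._add("od_b2", np.zeros(cfg.n_views * self._z_dim))
        else:  # shallow_cnn fusion of the V view latents
            self._add("cnn_c1_w", _he(rng, (16, cfg.n_views, 3, 3), cfg.n_views * 9))
            self._add("cnn_c1_b", np.zeros(16))
            self._add("cnn_c2_w", _he(rng, (32, 16, 3, 3), 16 * 9))
            self._add("cnn_c2_b", np.zeros(32))
            flat = 32 * self._cnn_flat_hw()
            self._add("cnn_fc_w", _he(rng, (flat, cfg.d_z_tilde), flat))
            self._add("cnn_fc_b", np.zeros(cfg.d_z_tilde))

        d = cfg.d_z_tilde
        self._add("cl_w1", _he(rng, (d, 16), d))
        self._add("cl_b1", np.zeros(16))
        self._add("cl_w2", _he(rng, (16, 8), 16))
        self._add("cl_b2", np.zeros(8))
        self._add("cl_w3", _he(rng, (8, 1), 8))
        self._add("cl_b3", np.zeros(1))

    def _latent_grid(self) -> tuple[int, int]:
        """2-D arrangement of a view latent for the shallow-CNN fusion."""
        if self._z_dim == GRID_ROWS * GRID_COLS:
            return GRID_ROWS, GRID_COLS
        side = int(round(np.sqrt(self._z_dim)))
        if side * side != self._z_dim:
            raise ValueError("d_z must be a perfect square for shallow_cnn fusion")
        return side, side

    def _cnn_flat_hw(self) -> int:
        h, w = self._latent_grid()
        h2 = (h + 1) // 2
        w2 = (w + 1) // 2
        return ((h2 + 1) // 2) * ((w2 + 1) // 2)

    # -- forward pieces ----------------------------------------------------

    def inner_forward(self, x: Tensor) -> tuple[Tensor, Tensor | None]:
        """Encode stacked heatmap pairs (N, 2, 24, 32) -> (z, reconstruction)."""
        p = self.params
        cfg = self.config
        if cfg.inner_mode == "difference_map":
            # x2 - x1 per image; parameter-free, no reconstruction. The input
            # carries no gradient, so this can stay outside the graph.
            n = x.data.shape[0]
            diff = x.data[:, 1] - x.data[:, 0]
            return Tensor(diff.reshape(n, -1)), None
        h = ad.conv2d(x, p["ie_c1_w"], p["ie_c1_b"], stride=2, padding=1).relu()
        h = ad.conv2d(h, p["ie_c2_w"], p["ie_c2_b"], stride=2, padding=1).relu()
        h = ad.conv2d(h, p["ie_c3_w"], p["ie_c3_b"], stride=1, padding=1).relu()
        n = h.data.shape[0]
        z = ad.matmul(h.reshape(n, -1), p["ie_fc_w"]) + p["ie_fc_b"]
        if not cfg.use_inner_decoder:
            return z, None
        g = (ad.matmul(z, p["id_fc_w"]) + p["id_fc_b"]).relu()
        g = g.reshape(n, 32, GRID_ROWS // 4, GRID_COLS // 4)
        g = ad.conv_transpose2d(g, p["id_c3_w"], p["id_c3_b"], stride=1, padding=1).relu()
        g = ad.conv_transpose2d(
            g, p["id_c2_w"], p["id_c2_b"], stride=2, padding=1, output_padding=1
        ).relu()
        xhat = ad.conv_transpose2d(
            g, p["id_c1_w"], p["id_c1_b"], stride=2, padding=1, output_padding=1
        ).sigmoid()
        return z, xhat

    def fusion_weights(self) -> np.ndarray:
        """Current softmax fusion weights (uniform when fusion is off)."""
        if "fusion_logits" in self.params:
            return ad.softmax(self.params["fusion_logits"]).data
        return np.full(self.config.n_views, 1.0 / self.config.n_views)

    def outer_forward(self, z: Tensor) -> tuple[Tensor, Tensor, Tensor | None]:
        """Map view latents (B, V, d_z) -> (z_tilde, Z, zhat or None)."""
        p = self.params
        cfg = self.config
        b, v, d = z.data.shape
        if v != cfg.n_views:
            raise ValueError(f"expected {cfg.n_views} views, got {v}")

        if cfg.outer_mode == "shallow_cnn":
            gh, gw = self._latent_grid()
            img = z.reshape(b, v, gh, gw)
            h = ad.conv2d(img, p["cnn_c1_w"], p["cnn_c1_b"], stride=2, padding=1).relu()
            h = ad.conv2d(h, p["cnn_c2_w"], p["cnn_c2_b"], stride=2, padding=1).relu()
            zc = ad.matmul(h.reshape(b, -1), p["cnn_fc_w"]) + p["cnn_fc_b"]
            return zc, zc, None

        zt = ad.matmul(z.reshape(b * v, d), p["oe_w"]) + p["oe_b"]
        zt = zt.reshape(b, v, cfg.d_z_tilde)
        if cfg.use_fusion_layer:
            w = ad.softmax(p["fusion_logits"])
            zz = (zt * w.reshape(1, v, 1)).sum(axis=1)
        else:
            zz = zt.mean(axis=1)  # direct (unweighted) view pooling
        zhat = None
        if cfg.use_outer_decoder:
            hmid = (ad.matmul(zz, p["od_w1"]) + p["od_b1"]).relu()
            zhat = (ad.matmul(hmid, p["od_w2"]) + p["od_b2"]).reshape(b, v, d)
        return zt, zz, zhat

    def classify(self, zz: Tensor) -> Tensor:
        """3-layer FC head on the common representation -> P(PwAD)."""
        p = self.params
        h = (ad.matmul(zz, p["cl_w1"]) + p["cl_b1"]).relu()
        h = (ad.matmul(h, p["cl_w2"]) + p["cl_b2"]).relu()
        logit = ad.matmul(h, p["cl_w3"]) + p["cl_b3"]
        return logit.reshape(-1).sigmoid()

    def forward(self, maps: np.ndarray, labels: np.ndarray | None = None) -> dict:
        """Full forward pass on (B, V, 2, 24, 32) heatmaps.

        Returns probabilities and, when labels are given, the per-subject
        averaged loss terms (Tensors, ready for ``backward``).
        """
        cfg = self.config
        b, v = maps.shape[0], maps.shape[1]
        x = Tensor(maps.reshape(b * v, 2, GRID_ROWS, GRID_COLS).astype(self._dtype))
        z_flat, xhat = self.inner_forward(x)
        z = z_flat.reshape(b, v, self._z_dim)
        zt, zz, zhat = self.outer_forward(z)
        probs = self.classify(zz)
        out = {"probs": probs, "z": z, "z_tilde": zt, "Z": zz}
        if labels is None:
            return out

        zero = Tensor(self._dtype(0.0))
        if xhat is not None:
            d = x - xhat
            l_inner = (d * d).sum() * 0.5 * (1.0 / b)
        else:
            l_inner = zero
        if zhat is not None:
            dz = z - zhat
            # fused-sum consistency term is identically zero by construction
            l_outer = (dz * dz).sum() * 0.5 * (1.0 / b)
        else:
            l_outer = zero
        y = np.asarray(labels, dtype=self._dtype)
        pc = probs.clip(PROB_EPS, 1.0 - PROB_EPS)
        l_cls = -(Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log()).sum() * (1.0 / b)
        total = cfg.w_cls * l_cls + cfg.w_inner * l_inner + cfg.w_outer * l_outer
        out.update(l_cls=l_cls, l_inner=l_inner, l_outer=l_outer, l_total=total)
        return out

    # -- training / inference ----------------------------------------------

    def fit(self, views: list[SubjectViews]) -> list[float]:
        """Train jointly on a cohort; returns the per-epoch mean total loss."""
        cfg = self.config
        maps = np.stack([v.maps for v in views])
        y = np.array([v.label for v in views], dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("training requires both classes")
        if maps.shape[1] != cfg.n_views:
            raise ValueError(f"cohort has {maps.shape[1]} views, config expects {cfg.n_views}")
        rng = np.random.default_rng(cfg.seed + 1)
        opt = ad.Adam(list(self.params.values()), lr=cfg.lr)
        n = len(views)
        trace = []
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                opt.zero_grad()
                out = self.forward(maps[idx], y[idx])
                out["l_total"].backward()
                opt.step()
                epoch_loss += float(out["l_total"].data) * len(idx)
            trace.append(epoch_loss / n)
        return trace

    def predict_proba(self, views: list[SubjectViews]) -> np.ndarray:
        """P(PwAD) per subject; deterministic for a trained model."""
        maps = np.stack([v.maps for v in views])
        return self.forward(maps)["probs"].data.copy()

    def predict(self, views: list[SubjectViews], threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(views) >= threshold).astype(int)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: parameter arrays + config."""
        arrays = {k: t.data for k, t in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "NestedAutoencoderClassifier":
        with np.load(path) as data:
            cfg = TrainConfig(**json.loads(bytes(data["__config__"]).decode()))
            model = cls(cfg)
            for k in model.params:
                model.params[k].data = data[k].copy()
        return model


# -- functional loss/training surface (numpy in, numpy out) -----------------


def inner_loss(x1, x2, xhat1, xhat2) -> float:
    """Reconstruction loss 1/2 * sum_v ||x_v - xhat_v||_F^2."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    return 0.5 * (
        float(((x1 - np.asarray(xhat1, float)) ** 2).sum())
        + float(((x2 - np.asarray(xhat2, float)) ** 2).sum())
    )


def outer_loss(z_list, zhat_list, z_tilde_list, Z, weights, first_term: str = "reconstruction") -> float:
    """1/2 * (sum_v ||z^v - zhat^v||^2 + ||Z - sum_v w_v z~^v||^2).

    ``first_term="latent"`` swaps the reconstruction zhat^v for the encoded
    z~^v in the first term (an alternative reading that only type-checks
    when the outer encoder preserves dimension).
    """
    z = np.asarray(z_list, float)
    zt = np.asarray(z_tilde_list, float)
    if first_term == "latent":
        if zt.shape != z.shape:
            raise ValueError("latent first term requires matching z / z~ dimensions")
        zhat = zt
    elif first_term == "reconstruction":
        zhat = np.asarray(zhat_list, float)
    else:
        raise ValueError(f"unknown first_term {first_term!r}")
    w = np.asarray(weights, float)
    fused = np.tensordot(w, zt, axes=(0, 0))
    return 0.5 * (float(((z - zhat) ** 2).sum()) + float(((np.asarray(Z, float) - fused) ** 2).sum()))


def classification_loss(probs, labels) -> float:
    """Binary cross-entropy -sum_i [y log p + (1-y) log(1-p)], p clamped."""
    p = np.clip(np.asarray(probs, float), PROB_EPS, 1.0 - PROB_EPS)
    y = np.asarray(labels, float)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())


def total_loss(l_cls: float, l_inner: float, l_outer: float, weights=(1.0, 1.0, 1.0)) -> float:
    """Weighted sum of the three loss components (default unweighted)."""
    return weights[0] * l_cls + weights[1] * l_inner + weights[2] * l_outer


def train(
    views: list[SubjectViews], config: TrainConfig | None = None
) -> tuple[NestedAutoencoderClassifier, list[float]]:
    """Train a fresh model on a cohort; returns (model, loss trace)."""
    cfg = config or TrainConfig()
    if views and views[0].maps.shape[0] != cfg.n_views:
        cfg = replace(cfg, n_views=views[0].maps.shape[0])
    model = NestedAutoencoderClassifier(cfg)
    trace = model.fit(views)
    return model, trace


def predict(model: NestedAutoencoderClassifier, views: list[SubjectViews]) -> np.ndarray:
    """P(PwAD) per subject for a trained model."""
    return model.predict_proba(views)
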
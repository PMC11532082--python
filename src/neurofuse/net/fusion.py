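"""The multi-level feature fusion network.

Two branches read one neuron each way — an FCN over the 43 morphometrics
and a CNN over the 3-view projection stack — and exchange information
through fusion modules (MLFMs) after CNN stages 2-4.  The final branch
features are merged (element-wise sum by default; concatenation and
averaging are selectable) and classified by a two-layer head with dropout.
"""

from __future__ import annotations

import numpy as np

from ..nn import Dropout, GlobalAvgPool2d, Linear, Module, ModuleList
from ..nn.tensor import Tensor, concat, softmax
from .backbones import build_backbone
from .config import FusionConfig
from .modules import FCNBlock, MLFM

__all__ = ["FusionNet", "cross_entropy", "cross_entropy_from_probs"]

_EPS = 1e-12


def cross_entropy_from_probs(probs: Tensor, onehot: np.ndarray) -> Tensor:
    """Multi-class cross entropy ``L = -(1/N) sum_ij y_ij log p_ij``.

    Probabilities are clamped at 1e-12 so a zero probability at the true
    class yields a large finite loss rather than an infinity.
    """
    y = np.asarray(onehot, dtype=float)
    if y.shape != probs.shape:
        raise ValueError("probability and label shapes differ")
    n = y.shape[0]
    logp = probs.clip_min(_EPS).log()
    return (logp * Tensor(y)).sum() * (-1.0 / n)


def cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    return cross_entropy_from_probs(softmax(logits, axis=-1), onehot)


class FusionNet(Module):
    """Dual-branch fusion classifier.

    ``forward`` maps a morphometric batch (N, 43) and an image batch
    (N, 3, H, W) to logits (N, n_classes).  MLFM modules are attached after
    backbone stages 2-4 (the first stage's features are too low-level to
    exchange); each records how often it fires in ``n_calls``.
    """

    def __init__(self, config: FusionConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.backbone = build_backbone(config.backbone, rng)
        channels = self.backbone.channels
        self.pool = GlobalAvgPool2d()

        if config.branch in ("both", "fcn"):
            dims = [config.n_features] + channels
            self.fcn_blocks = ModuleList(
                [FCNBlock(dims[i], dims[i + 1], rng) for i in range(4)]
            )
        else:
            self.fcn_blocks = None

        use_mlfm = config.branch == "both" and config.use_mlfm
        if use_mlfm:
            self.mlfms = ModuleList(
                [
                    MLFM(
                        channels[i],
                        config.n_groups,
                        config.fim_tokens,
                        rng,
                        use_fem=config.use_fem,
                        use_fim=config.use_fim,
                        learned_qkv=config.learned_qkv,
                    )
                    for i in (1, 2, 3)
                ]
            )
        else:
            self.mlfms = None

        d = channels[-1]
        if config.branch == "both":
            self.proj_l = Linear(d, d, rng)  # match FCN feature to fusion width
            head_in = 2 * d if config.fusion_strategy == "concat" else d
        else:
            self.proj_l = None
            head_in = d
        # dropout regularizes the hidden classifier layer; the output layer is
        # left undropped so the logits stay a clean class score
        self.head_fc1 = Linear(head_in, d, rng)
        self.head_drop1 = Dropout(config.dropout, np.random.default_rng(seed + 1))
        self.head_fc2 = Linear(d, config.n_classes, rng)

    # -- forward -----------------------------------------------------------

    def branch_features(self, x_feat: Tensor | None, x_img: Tensor | None):
        """Run both branches with fusion, returning (F_l, F_c) as available."""
        cfg = self.config
        f = x_feat
        c = None
        if cfg.branch in ("both", "cnn"):
            c = self.backbone.stem(x_img)
        for i in range(4):
            if self.fcn_blocks is not None:
                f = self.fcn_blocks[i](f)
            if c is not None:
                c = self.backbone.stages[i](c)
            if self.mlfms is not None and i >= 1:
                f, c = self.mlfms[i - 1](f, c)
        f_c = self.pool(c) if c is not None else None
        return f, f_c

    def forward(self, x_feat, x_img) -> Tensor:
        cfg = self.config
        x_feat = x_feat if isinstance(x_feat, Tensor) or x_feat is None else Tensor(x_feat)
        x_img = x_img if isinstance(x_img, Tensor) or x_img is None else Tensor(x_img)
        f_l, f_c = self.branch_features(x_feat, x_img)
        if cfg.branch == "fcn":
            fused = f_l
        elif cfg.branch == "cnn":
            fused = f_c
        else:
            f_l = self.proj_l(f_l)
            if cfg.fusion_strategy == "sum":
                fused = f_l + f_c
            elif cfg.fusion_strategy == "average":
                fused = (f_l + f_c) * 0.5
            else:
                fused = concat([f_l, f_c], axis=1)
        h = self.head_drop1(self.head_fc1(fused))
        return self.head_fc2(h)

    def predict_proba(self, x_feat, x_img) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            probs = softmax(self.forward(x_feat, x_img), axis=-1).data
        finally:
            self.train(was_training)
        return probs

    # -- checkpointing -----------------------------------------------------

    def save(self, path, extra: dict | None = None) -> None:
        """Single-file checkpoint: config + all parameters + BN running stats.

        ``extra`` may carry small JSON-serializable metadata (e.g. feature
        standardization statistics as lists, class names).
        """
        import json

        from ..nn.layers import _BatchNorm

        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        bns = [m for m in self.modules() if isinstance(m, _BatchNorm)]
        for i, bn in enumerate(bns):
            arrays[f"bn_mean_{i}"] = bn.running_mean
            arrays[f"bn_var_{i}"] = bn.running_var
        meta = {"config": self.config.to_dict(), "extra": extra or {}}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> tuple["FusionNet", dict]:
        """Rebuild a model from :meth:`save`; returns (model, extra)."""
        import json

        from ..nn.layers import _BatchNorm
        from .config import FusionConfig

        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        model = cls(FusionConfig.from_dict(meta["config"]), seed=0)
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"param_{i}"]
        bns = [m for m in model.modules() if isinstance(m, _BatchNorm)]
        for i, bn in enumerate(bns):
            bn.running_mean[...] = data[f"bn_mean_{i}"]
            bn.running_var[...] = data[f"bn_var_{i}"]
        return model, meta["extra"]

    def reset_mlfm_counters(self) -> None:
        if self.mlfms is not None:
            for m in self.mlfms:
                m.n_calls = 0

    def mlfm_call_counts(self) -> list[int]:
        return [m.n_calls for m in self.mlfms] if self.mlfms is not None else []
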
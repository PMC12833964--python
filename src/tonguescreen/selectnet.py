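"""SelectNet: a stepwise attention-based feature-selection network for
tabular (hand-crafted) tongue features.

The network repeats T steps, each composed of

* a 1-D residual block ``ReLU(Conv(ReLU(Conv(x)))) + x`` applied to the
  step carrier,
* a choice block that builds a per-feature selection vector
  ``M = softmax(S1) * softmax(S2)`` — S1 from a linear+ReLU+split of the
  original input, S2 from the residual block of the carrier — and gates
  the input as ``weighted = M * x``,
* an attention block: scaled dot-product attention between the gated
  input and the step carrier, a batch-normalised residual decision output
  ``x_decision = BN(x + v_decision)``, and the next carrier
  ``x_step' = BN(x_step + Linear(v_step))`` with ``v_step`` the value
  projection of the carrier.

The per-step selection vectors, aggregated over steps and samples, give a
normalised feature-importance vector used for top-k selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import (
    Tensor, Module, Linear, Conv1d, BatchNorm1d, Adam, soft_cross_entropy, stack,
)
from .cles import smooth_labels

__all__ = [
    "SelectNetConfig", "SelectionRecord", "SelectNetModel",
    "res_block_1d", "scaled_dot_attention",
    "selectnet_forward", "train_selectnet",
    "feature_importance", "select_top_k",
]


@dataclass(frozen=True)
class SelectNetConfig:
    feature_dim: int
    n_steps: int = 3
    attn_dim: int = 32
    n_classes: int = 2
    learning_rate: float = 1e-2
    epochs: int = 80
    batch_size: int = 64
    seed: int = 0
    two_layer_head: bool = False

    def __post_init__(self):
        if min(self.feature_dim, self.n_steps, self.attn_dim, self.n_classes) < 1:
            raise ValueError("all dimensions must be >= 1")


@dataclass
class SelectionRecord:
    """Per-step selection state of one forward pass."""

    S1: list[np.ndarray] = field(default_factory=list)  # softmaxed stage-1 gates
    S2: list[np.ndarray] = field(default_factory=list)  # softmaxed stage-2 gates
    M: list[np.ndarray] = field(default_factory=list)   # elementwise product
    importance: np.ndarray | None = None                # aggregate, sums to 1


class _ResBlock1d(Module):
    """Residual unit on feature vectors: two 1-channel 1-D convolutions
    (kernel 3, padding 1) with ReLU after each, plus an identity skip."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1d(1, 1, 3, rng, padding=1)
        self.conv2 = Conv1d(1, 1, 3, rng, padding=1)

    def __call__(self, x: Tensor) -> Tensor:
        n, f = x.shape
        h = x.reshape(n, 1, f)
        h = self.conv2(self.conv1(h).relu()).relu()
        return h.reshape(n, f) + x


def res_block_1d(x: np.ndarray, block: _ResBlock1d | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Functional wrapper around the residual block (used by the tests).

    With a fresh block and all weights zeroed the unit is the identity.
    """
    x = np.atleast_2d(np.asarray(x, float))
    if block is None:
        block = _ResBlock1d(rng or np.random.default_rng(0))
    return block(Tensor(x)).data


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor) -> tuple[Tensor, Tensor]:
    """softmax(q k^T / sqrt(d)) v over the token axis.

    q: (N, Tq, d); k: (N, Tk, d); v: (N, Tk, Dv).  Returns (output, weights);
    each weight row sums to 1, and a single key yields weight exactly 1.
    """
    d = q.shape[-1]
    scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(d))
    weights = scores.softmax(axis=-1)
    return weights @ v, weights


class _Step(Module):
    def __init__(self, cfg: SelectNetConfig, rng: np.random.Generator):
        super().__init__()
        F, d = cfg.feature_dim, cfg.attn_dim
        self.res = _ResBlock1d(rng)
        # gate-producing layers start with zero weights and a small positive
        # bias: constant logits make both selection softmaxes exactly uniform
        # at initialisation (concentration is learned signal, not init
        # noise), while the positive bias keeps the ReLUs off their dead
        # zero point so gradients reach the gates from the first step
        self.choice_linear = Linear(F, 2 * F, rng)
        self.choice_linear.weight.data[...] = 0.0
        self.choice_linear.bias.data[...] = 0.01
        for conv in (self.res.conv1, self.res.conv2):
            conv.conv.weight.data[...] = 0.0
            conv.conv.bias.data[...] = 0.01
        self.wq = Linear(F, d, rng)
        self.wk = Linear(F, d, rng)
        # value/step projections start at zero so the residual attention
        # paths grow from the identity and early gradients must flow
        # through the selection gates (zero-init residual-branch practice)
        self.wv = Linear(F, F, rng)
        self.wv.weight.data[...] = 0.0
        self.step_linear = Linear(F, F, rng)
        self.step_linear.weight.data[...] = 0.0
        self.bn_decision = BatchNorm1d(F)
        self.bn_step = BatchNorm1d(F)

    def choice_block(self, x: Tensor, s2_raw: Tensor):
        """Selection gating: M = softmax(S1) * softmax(S2); weighted = M * x."""
        F = x.shape[1]
        h = self.choice_linear(x).relu()
        s1_raw = h[:, :F]
        trans = h[:, F:]  # auxiliary transform half of the split
        s1 = s1_raw.softmax(axis=1)
        s2 = s2_raw.softmax(axis=1)
        m = s1 * s2
        return m * x, m, s1, s2, trans

    def attention_block(self, x: Tensor, trans: Tensor, x_step: Tensor):
        """Token attention between the gated input and the step carrier.

        Two tokens (the gated input and the carrier) attend to each other;
        the attention output at the input token is the decision value
        ``v_decision`` and the output at the carrier token is ``v_step``,
        so the next-step carrier depends on what the current step
        selected.
        """
        n, F = x.shape
        Q = stack([self.wq(x + trans), self.wq(x_step)], axis=1)  # (N, 2, d)
        K = stack([self.wk(x), self.wk(x_step)], axis=1)          # (N, 2, d)
        V = stack([self.wv(x), self.wv(x_step)], axis=1)          # (N, 2, F)
        out, _w = scaled_dot_attention(Q, K, V)
        v_decision = out[:, 0]
        v_step = out[:, 1]
        x_decision = self.bn_decision(x + v_decision)
        x_step_next = self.bn_step(x_step + self.step_linear(v_step))
        return x_decision, x_step_next

    def __call__(self, x0: Tensor, x_step: Tensor):
        s2_raw = self.res(x_step)
        weighted, m, s1, s2, trans = self.choice_block(x0, s2_raw)
        x_decision, x_step_next = self.attention_block(weighted, trans, x_step)
        return x_decision, x_step_next, m, s1, s2


class SelectNetModel(Module):
    def __init__(self, config: SelectNetConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.steps = [_Step(config, rng) for _ in range(config.n_steps)]
        F = config.feature_dim
        if config.two_layer_head:
            self.head1 = Linear(F, F, rng)
            self.head2 = Linear(F, config.n_classes, rng)
        else:
            self.head1 = None
            self.head2 = Linear(F, config.n_classes, rng)
        self.training_log: list[float] = []

    def logits(self, x: Tensor) -> tuple[Tensor, SelectionRecord]:
        record = SelectionRecord()
        x_step = x
        x_decision = x
        for step in self.steps:
            x_decision, x_step, m, s1, s2 = step(x, x_step)
            record.S1.append(s1.data)
            record.S2.append(s2.data)
            record.M.append(m.data)
        h = x_decision
        if self.head1 is not None:
            h = self.head1(h).relu()
        logits = self.head2(h)
        m_total = np.sum(record.M, axis=0).mean(axis=0)
        total = m_total.sum()
        record.importance = m_total / total if total > 0 else np.full_like(
            m_total, 1.0 / len(m_total))
        return logits, record

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path):
        arrays = {f"a{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(Path(path), config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SelectNetModel":
        with np.load(Path(path), allow_pickle=False) as data:
            cfg = SelectNetConfig(**json.loads(str(data["config"])))
            model = cls(cfg)
            for i, tgt in enumerate(model.state_arrays()):
                tgt[...] = data[f"a{i}"]
        return model


def selectnet_forward(x: np.ndarray, model: SelectNetModel) -> tuple[np.ndarray, SelectionRecord]:
    """Evaluation-mode forward pass: class probabilities + selection record."""
    x = np.atleast_2d(np.asarray(x, float))
    if np.isnan(x).any():
        raise ValueError("input contains NaN; normalise features first")
    model.eval()
    logits, record = model.logits(Tensor(x))
    probs = logits.softmax(axis=1).data
    return probs, record


def train_selectnet(table: np.ndarray, labels: np.ndarray,
                    config: SelectNetConfig) -> SelectNetModel:
    """Fit SelectNet with Adam on (soft) cross-entropy.

    ``labels`` may be hard {0..K-1} or an (n, K) soft-target matrix (e.g.
    label-smoothed).  Training is bit-reproducible for a given config.
    """
    X = np.asarray(table, float)
    y = np.asarray(labels, float)
    if y.ndim == 1:
        if len(np.unique(y)) < 2:
            raise ValueError("labels contain a single class")
        y = smooth_labels(y.astype(int), 0.0, config.n_classes)
    model = SelectNetModel(config)
    model.train()
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = X.shape[0]
    bs = min(config.batch_size, n)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            if len(idx) < 2:
                continue  # batch norm needs at least 2 samples
            logits, _ = model.logits(Tensor(X[idx]))
            loss = soft_cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        model.training_log.append(epoch_loss / n)
    model.eval()
    return model


def feature_importance(model: SelectNetModel, table: np.ndarray) -> np.ndarray:
    """Aggregated selection weights over a dataset; non-negative, sums to 1."""
    _, record = selectnet_forward(table, model)
    return record.importance


def select_top_k(model: SelectNetModel, table: np.ndarray, k: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Keep the k features with the highest aggregated importance.

    Ties break toward the lower feature index; the returned column order
    follows the original table (stable subset).
    """
    X = np.asarray(table, float)
    if k > X.shape[1]:
        raise ValueError("k exceeds the number of features")
    imp = feature_importance(model, X)
    # stable ranking: sort by (-importance, index)
    ranked = np.lexsort((np.arange(len(imp)), -imp))
    chosen = np.sort(ranked[:k])
    return X[:, chosen], chosen
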
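"""A small deterministic feed-forward softmax network in numpy.

The model maps a dense feature block plus an embedded trinucleotide index to
a 4-way allele probability.  Architecture: embedding lookup concatenated with
the dense block, a stack of ReLU layers (128/64/32 by default) and a 4-node
softmax head.  Trained by minimising the mean negative log-likelihood of the
observed allele with Adam and early stopping on validation loss.

Everything is seeded: two fits with the same seed produce identical weights.
Feature normalisation statistics are frozen before training (the inference
behaviour of batch normalisation), so prediction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_CLASSES = 4


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainConfig:
    hidden_layout: tuple[int, ...] = (128, 64, 32)
    learning_rate: float = 1e-3
    batch_size: int = 1024
    max_epochs: int = 100
    patience: int = 5  # early-stopping patience on validation NLL
    sample_weight_power: float = 1.0  # reserved; weights passed explicitly


class SoftmaxMLP:
    """Multinomial feed-forward network with an optional embedding input."""

    def __init__(self, dense_width: int, hidden_layout=(128, 64, 32),
                 embed_vocab: int = 0, embed_dim: int = 0, seed: int = 0):
        self.dense_width = dense_width
        self.hidden_layout = tuple(hidden_layout)
        self.embed_vocab = embed_vocab
        self.embed_dim = embed_dim if embed_vocab else 0
        self.seed = seed
        rng = np.random.default_rng(seed)
        widths = [dense_width + self.embed_dim, *hidden_layout, N_CLASSES]
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(2.0 / max(fan_in, 1))  # He init for ReLU stacks
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        if embed_vocab:
            self.E = rng.normal(0.0, 0.1, size=(embed_vocab, self.embed_dim))
        else:
            self.E = np.zeros((0, 0))

    # -- forward / backward -------------------------------------------------

    def _input(self, X: np.ndarray, tnc: np.ndarray | None) -> np.ndarray:
        if self.embed_dim:
            if tnc is None:
                raise ValueError("model expects trinucleotide indices")
            return np.hstack([X, self.E[tnc]])
        return X

    def forward(self, X: np.ndarray, tnc: np.ndarray | None = None) -> np.ndarray:
        """Class probabilities, shape (n, 4)."""
        h = self._input(np.asarray(X, dtype=float), tnc)
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return softmax(h @ self.W[-1] + self.b[-1])

    def nll(self, X, tnc, y, sample_weight=None) -> float:
        p = self.forward(X, tnc)
        ll = np.log(np.clip(p[np.arange(len(y)), y], 1e-300, None))
        if sample_weight is None:
            return float(-ll.mean())
        w = np.asarray(sample_weight, dtype=float)
        return float(-(w * ll).sum() / w.sum())

    def _grads(self, X, tnc, y, sample_weight):
        n = len(y)
        h = self._input(X, tnc)
        acts = [h]
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        p = softmax(acts[-1] @ self.W[-1] + self.b[-1])
        delta = p.copy()
        delta[np.arange(n), y] -= 1.0
        if sample_weight is None:
            delta /= n
        else:
            w = np.asarray(sample_weight, dtype=float)
            delta *= (w / w.sum())[:, None]
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (acts[i] > 0)
        gE = None
        if self.embed_dim:
            # after the loop, delta is the gradient at layer 0's pre-activation
            d_in = delta @ self.W[0].T
            d_emb = d_in[:, self.dense_width:]
            gE = np.zeros_like(self.E)
            np.add.at(gE, tnc, d_emb)
        return gW, gb, gE

    # -- training -----------------------------------------------------------

    def fit(self, X, tnc, y, X_val=None, tnc_val=None, y_val=None,
            sample_weight=None, val_weight=None,
            config: TrainConfig | None = None, seed: int = 0,
            verbose: bool = False) -> dict:
        """Adam + minibatches + early stopping; returns a history dict."""
        cfg = config or TrainConfig()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        rng = np.random.default_rng(seed)
        params = self.W + self.b + ([self.E] if self.embed_dim else [])
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        t = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        has_val = X_val is not None
        best_val = np.inf
        best_state = self.get_weights()
        stale = 0
        history = {"train_nll": [], "val_nll": []}
        init_nll = self.nll(X, tnc, y, sample_weight)
        n = len(y)
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                bt = tnc[idx] if tnc is not None else None
                bw = sample_weight[idx] if sample_weight is not None else None
                gW, gb, gE = self._grads(X[idx], bt, y[idx], bw)
                grads = gW + gb + ([gE] if self.embed_dim else [])
                t += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - beta2 ** t) / (1 - beta1 ** t)
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    p -= lr_t * mi / (np.sqrt(vi) + eps)
                if not np.isfinite(self.b[-1]).all():
                    raise FloatingPointError("non-finite parameters during training")
            tr = self.nll(X, tnc, y, sample_weight)
            history["train_nll"].append(tr)
            if has_val:
                vl = self.nll(X_val, tnc_val, y_val, val_weight)
                history["val_nll"].append(vl)
                if vl < best_val - 1e-9:
                    best_val = vl
                    best_state = self.get_weights()
                    stale = 0
                else:
                    stale += 1
                    if stale >= cfg.patience:
                        break
            if verbose:
                print(f"epoch {epoch}: train {tr:.6f}"
                      + (f" val {history['val_nll'][-1]:.6f}" if has_val else ""))
        if has_val:
            self.set_weights(best_state)
        history["initial_nll"] = init_nll
        history["final_train_nll"] = history["train_nll"][-1] if history["train_nll"] else init_nll
        history["final_val_nll"] = best_val if has_val else None
        history["epochs"] = len(history["train_nll"])
        return history

    # -- (de)serialisation ----------------------------------------------------

    def get_weights(self) -> dict:
        out = {f"W{i}": W.copy() for i, W in enumerate(self.W)}
        out.update({f"b{i}": b.copy() for i, b in enumerate(self.b)})
        if self.embed_dim:
            out["E"] = self.E.copy()
        return out

    def set_weights(self, state: dict) -> None:
        for i in range(len(self.W)):
            self.W[i] = state[f"W{i}"].copy()
            self.b[i] = state[f"b{i}"].copy()
        if self.embed_dim:
            self.E = state["E"].copy()

    def to_jsonable(self) -> dict:
        return {
            "dense_width": self.dense_width,
            "hidden_layout": list(self.hidden_layout),
            "embed_vocab": self.embed_vocab,
            "embed_dim": self.embed_dim,
            "weights": {k: v.tolist() for k, v in self.get_weights().items()},
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "SoftmaxMLP":
        model = cls(d["dense_width"], tuple(d["hidden_layout"]),
                    embed_vocab=d["embed_vocab"], embed_dim=d["embed_dim"])
        model.set_weights({k: np.asarray(v) for k, v in d["weights"].items()})
        return model
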
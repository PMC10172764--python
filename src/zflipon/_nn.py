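"""A compact NumPy transformer encoder for per-token binary classification.

Pre-layer-norm encoder blocks (multi-head self-attention + ReLU feed-forward),
learned token and positional embeddings, a scalar output head, hand-derived
backpropagation, Adam, and a one-cycle learning-rate schedule.  Written for
CPU-scale problems: float32 throughout, attention matrices cached only for the
current batch.

All randomness flows through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-5
_NEG = np.float32(-1e9)


def _linear(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    return x @ W + b


def _linear_back(x: np.ndarray, W: np.ndarray, dy: np.ndarray):
    x2 = x.reshape(-1, x.shape[-1])
    dy2 = dy.reshape(-1, dy.shape[-1])
    dW = x2.T @ dy2
    db = dy2.sum(axis=0)
    dx = dy @ W.T
    return dx, dW, db


def _layernorm(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv)


def _layernorm_back(dy: np.ndarray, g: np.ndarray, cache):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _softmax(x: np.ndarray) -> np.ndarray:
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class EncoderSpec:
    vocab_size: int
    d_model: int = 128
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 0  # 0 -> 2 * d_model
    max_len: int = 512

    @property
    def ff_dim(self) -> int:
        return self.d_ff or 2 * self.d_model

    @property
    def d_head(self) -> int:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        return self.d_model // self.n_heads


class TransformerTokenClassifier:
    """Token-level binary classifier over k-mer id sequences."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        self.spec = spec
        d, ff = spec.d_model, spec.ff_dim

        def w(*shape):
            return (rng.normal(0.0, 0.02, size=shape)).astype(np.float32)

        p: dict[str, np.ndarray] = {
            "tok_emb": w(spec.vocab_size, d),
            "pos_emb": w(spec.max_len, d),
            "lnf_g": np.ones(d, np.float32),
            "lnf_b": np.zeros(d, np.float32),
            "w_out": w(d, 1),
            "b_out": np.zeros(1, np.float32),
        }
        for l in range(spec.n_layers):
            p[f"l{l}.ln1_g"] = np.ones(d, np.float32)
            p[f"l{l}.ln1_b"] = np.zeros(d, np.float32)
            p[f"l{l}.Wq"] = w(d, d)
            p[f"l{l}.bq"] = np.zeros(d, np.float32)
            p[f"l{l}.Wk"] = w(d, d)
            p[f"l{l}.bk"] = np.zeros(d, np.float32)
            p[f"l{l}.Wv"] = w(d, d)
            p[f"l{l}.bv"] = np.zeros(d, np.float32)
            p[f"l{l}.Wo"] = w(d, d)
            p[f"l{l}.bo"] = np.zeros(d, np.float32)
            p[f"l{l}.ln2_g"] = np.ones(d, np.float32)
            p[f"l{l}.ln2_b"] = np.zeros(d, np.float32)
            p[f"l{l}.W1"] = w(d, ff)
            p[f"l{l}.b1"] = np.zeros(ff, np.float32)
            p[f"l{l}.W2"] = w(ff, d)
            p[f"l{l}.b2"] = np.zeros(d, np.float32)
        self.params = p

    # ------------------------------------------------------------------
    def _split_heads(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H, dh = self.spec.n_heads, self.spec.d_head
        return x.reshape(B, T, H, dh).transpose(0, 2, 1, 3)

    def _merge_heads(self, x: np.ndarray) -> np.ndarray:
        B, H, T, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)

    def forward(self, ids: np.ndarray, mask: np.ndarray, collect_attention: bool = False):
        """Return (logits, cache).  ``mask`` is True on real (non-PAD) tokens.

        With ``collect_attention`` the cache carries the per-layer attention
        tensors (B, H, T, T).
        """
        p = self.params
        B, T = ids.shape
        scale = np.float32(1.0 / np.sqrt(self.spec.d_head))
        key_bias = np.where(mask[:, None, None, :], np.float32(0.0), _NEG)

        x = (p["tok_emb"][ids] + p["pos_emb"][:T]).astype(np.float32)
        cache: dict = {"ids": ids, "mask": mask, "T": T, "layers": [], "attn": []}
        for l in range(self.spec.n_layers):
            lc: dict = {"x_in": x}
            h1, ln1c = _layernorm(x, p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
            q = self._split_heads(_linear(h1, p[f"l{l}.Wq"], p[f"l{l}.bq"]))
            k = self._split_heads(_linear(h1, p[f"l{l}.Wk"], p[f"l{l}.bk"]))
            v = self._split_heads(_linear(h1, p[f"l{l}.Wv"], p[f"l{l}.bv"]))
            s = q @ k.transpose(0, 1, 3, 2) * scale + key_bias
            a = _softmax(s)
            o = self._merge_heads(a @ v)
            attn_out = _linear(o, p[f"l{l}.Wo"], p[f"l{l}.bo"])
            x = x + attn_out
            h2, ln2c = _layernorm(x, p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
            f1 = _linear(h2, p[f"l{l}.W1"], p[f"l{l}.b1"])
            r1 = np.maximum(f1, 0.0)
            f2 = _linear(r1, p[f"l{l}.W2"], p[f"l{l}.b2"])
            x = x + f2
            lc.update(h1=h1, ln1c=ln1c, q=q, k=k, v=v, a=a, o=o, h2=h2, ln2c=ln2c, r1=r1)
            cache["layers"].append(lc)
            if collect_attention:
                cache["attn"].append(a)
        hf, lnfc = _layernorm(x, p["lnf_g"], p["lnf_b"])
        logits = (_linear(hf, p["w_out"], p["b_out"]))[..., 0]
        cache.update(x_final=x, hf=hf, lnfc=lnfc)
        return logits, cache

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        spec = self.spec
        scale = np.float32(1.0 / np.sqrt(spec.d_head))
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dhf, grads["w_out"], grads["b_out"] = _linear_back(
            cache["hf"], p["w_out"], dlogits[..., None].astype(np.float32)
        )
        dx, grads["lnf_g"], grads["lnf_b"] = _layernorm_back(dhf, p["lnf_g"], cache["lnfc"])

        for l in reversed(range(spec.n_layers)):
            lc = cache["layers"][l]
            # FFN branch
            df2 = dx
            dr1, grads[f"l{l}.W2"], grads[f"l{l}.b2"] = _linear_back(lc["r1"], p[f"l{l}.W2"], df2)
            df1 = dr1 * (lc["r1"] > 0)
            dh2, grads[f"l{l}.W1"], grads[f"l{l}.b1"] = _linear_back(lc["h2"], p[f"l{l}.W1"], df1)
            dxa, grads[f"l{l}.ln2_g"], grads[f"l{l}.ln2_b"] = _layernorm_back(
                dh2, p[f"l{l}.ln2_g"], lc["ln2c"]
            )
            dx = dx + dxa  # residual
            # attention branch
            dattn = dx
            do, grads[f"l{l}.Wo"], grads[f"l{l}.bo"] = _linear_back(lc["o"], p[f"l{l}.Wo"], dattn)
            do_h = self._split_heads(do)
            da = do_h @ lc["v"].transpose(0, 1, 3, 2)
            dv = lc["a"].transpose(0, 1, 3, 2) @ do_h
            a = lc["a"]
            ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
            dq = ds @ lc["k"] * scale
            dk = ds.transpose(0, 1, 3, 2) @ lc["q"] * scale
            dh1 = np.zeros_like(lc["h1"])
            for name, dmat in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
                dmerged = self._merge_heads(dmat)
                dh1_part, dW, db = _linear_back(lc["h1"], p[f"l{l}.{name}"], dmerged)
                grads[f"l{l}.{name}"] += dW
                grads[f"l{l}.b{name[1].lower()}"] += db
                dh1 += dh1_part
            dx_in, dg1, db1 = _layernorm_back(dh1, p[f"l{l}.ln1_g"], lc["ln1c"])
            grads[f"l{l}.ln1_g"] += dg1
            grads[f"l{l}.ln1_b"] += db1
            dx = dx + dx_in  # residual into the block input

        # embeddings
        T = cache["T"]
        grads["pos_emb"][:T] = dx.sum(axis=0)
        ids_flat = cache["ids"].reshape(-1)
        dx_flat = dx.reshape(-1, spec.d_model)
        np.add.at(grads["tok_emb"], ids_flat, dx_flat)
        return grads

    # ------------------------------------------------------------------
    def predict_proba(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(ids, mask)
        return 1.0 / (1.0 + np.exp(-logits))

    def attention_tensors(self, ids: np.ndarray, mask: np.ndarray) -> list[np.ndarray]:
        _, cache = self.forward(ids, mask, collect_attention=True)
        return cache["attn"]

    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].astype(np.float32)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray, mask: np.ndarray):
    """Masked mean binary cross-entropy; returns (loss, dlogits)."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    w = mask.astype(np.float64)
    n = max(w.sum(), 1.0)
    loss = float((per * w).sum() / n)
    dlogits = ((1.0 / (1.0 + np.exp(-z))) - y) * w / n
    return loss, dlogits.astype(np.float32)


class Adam:
    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            params[k] -= (lr * (m / c1) / (np.sqrt(v / c2) + self.eps)).astype(np.float32)


def one_cycle_lr(step: int, total_steps: int, max_lr: float, warmup_fraction: float = 0.30) -> float:
    """One-cycle policy: linear warmup to max_lr, then cosine anneal to ~0."""
    if total_steps <= 1:
        return max_lr
    warm = max(int(round(warmup_fraction * total_steps)), 1)
    start = max_lr / 25.0
    if step < warm:
        return start + (max_lr - start) * step / warm
    frac = (step - warm) / max(total_steps - warm, 1)
    floor = max_lr / 1000.0
    return floor + 0.5 * (max_lr - floor) * (1.0 + np.cos(np.pi * frac))
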
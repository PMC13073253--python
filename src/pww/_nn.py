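"""A small NumPy transformer encoder classifier with manual backpropagation.

The network maps a padded batch of token-embedding sequences to per-class
logits: a learned CLS vector is prepended, the tokens pass through
pre-layer-norm transformer encoder layers (multi-head self-attention with
key masking, then a GELU feed-forward block, both with residual
connections), and a fully connected layer reads the final CLS state out to
one logit per class.  Multi-label probabilities are independent sigmoids.

Everything is float64.  ``forward`` caches every intermediate; ``backward``
returns parameter gradients and the gradient with respect to the input
embeddings (needed for Integrated Gradients).  Gradients are validated
against central finite differences in the test suite.
"""
from __future__ import annotations

import numpy as np
from scipy.special import erf

_EPS = 1e-5
_NEG = -1e30
_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _gelu(x):
    # exact (erf-based) Gaussian error linear unit; smoothness matters for
    # the Integrated-Gradients path integral
    return 0.5 * x * (1.0 + erf(x * _INV_SQRT2))


def _gelu_grad(x):
    return 0.5 * (1.0 + erf(x * _INV_SQRT2)) + x * _INV_SQRT2PI * np.exp(-0.5 * x * x)


def _layer_norm_forward(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _layer_norm_backward(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    m1 = dxhat.mean(-1, keepdims=True)
    m2 = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _linear_forward(x, W, b):
    return x @ W + b, x


def _linear_backward(dy, W, x):
    dW = np.tensordot(x, dy, axes=(tuple(range(x.ndim - 1)),) * 2)
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dx = dy @ W.T
    return dx, dW, db


class TransformerClassifierNet:
    """Pre-LN transformer encoder with CLS readout, in plain NumPy.

    Parameters
    ----------
    embed_dim : token embedding dimension D (must divide by ``n_heads``).
    hidden_dim : feed-forward inner dimension.
    n_heads : attention heads per layer.
    n_layers : encoder layers.
    n_classes : output logits (independent binary labels).
    seed : weight-initialization seed.
    """

    def __init__(
        self,
        embed_dim: int,
        hidden_dim: int,
        n_heads: int,
        n_layers: int,
        n_classes: int,
        seed: int = 0,
        layer_norm: bool = False,
    ) -> None:
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.n_classes = n_classes
        self.layer_norm = layer_norm
        rng = np.random.default_rng(seed)
        D, F = embed_dim, hidden_dim

        def mat(shape, fan_in):
            return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)

        p = {"cls": rng.normal(0.0, 0.02, size=(D,))}
        for i in range(n_layers):
            p[f"ln1_g{i}"] = np.ones(D)
            p[f"ln1_b{i}"] = np.zeros(D)
            for nm in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{nm}{i}"] = mat((D, D), D)
                p[f"{nm[0]}b{nm[1]}{i}"] = np.zeros(D)  # bq/bk/bv/bo-style names
            p[f"ln2_g{i}"] = np.ones(D)
            p[f"ln2_b{i}"] = np.zeros(D)
            p[f"W1_{i}"] = mat((D, F), D)
            p[f"b1_{i}"] = np.zeros(F)
            p[f"W2_{i}"] = mat((F, D), F)
            p[f"b2_{i}"] = np.zeros(D)
        p["lnf_g"] = np.ones(D)
        p["lnf_b"] = np.zeros(D)
        p["Wout"] = np.zeros((D, n_classes))  # zero-initialized head: p = 0.5
        p["bout"] = np.zeros(n_classes)
        self.params = p

    # parameter-name helpers -------------------------------------------------
    @staticmethod
    def _bias_name(nm: str, i: int) -> str:
        return f"{nm[0]}b{nm[1]}{i}"

    # forward ----------------------------------------------------------------
    def forward(self, X: np.ndarray, mask: np.ndarray):
        """X: (B, T, D) padded token embeddings; mask: (B, T) True for valid.

        Returns (logits (B, C), cache).
        """
        p = self.params
        B, T, D = X.shape
        H = self.n_heads
        dh = D // H
        tok = np.concatenate(
            [np.broadcast_to(p["cls"], (B, 1, D)), X.astype(float)], axis=1
        )
        full_mask = np.concatenate([np.ones((B, 1), bool), mask.astype(bool)], axis=1)
        key_bias = np.where(full_mask[:, None, None, :], 0.0, _NEG)  # (B,1,1,T+1)

        cache = {"layers": [], "B": B, "T": T, "full_mask": full_mask}
        x = tok
        for i in range(self.n_layers):
            lc = {"x_in": x}
            if self.layer_norm:
                a, lc["ln1"] = _layer_norm_forward(x, p[f"ln1_g{i}"], p[f"ln1_b{i}"])
            else:
                a, lc["ln1"] = x, None
            lc["a"] = a
            q = a @ p[f"Wq{i}"] + p[self._bias_name("Wq", i)]
            k = a @ p[f"Wk{i}"] + p[self._bias_name("Wk", i)]
            v = a @ p[f"Wv{i}"] + p[self._bias_name("Wv", i)]
            qh = q.reshape(B, -1, H, dh).transpose(0, 2, 1, 3)
            kh = k.reshape(B, -1, H, dh).transpose(0, 2, 1, 3)
            vh = v.reshape(B, -1, H, dh).transpose(0, 2, 1, 3)
            logits = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh) + key_bias
            logits -= logits.max(-1, keepdims=True)
            ex = np.exp(logits)
            P = ex / ex.sum(-1, keepdims=True)
            ctx = P @ vh  # (B,H,T+1,dh)
            ctx_m = ctx.transpose(0, 2, 1, 3).reshape(B, -1, D)
            attn_out = ctx_m @ p[f"Wo{i}"] + p[self._bias_name("Wo", i)]
            x = x + attn_out
            lc.update(qh=qh, kh=kh, vh=vh, P=P, ctx_m=ctx_m, x_mid=x)
            if self.layer_norm:
                a2, lc["ln2"] = _layer_norm_forward(x, p[f"ln2_g{i}"], p[f"ln2_b{i}"])
            else:
                a2, lc["ln2"] = x, None
            lc["a2"] = a2
            pre = a2 @ p[f"W1_{i}"] + p[f"b1_{i}"]
            f = _gelu(pre)
            ffn = f @ p[f"W2_{i}"] + p[f"b2_{i}"]
            x = x + ffn
            lc.update(pre=pre, f=f)
            cache["layers"].append(lc)
        cls_state = x[:, 0]
        if self.layer_norm:
            h, lnf_cache = _layer_norm_forward(cls_state, p["lnf_g"], p["lnf_b"])
        else:
            h, lnf_cache = cls_state, None
        out_logits = h @ p["Wout"] + p["bout"]
        cache.update(x_top=x, h=h, lnf=lnf_cache, key_bias=key_bias)
        return out_logits, cache

    def predict_proba(self, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(X, mask)
        return 1.0 / (1.0 + np.exp(-logits))

    # backward ---------------------------------------------------------------
    def backward(self, cache, dlogits: np.ndarray):
        """Backpropagate d(loss)/d(out_logits); returns (grads, dX)."""
        p = self.params
        B, T = cache["B"], cache["T"]
        D, H = self.embed_dim, self.n_heads
        dh = D // H
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        grads["Wout"] = cache["h"].T @ dlogits
        grads["bout"] = dlogits.sum(0)
        dhad = dlogits @ p["Wout"].T
        if self.layer_norm:
            dcls_state, grads["lnf_g"], grads["lnf_b"] = _layer_norm_backward(
                dhad, cache["lnf"]
            )
        else:
            dcls_state = dhad
        dx = np.zeros_like(cache["x_top"])
        dx[:, 0] = dcls_state

        for i in reversed(range(self.n_layers)):
            lc = cache["layers"][i]
            # FFN block: x = x_mid + relu(LN2(x_mid) @ W1 + b1) @ W2 + b2
            dffn = dx
            df = dffn @ p[f"W2_{i}"].T
            grads[f"W2_{i}"] = np.tensordot(lc["f"], dffn, axes=((0, 1), (0, 1)))
            grads[f"b2_{i}"] = dffn.sum((0, 1))
            dpre = df * _gelu_grad(lc["pre"])
            grads[f"W1_{i}"] = np.tensordot(lc["a2"], dpre, axes=((0, 1), (0, 1)))
            grads[f"b1_{i}"] = dpre.sum((0, 1))
            da2 = dpre @ p[f"W1_{i}"].T
            if self.layer_norm:
                dmid_ln, grads[f"ln2_g{i}"], grads[f"ln2_b{i}"] = _layer_norm_backward(
                    da2, lc["ln2"]
                )
            else:
                dmid_ln = da2
            dx_mid = dx + dmid_ln  # residual + (LN) path

            # attention block: x_mid = x_in + MHA(LN1(x_in))
            dattn_out = dx_mid
            grads[f"Wo{i}"] = np.tensordot(
                lc["ctx_m"], dattn_out, axes=((0, 1), (0, 1))
            )
            grads[self._bias_name("Wo", i)] = dattn_out.sum((0, 1))
            dctx_m = dattn_out @ p[f"Wo{i}"].T
            dctx = dctx_m.reshape(B, -1, H, dh).transpose(0, 2, 1, 3)
            P, vh = lc["P"], lc["vh"]
            dP = dctx @ vh.transpose(0, 1, 3, 2)
            dvh = P.transpose(0, 1, 3, 2) @ dctx
            dlog = P * (dP - (dP * P).sum(-1, keepdims=True))
            dqh = dlog @ lc["kh"] / np.sqrt(dh)
            dkh = dlog.transpose(0, 1, 3, 2) @ lc["qh"] / np.sqrt(dh)
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, -1, D)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, -1, D)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, -1, D)
            a = lc["a"]
            grads[f"Wq{i}"] = np.tensordot(a, dq, axes=((0, 1), (0, 1)))
            grads[self._bias_name("Wq", i)] = dq.sum((0, 1))
            grads[f"Wk{i}"] = np.tensordot(a, dk, axes=((0, 1), (0, 1)))
            grads[self._bias_name("Wk", i)] = dk.sum((0, 1))
            grads[f"Wv{i}"] = np.tensordot(a, dv, axes=((0, 1), (0, 1)))
            grads[self._bias_name("Wv", i)] = dv.sum((0, 1))
            da = dq @ p[f"Wq{i}"].T + dk @ p[f"Wk{i}"].T + dv @ p[f"Wv{i}"].T
            if self.layer_norm:
                din_ln, grads[f"ln1_g{i}"], grads[f"ln1_b{i}"] = _layer_norm_backward(
                    da, lc["ln1"]
                )
            else:
                din_ln = da
            dx = dx_mid + din_ln

        grads["cls"] = dx[:, 0].sum(0)
        dX = dx[:, 1:]
        return grads, dX

    # serialization ----------------------------------------------------------
    def get_state(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()


def bce_loss_and_grad(logits: np.ndarray, Y: np.ndarray):
    """Mean binary cross-entropy over all (sample, class) cells.

    Returns (loss, d loss / d logits), computed in the numerically stable
    log-sum-exp form.
    """
    Y = Y.astype(float)
    # log(1 + exp(-|z|)) + max(z, 0) - z*y
    loss = np.mean(np.logaddexp(0.0, logits) - logits * Y)
    probs = 1.0 / (1.0 + np.exp(-logits))
    dlogits = (probs - Y) / logits.size
    return float(loss), dlogits


class AdamOptimizer:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8, weight_decay=0.0):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if self.weight_decay:
                g = g + self.weight_decay * params[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)
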
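"""Manually unrolled multilayer LSTM risk model.

The network is a unidirectional, multilayer LSTM over six epoch vectors,
followed by batch normalisation, dropout and a fully connected head that
maps the final hidden state of the top layer to a single logit; a sigmoid
turns the logit into a risk probability.  The recurrence is the standard
LSTM cell:

    i_t = sigmoid(W_ih^i x_t + W_hh^i h_{t-1} + b^i)
    f_t = sigmoid(W_ih^f x_t + W_hh^f h_{t-1} + b^f)
    g_t = tanh  (W_ih^g x_t + W_hh^g h_{t-1} + b^g)     (candidate)
    o_t = sigmoid(W_ih^o x_t + W_hh^o h_{t-1} + b^o)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

The cell is unrolled by hand — every gate activation, cell state and
candidate pre-activation is retained per step and per layer — so that
relevance can later be propagated backward through the exact forward
computational graph (:mod:`iwsrisk.lrp`).  Training uses analytic
backpropagation through time with an Adam optimiser; all randomness
(initialisation, shuffling, dropout masks) is driven by one integer seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

GATES = ("i", "f", "g", "o")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


@dataclass
class LayerParams:
    """Weights of one LSTM layer, keyed by gate ('i', 'f', 'g', 'o')."""

    W_ih: dict[str, np.ndarray]  # (input_dim, H) each
    W_hh: dict[str, np.ndarray]  # (H, H) each
    b: dict[str, np.ndarray]  # (H,) each


@dataclass
class LSTMParams:
    """All parameters of the model, including batch-norm statistics."""

    layers: list[LayerParams]
    gamma: np.ndarray  # BN scale (H,)
    beta: np.ndarray  # BN shift (H,)
    running_mean: np.ndarray
    running_var: np.ndarray
    w_out: np.ndarray  # FC head weights (H,)
    b_out: float
    input_dim: int
    hidden_dim: int
    num_layers: int
    bn_eps: float = 1e-5

    def trainable(self) -> list[tuple[str, np.ndarray]]:
        """Named trainable arrays in a fixed order (BN statistics excluded)."""
        out: list[tuple[str, np.ndarray]] = []
        for li, lp in enumerate(self.layers):
            for g in GATES:
                out.append((f"l{li}.W_ih.{g}", lp.W_ih[g]))
                out.append((f"l{li}.W_hh.{g}", lp.W_hh[g]))
                out.append((f"l{li}.b.{g}", lp.b[g]))
        out.append(("gamma", self.gamma))
        out.append(("beta", self.beta))
        out.append(("w_out", self.w_out))
        return out

    def copy(self) -> "LSTMParams":
        return copy.deepcopy(self)

    def folded_head(self) -> tuple[np.ndarray, float]:
        """Fold batch norm (running statistics) into the FC head.

        Returns (w_eff, b_eff) such that logit = w_eff . h_T + b_eff for an
        eval-mode forward pass.
        """
        inv_std = 1.0 / np.sqrt(self.running_var + self.bn_eps)
        w_eff = self.w_out * self.gamma * inv_std
        b_eff = self.b_out + float(
            self.w_out @ (self.beta - self.gamma * self.running_mean * inv_std)
        )
        return w_eff, b_eff


def init_params(
    input_dim: int, hidden_dim: int, num_layers: int = 2, seed: int = 0
) -> LSTMParams:
    """Draw all weights i.i.d. uniform on [-1/sqrt(H), +1/sqrt(H)].

    Deterministic given the seed.  Batch-norm affine parameters start at
    the identity (scale 1, shift 0) with zero-mean/unit-variance running
    statistics.
    """
    if input_dim < 1 or hidden_dim < 1 or num_layers < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    bound = 1.0 / np.sqrt(hidden_dim)

    def u(*shape: int) -> np.ndarray:
        return rng.uniform(-bound, bound, size=shape)

    layers = []
    for li in range(num_layers):
        d = input_dim if li == 0 else hidden_dim
        layers.append(
            LayerParams(
                W_ih={g: u(d, hidden_dim) for g in GATES},
                W_hh={g: u(hidden_dim, hidden_dim) for g in GATES},
                b={g: u(hidden_dim) for g in GATES},
            )
        )
    return LSTMParams(
        layers=layers,
        gamma=np.ones(hidden_dim),
        beta=np.zeros(hidden_dim),
        running_mean=np.zeros(hidden_dim),
        running_var=np.ones(hidden_dim),
        w_out=u(hidden_dim),
        b_out=float(rng.uniform(-bound, bound)),
        input_dim=input_dim,
        hidden_dim=hidden_dim,
        num_layers=num_layers,
    )


@dataclass
class LSTMTrace:
    """Every intermediate of one eval-mode forward pass, per layer and step.

    For layer l (0-based) and step t (0-based): ``x[l][t]`` is the layer
    input, ``i/f/o/g`` the gate activations and candidate, ``zg`` the
    candidate pre-activation, ``c``/``h`` the cell and hidden states.
    ``h`` and ``c`` include the zero initial state at index 0, so
    ``h[l][t+1]`` is the state after step t.
    """

    x: list[np.ndarray]  # per layer: (T, D_l)
    i: list[np.ndarray]  # per layer: (T, H)
    f: list[np.ndarray]
    o: list[np.ndarray]
    g: list[np.ndarray]
    zg: list[np.ndarray]
    c: list[np.ndarray]  # per layer: (T+1, H), c[l][0] = 0
    h: list[np.ndarray]  # per layer: (T+1, H), h[l][0] = 0


@dataclass
class Prediction:
    logit: float
    prob: float
    trace: LSTMTrace | None = None


def lstm_cell_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, layer: LayerParams
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """One LSTM cell update; returns (h_t, c_t, gate trace).

    The trace dict holds i, f, o, the candidate g, its pre-activation zg,
    and c_t / h_t.
    """
    for arr in (x_t, h_prev, c_prev):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite input to LSTM cell")
    zi = x_t @ layer.W_ih["i"] + h_prev @ layer.W_hh["i"] + layer.b["i"]
    zf = x_t @ layer.W_ih["f"] + h_prev @ layer.W_hh["f"] + layer.b["f"]
    zg = x_t @ layer.W_ih["g"] + h_prev @ layer.W_hh["g"] + layer.b["g"]
    zo = x_t @ layer.W_ih["o"] + h_prev @ layer.W_hh["o"] + layer.b["o"]
    i = _sigmoid(zi)
    f = _sigmoid(zf)
    g = np.tanh(zg)
    o = _sigmoid(zo)
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c, {"i": i, "f": f, "o": o, "g": g, "zg": zg, "c": c, "h": h}


def forward(
    window: np.ndarray,
    params: LSTMParams,
    mode: str = "eval",
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Prediction:
    """Forward pass over one (T, input_dim) window, retaining a full trace.

    In eval mode batch norm uses running statistics and dropout is
    inactive, so the pass is deterministic.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != params.input_dim:
        raise ValueError(
            f"window must be (T, {params.input_dim}); got {window.shape}"
        )
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    T = window.shape[0]
    H = params.hidden_dim
    tr = LSTMTrace(x=[], i=[], f=[], o=[], g=[], zg=[], c=[], h=[])
    layer_input = window
    for lp in params.layers:
        h = np.zeros(H)
        c = np.zeros(H)
        hs = [h]
        cs = [c]
        gates: dict[str, list[np.ndarray]] = {k: [] for k in ("i", "f", "o", "g", "zg")}
        for t in range(T):
            h, c, gt = lstm_cell_step(layer_input[t], hs[-1], cs[-1], lp)
            hs.append(h)
            cs.append(c)
            for k in gates:
                gates[k].append(gt[k])
        tr.x.append(np.asarray(layer_input, dtype=float))
        for k in ("i", "f", "o", "g", "zg"):
            getattr(tr, k).append(np.asarray(gates[k]))
        tr.c.append(np.asarray(cs))
        tr.h.append(np.asarray(hs))
        layer_input = np.asarray(hs[1:])

    h_last = tr.h[-1][-1]
    inv_std = 1.0 / np.sqrt(params.running_var + params.bn_eps)
    h_bn = params.gamma * (h_last - params.running_mean) * inv_std + params.beta
    if mode == "train" and dropout_rate > 0.0:
        if rng is None:
            raise ValueError("train-mode dropout needs an rng")
        mask = (rng.random(H) >= dropout_rate) / (1.0 - dropout_rate)
        h_bn = h_bn * mask
    logit = float(h_bn @ params.w_out + params.b_out)
    return Prediction(logit=logit, prob=float(_sigmoid(np.array(logit))), trace=tr)


# ---------------------------------------------------------------------------
# batched forward / backward used by the training loop


def _forward_batch(
    params: LSTMParams,
    X: np.ndarray,
    train: bool,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    bn_momentum: float = 0.1,
    update_bn: bool = False,
) -> tuple[np.ndarray, dict]:
    """Batched forward over X (B, T, D); returns (logits, cache)."""
    B, T, _ = X.shape
    H = params.hidden_dim
    cache: dict = {"layers": [], "B": B, "T": T}
    inp = X
    for lp in params.layers:
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        lc = {
            "x": inp,
            "i": np.empty((B, T, H)),
            "f": np.empty((B, T, H)),
            "o": np.empty((B, T, H)),
            "g": np.empty((B, T, H)),
            "c": np.empty((B, T + 1, H)),
            "h": np.empty((B, T + 1, H)),
        }
        lc["c"][:, 0] = 0.0
        lc["h"][:, 0] = 0.0
        for t in range(T):
            x_t = inp[:, t]
            zi = x_t @ lp.W_ih["i"] + h @ lp.W_hh["i"] + lp.b["i"]
            zf = x_t @ lp.W_ih["f"] + h @ lp.W_hh["f"] + lp.b["f"]
            zg = x_t @ lp.W_ih["g"] + h @ lp.W_hh["g"] + lp.b["g"]
            zo = x_t @ lp.W_ih["o"] + h @ lp.W_hh["o"] + lp.b["o"]
            i = _sigmoid(zi)
            f = _sigmoid(zf)
            g = np.tanh(zg)
            o = _sigmoid(zo)
            c = f * c + i * g
            h = o * np.tanh(c)
            lc["i"][:, t] = i
            lc["f"][:, t] = f
            lc["o"][:, t] = o
            lc["g"][:, t] = g
            lc["c"][:, t + 1] = c
            lc["h"][:, t + 1] = h
        cache["layers"].append(lc)
        inp = lc["h"][:, 1:]

    h_last = cache["layers"][-1]["h"][:, -1]  # (B, H)
    if train:
        mu = h_last.mean(axis=0)
        var = h_last.var(axis=0)
        if update_bn:
            n = max(B, 2)
            params.running_mean[:] = (1 - bn_momentum) * params.running_mean + bn_momentum * mu
            params.running_var[:] = (
                1 - bn_momentum
            ) * params.running_var + bn_momentum * var * n / (n - 1)
    else:
        mu = params.running_mean
        var = params.running_var
    inv_std = 1.0 / np.sqrt(var + params.bn_eps)
    xhat = (h_last - mu) * inv_std
    h_bn = params.gamma * xhat + params.beta
    if train and dropout_rate > 0.0:
        mask = (rng.random(h_bn.shape) >= dropout_rate) / (1.0 - dropout_rate)
    else:
        mask = np.ones_like(h_bn)
    h_drop = h_bn * mask
    logits = h_drop @ params.w_out + params.b_out
    cache.update(
        h_last=h_last, xhat=xhat, inv_std=inv_std, mask=mask, h_drop=h_drop, train=train
    )
    return logits, cache


def _bce_loss_grad(
    logits: np.ndarray, y: np.ndarray, pos_weight: float | None = None
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits.

    Logits are clamped to [-30, 30] inside the loss only; the gradient is
    zero outside the clamp.
    """
    z = np.clip(logits, -30.0, 30.0)
    wp = 1.0 if pos_weight is None else pos_weight
    losses = wp * y * _softplus(-z) + (1 - y) * _softplus(z)
    p = _sigmoid(z)
    grad = (wp * y * (p - 1) + (1 - y) * p) / len(y)
    grad = np.where(np.abs(logits) <= 30.0, grad, 0.0)
    return float(losses.mean()), grad


def _backward_batch(params: LSTMParams, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
    """Backprop through head, batch norm and the unrolled recurrence."""
    B, T = cache["B"], cache["T"]
    grads: dict[str, np.ndarray] = {}
    grads["w_out"] = cache["h_drop"].T @ dlogits
    grads["b_out"] = float(dlogits.sum())
    dh_drop = np.outer(dlogits, params.w_out)
    dh_bn = dh_drop * cache["mask"]
    grads["gamma"] = (dh_bn * cache["xhat"]).sum(axis=0)
    grads["beta"] = dh_bn.sum(axis=0)
    dxhat = dh_bn * params.gamma
    if cache["train"]:
        xhat = cache["xhat"]
        dh_last = (
            cache["inv_std"]
            / B
            * (B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )
    else:
        dh_last = dxhat * cache["inv_std"]

    # gradient w.r.t. the top layer's hidden sequence: only the final step
    H = params.hidden_dim
    dH_seq = np.zeros((B, T, H))
    dH_seq[:, -1] = dh_last
    for li in range(params.num_layers - 1, -1, -1):
        lp = params.layers[li]
        lc = cache["layers"][li]
        dW_ih = {g: np.zeros_like(lp.W_ih[g]) for g in GATES}
        dW_hh = {g: np.zeros_like(lp.W_hh[g]) for g in GATES}
        db = {g: np.zeros_like(lp.b[g]) for g in GATES}
        dX = np.zeros_like(lc["x"], dtype=float)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, o, g = lc["i"][:, t], lc["f"][:, t], lc["o"][:, t], lc["g"][:, t]
            c = lc["c"][:, t + 1]
            c_prev = lc["c"][:, t]
            h_prev = lc["h"][:, t]
            x_t = lc["x"][:, t]
            tanh_c = np.tanh(c)
            dh = dH_seq[:, t] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1 - tanh_c**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = {
                "i": di * i * (1 - i),
                "f": df * f * (1 - f),
                "g": dg * (1 - g**2),
                "o": do * o * (1 - o),
            }
            dh_next = np.zeros((B, H))
            for gate in GATES:
                dW_ih[gate] += x_t.T @ dz[gate]
                dW_hh[gate] += h_prev.T @ dz[gate]
                db[gate] += dz[gate].sum(axis=0)
                dh_next += dz[gate] @ lp.W_hh[gate].T
                dX[:, t] += dz[gate] @ lp.W_ih[gate].T
        for gate in GATES:
            grads[f"l{li}.W_ih.{gate}"] = dW_ih[gate]
            grads[f"l{li}.W_hh.{gate}"] = dW_hh[gate]
            grads[f"l{li}.b.{gate}"] = db[gate]
        dH_seq = dX if li > 0 else dH_seq  # layer below receives dX at all steps
    return grads


def loss_and_grads(
    params: LSTMParams,
    X: np.ndarray,
    y: np.ndarray,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    train: bool = True,
    pos_weight: float | None = None,
    update_bn: bool = False,
    bn_momentum: float = 0.1,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean BCE loss and analytic gradients for one minibatch."""
    logits, cache = _forward_batch(
        params, X, train=train, dropout_rate=dropout_rate, rng=rng,
        update_bn=update_bn, bn_momentum=bn_momentum,
    )
    loss, dlogits = _bce_loss_grad(logits, y, pos_weight)
    grads = _backward_batch(params, cache, dlogits)
    grads["b_out"] = np.asarray(grads["b_out"])
    return loss, grads


def predict_logits(params: LSTMParams, X: np.ndarray) -> np.ndarray:
    """Eval-mode logits for a (N, T, D) batch of windows."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    logits, _ = _forward_batch(params, X, train=False)
    return logits


def predict_proba(params: LSTMParams, X: np.ndarray) -> np.ndarray:
    """Raw (uncalibrated) eval-mode probabilities for a batch of windows."""
    X = np.asarray(X, dtype=float)
    if X.size and (X.min() < 0.0 or X.max() > 1.0):
        import warnings

        warnings.warn("input values outside [0, 1]; did you forget to scale?")
    return _sigmoid(predict_logits(params, X))


@dataclass
class TrainConfig:
    hidden_dim: int = 64
    num_layers: int = 2
    dropout_rate: float = 0.3
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 25
    seed: int = 0
    pos_weight: float | None = None
    bn_momentum: float = 0.1


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def train(
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[LSTMParams, TrainHistory]:
    """Fit the model by minibatch Adam on binary cross-entropy.

    Early stopping monitors validation loss (eval-mode pass with running
    batch-norm statistics); the parameters from the best epoch are
    returned.  Deterministic given ``config.seed``.
    """
    cfg = config or TrainConfig()
    train_X = np.asarray(train_X, dtype=float)
    val_X = np.asarray(val_X, dtype=float)
    train_y = np.asarray(train_y, dtype=float)
    val_y = np.asarray(val_y, dtype=float)
    if len(train_X) == 0 or len(val_X) == 0:
        raise ValueError("empty train or validation split")
    if len(np.unique(train_y)) < 2:
        raise ValueError("training labels are single-class")

    rng = np.random.default_rng(cfg.seed)
    params = init_params(train_X.shape[2], cfg.hidden_dim, cfg.num_layers, seed=cfg.seed)
    names = [n for n, _ in params.trainable()] + ["b_out"]
    m = {n: 0.0 for n in names}
    v = {n: 0.0 for n in names}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history = TrainHistory()
    best_val = np.inf
    best_params = params.copy()
    bad_epochs = 0
    n = len(train_X)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch statistics need >= 2 samples
            loss, grads = loss_and_grads(
                params,
                train_X[idx],
                train_y[idx],
                dropout_rate=cfg.dropout_rate,
                rng=rng,
                train=True,
                pos_weight=cfg.pos_weight,
                update_bn=True,
                bn_momentum=cfg.bn_momentum,
            )
            epoch_loss += loss * len(idx)
            step += 1
            arrays = dict(params.trainable())
            arrays["b_out"] = None  # scalar handled below
            for name in names:
                gr = grads[name]
                m[name] = beta1 * m[name] + (1 - beta1) * gr
                v[name] = beta2 * v[name] + (1 - beta2) * gr**2
                mhat = m[name] / (1 - beta1**step)
                vhat = v[name] / (1 - beta2**step)
                upd = cfg.lr * mhat / (np.sqrt(vhat) + eps)
                if name == "b_out":
                    params.b_out -= float(upd)
                else:
                    arrays[name] -= upd
        history.train_loss.append(epoch_loss / n)

        val_logits = predict_logits(params, val_X)
        val_loss, _ = _bce_loss_grad(val_logits, val_y, cfg.pos_weight)
        history.val_loss.append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = params.copy()
            history.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    return best_params, history


# ---------------------------------------------------------------------------
# serialization


def save_model(params: LSTMParams, out_dir: str | Path) -> None:
    """Write a model bundle: meta.json + params.npz.

    The layout is documented in meta.json so the explainer can reload the
    model without the training stack.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for li, lp in enumerate(params.layers):
        for g in GATES:
            arrays[f"l{li}.W_ih.{g}"] = lp.W_ih[g]
            arrays[f"l{li}.W_hh.{g}"] = lp.W_hh[g]
            arrays[f"l{li}.b.{g}"] = lp.b[g]
    arrays.update(
        gamma=params.gamma,
        beta=params.beta,
        running_mean=params.running_mean,
        running_var=params.running_var,
        w_out=params.w_out,
    )
    np.savez(out / "params.npz", **arrays)
    meta = {
        "format": "iwsrisk-lstm-v1",
        "input_dim": params.input_dim,
        "hidden_dim": params.hidden_dim,
        "num_layers": params.num_layers,
        "bn_eps": params.bn_eps,
        "b_out": params.b_out,
        "arrays": sorted(arrays),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(model_dir: str | Path) -> LSTMParams:
    d = Path(model_dir)
    meta = json.loads((d / "meta.json").read_text())
    npz = np.load(d / "params.npz")
    layers = []
    for li in range(meta["num_layers"]):
        layers.append(
            LayerParams(
                W_ih={g: npz[f"l{li}.W_ih.{g}"] for g in GATES},
                W_hh={g: npz[f"l{li}.W_hh.{g}"] for g in GATES},
                b={g: npz[f"l{li}.b.{g}"] for g in GATES},
            )
        )
    return LSTMParams(
        layers=layers,
        gamma=npz["gamma"],
        beta=npz["beta"],
        running_mean=npz["running_mean"],
        running_var=npz["running_var"],
        w_out=npz["w_out"],
        b_out=float(meta["b_out"]),
        input_dim=meta["input_dim"],
        hidden_dim=meta["hidden_dim"],
        num_layers=meta["num_layers"],
        bn_eps=meta["bn_eps"],
    )
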
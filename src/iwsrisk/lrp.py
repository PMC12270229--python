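"""Layer-wise relevance propagation through the unrolled LSTM.

The model's pre-calibration logit is taken as the initial relevance and
redistributed backward through the network — through the batch-norm-folded
fully connected head onto the final hidden state, then recursively through
time and layers — until every input feature at every epoch carries a
signed relevance score.

Propagation rules, applied to the stored forward trace:

* head (epsilon rule for a linear layer):
  R(h_k) = h_k w_k / (y + eps * sign(y)) * R(y), with R(y) = y;
* hidden -> cell: R(c_t) = R(h_t) * o_t * (1 - tanh^2(c_t)), following the
  derivative of h_t = o_t * tanh(c_t) with respect to c_t;
* cell split: R(c_t) is divided between the forget branch f_t * c_{t-1}
  (forwarded to step t-1) and the input branch i_t * g_t in proportion to
  the branches' magnitudes (epsilon-stabilised);
* candidate: the input-branch relevance is scaled by the input gate,
  R(g_t) = R(i*g) * i_t;
* candidate pre-activation (epsilon rule): R(g_t) is redistributed over
  the concatenated gate input [h_{t-1}, x_t] using the candidate weights,
  crediting the previous hidden state (continuing the recursion through
  time) and the current input (the explanation output at layer 1, or the
  lower layer's hidden state in a stacked model).

Only the candidate pathway carries relevance for new information; the
input, forget and output gate pre-activations act as regulators and
receive none.  The hidden->cell and candidate rules rescale rather than
conserve relevance; a strict-conservation variant (cell relevance passed
through unscaled) is available for comparison.  Bias terms absorb no
relevance: denominators are bias-inclusive pre-activations while
numerators use input contributions only, and the resulting leakage is
reported per window as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import LSTMParams, forward
from .schema import DEFAULT_SCHEMA, Schema


def _sign(x: np.ndarray | float) -> np.ndarray:
    """Sign with sign(0) := +1."""
    return np.where(np.asarray(x) >= 0, 1.0, -1.0)


def lrp_epsilon_linear(
    R_out: np.ndarray | float,
    a: np.ndarray,
    w: np.ndarray,
    z: np.ndarray | float,
    eps: float,
) -> np.ndarray:
    """Epsilon-rule relevance redistribution through a linear map.

    For a single output unit: R_j = a_j w_j / (z + eps*sign(z)) * R_out
    with ``w`` of shape (J,), scalar ``z`` and ``R_out``.  For multiple
    output units ``w`` is (J, K), ``z`` and ``R_out`` are (K,), and the
    per-unit relevances are summed over outputs.  ``z`` must be the
    bias-inclusive pre-activation from the forward trace.
    """
    a = np.asarray(a, dtype=float)
    w = np.asarray(w, dtype=float)
    if eps < 0:
        raise ValueError("eps must be >= 0")
    denom = np.asarray(z, dtype=float) + eps * _sign(z)
    if np.any(denom == 0):
        raise ZeroDivisionError("zero stabilised denominator (eps=0 with z=0)")
    if w.ndim == 1:
        return a * w / denom * R_out
    contrib = (a[:, None] * w) / denom[None, :] * np.asarray(R_out)[None, :]
    return contrib.sum(axis=1)


def lrp_hidden_to_cell(R_h: np.ndarray, o_t: np.ndarray, c_t: np.ndarray) -> np.ndarray:
    """Relevance flowing from the hidden state into the cell state."""
    R_h, o_t, c_t = np.broadcast_arrays(R_h, o_t, c_t)
    return R_h * o_t * (1.0 - np.tanh(c_t) ** 2)


def lrp_cell_split(
    R_c: np.ndarray,
    f_t: np.ndarray,
    c_prev: np.ndarray,
    i_t: np.ndarray,
    g_t: np.ndarray,
    eps: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Split cell relevance between the forget and input branches.

    Returns (R to f_t*c_{t-1}, R to i_t*g_t); with eps=0 the two sum to
    R_c exactly.
    """
    forget = f_t * c_prev
    inp = i_t * g_t
    denom = forget + inp
    denom = denom + eps * _sign(denom)
    if np.any(denom == 0):
        # eps = 0 with exactly cancelling branches: no relevance to carry
        safe = np.where(denom == 0, 1.0, denom)
        R_f = np.where(denom == 0, 0.0, forget / safe * R_c)
        R_i = np.where(denom == 0, 0.0, inp / safe * R_c)
        return R_f, R_i
    return forget / denom * R_c, inp / denom * R_c


def lrp_candidate(R_input_branch: np.ndarray, i_t: np.ndarray) -> np.ndarray:
    """Relevance onto the candidate: gate the input-branch relevance by i_t."""
    return R_input_branch * i_t


@dataclass
class RelevanceMap:
    """Per-feature, per-epoch relevance for one prediction.

    ``values`` has shape (lookback, n_features); positive scores push the
    logit up, negative scores push it down.
    """

    values: np.ndarray
    logit: float
    epsilon: float
    window_id: str | int | None = None
    schema: Schema = field(default_factory=lambda: DEFAULT_SCHEMA)
    diagnostics: dict = field(default_factory=dict)

    @property
    def aggregate(self) -> np.ndarray:
        """Per-feature relevance summed over epochs."""
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        t, _ = self.values.shape
        rows = []
        for ti in range(t):
            for fi, name in enumerate(self.schema.names):
                rows.append(
                    {
                        "window_id": self.window_id,
                        "epoch": ti + 1,
                        "feature_name": name,
                        "relevance": self.values[ti, fi],
                    }
                )
        return pd.DataFrame(rows)


def explain(
    params: LSTMParams,
    window: np.ndarray,
    epsilon: float = 1e-3,
    strict_conservation: bool = False,
    window_id: str | int | None = None,
) -> RelevanceMap:
    """Propagate the logit's relevance back onto the input features.

    Runs an eval-mode forward pass to populate the trace, folds batch norm
    into the head, then recurses from the last step and top layer down to
    the first step and layer 1.  Cell relevance at step t accumulates two
    sources: the hidden-state contribution at t and the forget-branch
    share forwarded from step t+1.  Relevance assigned to a stacked
    layer's input re-enters the layer below as hidden-state relevance at
    the same step.  Initial states are zero, so no relevance escapes
    through h_0/c_0.
    """
    pred = forward(window, params, mode="eval")
    tr = pred.trace
    if tr is None:
        raise ValueError("forward trace missing")
    T = window.shape[0]
    H = params.hidden_dim
    L = params.num_layers
    y = pred.logit

    R_h = [np.zeros((T + 1, H)) for _ in range(L)]
    R_c = [np.zeros((T + 1, H)) for _ in range(L)]
    R_x = np.zeros((T, params.input_dim))

    w_eff, _ = params.folded_head()
    h_last = tr.h[-1][-1]
    R_h[-1][T] = lrp_epsilon_linear(y, h_last, w_eff, y, epsilon)
    head_leak = y - R_h[-1][T].sum()

    candidate_leak = 0.0
    for t in range(T, 0, -1):  # state index; step t uses gates at t-1
        for l in range(L - 1, -1, -1):
            i_t = tr.i[l][t - 1]
            f_t = tr.f[l][t - 1]
            o_t = tr.o[l][t - 1]
            g_t = tr.g[l][t - 1]
            zg = tr.zg[l][t - 1]
            c_t = tr.c[l][t]
            c_prev = tr.c[l][t - 1]
            h_prev = tr.h[l][t - 1]
            x_t = tr.x[l][t - 1]

            if strict_conservation:
                from_hidden = R_h[l][t]
            else:
                from_hidden = lrp_hidden_to_cell(R_h[l][t], o_t, c_t)
            R_c_total = R_c[l][t] + from_hidden
            R_f, R_i = lrp_cell_split(R_c_total, f_t, c_prev, i_t, g_t, epsilon)
            R_c[l][t - 1] += R_f
            R_g = lrp_candidate(R_i, i_t)

            a_vec = np.concatenate([h_prev, x_t])
            W_cat = np.vstack([params.layers[l].W_hh["g"], params.layers[l].W_ih["g"]])
            R_in = lrp_epsilon_linear(R_g, a_vec, W_cat, zg, epsilon)
            candidate_leak += float(R_g.sum() - R_in.sum())
            R_h[l][t - 1] += R_in[:H]
            if l > 0:
                R_h[l - 1][t] += R_in[H:]
            else:
                R_x[t - 1] = R_in[H:]

    return RelevanceMap(
        values=R_x,
        logit=y,
        epsilon=epsilon,
        window_id=window_id,
        diagnostics={
            "head_bias_leak": float(head_leak),
            "candidate_bias_leak": candidate_leak,
        },
    )


def explain_dataset(
    params: LSTMParams,
    X: np.ndarray,
    epsilon: float = 1e-3,
    strict_conservation: bool = False,
) -> list[RelevanceMap]:
    """Relevance maps for every window in a (N, T, D) stack."""
    return [
        explain(params, X[n], epsilon, strict_conservation, window_id=n)
        for n in range(len(X))
    ]


def aggregate_importance(
    maps: list[RelevanceMap], schema: Schema = DEFAULT_SCHEMA
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort-level importance from a collection of relevance maps.

    Returns (per_feature, per_feature_epoch).  The per-(feature, epoch)
    score is the mean relevance over windows; the per-feature signed score
    sums those means over epochs, and ``mean_abs`` is the mean over
    windows of the absolute per-window aggregate (robust to sign
    cancellation across windows).  Both signed and absolute rankings are
    emitted.
    """
    if not maps:
        raise ValueError("need at least one relevance map")
    stack = np.stack([m.values for m in maps])  # (N, T, F)
    mean_te = stack.mean(axis=0)  # (T, F)
    signed = mean_te.sum(axis=0)
    mean_abs = np.abs(stack.sum(axis=1)).mean(axis=0)

    per_feature = pd.DataFrame(
        {
            "feature_name": schema.names,
            "signed_relevance": signed,
            "mean_abs_relevance": mean_abs,
        }
    )
    per_feature["rank_signed"] = (
        per_feature["signed_relevance"].abs().rank(ascending=False, method="min").astype(int)
    )
    per_feature["rank_abs"] = (
        per_feature["mean_abs_relevance"].rank(ascending=False, method="min").astype(int)
    )
    per_feature = per_feature.sort_values("rank_abs").reset_index(drop=True)

    t = mean_te.shape[0]
    per_fe = pd.DataFrame(
        [
            {
                "feature_name": schema.names[fi],
                "epoch": ti + 1,
                "mean_relevance": mean_te[ti, fi],
            }
            for fi in range(len(schema.names))
            for ti in range(t)
        ]
    )
    return per_feature, per_fe


def plot_relevance_heatmap(per_feature_epoch: pd.DataFrame, out_path: str, top: int = 30):
    """Epochs-by-features heatmap of mean relevance (top features by |score|)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = per_feature_epoch.pivot(
        index="feature_name", columns="epoch", values="mean_relevance"
    )
    order = pivot.abs().sum(axis=1).sort_values(ascending=False).index[:top]
    pivot = pivot.loc[order]
    fig, ax = plt.subplots(figsize=(8, max(4, 0.25 * len(pivot))))
    vmax = np.abs(pivot.to_numpy()).max() or 1.0
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns)
    ax.set_yticks(range(len(pivot)), pivot.index, fontsize=6)
    ax.set_xlabel("time epoch")
    fig.colorbar(im, ax=ax, label="mean relevance")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
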
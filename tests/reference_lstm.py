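"""Independent reference forward pass for the multilayer LSTM.

A deliberately plain, separately written unroll of the LSTM recurrence and
head, used only as a test oracle for forward-pass equivalence.  It shares
no code with the package implementation: gate pre-activations are formed
from a single stacked weight matrix applied to the concatenated
[h_{t-1}, x_t] vector, and the whole pass works on one window at a time
with explicit Python loops.
"""

import math

import numpy as np


def _sig(v):
    return np.array([1.0 / (1.0 + math.exp(-x)) for x in v])


def reference_logit(params, window) -> float:
    """Eval-mode logit for one (T, D) window, from first principles."""
    x_seq = [np.asarray(row, dtype=float) for row in window]
    for layer in params.layers:
        H = layer.b["i"].shape[0]
        # stacked map: z_gate = [W_hh_gate; W_ih_gate]^T @ [h, x] + b_gate
        h = np.zeros(H)
        c = np.zeros(H)
        out_seq = []
        for x in x_seq:
            hx = np.concatenate([h, x])
            z = {}
            for gate in ("i", "f", "g", "o"):
                W = np.vstack([layer.W_hh[gate], layer.W_ih[gate]])
                z[gate] = W.T @ hx + layer.b[gate]
            i_g = _sig(z["i"])
            f_g = _sig(z["f"])
            cand = np.tanh(z["g"])
            o_g = _sig(z["o"])
            c = f_g * c + i_g * cand
            h = o_g * np.tanh(c)
            out_seq.append(h.copy())
        x_seq = out_seq
    h_final = x_seq[-1]
    normed = (h_final - params.running_mean) / np.sqrt(params.running_var + params.bn_eps)
    affine = params.gamma * normed + params.beta
    return float(np.dot(affine, params.w_out) + params.b_out)
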
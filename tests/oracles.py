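"""Independent straight-line reference implementations used as oracles.

Everything here is deliberately naive: explicit zero padding, triple loops
over output positions and kernel taps, scalar formulas.  These functions
share no code with the package's compute path.
"""

import numpy as np


def same_pad(size, kernel, stride, dilation):
    eff = dilation * (kernel - 1) + 1
    out = int(np.ceil(size / stride))
    total = max((out - 1) * stride + eff - size, 0)
    return total // 2, total - total // 2


def conv2d_loop(x, kern, bias=None, stride=1, dilation=1):
    """x: (H, W, Cin); kern: (kh, kw, Cin, Cout). SAME zero padding."""
    h, w, cin = x.shape
    kh, kw, _, cout = kern.shape
    pt, pb = same_pad(h, kh, stride, dilation)
    pl, pr = same_pad(w, kw, stride, dilation)
    xp = np.zeros((h + pt + pb, w + pl + pr, cin))
    xp[pt: pt + h, pl: pl + w] = x
    ho, wo = int(np.ceil(h / stride)), int(np.ceil(w / stride))
    out = np.zeros((ho, wo, cout))
    for oy in range(ho):
        for ox in range(wo):
            for i in range(kh):
                for j in range(kw):
                    py = oy * stride + i * dilation
                    px = ox * stride + j * dilation
                    for f in range(cout):
                        out[oy, ox, f] += np.dot(xp[py, px], kern[i, j, :, f])
    if bias is not None:
        out += bias
    return out


def bn_loop(x, gamma, beta, mean, var, eps=1e-5):
    return gamma * (x - mean) / np.sqrt(var + eps) + beta


def relu_loop(x):
    return np.maximum(x, 0.0)


def sigmoid_loop(x):
    return 1.0 / (1.0 + np.exp(-x))


def dilated_conv_loop(x, kern, bias, dilation):
    """ReLU(dilated SAME conv + bias), the straight-line form."""
    return relu_loop(conv2d_loop(x, kern, bias, stride=1, dilation=dilation))


def residual_unit_loop(x, weights, stride, activation_after_add=True):
    """conv(S)-BN-ReLU-conv-BN + shortcut, evaluated tap by tap."""
    def bn(z, params):
        c = z.shape[-1]
        return bn_loop(z,
                       params.get("gamma", np.ones(c)),
                       params.get("beta", np.zeros(c)),
                       params.get("mean", np.zeros(c)),
                       params.get("var", np.ones(c)))

    h = conv2d_loop(x, weights["conv1"], stride=stride)
    h = relu_loop(bn(h, weights.get("bn1", {})))
    h = conv2d_loop(h, weights["conv2"], stride=1)
    h = bn(h, weights.get("bn2", {}))
    if "shortcut" in weights:
        s = conv2d_loop(x, weights["shortcut"], stride=stride)
    else:
        s = x
    y = h + s
    return relu_loop(y) if activation_after_add else y


def attention_gate_loop(h, g, weights):
    """sigmoid(Wk[Wint relu(Wh h + Wg g + b_hg) + b_int] + b_k) * h."""
    mixed = (conv2d_loop(h, weights["Wh"])
             + conv2d_loop(g, weights["Wg"])
             + weights.get("b_hg", 0.0))
    inter = conv2d_loop(relu_loop(mixed), weights["Wint"],
                        weights.get("b_int"))
    alpha = sigmoid_loop(conv2d_loop(inter, weights["Wk"],
                                     weights.get("b_k")))
    return alpha * h


def confusion_loop(gold, pred):
    """Pixel-by-pixel confusion counting."""
    tp = fp = fn = tn = 0
    for a, b in zip(np.ravel(gold), np.ravel(pred)):
        if a == 1 and b == 1:
            tp += 1
        elif a == 0 and b == 1:
            fp += 1
        elif a == 1 and b == 0:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def roc_auc_threshold_sweep(y, scores):
    """Trapezoidal ROC-AUC from an exhaustive threshold sweep."""
    y = np.asarray(y).ravel()
    s = np.asarray(scores).ravel()
    thresholds = np.unique(np.concatenate(([np.inf], s)))[::-1]
    pts = []
    pos, neg = (y == 1).sum(), (y == 0).sum()
    for t in thresholds:
        pred = s >= t
        tpr = (pred & (y == 1)).sum() / pos
        fpr = (pred & (y == 0)).sum() / neg
        pts.append((fpr, tpr))
    pts = sorted(pts)
    auc = 0.0
    for (f0, t0), (f1, t1) in zip(pts[:-1], pts[1:]):
        auc += (f1 - f0) * (t0 + t1) / 2.0
    return auc
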
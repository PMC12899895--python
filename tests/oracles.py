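"""Brute-force reference implementations used as independent oracles.

These expand every output element by explicit complex scalar arithmetic
and stay deliberately independent of the package's vectorized/FFT paths.
"""

import numpy as np


def complex_conv2d_oracle(x: np.ndarray, w: np.ndarray, stride=(1, 1),
                          padding=(0, 0), groups=1, bias=None) -> np.ndarray:
    """Elementwise complex cross-correlation. x: (B,Cin,H,W) complex,
    w: (Cout,Cing,kH,kW) complex, bias: (Cout,) complex or None."""
    B, Cin, H, W = x.shape
    Cout, Cing, kH, kW = w.shape
    sh, sw = stride
    ph, pw = padding
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho = (H + 2 * ph - kH) // sh + 1
    Wo = (W + 2 * pw - kW) // sw + 1
    cog = Cout // groups
    out = np.zeros((B, Cout, Ho, Wo), dtype=complex)
    for b in range(B):
        for o in range(Cout):
            g = o // cog
            for i in range(Ho):
                for j in range(Wo):
                    acc = 0.0 + 0.0j
                    for ci in range(Cing):
                        cin = g * Cing + ci
                        for u in range(kH):
                            for v in range(kW):
                                acc += xp[b, cin, i * sh + u, j * sw + v] * w[o, ci, u, v]
                    out[b, o, i, j] = acc
    if bias is not None:
        out += bias[None, :, None, None]
    return out


def complex_linear_oracle(x: np.ndarray, w: np.ndarray, b=None) -> np.ndarray:
    """y[n, o] = sum_i w[o, i] * x[n, i] + b[o], all complex."""
    B, din = x.shape
    dout = w.shape[0]
    out = np.zeros((B, dout), dtype=complex)
    for n in range(B):
        for o in range(dout):
            acc = 0.0 + 0.0j
            for i in range(din):
                acc += w[o, i] * x[n, i]
            out[n, o] = acc
    if b is not None:
        out += b[None, :]
    return out


def segment_offsets_oracle(total: int, win: int, hop: int):
    """Enumerate every valid window start by scanning one sample at a time."""
    return [s for s in range(0, total) if s % hop == 0 and s + win <= total]


def numerical_gradient(f, arr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar f() w.r.t. arr (mutated in place)."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        fp = f()
        arr[i] = old - eps
        fm = f()
        arr[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
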
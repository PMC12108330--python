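"""Independent brute-force oracles used to freeze expected values.

Each oracle evaluates the defining formula directly (nested loops,
exhaustive counting), deliberately sharing no code with the implementation
it checks.
"""

import numpy as np


def dwt2_bruteforce(image, lo, hi):
    """Direct evaluation of the separable decimated double sum with
    periodic index wrap: out[x, y] = sum_{m,n} f[m,n] a[(m-2x) mod H] b[(n-2y) mod W]."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    oh, ow = h // 2, w // 2

    def band(fa, fb):
        out = np.zeros((oh, ow))
        for x in range(oh):
            for y in range(ow):
                acc = 0.0
                for m in range(h):
                    for n in range(w):
                        ja = (m - 2 * x) % h
                        jb = (n - 2 * y) % w
                        va = fa[ja] if ja < len(fa) else 0.0
                        vb = fb[jb] if jb < len(fb) else 0.0
                        acc += image[m, n] * va * vb
                out[x, y] = acc
        return out

    return band(lo, lo), band(lo, hi), band(hi, lo), band(hi, hi)


def patch_mean_bruteforce(fmap, grid):
    """Exhaustive patch averaging of a (C, H, W) map to a grid x grid output."""
    c, h, w = fmap.shape
    ph, pw = h // grid, w // grid
    out = np.zeros((c, grid, grid))
    for ch in range(c):
        for i in range(grid):
            for j in range(grid):
                out[ch, i, j] = fmap[ch, i * ph:(i + 1) * ph,
                                     j * pw:(j + 1) * pw].mean()
    return out


def confusion_bruteforce(pred, gt):
    """Per-pixel tally by explicit iteration (foreground positive)."""
    tp = fp = fn = tn = 0
    for p, g in zip(np.asarray(pred).ravel(), np.asarray(gt).ravel()):
        p, g = bool(p), bool(g)
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def iou_bruteforce(pred, gt, cls):
    """Set-arithmetic IoU for one class label."""
    p = {i for i, v in enumerate(np.asarray(pred).ravel()) if (v > 0) == bool(cls)}
    g = {i for i, v in enumerate(np.asarray(gt).ravel()) if (v > 0) == bool(cls)}
    union = p | g
    if not union:
        return None
    return len(p & g) / len(union)


def numeric_gradient(func, x, eps=1e-5):
    """Central finite differences of a scalar function of one array."""
    x = x.astype(np.float64)
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = func(x)
        x[idx] = orig - eps
        lo = func(x)
        x[idx] = orig
        grad[idx] = (hi - lo) / (2 * eps)
        it.iternext()
    return grad
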
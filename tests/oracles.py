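"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and libraries) used by the package
implementation: GLCM statistics by explicit pixel-pair enumeration, Gabor
responses by direct spatial convolution, and AUC by enumerating all
positive-negative pairs.
"""

import math

import numpy as np


def quantize_oracle(pixels: np.ndarray, n_gray: int) -> np.ndarray:
    arr = np.asarray(pixels, dtype=float)
    vmin, vmax = arr.min(), arr.max()
    if vmax == vmin:
        return np.zeros(arr.shape, dtype=int)
    q = np.floor((arr - vmin) / (vmax - vmin) * n_gray).astype(int)
    return np.minimum(q, n_gray - 1)


def glcm_stats_oracle(pixels: np.ndarray, n_gray: int, d: int, angle_deg: int
                      ) -> dict[str, float]:
    """Symmetric normalized GLCM statistics by explicit pair enumeration."""
    q = quantize_oracle(pixels, n_gray)
    rad = math.radians(angle_deg)
    dr, dc = int(round(math.sin(rad) * d)), int(round(math.cos(rad) * d))
    h, w = q.shape
    counts = np.zeros((n_gray, n_gray), dtype=float)
    for r in range(h):
        for c in range(w):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                counts[q[r, c], q[rr, cc]] += 1
                counts[q[rr, cc], q[r, c]] += 1  # symmetric
    if counts.sum() == 0:
        counts[0, 0] = 1.0
    p = counts / counts.sum()
    contrast = corr_num = energy = uniformity = 0.0
    mu_i = sum(i * p[i, j] for i in range(n_gray) for j in range(n_gray))
    mu_j = sum(j * p[i, j] for i in range(n_gray) for j in range(n_gray))
    var_i = sum((i - mu_i) ** 2 * p[i, j]
                for i in range(n_gray) for j in range(n_gray))
    var_j = sum((j - mu_j) ** 2 * p[i, j]
                for i in range(n_gray) for j in range(n_gray))
    for i in range(n_gray):
        for j in range(n_gray):
            contrast += (i - j) ** 2 * p[i, j]
            corr_num += (i - mu_i) * (j - mu_j) * p[i, j]
            energy += p[i, j] ** 2
            uniformity += p[i, j] / (1.0 + (i - j) ** 2)
    correlation = corr_num / math.sqrt(var_i * var_j) \
        if var_i > 0 and var_j > 0 else 0.0
    return {"contrast": contrast, "correlation": correlation,
            "energy": energy, "uniformity": uniformity}


def gabor_response_oracle(image01: np.ndarray, kernel: np.ndarray
                          ) -> np.ndarray:
    """Magnitude of the complex Gabor response by direct spatial convolution
    with symmetric (reflected) boundary handling, 'same' output."""
    from scipy.ndimage import convolve

    re = convolve(image01, np.real(kernel), mode="reflect")
    im = convolve(image01, np.imag(kernel), mode="reflect")
    return np.hypot(re, im)


def auc_oracle(scores, labels) -> float:
    """Mann-Whitney AUC by enumerating every positive-negative pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
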
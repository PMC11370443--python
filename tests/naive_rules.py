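"""Deliberately naive per-pixel double-loop rule implementations.

These serve as independent oracles for the vectorized classifiers: each
follows the written rule definition literally, one pixel at a time, with
no shared code with the production path.
"""

import math

import numpy as np


def naive_mts(img, cfg):
    h, w, _ = img.shape
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            r, g, b = (float(v) for v in img[i, j])
            denom = r if r != 0 else 1.0
            out[i, j] = (r <= cfg.mts_r_max) and (b / denom >= cfg.mts_br_ratio_min)
    return out


def naive_ttc(img, cfg):
    h, w, _ = img.shape
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            vals = [float(v) for v in img[i, j]]
            mean = sum(vals) / 3.0
            std = math.sqrt(sum((v - mean) ** 2 for v in vals) / 3.0)
            out[i, j] = std <= cfg.ttc_std_max
    return out


def naive_psr(img, cfg):
    h, w, _ = img.shape
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            r, g, b = (float(v) for v in img[i, j])
            mean_gb = (g + b) / 2.0
            if cfg.psr_literal_or:
                out[i, j] = (r > mean_gb) or (r - mean_gb >= cfg.psr_thd)
            else:
                out[i, j] = (r > mean_gb) and (r - mean_gb >= cfg.psr_thd)
    return out


def naive_he(img, cfg):
    """Two-step transform followed by the green threshold, pixel by pixel."""
    h, w, _ = img.shape
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            r, g, b = (int(v) for v in img[i, j])
            if r > cfg.he_channel_cap:
                r = 0
            if g > cfg.he_channel_cap:
                g = 0
            if b > cfg.he_channel_cap:
                b = 0
            if r < g or b < g:
                out[i, j] = g >= cfg.he_g_min
    return out


NAIVE_RULES = {"MTS": naive_mts, "TTC": naive_ttc, "PSR": naive_psr, "HE": naive_he}
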
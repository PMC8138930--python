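"""Independent straight-line transcriptions of the preprocessing and
kinematics formulas, written with plain Python loops.

These deliberately avoid the package's implementations (and its vectorized
numpy idioms) so that agreement between the two routes is a meaningful
check, not a tautology.
"""

import math

import numpy as np


def oracle_clip(values, bounds):
    """bounds: list of (lo, hi) per column; outside the closed interval -> NaN."""
    values = np.asarray(values, dtype=float)
    out = values.copy()
    for t in range(out.shape[0]):
        for j in range(out.shape[1]):
            v = out[t, j]
            lo, hi = bounds[j]
            if not math.isnan(v) and (v < lo or v > hi):
                out[t, j] = math.nan
    return out


def oracle_window(values, window):
    values = np.asarray(values, dtype=float)
    t = len(values)
    if t >= window:
        return values[t - window :].copy()
    out = np.full((window, values.shape[1]), math.nan)
    out[window - t :] = values
    return out


def oracle_hourly_means(matrices):
    """Fill each missing cell with the naive mean of present values there."""
    n_rows, n_cols = matrices[0].shape
    out = [m.copy() for m in matrices]
    for t in range(n_rows):
        for j in range(n_cols):
            present = [m[t, j] for m in matrices if not math.isnan(m[t, j])]
            if not present:
                continue
            mean = sum(present) / len(present)
            for m in out:
                if math.isnan(m[t, j]):
                    m[t, j] = mean
    return out


def oracle_interpolate(values):
    """Linear interpolation against row index; nearest extension at edges."""
    values = np.asarray(values, dtype=float)
    out = values.copy()
    for j in range(values.shape[1]):
        present = [t for t in range(len(values)) if not math.isnan(values[t, j])]
        assert present, "oracle expects at least one observed value per column"
        for t in range(len(values)):
            if not math.isnan(values[t, j]):
                continue
            if t < present[0]:
                out[t, j] = values[present[0], j]
            elif t > present[-1]:
                out[t, j] = values[present[-1], j]
            else:
                left = max(p for p in present if p < t)
                right = min(p for p in present if p > t)
                slope = (values[right, j] - values[left, j]) / (right - left)
                out[t, j] = slope * (t - left) + values[left, j]
    return out


def oracle_smooth(values, width=3):
    values = np.asarray(values, dtype=float)
    out = values.copy()
    for t in range(len(values)):
        start = max(0, t - width + 1)
        for j in range(values.shape[1]):
            window = values[start : t + 1, j]
            out[t, j] = window.sum() / len(window)
    return out


def oracle_normalize(matrices):
    maxima = []
    n_cols = matrices[0].shape[1]
    for j in range(n_cols):
        maxima.append(max(float(m[:, j].max()) for m in matrices))
    scaled = []
    for m in matrices:
        s = m.copy()
        for j in range(n_cols):
            s[:, j] = s[:, j] / maxima[j]
        scaled.append(s)
    return scaled, np.array(maxima)


def oracle_median(values):
    """Midpoint-of-central-order-statistics median of a 1-D sequence."""
    ordered = sorted(float(v) for v in values)
    n = len(ordered)
    if n % 2:
        return ordered[n // 2]
    return (ordered[n // 2 - 1] + ordered[n // 2]) / 2.0


def oracle_kf(matrix, sepsis_components, eps=1e-12):
    """Unit-vector components + velocity/acceleration projections per hour."""
    matrix = np.asarray(matrix, dtype=float)
    t_len, n = matrix.shape
    rel = [[matrix[t, j] - sepsis_components[j] for j in range(n)] for t in range(t_len)]
    vel = [[0.0] * n for _ in range(t_len)]
    for t in range(1, t_len):
        vel[t] = [rel[t][j] - rel[t - 1][j] for j in range(n)]
    acc = [[0.0] * n for _ in range(t_len)]
    for t in range(2, t_len):
        acc[t] = [vel[t][j] - vel[t - 1][j] for j in range(n)]
    out = np.zeros((t_len, n + 2))
    for t in range(t_len):
        dist = math.sqrt(sum(c * c for c in rel[t]))
        if dist <= eps:
            e = [0.0] * n
        else:
            e = [c / dist for c in rel[t]]
        out[t, :n] = e
        out[t, n] = sum(vel[t][j] * e[j] for j in range(n))
        out[t, n + 1] = sum(acc[t][j] * e[j] for j in range(n))
    return out
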
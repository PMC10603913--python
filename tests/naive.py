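"""Independent naive-loop oracles used by the test suite.

Everything here is implemented with plain Python scans, straight from the
stated definitions, and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


# --- preprocessing oracles -------------------------------------------------


def naive_out_of_range(values, valid, lo, hi):
    vals = list(values)
    flags = list(valid)
    for i, v in enumerate(vals):
        if not math.isnan(v) and (v < lo or v > hi):
            vals[i] = float("nan")
            flags[i] = False
    return vals, flags


def naive_forward_fill(values, valid, cap):
    """Fill blanks with the last ORIGINAL valid value, at most `cap` steps."""
    vals = list(values)
    flags = list(valid)
    filled = [False] * len(vals)
    last = None
    age = 0
    for i in range(len(vals)):
        if flags[i]:
            last = vals[i]
            age = 0
        else:
            age += 1
            if last is not None and age <= cap:
                vals[i] = last
                flags[i] = True
                filled[i] = True
    return vals, flags, filled


def naive_sections(quality, threshold, min_len, t0=0, interval=1):
    """Run-length scan for maximal runs with quality strictly above threshold."""
    out = []
    i = 0
    n = len(quality)
    while i < n:
        if quality[i] > threshold:
            j = i
            while j + 1 < n and quality[j + 1] > threshold:
                j += 1
            start = t0 + i * interval
            end = t0 + j * interval + interval
            if end - start >= min_len:
                out.append((start, end))
            i = j + 1
        else:
            i += 1
    return out


# --- predictor oracles -----------------------------------------------------


def naive_rolling_mean(values, valid, window, min_frac):
    n = len(values)
    out = [float("nan")] * n
    for i in range(n):
        if i + 1 < window:
            continue
        idx = range(i + 1 - window, i + 1)
        good = [values[j] for j in idx if valid[j]]
        if len(good) + 1e-9 >= min_frac * window and good:
            out[i] = sum(good) / len(good)
    return out


def naive_expanding_mean(values, valid, warmup, t=None):
    n = len(values)
    out = [float("nan")] * n
    total = 0.0
    count = 0
    for i in range(n):
        if valid[i]:
            total += values[i]
            count += 1
        if count > 0 and i >= warmup:
            out[i] = total / count
    return out


# --- peak-detection oracle (scipy's documented definitions, re-derived) ----


def naive_local_maxima(x):
    """Peaks: samples whose two direct neighbours are smaller; equal-valued
    plateaus yield the (lower-)middle sample.  Edges are never peaks."""
    peaks = []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                peaks.append(i + (j - i) // 2)
            i = j + 1
        else:
            i += 1
    return peaks


def naive_prominence(x, peak):
    """Prominence and base positions: walk out from the peak while the signal
    stays at or below the peak height, tracking the minima."""
    height = x[peak]
    i = peak
    left_min, left_base = height, peak
    while i > 0 and x[i - 1] <= height:
        i -= 1
        if x[i] < left_min:
            left_min, left_base = x[i], i
    i = peak
    right_min, right_base = height, peak
    while i < len(x) - 1 and x[i + 1] <= height:
        i += 1
        if x[i] < right_min:
            right_min, right_base = x[i], i
    return height - max(left_min, right_min), left_base, right_base


def naive_width(x, peak, prominence, left_base, right_base, rel_height=0.5):
    """Width at the evaluation height `peak - rel_height * prominence`, with
    linear interpolation of the crossing points inside the base interval."""
    height = x[peak] - rel_height * prominence
    i = peak
    while i > left_base and x[i] > height:
        i -= 1
    left_ip = float(i)
    if x[i] < height:
        left_ip += (height - x[i]) / (x[i + 1] - x[i])
    i = peak
    while i < right_base and x[i] > height:
        i += 1
    right_ip = float(i)
    if x[i] < height:
        right_ip -= (height - x[i]) / (x[i - 1] - x[i])
    return right_ip - left_ip


def naive_detect(x, min_distance, min_prominence, width_lo, width_hi):
    """Full naive detection pipeline for one direction on a unit-interval
    grid: plateau-middle peaks, greedy higher-prominence-wins distance
    suppression (ties to the earlier peak), then prominence and width-bounds
    filters.  Returns (index, prominence, width) triples."""
    x = [float(v) for v in x]
    if len(x) < 3:
        return []
    peaks = naive_local_maxima(x)
    info = []
    for p in peaks:
        prom, lb, rb = naive_prominence(x, p)
        width = naive_width(x, p, prom, lb, rb)
        info.append((p, prom, width))
    order = sorted(range(len(info)), key=lambda k: (-info[k][1], info[k][0]))
    taken = []
    keep = [False] * len(info)
    for k in order:
        p = info[k][0]
        if all(abs(p - q) >= min_distance for q in taken):
            keep[k] = True
            taken.append(p)
    out = []
    for k, (p, prom, width) in enumerate(info):
        if keep[k] and prom >= min_prominence and width_lo <= width <= width_hi:
            out.append((p, prom, width))
    return out


# --- statistics oracle -----------------------------------------------------


def naive_welch(a, b):
    """Textbook Welch statistic and Welch-Satterthwaite df."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


# --- foot oracle -----------------------------------------------------------


def naive_region_sums(grid_frame, row_regions):
    """grid_frame: rows x cols nested lists; row_regions: dict region -> rows."""
    out = {}
    for region, rows in row_regions.items():
        out[region] = sum(sum(grid_frame[r]) for r in rows)
    return out
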
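"""Independent brute-force reference implementations used only by tests.

These are written from the definitions with plain Python loops, deliberately
sharing no code with the package, so agreement is a real cross-check.
"""

import math


def percentile_linear(values, p):
    """Linear-interpolation percentile between order statistics."""
    v = sorted(values)
    n = len(v)
    if n == 1:
        return v[0]
    pos = p / 100.0 * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def aih(values, p):
    """Height at which the running sum of sorted heights reaches p% of total."""
    v = sorted(values)
    total = sum(v)
    run = 0.0
    for z in v:
        run += z
        if run >= p / 100.0 * total - 1e-12 * total:
            return z
    return v[-1]


def moments(values):
    n = len(values)
    mean = sum(values) / n
    out = {
        "H_mean": mean,
        "H_sqrt": math.sqrt(sum(z * z for z in values) / n),
        "H_min": min(values),
        "H_max": max(values),
        "H_median": percentile_linear(values, 50),
        "H_aad": sum(abs(z - mean) for z in values) / n,
    }
    med = out["H_median"]
    out["H_mad"] = percentile_linear([abs(z - med) for z in values], 50)
    if n >= 2:
        var1 = sum((z - mean) ** 2 for z in values) / (n - 1)
        sd1 = math.sqrt(var1)
        out["H_std"] = sd1
        out["H_cv"] = sd1 / mean if mean else float("nan")
        m2 = sum((z - mean) ** 2 for z in values) / n
        m3 = sum((z - mean) ** 3 for z in values) / n
        m4 = sum((z - mean) ** 4 for z in values) / n
        if m2 > 0:
            out["H_skew"] = m3 / m2**1.5
            out["H_curt"] = m4 / m2**2
    return out


def densities(all_z, cutoff, n_layers, denominator="all"):
    above = [z for z in all_z if z > cutoff]
    if not above:
        return [0.0] * n_layers
    denom = len(all_z) if denominator == "all" else len(above)
    zmax = max(above)
    if zmax == cutoff:
        counts = [len(above)] + [0] * (n_layers - 1)
        return [c / denom for c in counts]
    width = (zmax - cutoff) / n_layers
    counts = [0] * n_layers
    for z in above:
        i = int((z - cutoff) / width)
        i = min(i, n_layers - 1)  # top bin closed
        counts[i] += 1
    return [c / denom for c in counts]


def regression_metrics(y_true, y_pred):
    m = len(y_true)
    resid = [a - b for a, b in zip(y_true, y_pred)]
    rmse = math.sqrt(sum(r * r for r in resid) / m)
    mae = sum(abs(r) for r in resid) / m
    ybar = sum(y_true) / m
    ss_tot = sum((y - ybar) ** 2 for y in y_true)
    r2 = 1 - sum(r * r for r in resid) / ss_tot if ss_tot > 0 else float("nan")
    rrmse = 100 * rmse / ybar if ybar else float("nan")
    return {"r2": r2, "rmse": rmse, "rrmse": rrmse, "mae": mae}


def point_in_polygon(px, py, corners):
    """Ray casting with on-boundary points counted inside."""
    n = len(corners)
    inside = False
    for i in range(n):
        x1, y1 = corners[i]
        x2, y2 = corners[(i + 1) % n]
        # boundary check
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12:
            return True
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside
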
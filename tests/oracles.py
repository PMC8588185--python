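"""Independent brute-force oracles: deliberately naive loop implementations
kept free of any package internals beyond the data containers."""

from __future__ import annotations

import numpy as np

MISSING_DB = -999.0


def com_oracle(values, range_bins, threshold_db):
    """Per-ping linear-power center of mass by explicit loops."""
    out = []
    for row in values:
        num = den = 0.0
        for v, r in zip(row, range_bins):
            if v >= threshold_db and v > MISSING_DB:
                w = 10.0 ** (v / 10.0)
                num += w * r
                den += w
        out.append(num / den if den > 0 else np.nan)
    return np.array(out)


def limits_oracle(values, range_bins, threshold_db, min_run_bins=2):
    """Per-ping min/max above-threshold range after removing short runs."""
    lowers, uppers = [], []
    for row in values:
        mask = [(v >= threshold_db and v > MISSING_DB) for v in row]
        # remove runs shorter than min_run_bins
        cleaned = list(mask)
        i = 0
        while i < len(mask):
            if mask[i]:
                j = i
                while j < len(mask) and mask[j]:
                    j += 1
                if j - i < min_run_bins:
                    for k in range(i, j):
                        cleaned[k] = False
                i = j
            else:
                i += 1
        idx = [k for k, m in enumerate(cleaned) if m]
        if idx:
            lowers.append(range_bins[min(idx)])
            uppers.append(range_bins[max(idx)])
        else:
            lowers.append(np.nan)
            uppers.append(np.nan)
    return np.array(lowers), np.array(uppers)


def flood_fill_oracle(mask):
    """4-connected components by explicit stack-based flood fill, ordered by
    (first ping, first bin); returns a list of sorted pixel-tuple sets."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    regions = []
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                pix = []
                while stack:
                    a, b = stack.pop()
                    pix.append((a, b))
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        na, nb = a + da, b + db
                        if (
                            0 <= na < mask.shape[0]
                            and 0 <= nb < mask.shape[1]
                            and mask[na, nb]
                            and not seen[na, nb]
                        ):
                            seen[na, nb] = True
                            stack.append((na, nb))
                regions.append(sorted(pix))
    regions.sort(key=lambda r: r[0])
    return regions


def filter_oracle(regions, values, min_size_px, min_level_db):
    """Exhaustive double-threshold scan; mean level in the linear domain."""
    kept = []
    for pix in regions:
        if len(pix) < min_size_px:
            continue
        mean_pow = np.mean([10.0 ** (values[a, b] / 10.0) for a, b in pix])
        if 10.0 * np.log10(mean_pow) < min_level_db:
            continue
        kept.append(sorted(pix))
    return kept


def ols_slope_oracle(x, y):
    """Closed-form OLS slope: cov(x, y) / var(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    return float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())


def tilt_oracle(values, range_bins, pixels):
    """Per-ping max pixel (ties -> smallest bin), then closed-form OLS."""
    by_ping = {}
    for a, b in pixels:
        by_ping.setdefault(a, []).append(b)
    pings = sorted(by_ping)
    rs = []
    for p in pings:
        bs = by_ping[p]
        best_v = max(values[p, b] for b in bs)
        best_b = min(b for b in bs if values[p, b] == best_v)
        rs.append(range_bins[best_b])
    return ols_slope_oracle(pings, rs)


def erosion_oracle(mask, structure):
    """Binary erosion with zero padding by explicit loops."""
    mask = np.asarray(mask, dtype=bool)
    sy, sx = structure.shape
    cy, cx = sy // 2, sx // 2
    out = np.zeros_like(mask)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            ok = True
            for a in range(sy):
                for b in range(sx):
                    if structure[a, b]:
                        ni, nj = i + a - cy, j + b - cx
                        val = (
                            mask[ni, nj]
                            if 0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                            else False
                        )
                        if not val:
                            ok = False
            out[i, j] = ok
    return out


def dilation_oracle(mask, structure):
    mask = np.asarray(mask, dtype=bool)
    sy, sx = structure.shape
    cy, cx = sy // 2, sx // 2
    out = np.zeros_like(mask)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            hit = False
            for a in range(sy):
                for b in range(sx):
                    if structure[a, b]:
                        ni, nj = i - (a - cy), j - (b - cx)
                        if 0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]:
                            if mask[ni, nj]:
                                hit = True
            out[i, j] = hit
    return out


def levene_oracle(groups_values):
    """Hand-computed Levene W: one-way ANOVA F on |x - group mean|."""
    zs = [np.abs(np.asarray(g, float) - np.mean(g)) for g in groups_values]
    all_z = np.concatenate(zs)
    k = len(zs)
    n = all_z.size
    zbar = all_z.mean()
    ssb = sum(len(z) * (z.mean() - zbar) ** 2 for z in zs)
    ssw = sum(((z - z.mean()) ** 2).sum() for z in zs)
    if ssb <= 1e-300:
        return 0.0
    return (ssb / (k - 1)) / (ssw / (n - k))


def anova_ss_oracle(y, fa, fb):
    """Balanced two-way ANOVA sums of squares by explicit design-matrix
    least squares (sum-to-zero coding, full-rank balanced design)."""
    y = np.asarray(y, float)
    la = sorted(set(fa))
    lb = sorted(set(fb))

    def contrast(labels, levels):
        X = np.zeros((len(labels), len(levels) - 1))
        for r, lab in enumerate(labels):
            i = levels.index(lab)
            if i < len(levels) - 1:
                X[r, i] = 1
            else:
                X[r, :] = -1
        return X

    Xa = contrast(list(fa), la)
    Xb = contrast(list(fb), lb)
    Xab = np.column_stack(
        [Xa[:, i] * Xb[:, j] for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
    )
    one = np.ones((y.size, 1))

    def sse(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    full = np.hstack([one, Xa, Xb, Xab])
    s_full = sse(full)
    return {
        "factor_a": sse(np.hstack([one, Xb, Xab])) - s_full,
        "factor_b": sse(np.hstack([one, Xa, Xab])) - s_full,
        "interaction": sse(np.hstack([one, Xa, Xb])) - s_full,
        "resid": s_full,
    }


def tukey_sig_oracle(values, groups, alpha):
    """Pairwise Tukey-Kramer significance by direct studentized-range math."""
    from scipy.stats import studentized_range

    values = np.asarray(values, float)
    labels = sorted(set(groups), key=list(groups).index)
    k = len(labels)
    means = {g: values[np.asarray(groups) == g].mean() for g in labels}
    ns = {g: int((np.asarray(groups) == g).sum()) for g in labels}
    resid = np.concatenate(
        [values[np.asarray(groups) == g] - means[g] for g in labels]
    )
    dfe = values.size - k
    mse = (resid**2).sum() / dfe
    qc = studentized_range.ppf(1 - alpha, k, dfe)
    sig = {}
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1 :]:
            se = np.sqrt(mse / 2 * (1 / ns[g1] + 1 / ns[g2]))
            sig[(g1, g2)] = abs(means[g1] - means[g2]) / se > qc
    return sig
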
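"""Event-wise behavioral table, composite response scoring (B0/B1/B2), and
the Levene / two-way ANOVA / Tukey homogeneous-subset layer.

The ANOVA is an unbalanced two-way design with interaction, Type III sums of
squares under sum-to-zero contrasts, computed by explicit design-matrix least
squares.  Interaction columns aliased by empty cells are dropped, reducing
the interaction degrees of freedom accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .envelope import SchoolEnvelope, aggregate_envelope
from .io import EventSchedule
from .traces import Trace, summarize_traces

__all__ = [
    "LEVEL_CLASSES",
    "classify_level",
    "build_event_table",
    "composite_score",
    "classify_behavior",
    "score_event_table",
    "levene_test",
    "two_way_anova",
    "AnovaResult",
    "tukey_subsets",
    "synthetic_event_table",
]

LEVEL_CLASSES = ("background", "low", "medium", "high", "very_high")

#: Default B0/B1/B2 cut points in baseline-SD units of |composite score|.
DEFAULT_T1 = 0.5
DEFAULT_T2 = 2.0

_DELTA_COLS = ("delta_depth", "delta_extent", "delta_length", "delta_tilt")


def classify_level(spl_db: float) -> str:
    """SPL level class, half-open bins:
    background < 120 <= low < 140 <= medium < 150 <= high < 170 <= very_high."""
    if not np.isfinite(spl_db):
        raise ValueError("spl_db must be finite")
    if spl_db < 120:
        return "background"
    if spl_db < 140:
        return "low"
    if spl_db < 150:
        return "medium"
    if spl_db < 170:
        return "high"
    return "very_high"


# ---------------------------------------------------------------------------
# Event table


def build_event_table(
    schedule: EventSchedule,
    env: SchoolEnvelope,
    traces: list[Trace],
    transducer_depth: float,
    baseline_s: float = 300.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Join per-event envelope and trace aggregates into the behavioral table.

    For each event the response window is the event window and the baseline
    window is the preceding ``baseline_s`` seconds.  Envelope ranges are
    converted to depth below the surface.  Returns (table, skipped_event_ids)
    where skipped events fall outside the data span.
    """
    t_lo, t_hi = float(env.ping_times[0]), float(env.ping_times[-1])
    skipped: list[str] = []
    resp_windows, base_windows, kept = [], [], []
    for row in schedule.rows.itertuples():
        t0, t1 = float(row.start_time), float(row.start_time + row.duration_s)
        if t1 <= t_lo or t0 >= t_hi:
            skipped.append(str(row.event_id))
            continue
        kept.append(row)
        resp_windows.append((str(row.event_id), t0, t1))
        base_windows.append((str(row.event_id), t0 - baseline_s, t0))

    resp_env = aggregate_envelope(env, resp_windows)
    base_env = aggregate_envelope(env, base_windows)
    resp_tr = summarize_traces(traces, resp_windows)
    base_tr = summarize_traces(traces, base_windows)

    def depth(r):  # range -> depth below surface, clamped at 0
        return np.clip(transducer_depth - r, 0.0, None)

    rows = []
    for i, row in enumerate(kept):
        re_, be_ = resp_env.iloc[i], base_env.iloc[i]
        rt_, bt_ = resp_tr.iloc[i], base_tr.iloc[i]
        extent = re_.upper_limit - re_.lower_limit  # in range units == m
        base_extent = be_.upper_limit - be_.lower_limit
        rows.append(
            {
                "event_id": str(row.event_id),
                "source_type": row.source_type,
                "spl_db": float(row.spl_db),
                "level_class": classify_level(float(row.spl_db)),
                "avg_depth": depth(re_.com),
                "upper_limit": depth(re_.upper_limit),
                "lower_limit": depth(re_.lower_limit),
                "extent": extent,
                "avg_trace_length": rt_.mean_length_pings,
                "avg_trace_tilt": rt_.mean_tilt,
                "n_traces": rt_.n_traces,
                "valid_fraction": re_.valid_fraction,
                "baseline_depth": depth(be_.com),
                "baseline_extent": base_extent,
                "baseline_length": bt_.mean_length_pings,
                "baseline_tilt": bt_.mean_tilt,
                "delta_depth": depth(re_.com) - depth(be_.com),
                "delta_extent": extent - base_extent,
                "delta_length": rt_.mean_length_pings - bt_.mean_length_pings,
                "delta_tilt": rt_.mean_tilt - bt_.mean_tilt,
                "missing": not bool(re_.valid_fraction > 0),
            }
        )
    return pd.DataFrame(rows), skipped


# ---------------------------------------------------------------------------
# Composite score and behavior classes


def composite_score(
    table: pd.DataFrame,
    baseline_mask: np.ndarray | None = None,
    delta_cols: tuple[str, ...] = _DELTA_COLS,
) -> tuple[np.ndarray, np.ndarray]:
    """First principal component of the z-scored response-change variables.

    Variables are z-scored against the rows selected by ``baseline_mask``
    (default: all rows).  Zero-variance variables are dropped with a warning;
    if all are dropped this is an error.  The sign is fixed so that larger
    scores mean stronger responses (positive correlation with the row norm of
    the z matrix).  Returns (scores, loadings); rows with missing variables
    get NaN scores.
    """
    cols = [c for c in delta_cols if c in table.columns]
    if not cols:
        raise ValueError("no response-change columns present")
    X = table[cols].to_numpy(dtype=float)
    if baseline_mask is None:
        baseline_mask = np.ones(len(table), dtype=bool)
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    ref = X[baseline_mask]

    # drop variables too sparsely observed to score against
    usable = np.isfinite(X).mean(axis=0) >= 0.75
    if not usable.any():
        raise ValueError("all response variables are missing")
    if not usable.all():
        dropped = [c for c, k in zip(cols, usable) if not k]
        warnings.warn(f"sparse variable(s) dropped from PCA: {dropped}",
                      stacklevel=2)
    X = X[:, usable]
    ref = ref[:, usable]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(ref, axis=0)
        sd = np.nanstd(ref, axis=0, ddof=1)
        # no baseline spread -> fall back to the overall spread
        overall_sd = np.nanstd(X, axis=0, ddof=1)
    sd = np.where(np.isfinite(sd) & (sd > 0), sd, overall_sd)
    mu = np.where(np.isfinite(mu), mu, np.nanmean(X, axis=0))
    inert = ~(np.isfinite(sd) & (sd > 0))  # globally constant: contributes 0
    sd = np.where(inert, 1.0, sd)

    Z = (X - mu) / sd
    Z[:, inert] = 0.0
    complete = np.all(np.isfinite(Z), axis=1)
    if complete.sum() < 3:
        raise ValueError("need >= 3 complete records for the composite score")
    Zc = Z[complete]
    scores = np.full(len(table), np.nan)
    if not np.any(Zc):
        scores[complete] = 0.0
        return scores, np.zeros(Z.shape[1])
    # PC1 of the baseline-referenced z matrix (no re-centering: the origin is
    # the baseline state, so scores stay in baseline-SD units)
    _, _, vt = np.linalg.svd(Zc, full_matrices=False)
    loading = vt[0]
    scores[complete] = Zc @ loading
    strength = np.linalg.norm(Zc, axis=1)
    corr = np.corrcoef(scores[complete], strength)[0, 1] if Zc.shape[0] > 1 else 1.0
    if np.isfinite(corr) and corr < 0:
        loading = -loading
        scores = -scores
    return scores, loading


def classify_behavior(
    scores: np.ndarray, t1: float = DEFAULT_T1, t2: float = DEFAULT_T2
) -> np.ndarray:
    """Map |score| to behavior classes: < t1 -> B0, < t2 -> B1, else B2.
    NaN scores map to the empty string."""
    if not 0 <= t1 <= t2:
        raise ValueError("need 0 <= t1 <= t2")
    a = np.abs(np.asarray(scores, dtype=float))
    out = np.where(a < t1, "B0", np.where(a < t2, "B1", "B2"))
    return np.where(np.isfinite(a), out, "")


def score_event_table(
    table: pd.DataFrame,
    t1: float = DEFAULT_T1,
    t2: float = DEFAULT_T2,
) -> pd.DataFrame:
    """Append composite scores and B0/B1/B2 classes to an event table,
    z-scoring against background-class events when present."""
    table = table.copy()
    mask = (table["level_class"] == "background").to_numpy()
    if mask.sum() < 2:
        mask = np.ones(len(table), dtype=bool)
    scores, _ = composite_score(table, baseline_mask=mask)
    table["composite_score"] = scores
    table["behavior_class"] = classify_behavior(scores, t1, t2)
    return table


# ---------------------------------------------------------------------------
# Levene's test


def levene_test(values, groups) -> tuple[float, float]:
    """Classic Levene test on absolute deviations from group means.

    Returns (W, p).  W is the one-way ANOVA F statistic computed on
    z = |x - mean of its group|.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    zs = []
    for g in labels:
        x = values[groups == g]
        if x.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        zs.append(np.abs(x - x.mean()))
    n_total = values.size
    k = len(labels)
    zbar = np.concatenate(zs).mean()
    ss_between = sum(z.size * (z.mean() - zbar) ** 2 for z in zs)
    ss_within = sum(((z - z.mean()) ** 2).sum() for z in zs)
    if ss_between <= 1e-300:
        return 0.0, 1.0
    if ss_within <= 0:
        return np.inf, 0.0
    w = (ss_between / (k - 1)) / (ss_within / (n_total - k))
    p = float(sps.f.sf(w, k - 1, n_total - k))
    return float(w), p


# ---------------------------------------------------------------------------
# Two-way ANOVA, Type III


@dataclass
class AnovaResult:
    """Effect table of an unbalanced two-way ANOVA with interaction."""

    effects: pd.DataFrame  # rows: factor_a, factor_b, interaction
    ss_resid: float
    df_resid: int
    n: int

    @property
    def ms_resid(self) -> float:
        return self.ss_resid / self.df_resid


def _sum_contrast(labels: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero contrast columns (n x (k-1)) for a factor."""
    n, k = labels.size, len(levels)
    X = np.zeros((n, k - 1))
    index = {lv: i for i, lv in enumerate(levels)}
    for row, lab in enumerate(labels):
        i = index[lab]
        if i < k - 1:
            X[row, i] = 1.0
        else:
            X[row, :] = -1.0
    return X


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), rank


def two_way_anova(values, factor_a, factor_b) -> AnovaResult:
    """Unbalanced two-way ANOVA with interaction, Type III SS under
    sum-to-zero contrasts.

    Interaction columns aliased by empty cells are dropped (the interaction
    df shrinks accordingly).  A factor with a single level contributes no
    effect row, reducing to a one-way analysis.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b) if factor_b is not None else np.zeros(y.size, dtype=int)
    if y.size != fa.size or y.size != fb.size:
        raise ValueError("values and factors must have equal length")
    lev_a = list(pd.unique(fa))
    lev_b = list(pd.unique(fb))
    if len(lev_a) < 2:
        raise ValueError("factor_a needs >= 2 levels")
    Xa = _sum_contrast(fa, lev_a)
    Xb = _sum_contrast(fb, lev_b) if len(lev_b) > 1 else np.empty((y.size, 0))
    ones = np.ones((y.size, 1))

    main = np.hstack([ones, Xa, Xb])
    rank_main = np.linalg.matrix_rank(main)
    if rank_main < main.shape[1]:
        raise ValueError("singular design: main effects aliased "
                         f"(rank {rank_main} < {main.shape[1]} columns)")

    # interaction columns, keeping only those that increase the rank
    inter_cols = []
    current = main
    rank = rank_main
    for i in range(Xa.shape[1]):
        for j in range(Xb.shape[1]):
            col = (Xa[:, i] * Xb[:, j])[:, None]
            cand = np.hstack([current, col])
            r = np.linalg.matrix_rank(cand)
            if r > rank:
                inter_cols.append(col)
                current = cand
                rank = r
    Xab = np.hstack(inter_cols) if inter_cols else np.empty((y.size, 0))

    X_full = np.hstack([ones, Xa, Xb, Xab])
    if y.size <= rank:
        raise ValueError("no residual degrees of freedom")
    sse_full, rank_full = _sse(X_full, y)
    df_resid = y.size - rank_full

    blocks = {"factor_a": Xa}
    if Xb.shape[1]:
        blocks["factor_b"] = Xb
    if Xab.shape[1]:
        blocks["interaction"] = Xab

    rows = []
    for name, block in blocks.items():
        others = [ones] + [b for n2, b in blocks.items() if n2 != name]
        sse_red, _ = _sse(np.hstack(others), y)
        ss = max(sse_red - sse_full, 0.0)
        df = block.shape[1]
        ms = ss / df
        mse = sse_full / df_resid if df_resid > 0 else np.nan
        if not np.isfinite(mse):
            f_stat = p = np.nan
        elif mse == 0.0:
            # degenerate: no residual variation at all
            f_stat = 0.0 if ms <= 1e-300 else np.inf
            p = 1.0 if f_stat == 0.0 else 0.0
        else:
            f_stat = ms / mse
            p = float(sps.f.sf(f_stat, df, df_resid))
        rows.append({"effect": name, "ss": ss, "df": df, "F": f_stat, "p": p})
    return AnovaResult(
        effects=pd.DataFrame(rows).set_index("effect"),
        ss_resid=sse_full,
        df_resid=df_resid,
        n=y.size,
    )


# ---------------------------------------------------------------------------
# Tukey-Kramer homogeneous subsets


def tukey_subsets(values, groups, alpha: float = 0.05,
                  ms_error: float | None = None, df_error: int | None = None):
    """All-pairs Tukey-Kramer comparisons and maximal homogeneous subsets.

    If ``ms_error``/``df_error`` are not supplied they come from the one-way
    ANOVA residual.  Returns (subsets, pairwise) where ``subsets`` is a list
    of lists of group labels ordered by mean — each a maximal set with no
    significant pair inside — and ``pairwise`` is a DataFrame of pairwise
    mean differences, q statistics and p-values.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    means = np.array([values[groups == g].mean() for g in labels])
    ns = np.array([np.sum(groups == g) for g in labels])
    if ms_error is None or df_error is None:
        resid = np.concatenate(
            [values[groups == g] - values[groups == g].mean() for g in labels]
        )
        df_error = int(values.size - k)
        if df_error <= 0:
            raise ValueError("no residual degrees of freedom for Tukey test")
        ms_error = float((resid**2).sum() / df_error)

    order = np.argsort(means, kind="stable")
    labels_s = [labels[i] for i in order]
    means_s = means[order]
    ns_s = ns[order]

    qcrit = sps.studentized_range.ppf(1 - alpha, k, df_error)

    def significant(i: int, j: int) -> bool:
        se = np.sqrt(ms_error / 2.0 * (1.0 / ns_s[i] + 1.0 / ns_s[j]))
        if se == 0:
            return means_s[i] != means_s[j]
        return abs(means_s[i] - means_s[j]) / se > qcrit

    pairs = []
    for a in range(k):
        for b in range(a + 1, k):
            se = np.sqrt(ms_error / 2.0 * (1.0 / ns_s[a] + 1.0 / ns_s[b]))
            q = abs(means_s[a] - means_s[b]) / se if se > 0 else np.inf
            pairs.append(
                {
                    "group_1": labels_s[a],
                    "group_2": labels_s[b],
                    "mean_diff": means_s[b] - means_s[a],
                    "q": q,
                    "p": float(sps.studentized_range.sf(q, k, df_error)),
                    "significant": significant(a, b),
                }
            )
    pairwise = pd.DataFrame(pairs)

    # maximal contiguous runs (in mean order) with no significant pair inside
    subsets: list[list] = []
    for start in range(k):
        end = start
        while end + 1 < k and not any(
            significant(i, end + 1) for i in range(start, end + 1)
        ):
            end += 1
        run = labels_s[start : end + 1]
        if not any(set(run) <= set(s) for s in subsets):
            subsets.append(run)
    return subsets, pairwise


# ---------------------------------------------------------------------------
# Synthetic event tables (test harness for the statistics layer)


def synthetic_event_table(
    seed: int,
    n_per_cell: int = 4,
    source_types: tuple[str, ...] = ("tone", "chirp", "windmill", "white"),
    level_classes: tuple[str, ...] = ("low", "medium", "high", "very_high"),
    level_effect: float = 0.0,
    type_effect: float = 0.0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Generate a per-event response table with controllable main effects.

    The response (``avg_depth``) is ``level_effect * level index +
    type_effect * type index + N(0, noise_sd)``; used to measure detection
    power and false-positive rates of the ANOVA layer.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ti, st in enumerate(source_types):
        for li, lc in enumerate(level_classes):
            for _ in range(n_per_cell):
                rows.append(
                    {
                        "source_type": st,
                        "level_class": lc,
                        "avg_depth": level_effect * li
                        + type_effect * ti
                        + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
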
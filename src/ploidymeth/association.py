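"""Associations among TEs, methylation, and expression.

Distance between two half-open intervals is the gap in bp; intervals
that intersect — and book-ended intervals with a 0-bp gap — are at
distance 0, but the body-overlap flag is set only on true
intersection. Expression groups follow the
threshold-plus-tertiles scheme: features below a small FPKM floor are
"none"-expressed, the rest are ranked and split into equal thirds
(low/middle/high, remainders to the lower groups).
"""

from __future__ import annotations

from dataclasses import dataclass
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ploidymeth.profiles import MethylationProfile, compute_profile


def _interval_gap(a_start: int, a_end: int, b_start, b_end):
    """Gap in bp between half-open intervals (0 if they intersect or
    are book-ended). Vectorized over b."""
    return np.maximum(0, np.maximum(b_start - a_end, a_start - b_end))


# ---------------------------------------------------------------------------
# proximity


def nearest_te(features: pd.DataFrame, tes: pd.DataFrame) -> pd.DataFrame:
    """Nearest TE per feature.

    Returns one row per feature: ``feature_id kind nearest_te
    distance body_overlap te_class te_order``. Distance ties are
    broken by lower TE start, then TE id. Features on chromosomes
    without TEs get distance NaN and nearest_te "".
    """
    if features.empty or tes.empty:
        raise ValueError("both feature and TE sets must be non-empty")
    rows = []
    te_by_chrom = {c: g.reset_index(drop=True) for c, g in tes.groupby("chrom", sort=False)}
    for f in features.itertuples(index=False):
        grp = te_by_chrom.get(f.chrom)
        if grp is None or grp.empty:
            rows.append((f.id, f.kind, "", np.nan, False, "", ""))
            continue
        ts = grp["start"].to_numpy()
        te = grp["end"].to_numpy()
        gaps = _interval_gap(f.start, f.end, ts, te)
        best = gaps.min()
        cand = np.flatnonzero(gaps == best)
        ids = grp["id"].to_numpy()
        pick = cand[np.lexsort((ids[cand], ts[cand]))[0]]
        overlap = bool((ts[pick] < f.end) and (f.start < te[pick]))
        rows.append((f.id, f.kind, ids[pick], float(best), overlap,
                     grp["te_class"].iat[pick], grp["te_order"].iat[pick]))
    return pd.DataFrame(rows, columns=["feature_id", "kind", "nearest_te", "distance",
                                       "body_overlap", "te_class", "te_order"])


def count_flank_tes(features: pd.DataFrame, tes: pd.DataFrame,
                    flank: int = 4000) -> pd.Series:
    """Number of TEs intersecting either flank of each feature.

    Flanks are ``[start-flank, start)`` and ``[end, end+flank)``; a TE
    intersecting both flanks counts once; TEs confined to the body
    count zero. Indexed by feature id.
    """
    counts = {}
    te_by_chrom = {c: g for c, g in tes.groupby("chrom", sort=False)}
    for f in features.itertuples(index=False):
        grp = te_by_chrom.get(f.chrom)
        if grp is None:
            counts[f.id] = 0
            continue
        ts = grp["start"].to_numpy()
        te = grp["end"].to_numpy()
        left = (ts < f.start) & (te > f.start - flank)
        right = (ts < f.end + flank) & (te > f.end)
        counts[f.id] = int((left | right).sum())
    return pd.Series(counts, name="flank_te_count")


def proximity_table(features: pd.DataFrame, tes: pd.DataFrame,
                    flank: int = 4000) -> pd.DataFrame:
    """Combined nearest-TE and flank-count table for PCGs/lncRNAs."""
    near = nearest_te(features, tes)
    near["flank_te_count"] = count_flank_tes(features, tes, flank).reindex(
        near["feature_id"]).to_numpy()
    return near


# ---------------------------------------------------------------------------
# lncRNA / TE overlap classification


def overlap_classification(features: pd.DataFrame, tes: pd.DataFrame,
                           windows: tuple[int, ...] = (0, 2000, 4000, 8000)) -> pd.DataFrame:
    """Fraction of features with >= 1 TE within each flank window.

    Window 0 is the feature body; window w counts TEs intersecting the
    feature extended by w on both sides, so fractions are monotone
    non-decreasing in w. Fractions are reported for any TE, for each
    TE class, and for each order present in the TE set.
    """
    n = len(features)
    if n == 0:
        raise ValueError("feature set is empty")
    te_by_chrom = {c: g for c, g in tes.groupby("chrom", sort=False)}
    categories = (["any", "class_I", "class_II"]
                  + [f"order_{o}" for o in sorted(tes["te_order"].unique())]
                  if not tes.empty else ["any", "class_I", "class_II"])
    rows = []
    for w in windows:
        hits = {cat: 0 for cat in categories}
        for f in features.itertuples(index=False):
            grp = te_by_chrom.get(f.chrom)
            if grp is None:
                continue
            ts = grp["start"].to_numpy()
            te = grp["end"].to_numpy()
            inter = (ts < f.end + w) & (te > f.start - w)
            if not inter.any():
                continue
            hits["any"] += 1
            cls = grp["te_class"].to_numpy()[inter]
            if (cls == "I").any():
                hits["class_I"] += 1
            if (cls == "II").any():
                hits["class_II"] += 1
            for order in np.unique(grp["te_order"].to_numpy()[inter]):
                hits[f"order_{order}"] += 1
        for cat in categories:
            rows.append((w, cat, hits[cat] / n))
    return pd.DataFrame(rows, columns=["window", "category", "fraction"])


# ---------------------------------------------------------------------------
# expression stratification


def expression_groups(mean_fpkm: pd.Series, none_threshold: float = 0.1) -> pd.Series:
    """Partition features into none/low/middle/high expression groups.

    Features with mean FPKM below ``none_threshold`` are "none"; the
    remainder are ranked by FPKM (ties broken by feature id for
    determinism) and split into three equal groups, with remainders
    assigned to the lower groups.
    """
    labels = pd.Series("none", index=mean_fpkm.index, name="group", dtype=object)
    expressed = mean_fpkm[mean_fpkm >= none_threshold]
    n = len(expressed)
    if n == 0:
        warnings.warn("all features below the expression threshold; only 'none' labels")
        return labels
    order = expressed.reset_index()
    order.columns = ["feature_id", "fpkm"]
    order = order.sort_values(["fpkm", "feature_id"], kind="mergesort")
    base, rem = divmod(n, 3)
    n_low = base + (1 if rem >= 1 else 0)
    n_mid = base + (1 if rem >= 2 else 0)
    ids = order["feature_id"].to_numpy()
    labels.loc[ids[:n_low]] = "low"
    labels.loc[ids[n_low:n_low + n_mid]] = "middle"
    labels.loc[ids[n_low + n_mid:]] = "high"
    return labels


def profile_by_group(records: pd.DataFrame, features: pd.DataFrame,
                     labels: pd.Series, context: str,
                     **profile_kwargs) -> dict[str, MethylationProfile]:
    """One metagene profile per expression group; empty groups are
    omitted with a warning."""
    out = {}
    for group in ("none", "low", "middle", "high"):
        ids = labels.index[labels == group]
        subset = features[features["id"].isin(ids)]
        if subset.empty:
            warnings.warn(f"expression group {group!r} is empty; omitted")
            continue
        out[group] = compute_profile(records, subset, context, **profile_kwargs)
    return out


# ---------------------------------------------------------------------------
# TE methylation by distance from genes


def methylation_by_distance(tes: pd.DataFrame, anchors: pd.DataFrame,
                            records: pd.DataFrame, context: str,
                            bin_size: int = 500, max_distance: int = 8000,
                            te_class: str | None = None,
                            te_order: str | None = None) -> pd.DataFrame:
    """TE-body methylation binned by distance to the nearest anchor.

    Each TE (optionally restricted by class/order) is assigned the gap
    distance to its nearest anchor feature (0 = overlapping the anchor
    body); TEs farther than ``max_distance`` are dropped. Cytosine
    counts within TE bodies are pooled per distance bin; empty bins
    have level NaN.
    """
    sel = tes
    if te_class is not None:
        sel = sel[sel["te_class"] == te_class]
    if te_order is not None:
        sel = sel[sel["te_order"] == te_order]
    if sel.empty:
        raise ValueError("no TEs after class/order filtering")
    near = nearest_te(sel, anchors)  # anchors act as the "TE" set here
    dist = near.set_index("feature_id")["distance"]

    sub = records[records["context"] == context]
    by_chrom = {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        by_chrom[chrom] = (pos[order], grp["n_meth"].to_numpy()[order],
                           grp["n_total"].to_numpy()[order])

    n_bins = max_distance // bin_size
    acc_m = np.zeros(n_bins, dtype=np.int64)
    acc_t = np.zeros(n_bins, dtype=np.int64)
    n_tes = np.zeros(n_bins, dtype=np.int64)
    for te in sel.itertuples(index=False):
        d = dist.get(te.id, np.nan)
        if not np.isfinite(d) or d >= max_distance:
            continue
        b = int(d // bin_size)
        n_tes[b] += 1
        entry = by_chrom.get(te.chrom)
        if entry is None:
            continue
        pos, nm, nt = entry
        lo = np.searchsorted(pos, te.start, side="left")
        hi = np.searchsorted(pos, te.end, side="left")
        acc_m[b] += nm[lo:hi].sum()
        acc_t[b] += nt[lo:hi].sum()

    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(acc_t > 0, acc_m / np.maximum(acc_t, 1), np.nan)
    return pd.DataFrame({
        "bin_start": np.arange(n_bins) * bin_size,
        "bin_end": (np.arange(n_bins) + 1) * bin_size,
        "n_tes": n_tes, "n_meth": acc_m, "n_total": acc_t, "level": level,
    })


# ---------------------------------------------------------------------------
# group tests


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    pvalue: float
    test: str
    degenerate: bool = False


def group_tests(values_a, values_b, test: str = "t") -> GroupTestResult:
    """Two-sided two-sample test between groups.

    ``test="t"`` is Welch's t; both groups need n >= 2, and zero
    variance in both groups flags the result degenerate.
    ``test="wilcoxon"`` is the rank-sum test: exact when the combined
    sample is small (n <= 20) and tie-free, otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "t":
        if a.size < 2 or b.size < 2:
            raise ValueError("Welch t needs n >= 2 per group")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a[0] == b[0]:
                return GroupTestResult(0.0, 1.0, "t", degenerate=True)
            return GroupTestResult(math.inf if a[0] > b[0] else -math.inf,
                                   0.0, "t", degenerate=True)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return GroupTestResult(float(t), float(p), "t")
    if test == "wilcoxon":
        if a.size < 1 or b.size < 1:
            raise ValueError("rank-sum test needs n >= 1 per group")
        pooled = np.concatenate([a, b])
        ties = len(np.unique(pooled)) < pooled.size
        method = "exact" if (pooled.size <= 20 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return GroupTestResult(float(res.statistic), float(min(res.pvalue, 1.0)), "wilcoxon")
    raise ValueError(f"unknown test {test!r}; use 't' or 'wilcoxon'")
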
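"""Sliding-window detection of differentially methylated regions.

Windows are tiled along each chromosome (200 bp, 100-bp step by
default). Within a window, cytosines of the requested context with
pooled coverage >= 4 in *both* cytotypes at shared positions are
retained; a window is tested only if it holds at least the
context-specific minimum number of such sites (allC: 20, CG: 5,
CHG: 5, CHH: 15). The test is Fisher's exact on the pooled 2x2 table
[n_meth, n_unmeth] x cytotype, with Benjamini–Hochberg correction
across all tested windows of that context. Windows passing
|Δ ratio| >= 0.25 (0.20 for allC) and q <= 0.05 are kept and
overlapping/book-ended same-direction windows merged into maximal
DMRs, with ratios recomputed over the merged interval and the minimum
q retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: (minimum shared sites per window, minimum |Δ ratio|) per context.
CONTEXT_CRITERIA = {
    "allC": (20, 0.20),
    "CG": (5, 0.25),
    "CHG": (5, 0.25),
    "CHH": (15, 0.25),
}

DMR_COLUMNS = ["chrom", "start", "end", "context", "n_sites",
               "ratio_2x", "ratio_4x", "delta", "p", "q", "direction"]


@dataclass(frozen=True)
class DMRCriteria:
    """Thresholds of the window test for one context."""

    context: str = "CG"
    min_sites: int = 5
    min_delta: float = 0.25
    max_q: float = 0.05
    min_coverage: int = 4
    window: int = 200
    step: int = 100

    @classmethod
    def for_context(cls, context: str, window: int = 200, step: int = 100,
                    max_q: float = 0.05, min_coverage: int = 4) -> "DMRCriteria":
        if context not in CONTEXT_CRITERIA:
            raise ValueError(f"unknown context {context!r}; use one of {list(CONTEXT_CRITERIA)}")
        min_sites, min_delta = CONTEXT_CRITERIA[context]
        return cls(context=context, min_sites=min_sites, min_delta=min_delta,
                   max_q=max_q, min_coverage=min_coverage, window=window, step=step)

    def __post_init__(self):
        if self.min_sites < 1 or self.min_delta <= 0 or not 0 < self.max_q < 1:
            raise ValueError("thresholds must be positive and q in (0,1)")
        if self.step > self.window or self.step < 1:
            raise ValueError("need 1 <= step <= window")


def scan_windows(chrom_lengths: dict[str, int], window: int, step: int) -> pd.DataFrame:
    """Tile half-open windows over each chromosome; the final window is
    truncated at the chromosome end."""
    if not (1 <= step <= window):
        raise ValueError("need 1 <= step <= window")
    rows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + window, length)))
            if start + window >= length:
                break
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def pool_replicates(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum counts across replicates per (chrom, pos, strand, context)."""
    cat = pd.concat(replicates, ignore_index=True)
    pooled = (cat.groupby(["chrom", "pos", "strand", "context"], sort=False, as_index=False)
                 [["n_meth", "n_total"]].sum())
    return pooled.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def _shared_sites(rec_a: pd.DataFrame, rec_b: pd.DataFrame, context: str,
                  min_coverage: int) -> pd.DataFrame:
    """Inner-join the two cytotypes on site identity, keeping sites of
    the requested context covered >= min_coverage in both groups."""
    keys = ["chrom", "pos", "strand"]
    if context != "allC":
        rec_a = rec_a[rec_a["context"] == context]
        rec_b = rec_b[rec_b["context"] == context]
    a = rec_a[rec_a["n_total"] >= min_coverage][keys + ["n_meth", "n_total"]]
    b = rec_b[rec_b["n_total"] >= min_coverage][keys + ["n_meth", "n_total"]]
    m = a.merge(b, on=keys, suffixes=("_2x", "_4x"))
    return m.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def _fisher_two_sided(m2: int, u2: int, m4: int, u4: int) -> float:
    _, p = stats.fisher_exact([[m2, u2], [m4, u4]], alternative="two-sided")
    return p


def call_dmrs(records_2x: pd.DataFrame, records_4x: pd.DataFrame,
              criteria: DMRCriteria,
              chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Call DMRs between two cytotypes (replicates already pooled).

    Returns a DataFrame of merged DMRs with per-group weighted ratios,
    delta = ratio_4x - ratio_2x, q (minimum over merged windows), and
    direction ("hyper"/"hypo", the 4x level relative to 2x).
    """
    if records_2x.empty or records_4x.empty:
        raise ValueError("both cytotypes need cytosine records")
    shared = _shared_sites(records_2x, records_4x, criteria.context, criteria.min_coverage)
    if chrom_lengths is None:
        if shared.empty:
            return pd.DataFrame(columns=DMR_COLUMNS)
        chrom_lengths = {c: int(g["pos"].max()) + 1 for c, g in shared.groupby("chrom")}

    tested = []  # (chrom, start, end, n_sites, m2, t2, m4, t4)
    per_chrom = {}
    for chrom, grp in shared.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        m2 = grp["n_meth_2x"].to_numpy()
        t2 = grp["n_total_2x"].to_numpy()
        m4 = grp["n_meth_4x"].to_numpy()
        t4 = grp["n_total_4x"].to_numpy()
        per_chrom[chrom] = (pos, m2, t2, m4, t4)
        if chrom not in chrom_lengths:
            continue
        cm2 = np.concatenate([[0], np.cumsum(m2)])
        ct2 = np.concatenate([[0], np.cumsum(t2)])
        cm4 = np.concatenate([[0], np.cumsum(m4)])
        ct4 = np.concatenate([[0], np.cumsum(t4)])
        wins = scan_windows({chrom: chrom_lengths[chrom]}, criteria.window, criteria.step)
        lo = np.searchsorted(pos, wins["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, wins["end"].to_numpy(), side="left")
        n_sites = hi - lo
        ok = np.flatnonzero(n_sites >= criteria.min_sites)
        for i in ok:
            tested.append((chrom, int(wins["start"].iat[i]), int(wins["end"].iat[i]),
                           int(n_sites[i]),
                           int(cm2[hi[i]] - cm2[lo[i]]), int(ct2[hi[i]] - ct2[lo[i]]),
                           int(cm4[hi[i]] - cm4[lo[i]]), int(ct4[hi[i]] - ct4[lo[i]])))

    if not tested:
        return pd.DataFrame(columns=DMR_COLUMNS)

    win = pd.DataFrame(tested, columns=["chrom", "start", "end", "n_sites",
                                        "m2", "t2", "m4", "t4"])
    win["ratio_2x"] = win["m2"] / win["t2"]
    win["ratio_4x"] = win["m4"] / win["t4"]
    win["delta"] = win["ratio_4x"] - win["ratio_2x"]
    pvals = np.empty(len(win))
    cache: dict[tuple, float] = {}
    for i, row in enumerate(win.itertuples(index=False)):
        key = (row.m2, row.t2 - row.m2, row.m4, row.t4 - row.m4)
        p = cache.get(key)
        if p is None:
            p = _fisher_two_sided(*key)
            cache[key] = p
        pvals[i] = p
    win["p"] = pvals
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    win["q"] = q

    sig = win[(win["q"] <= criteria.max_q)
              & (win["delta"].abs() >= criteria.min_delta)].copy()
    if sig.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    sig["direction"] = np.where(sig["delta"] > 0, "hyper", "hypo")
    return _merge_windows(sig, per_chrom, criteria)


def _merge_windows(sig: pd.DataFrame, per_chrom: dict, criteria: DMRCriteria) -> pd.DataFrame:
    """Merge overlapping/book-ended significant windows of the same
    direction; recompute ratios over the union and keep the minimum q.
    A merged region whose recomputed |delta| drops below the threshold
    is discarded (keeps the DMR contract |delta| >= min_delta)."""
    out = []
    sig = sig.sort_values(["chrom", "direction", "start"], kind="mergesort")
    for (chrom, direction), grp in sig.groupby(["chrom", "direction"], sort=False):
        cur_start = cur_end = None
        cur_q = np.inf
        cur_sites = 0
        for row in grp.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end, cur_q, cur_sites = row.start, row.end, row.q, row.n_sites
            elif row.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, row.end)
                cur_q = min(cur_q, row.q)
                cur_sites = max(cur_sites, row.n_sites)
            else:
                out.append((chrom, cur_start, cur_end, cur_q, direction))
                cur_start, cur_end, cur_q, cur_sites = row.start, row.end, row.q, row.n_sites
        if cur_start is not None:
            out.append((chrom, cur_start, cur_end, cur_q, direction))

    rows = []
    for chrom, start, end, qmin, direction in out:
        pos, m2, t2, m4, t4 = per_chrom[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        s2, s4 = t2[lo:hi].sum(), t4[lo:hi].sum()
        r2 = m2[lo:hi].sum() / s2
        r4 = m4[lo:hi].sum() / s4
        delta = r4 - r2
        if abs(delta) < criteria.min_delta:
            continue
        rows.append((chrom, start, end, criteria.context, hi - lo,
                     r2, r4, delta, np.nan, qmin,
                     "hyper" if delta > 0 else "hypo"))
    dmrs = pd.DataFrame(rows, columns=DMR_COLUMNS)
    return dmrs.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def summarize_dmrs(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Per-context counts and the hyper fraction hyper/(hyper+hypo);
    the fraction is NaN for contexts with no DMRs."""
    rows = []
    contexts = list(dict.fromkeys(dmrs["context"])) if not dmrs.empty else []
    for context in contexts:
        sub = dmrs[dmrs["context"] == context]
        n_hyper = int((sub["direction"] == "hyper").sum())
        n_hypo = int((sub["direction"] == "hypo").sum())
        total = n_hyper + n_hypo
        rows.append((context, total, n_hyper, n_hypo,
                     n_hyper / total if total else np.nan))
    return pd.DataFrame(rows, columns=["context", "n_dmrs", "n_hyper", "n_hypo",
                                       "hyper_fraction"])


def annotate_dmr_location(dmrs: pd.DataFrame, features: pd.DataFrame,
                          flank: int = 4000) -> pd.DataFrame:
    """Assign each DMR a genomic annotation and a gene-flank flag.

    Annotation is decided by base-pair majority among overlapped
    feature kinds, ties broken by precedence PCG > lncRNA > TE; no
    overlap gives "intergenic". The flank flag is set when the DMR
    midpoint lies within ``flank`` bp of a PCG or lncRNA interval
    (inside counts).
    """
    precedence = {"PCG": 0, "lncRNA": 1, "TE": 2}
    trees: dict[str, IntervalTree] = {}
    gene_iv: dict[str, list[tuple[int, int]]] = {}
    for row in features.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.kind)
        if row.kind in ("PCG", "lncRNA"):
            gene_iv.setdefault(row.chrom, []).append((row.start, row.end))

    out = dmrs.copy()
    annotations, flags = [], []
    for row in out.itertuples(index=False):
        overlap_bp: dict[str, int] = {}
        tree = trees.get(row.chrom)
        if tree is not None:
            for iv in tree.overlap(row.start, row.end):
                bp = min(iv.end, row.end) - max(iv.begin, row.start)
                overlap_bp[iv.data] = overlap_bp.get(iv.data, 0) + bp
        if overlap_bp:
            best = min(overlap_bp.items(), key=lambda kv: (-kv[1], precedence[kv[0]]))
            annotations.append(best[0])
        else:
            annotations.append("intergenic")
        mid = (row.start + row.end) // 2
        near = False
        for gs, ge in gene_iv.get(row.chrom, ()):
            if gs - flank <= mid < ge + flank:
                near = True
                break
        flags.append(near)
    out["annotation"] = annotations
    out["gene_flank"] = flags
    return out


def score_dmr_calls(dmrs: pd.DataFrame, truth_dmrs: pd.DataFrame,
                    context: str | None = None) -> dict:
    """Sensitivity and empirical FDR of DMR calls against planted truth.

    A planted DMR is recovered when at least one call of its context
    overlaps it with matching direction; a call is a false discovery
    when it overlaps no planted DMR of its context.
    """
    calls = dmrs if context is None else dmrs[dmrs["context"] == context]
    truth = truth_dmrs if context is None else truth_dmrs[truth_dmrs["context"] == context]

    def overlaps(a, b):
        return a.chrom == b.chrom and a.start < b.end and b.start < a.end

    recovered = 0
    for t in truth.itertuples(index=False):
        for c in calls.itertuples(index=False):
            if overlaps(t, c) and t.direction == c.direction:
                recovered += 1
                break
    false_calls = 0
    for c in calls.itertuples(index=False):
        if not any(overlaps(t, c) for t in truth.itertuples(index=False)):
            false_calls += 1
    n_calls = len(calls)
    return {
        "n_truth": len(truth),
        "n_calls": n_calls,
        "sensitivity": recovered / len(truth) if len(truth) else float("nan"),
        "fdr": false_calls / n_calls if n_calls else 0.0,
    }
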
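"""Metagene methylation profiles: scaled feature bodies with 2-kb flanks.

A profile is a vector of weighted methylation levels over 20 upstream
100-bp bins, a configurable number of equal-width (percentile) body
bins, and 20 downstream 100-bp bins, all ordered 5'→3' in feature
orientation. Per-bin levels pool raw counts across features
(Σ n_meth / Σ n_total per bin), matching the weighted-level definition
used everywhere else; a mean-of-feature-means alternative is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MethylationProfile:
    """Per-bin pooled counts and levels over flank-body-flank bins."""

    kind: str
    context: str
    flank: int
    flank_bin: int
    body_bins: int
    n_meth: np.ndarray
    n_total: np.ndarray
    n_features: int
    n_skipped: int = 0
    feature_level_sum: np.ndarray | None = None
    feature_level_n: np.ndarray | None = None

    @property
    def n_flank_bins(self) -> int:
        return self.flank // self.flank_bin

    @property
    def n_bins(self) -> int:
        return 2 * self.n_flank_bins + self.body_bins

    @property
    def levels(self) -> np.ndarray:
        """Pooled-count level per bin; NaN where no reads."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_total > 0, self.n_meth / np.maximum(self.n_total, 1), np.nan)

    @property
    def mean_of_means(self) -> np.ndarray:
        """Per-bin mean of per-feature levels (unweighted across features)."""
        if self.feature_level_sum is None:
            raise ValueError("profile built without per-feature means")
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.feature_level_n > 0,
                            self.feature_level_sum / np.maximum(self.feature_level_n, 1), np.nan)

    @property
    def bin_labels(self) -> list[str]:
        nf = self.n_flank_bins
        return ([f"U{i + 1:02d}" for i in range(nf)]
                + [f"B{i + 1:02d}" for i in range(self.body_bins)]
                + [f"D{i + 1:02d}" for i in range(nf)])

    def body_slice(self) -> slice:
        return slice(self.n_flank_bins, self.n_flank_bins + self.body_bins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "kind": self.kind, "context": self.context,
            "bin": np.arange(self.n_bins), "label": self.bin_labels,
            "level": self.levels, "n_meth": self.n_meth, "n_total": self.n_total,
        })


def _bin_positions(pos: np.ndarray, start: int, end: int, strand: str,
                   flank: int, flank_bin: int, body_bins: int) -> np.ndarray:
    """Map reference positions to profile bin indices for one feature.

    Positions outside [start-flank, end+flank) map to -1. Minus-strand
    features are handled by measuring every distance from the
    feature's 5' end on its own strand, so a reverse-complemented
    layout yields the exactly reversed bin assignment.
    """
    n_flank = flank // flank_bin
    length = end - start
    bins = np.full(pos.shape, -1, dtype=np.int64)

    if strand != "-":
        up = (pos >= start - flank) & (pos < start)
        body = (pos >= start) & (pos < end)
        down = (pos >= end) & (pos < end + flank)
        bins[up] = (pos[up] - (start - flank)) // flank_bin
        bins[body] = n_flank + (pos[body] - start) * body_bins // length
        bins[down] = n_flank + body_bins + (pos[down] - end) // flank_bin
    else:
        # distances measured from the 3' reference side (= 5' of the feature)
        up = (pos >= end) & (pos < end + flank)          # upstream on minus strand
        body = (pos >= start) & (pos < end)
        down = (pos >= start - flank) & (pos < start)
        bins[up] = (end + flank - 1 - pos[up]) // flank_bin
        bins[body] = n_flank + (end - 1 - pos[body]) * body_bins // length
        bins[down] = n_flank + body_bins + (start - 1 - pos[down]) // flank_bin
    return bins


def compute_profile(records: pd.DataFrame, features: pd.DataFrame, context: str,
                    flank: int = 2000, flank_bin: int = 100, body_bins: int = 20,
                    kind: str | None = None, min_coverage: int = 1,
                    track_feature_means: bool = False) -> MethylationProfile:
    """Average methylation profile of a feature set.

    Counts are pooled per bin across all features; flank bins
    truncated at chromosome edges simply receive fewer cytosines.
    Features shorter than ``body_bins`` bases are skipped (counted in
    ``n_skipped``). ``kind`` restricts (and labels) the feature subset.
    """
    feats = features if kind is None else features[features["kind"] == kind]
    label = kind if kind is not None else (
        feats["kind"].iloc[0] if len(feats) and feats["kind"].nunique() == 1 else "mixed")
    if feats.empty:
        raise ValueError("feature set is empty")

    n_flank = flank // flank_bin
    n_bins = 2 * n_flank + body_bins
    acc_m = np.zeros(n_bins, dtype=np.int64)
    acc_t = np.zeros(n_bins, dtype=np.int64)
    fm_sum = np.zeros(n_bins) if track_feature_means else None
    fm_n = np.zeros(n_bins, dtype=np.int64) if track_feature_means else None

    sub = records[(records["context"] == context) & (records["n_total"] >= min_coverage)]
    by_chrom = {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        by_chrom[chrom] = (pos[order], grp["n_meth"].to_numpy()[order],
                           grp["n_total"].to_numpy()[order])

    n_used = n_skipped = 0
    for row in feats.itertuples(index=False):
        if row.end - row.start < body_bins:
            n_skipped += 1
            continue
        n_used += 1
        entry = by_chrom.get(row.chrom)
        if entry is None:
            continue
        pos, nm, nt = entry
        lo = np.searchsorted(pos, row.start - flank, side="left")
        hi = np.searchsorted(pos, row.end + flank, side="left")
        if hi == lo:
            continue
        bins = _bin_positions(pos[lo:hi], row.start, row.end, row.strand,
                              flank, flank_bin, body_bins)
        ok = bins >= 0
        np.add.at(acc_m, bins[ok], nm[lo:hi][ok])
        np.add.at(acc_t, bins[ok], nt[lo:hi][ok])
        if track_feature_means:
            fm = np.bincount(bins[ok], weights=nm[lo:hi][ok], minlength=n_bins)
            ft = np.bincount(bins[ok], weights=nt[lo:hi][ok], minlength=n_bins)
            covered = ft > 0
            fm_sum[covered] += fm[covered] / ft[covered]
            fm_n[covered] += 1

    return MethylationProfile(
        kind=label, context=context, flank=flank, flank_bin=flank_bin,
        body_bins=body_bins, n_meth=acc_m, n_total=acc_t,
        n_features=n_used, n_skipped=n_skipped,
        feature_level_sum=fm_sum, feature_level_n=fm_n,
    )


@dataclass(frozen=True)
class ProfileComparison:
    statistic: float
    pvalue: float
    n_bins: int
    degenerate: bool = False


def compare_profiles(profile_a: MethylationProfile,
                     profile_b: MethylationProfile) -> ProfileComparison:
    """Paired two-sided t-test over per-bin levels.

    Bins undefined in either profile are dropped pairwise. Identical
    profiles give t = 0, p = 1. A constant nonzero difference has zero
    variance; the comparison is then flagged degenerate and the
    p-value reported as 0.0 (< 1e-10).
    """
    if (profile_a.n_bins != profile_b.n_bins
            or profile_a.body_bins != profile_b.body_bins):
        raise ValueError("profiles have different bin structure")
    a, b = profile_a.levels, profile_b.levels
    ok = ~(np.isnan(a) | np.isnan(b))
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"only {n} paired bins; need at least 3")
    diff = a[ok] - b[ok]
    if np.all(diff == 0.0):
        return ProfileComparison(0.0, 1.0, n)
    if np.ptp(diff) <= 1e-9 * max(1.0, float(np.abs(diff).max())):
        return ProfileComparison(np.inf if diff[0] > 0 else -np.inf, 0.0, n, degenerate=True)
    t, p = stats.ttest_rel(a[ok], b[ok])
    return ProfileComparison(float(t), float(p), n)


def write_profile_tsv(profiles: list[MethylationProfile], path) -> None:
    frames = [p.to_frame() for p in profiles]
    out = pd.concat(frames, ignore_index=True)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#kind\tcontext\tbin\tlabel\tlevel\tn_meth\tn_total\n")
        out.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")
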
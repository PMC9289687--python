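"""Context assignment, methylcytosine calling, and weighted levels.

Plant cytosine methylation occurs in three sequence contexts — CG,
CHG, and CHH (H = A, T, or C) — read 5'→3' on the strand carrying the
cytosine. A cytosine is *called* methylated when its methylated read
count is inconsistent with the bisulfite non-conversion/sequencing
error rate ε under a one-sided binomial test, with Benjamini–Hochberg
FDR control applied within each context class (the genome-wide CHH
base rate is an order of magnitude below CG, so pooling contexts would
distort the null mixture).

The *weighted methylation level* of a set of cytosines is
Σ n_meth / Σ n_total — read-weighted, not site-averaged — and is
undefined (NaN) when no reads cover the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MethylationCallParams:
    """Parameters of the methylcytosine caller.

    error_rate
        Combined bisulfite non-conversion and sequencing error rate ε.
    alpha
        FDR threshold for the Benjamini–Hochberg-adjusted binomial
        p-values.
    min_coverage
        Minimum read coverage to call a methylation status for a base;
        below it the status is left uncalled.
    """

    error_rate: float = 0.005
    alpha: float = 0.05
    min_coverage: int = 4

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_coverage < 1:
            raise ValueError(f"min_coverage must be >= 1, got {self.min_coverage}")


# ---------------------------------------------------------------------------
# context assignment


def assign_context(sequence: str, pos: int, strand: str) -> str:
    """Sequence context of the cytosine at ``pos`` on ``strand``.

    Returns "CG", "CHG", "CHH", or "undefined" when the needed
    downstream bases run past the sequence end or are N. Raises
    ``ValueError`` if the base at (pos, strand) is not a cytosine on
    that strand (a G on the forward sequence for strand "-").
    """
    seq = sequence.upper()
    n = len(seq)
    if not 0 <= pos < n:
        raise ValueError(f"position {pos} outside sequence of length {n}")
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"base at +{pos} is {seq[pos]!r}, not C")
        nxt = seq[pos + 1] if pos + 1 < n else None
        nxt2 = seq[pos + 2] if pos + 2 < n else None
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"base at -{pos} is {seq[pos]!r}, not C on reverse strand")
        # 5'->3' on the minus strand walks leftward on the forward axis
        nxt = seq[pos - 1].translate(_COMPLEMENT) if pos - 1 >= 0 else None
        nxt2 = seq[pos - 2].translate(_COMPLEMENT) if pos - 2 >= 0 else None
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")

    if nxt is None or nxt == "N":
        return "undefined"
    if nxt == "G":
        return "CG"
    if nxt2 is None or nxt2 == "N":
        return "undefined"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def genome_cytosines(sequence: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All context-callable cytosines of one chromosome, both strands.

    Returns (positions, strands, contexts) as numpy arrays ordered by
    position then strand; cytosines whose context is undefined
    (sequence edge or N in the needed bases) are excluded.
    """
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    n = arr.size
    C, G, N = ord("C"), ord("G"), ord("N")

    pos_list, strand_list, ctx_list = [], [], []

    # forward strand: context from bases pos+1, pos+2
    is_c = arr == C
    nxt = np.full(n, N, dtype=np.uint8)
    nxt[:-1] = arr[1:]
    nxt2 = np.full(n, N, dtype=np.uint8)
    nxt2[:-2] = arr[2:]
    valid1 = (nxt != N) & is_c
    cg = valid1 & (nxt == G)
    rest = valid1 & (nxt != G) & (nxt2 != N)
    chg = rest & (nxt2 == G)
    chh = rest & (nxt2 != G)
    for mask, label in ((cg, "CG"), (chg, "CHG"), (chh, "CHH")):
        p = np.flatnonzero(mask)
        pos_list.append(p)
        strand_list.append(np.zeros(p.size, dtype=np.uint8))
        ctx_list.append(np.full(p.size, {"CG": 0, "CHG": 1, "CHH": 2}[label], dtype=np.uint8))

    # reverse strand: C appears as G on forward; context from pos-1, pos-2
    is_g = arr == G
    prv = np.full(n, N, dtype=np.uint8)
    prv[1:] = arr[:-1]
    prv2 = np.full(n, N, dtype=np.uint8)
    prv2[2:] = arr[:-2]
    valid1 = (prv != N) & is_g
    cg = valid1 & (prv == C)  # complement of C is G
    rest = valid1 & (prv != C) & (prv2 != N)
    chg = rest & (prv2 == C)
    chh = rest & (prv2 != C)
    for mask, label in ((cg, "CG"), (chg, "CHG"), (chh, "CHH")):
        p = np.flatnonzero(mask)
        pos_list.append(p)
        strand_list.append(np.ones(p.size, dtype=np.uint8))
        ctx_list.append(np.full(p.size, {"CG": 0, "CHG": 1, "CHH": 2}[label], dtype=np.uint8))

    pos = np.concatenate(pos_list)
    strand_code = np.concatenate(strand_list)
    ctx_code = np.concatenate(ctx_list)
    order = np.lexsort((strand_code, pos))
    pos, strand_code, ctx_code = pos[order], strand_code[order], ctx_code[order]
    strands = np.where(strand_code == 0, "+", "-")
    contexts = np.array(["CG", "CHG", "CHH"], dtype=object)[ctx_code]
    return pos, strands, contexts


# ---------------------------------------------------------------------------
# methylcytosine calling


def call_methylated(records: pd.DataFrame, params: MethylationCallParams | None = None) -> pd.DataFrame:
    """Call the methylation status of each cytosine.

    For each record with ``n_total >= min_coverage`` a one-sided
    binomial p-value P(X >= n_meth | n_total, ε) is computed and
    Benjamini–Hochberg correction is applied across all tested
    cytosines of the same context; q <= alpha yields "yes", otherwise
    "no". Records below the coverage floor get "uncalled".

    Returns a copy with added columns ``p_meth``, ``q_meth`` (NaN for
    uncalled) and ``is_methylated`` in {"yes", "no", "uncalled"}.
    """
    if params is None:
        params = MethylationCallParams()
    out = records.copy()
    n = len(out)
    p_val = np.full(n, np.nan)
    q_val = np.full(n, np.nan)
    status = np.full(n, "uncalled", dtype=object)

    tested = out["n_total"].to_numpy() >= params.min_coverage
    if tested.any():
        nm = out.loc[tested, "n_meth"].to_numpy()
        nt = out.loc[tested, "n_total"].to_numpy()
        # P(X >= n_meth); sf(k-1) = P(X > k-1)
        p_val[tested] = stats.binom.sf(nm - 1, nt, params.error_rate)
        ctx = out["context"].to_numpy()
        for context in np.unique(ctx[tested]):
            sel = tested & (ctx == context)
            rej, q, _, _ = multipletests(p_val[sel], alpha=params.alpha, method="fdr_bh")
            q_val[sel] = q
            status[sel] = np.where(rej, "yes", "no")

    out["p_meth"] = p_val
    out["q_meth"] = q_val
    out["is_methylated"] = status
    return out


# ---------------------------------------------------------------------------
# weighted levels


def weighted_level(records: pd.DataFrame, context: str | None = None,
                   region: tuple[str, int, int] | None = None,
                   min_coverage: int = 1) -> float:
    """Weighted methylation level Σ n_meth / Σ n_total.

    Parameters
    ----------
    records
        Cytosine table.
    context
        Restrict to one context; None pools all contexts.
    region
        Optional (chrom, start, end), 0-based half-open.
    min_coverage
        Cytosines with ``n_total`` below this contribute nothing.

    Returns NaN (undefined, distinct from 0) when no reads remain.
    """
    mask = records["n_total"].to_numpy() >= min_coverage
    if context is not None:
        mask &= records["context"].to_numpy() == context
    if region is not None:
        chrom, start, end = region
        mask &= (records["chrom"].to_numpy() == chrom)
        pos = records["pos"].to_numpy()
        mask &= (pos >= start) & (pos < end)
    total = int(records["n_total"].to_numpy()[mask].sum())
    if total == 0:
        return float("nan")
    return float(records["n_meth"].to_numpy()[mask].sum()) / total


def merge_cg_strands(records: pd.DataFrame) -> pd.DataFrame:
    """Combine counts of symmetric CG pairs into one record per site.

    The forward C of a CG dinucleotide at pos p pairs with the reverse
    C at p+1; merged records keep the forward position and strand "+".
    Non-CG records and unpaired CG records pass through unchanged.
    """
    cg = records[records["context"] == "CG"]
    rest = records[records["context"] != "CG"]
    if cg.empty:
        return records.copy()
    plus = cg[cg["strand"] == "+"].copy()
    minus = cg[cg["strand"] == "-"].copy()
    minus["pair_pos"] = minus["pos"] - 1
    merged = plus.merge(
        minus[["chrom", "pair_pos", "n_meth", "n_total"]],
        left_on=["chrom", "pos"], right_on=["chrom", "pair_pos"],
        how="outer", suffixes=("", "_rev"), indicator=True,
    )
    paired = merged["_merge"] == "both"
    merged.loc[paired, "n_meth"] = merged.loc[paired, "n_meth"] + merged.loc[paired, "n_meth_rev"]
    merged.loc[paired, "n_total"] = merged.loc[paired, "n_total"] + merged.loc[paired, "n_total_rev"]
    only_minus = merged["_merge"] == "right_only"
    merged.loc[only_minus, "pos"] = merged.loc[only_minus, "pair_pos"] + 1
    merged.loc[only_minus, "strand"] = "-"
    merged.loc[only_minus, "n_meth"] = merged.loc[only_minus, "n_meth_rev"]
    merged.loc[only_minus, "n_total"] = merged.loc[only_minus, "n_total_rev"]
    merged["strand"] = merged["strand"].fillna("+")
    merged["context"] = "CG"
    out = pd.concat(
        [merged[["chrom", "pos", "strand", "context", "n_meth", "n_total"]], rest],
        ignore_index=True,
    )
    out["pos"] = out["pos"].astype(np.int64)
    out["n_meth"] = out["n_meth"].astype(np.int64)
    out["n_total"] = out["n_total"].astype(np.int64)
    return out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def estimate_error_rate(records: pd.DataFrame, control_chrom: str) -> float:
    """Estimate ε from an unmethylated control sequence (e.g. a
    chloroplast genome or spiked lambda DNA): the pooled weighted level
    of the control is the apparent non-conversion rate."""
    level = weighted_level(records, region=None, context=None) if control_chrom is None else \
        weighted_level(records[records["chrom"] == control_chrom])
    if np.isnan(level):
        raise ValueError(f"control sequence {control_chrom!r} has no covered cytosines")
    return level


# ---------------------------------------------------------------------------
# replicate QC


def window_levels(records: pd.DataFrame, chrom_lengths: dict[str, int],
                  window: int, context: str | None = None) -> pd.DataFrame:
    """Weighted level per non-overlapping window, one row per window
    (chrom, start, end, level, n_total); uncovered windows get NaN."""
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = records[records["chrom"] == chrom]
        if context is not None:
            sub = sub[sub["context"] == context]
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        nm = sub["n_meth"].to_numpy()[order]
        nt = sub["n_total"].to_numpy()[order]
        cm = np.concatenate([[0], np.cumsum(nm)])
        ct = np.concatenate([[0], np.cumsum(nt)])
        for start in range(0, length, window):
            end = min(start + window, length)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            tot = ct[hi] - ct[lo]
            lvl = (cm[hi] - cm[lo]) / tot if tot > 0 else np.nan
            rows.append((chrom, start, end, lvl, tot))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "level", "n_total"])


def replicate_correlation(replicates: list[pd.DataFrame],
                          chrom_lengths: dict[str, int],
                          window: int = 10_000,
                          context: str | None = None) -> np.ndarray:
    """Pairwise Pearson correlation of per-window weighted levels.

    Windows lacking coverage in any replicate are dropped. Raises
    ``ValueError`` with fewer than two replicates or fewer than two
    usable windows.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicates")
    levels = np.column_stack(
        [window_levels(r, chrom_lengths, window, context)["level"].to_numpy()
         for r in replicates]
    )
    usable = ~np.isnan(levels).any(axis=1)
    if usable.sum() < 2:
        raise ValueError("fewer than two windows covered in all replicates")
    return np.corrcoef(levels[usable].T)
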
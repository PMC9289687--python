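"""Sliding-window DMR detection: thresholds, oracle equivalence, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ploidymeth.dmr import (
    CONTEXT_CRITERIA,
    DMRCriteria,
    annotate_dmr_location,
    call_dmrs,
    pool_replicates,
    scan_windows,
    score_dmr_calls,
    summarize_dmrs,
)

from conftest import make_features, make_records


class TestScanWindows:
    def test_basic_tiling(self):
        w = scan_windows({"c": 500}, 200, 100)
        assert list(map(tuple, w[["start", "end"]].to_numpy())) == [
            (0, 200), (100, 300), (200, 400), (300, 500)]

    def test_short_chromosome_truncates(self):
        w = scan_windows({"c": 150}, 200, 100)
        assert list(map(tuple, w[["start", "end"]].to_numpy())) == [(0, 150)]

    def test_disjoint_tiling_covers_chromosome(self):
        w = scan_windows({"c": 1000}, 200, 200)
        assert w["start"].iloc[0] == 0 and w["end"].iloc[-1] == 1000
        assert (w["start"].to_numpy()[1:] == w["end"].to_numpy()[:-1]).all()

    def test_bad_geometry(self):
        with pytest.raises(ValueError):
            scan_windows({"c": 100}, 100, 200)


def toy_counts(rng, chrom, n_sites, spacing, p2, p4, depth=20, start=0, context="CG"):
    pos = start + np.arange(n_sites) * spacing
    nt2 = rng.poisson(depth, n_sites) + 4
    nt4 = rng.poisson(depth, n_sites) + 4
    rec2 = pd.DataFrame({"chrom": chrom, "pos": pos, "strand": "+", "context": context,
                         "n_meth": rng.binomial(nt2, p2), "n_total": nt2})
    rec4 = pd.DataFrame({"chrom": chrom, "pos": pos, "strand": "+", "context": context,
                         "n_meth": rng.binomial(nt4, p4), "n_total": nt4})
    return rec2, rec4


def brute_force_dmr_windows(rec2, rec4, criteria, chrom_lengths):
    """Exhaustive per-window re-derivation: explicit shared-site
    filtering, hypergeometric two-sided Fisher, then BH."""
    rows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            end = min(start + criteria.window, length)
            m2 = t2 = m4 = t4 = n_sites = 0
            for r in rec2[rec2["chrom"] == chrom].itertuples(index=False):
                if not (start <= r.pos < end) or r.context != criteria.context:
                    continue
                if r.n_total < criteria.min_coverage:
                    continue
                match = rec4[(rec4["chrom"] == chrom) & (rec4["pos"] == r.pos)
                             & (rec4["strand"] == r.strand)]
                if match.empty or match.iloc[0]["n_total"] < criteria.min_coverage:
                    continue
                n_sites += 1
                m2 += r.n_meth
                t2 += r.n_total
                m4 += int(match.iloc[0]["n_meth"])
                t4 += int(match.iloc[0]["n_total"])
            if n_sites >= criteria.min_sites:
                p = stats.fisher_exact([[m2, t2 - m2], [m4, t4 - m4]])[1]
                rows.append((chrom, start, end, n_sites, m2 / t2, m4 / t4, p))
            if start + criteria.window >= length:
                break
            start += criteria.step
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                     "ratio_2x", "ratio_4x", "p"])
    if not df.empty:
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["delta"] = df["ratio_4x"] - df["ratio_2x"]
    return df


class TestThresholdFidelity:
    def test_small_delta_never_emitted(self):
        """|delta| = 0.10 windows are rejected in every context even at
        overwhelming significance."""
        for context in ("CG", "CHG", "CHH"):
            n_sites = CONTEXT_CRITERIA[context][0]
            pos = np.arange(n_sites) * 5
            # deterministic counts: exactly 0.40 vs 0.50 per site, deep coverage
            rec2 = make_records([("c", p, "+", context, 400, 1000) for p in pos])
            rec4 = make_records([("c", p, "+", context, 500, 1000) for p in pos])
            dmrs = call_dmrs(rec2, rec4, DMRCriteria.for_context(context), {"c": 300})
            assert dmrs.empty, context

    def test_window_below_site_minimum_not_tested(self):
        """4 CG sites in a window: below the >= 5 rule, never evaluated."""
        rec2 = make_records([("c", p, "+", "CG", 0, 100) for p in (10, 50, 90, 130)])
        rec4 = make_records([("c", p, "+", "CG", 100, 100) for p in (10, 50, 90, 130)])
        dmrs = call_dmrs(rec2, rec4, DMRCriteria.for_context("CG"), {"c": 200})
        assert dmrs.empty

    def test_low_coverage_sites_never_contribute(self):
        """Sites with pooled coverage 3 in either group are excluded, so a
        window carried only by them is never tested."""
        pos = np.arange(10) * 15
        rec2 = make_records([("c", p, "+", "CG", 0, 3) for p in pos])
        rec4 = make_records([("c", p, "+", "CG", 30, 30) for p in pos])
        dmrs = call_dmrs(rec2, rec4, DMRCriteria.for_context("CG"), {"c": 200})
        assert dmrs.empty

    def test_strong_window_called_with_exact_fisher(self):
        """20 shared CG sites, 100/200 vs 190/200 pooled: delta 0.45,
        Fisher p astronomically small, called hyper."""
        pos = np.arange(20) * 9
        rec2 = make_records([("c", p, "+", "CG", 5, 10) for p in pos])
        meths = [10, 9] * 10  # 190 of 200
        rec4 = make_records([("c", p, "+", "CG", m, 10) for p, m in zip(pos, meths)])
        dmrs = call_dmrs(rec2, rec4, DMRCriteria.for_context("CG"), {"c": 180})
        assert len(dmrs) == 1
        d = dmrs.iloc[0]
        assert d["direction"] == "hyper"
        assert d["delta"] == pytest.approx(0.45)
        # independent hypergeometric tail for the pooled table
        p_oracle = stats.fisher_exact([[100, 100], [190, 10]])[1]
        assert p_oracle < 1e-20 and d["q"] <= p_oracle * 10


class TestOracleEquivalence:
    def test_window_statistics_match_brute_force(self):
        """Window-level (ratio, p, q) equal an exhaustive per-window
        enumeration on a ~50-window toy input."""
        rng = np.random.default_rng(12)
        chrom_lengths = {"cA": 2600, "cB": 2600}
        pieces2, pieces4 = [], []
        for chrom in chrom_lengths:
            for block in range(5):
                p2 = rng.uniform(0.1, 0.9)
                p4 = np.clip(p2 + rng.choice([-0.4, 0, 0.4]), 0.02, 0.98)
                r2, r4 = toy_counts(rng, chrom, 8, 30, p2, p4, start=block * 500)
                pieces2.append(r2)
                pieces4.append(r4)
        rec2 = pd.concat(pieces2, ignore_index=True)
        rec4 = pd.concat(pieces4, ignore_index=True)
        criteria = DMRCriteria.for_context("CG")
        oracle = brute_force_dmr_windows(rec2, rec4, criteria, chrom_lengths)
        sig = oracle[(oracle["q"] <= criteria.max_q)
                     & (oracle["delta"].abs() >= criteria.min_delta)]
        dmrs = call_dmrs(rec2, rec4, criteria, chrom_lengths)
        # every significant oracle window lies inside a called DMR with same direction
        for w in sig.itertuples(index=False):
            hit = dmrs[(dmrs["chrom"] == w.chrom) & (dmrs["start"] <= w.start)
                       & (dmrs["end"] >= w.end)]
            assert len(hit) == 1
            assert hit.iloc[0]["direction"] == ("hyper" if w.delta > 0 else "hypo")
            assert hit.iloc[0]["q"] <= w.q + 1e-12
        # and no called DMR exists without a supporting significant window
        for d in dmrs.itertuples(index=False):
            support = sig[(sig["chrom"] == d.chrom) & (sig["start"] >= d.start)
                          & (sig["end"] <= d.end)]
            assert not support.empty
            assert d.q == pytest.approx(support["q"].min())

    def test_pool_replicates_sums_counts(self):
        r1 = make_records([("c", 1, "+", "CG", 2, 5)])
        r2 = make_records([("c", 1, "+", "CG", 3, 6), ("c", 9, "-", "CHH", 0, 2)])
        pooled = pool_replicates([r1, r2])
        cg = pooled[pooled["context"] == "CG"].iloc[0]
        assert (cg["n_meth"], cg["n_total"]) == (5, 11)
        assert len(pooled) == 2


class TestMergingAndMonotonicity:
    def _sig_input(self):
        rng = np.random.default_rng(21)
        return toy_counts(rng, "c", 60, 10, 0.2, 0.7, depth=30)

    def test_merged_dmrs_never_overlap(self):
        rec2, rec4 = self._sig_input()
        dmrs = call_dmrs(rec2, rec4, DMRCriteria.for_context("CG"), {"c": 700})
        d = dmrs.sort_values("start")
        assert (d["start"].to_numpy()[1:] >= d["end"].to_numpy()[:-1]).all()

    def test_raising_min_delta_never_increases_count(self):
        rec2, rec4 = self._sig_input()
        counts = []
        for min_delta in (0.25, 0.4, 0.6, 0.9):
            crit = DMRCriteria(context="CG", min_sites=5, min_delta=min_delta)
            counts.append(len(call_dmrs(rec2, rec4, crit, {"c": 700})))
        assert counts == sorted(counts, reverse=True)

    def test_empty_cytotype_raises(self):
        rec2, _ = self._sig_input()
        with pytest.raises(ValueError, match="both cytotypes"):
            call_dmrs(rec2, rec2.iloc[:0], DMRCriteria.for_context("CG"), {"c": 700})


class TestSummarize:
    def _dmr_frame(self, directions, context="CG"):
        return pd.DataFrame({
            "chrom": "c", "start": np.arange(len(directions)) * 1000,
            "end": np.arange(len(directions)) * 1000 + 200, "context": context,
            "n_sites": 10, "ratio_2x": 0.3, "ratio_4x": 0.6, "delta": 0.3,
            "p": 1e-5, "q": 1e-4, "direction": directions})

    def test_hyper_fraction(self):
        s = summarize_dmrs(self._dmr_frame(["hyper", "hyper", "hypo", "hypo"]))
        assert s.iloc[0]["hyper_fraction"] == 0.5
        assert s.iloc[0]["n_dmrs"] == 4

    def test_empty_set(self):
        s = summarize_dmrs(pd.DataFrame(columns=["context", "direction"]))
        assert s.empty

    def test_directions_match_planted_truth(self, dmr_recovery_run):
        cfg, genome, features, planted, rec2, rec4 = dmr_recovery_run
        dmrs = call_dmrs(rec2, rec4, DMRCriteria.for_context("CG"),
                         {c: cfg.chrom_length for c in genome})
        hyper_truth = planted[planted["direction"] == "hyper"]
        for t in hyper_truth.itertuples(index=False):
            hits = dmrs[(dmrs["chrom"] == t.chrom) & (dmrs["start"] < t.end)
                        & (dmrs["end"] > t.start)]
            assert (hits["direction"] == "hyper").all()


class TestRecovery:
    def test_planted_cg_dmrs_recovered(self, dmr_recovery_run):
        """Sensitivity >= 0.9 and empirical FDR <= 0.1 at 30x depth with
        delta-0.4 planted CG DMRs."""
        cfg, genome, features, planted, rec2, rec4 = dmr_recovery_run
        dmrs = call_dmrs(rec2, rec4, DMRCriteria.for_context("CG"),
                         {c: cfg.chrom_length for c in genome})
        score = score_dmr_calls(dmrs, planted, "CG")
        assert score["sensitivity"] >= 0.9
        assert score["fdr"] <= 0.1


class TestAnnotation:
    def _features(self):
        return make_features([
            ("g1", "c", 10_000, 14_000, "+", "PCG", "", "", ""),
            ("l1", "c", 30_000, 31_000, "+", "lncRNA", "lincRNA", "", ""),
            ("t1", "c", 15_000, 18_000, ".", "TE", "", "I", "Gypsy"),
        ])

    def _dmr(self, start, end):
        return pd.DataFrame([{"chrom": "c", "start": start, "end": end,
                              "context": "CG", "n_sites": 10, "ratio_2x": 0.3,
                              "ratio_4x": 0.6, "delta": 0.3, "p": 1e-6, "q": 1e-5,
                              "direction": "hyper"}])

    def test_te_body_near_gene_flank_flag(self):
        out = annotate_dmr_location(self._dmr(15_100, 15_300), self._features())
        assert out.iloc[0]["annotation"] == "TE"
        assert bool(out.iloc[0]["gene_flank"])  # midpoint 1.2 kb from g1

    def test_intergenic_far_from_genes(self):
        out = annotate_dmr_location(self._dmr(50_000, 50_200), self._features())
        assert out.iloc[0]["annotation"] == "intergenic"
        assert not bool(out.iloc[0]["gene_flank"])

    def test_bp_majority_wins(self):
        # DMR [13700, 14200): 300 bp over g1 (PCG), 0 over TE -> PCG;
        # DMR [13900, 16400): 100 bp PCG, 1400 bp TE -> TE
        out1 = annotate_dmr_location(self._dmr(13_700, 14_200), self._features())
        out2 = annotate_dmr_location(self._dmr(13_900, 16_400), self._features())
        assert out1.iloc[0]["annotation"] == "PCG"
        assert out2.iloc[0]["annotation"] == "TE"

    def test_majority_matches_overlap_oracle_on_random_layout(self):
        rng = np.random.default_rng(33)
        feats = []
        for i in range(40):
            s = int(rng.integers(0, 95_000))
            L = int(rng.integers(200, 5000))
            kind = rng.choice(["PCG", "lncRNA", "TE"])
            feats.append((f"f{i}", "c", s, s + L, "+", kind, "",
                          "I" if kind == "TE" else "", "Gypsy" if kind == "TE" else ""))
        features = make_features(feats)
        precedence = {"PCG": 0, "lncRNA": 1, "TE": 2}
        for j in range(30):
            s = int(rng.integers(0, 99_000))
            e = s + int(rng.integers(100, 1000))
            out = annotate_dmr_location(self._dmr(s, e), features)
            bp = {}
            for f in features.itertuples(index=False):
                ov = min(e, f.end) - max(s, f.start)
                if ov > 0:
                    bp[f.kind] = bp.get(f.kind, 0) + ov
            expected = (min(bp.items(), key=lambda kv: (-kv[1], precedence[kv[0]]))[0]
                        if bp else "intergenic")
            assert out.iloc[0]["annotation"] == expected
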
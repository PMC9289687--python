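"""Synthetic WGBS methylomes with planted ground truth.

The generator emulates the statistical structure of a highly
TE-dense plant genome assayed by whole-genome bisulfite sequencing in
two cytotypes (diploid 2x and autotetraploid 4x):

* a random genome with configurable GC content and feature densities;
  TEs cover ~60% of the sequence and carry the highest methylation,
  lncRNAs are intermediate, and PCG bodies the lowest;
* per-cytosine true methylation probabilities built from stratum
  baselines (TE body by order > lncRNA region > PCG region >
  intergenic) times a metagene shape: a CG peak over PCG bodies and a
  CHG/CHH body dip, with smooth ramps at the body edges;
* a per-gene latent activity that couples expression and body
  CHG/CHH methylation (silenced genes are more heavily methylated),
  negatively for PCGs and positively for lncRNAs;
* planted DMRs — intervals where the 4x probability is offset from
  the 2x probability by a known signed delta — recorded in a truth
  table for sensitivity/FDR scoring;
* observed counts: read depth per cytosine is negative-binomial
  (uneven WGBS coverage, exercising coverage filters) and methylated
  counts are binomial with a symmetric error rate ε folding failed
  bisulfite conversion and sequencing error together;
* expression tables where log-FPKM responds to TE proximity and
  abundance with kind-specific signs: suppression for PCGs,
  activation for lncRNAs.

Default stratum levels are calibrated so the genome-wide weighted
levels land near mCG 0.67, mCHG 0.49, and mCHH 0.06. One global seed
is expanded into per-(sample, chromosome) substreams, so results do
not depend on iteration order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ploidymeth.constants import CLASS_I_ORDERS, CONTEXTS, FEATURE_COLUMNS, TE_ORDERS
from ploidymeth.methylation import genome_cytosines

_CTX_CODE = {"CG": 0, "CHG": 1, "CHH": 2}
_CYTOTYPES = ("2x", "4x")


def _default_te_order_weights() -> dict[str, float]:
    return {
        "Gypsy": 0.35, "Copia": 0.15, "LINE": 0.05, "LTR_other": 0.10,
        "SINE": 0.01, "Helitron": 0.08, "hAT": 0.05, "MITE": 0.12,
        "Stowaway": 0.04, "Harbinger": 0.02, "other": 0.03,
    }


def _default_levels() -> dict[str, dict[str, float]]:
    # baseline methylation probability per stratum and context
    return {
        "intergenic": {"CG": 0.50, "CHG": 0.42, "CHH": 0.035},
        "pcg": {"CG": 0.42, "CHG": 0.30, "CHH": 0.035},
        "lncrna": {"CG": 0.55, "CHG": 0.40, "CHH": 0.05},
    }


def _default_te_levels() -> dict[str, dict[str, float]]:
    return {
        "Gypsy": {"CG": 0.83, "CHG": 0.68, "CHH": 0.065},
        "Copia": {"CG": 0.79, "CHG": 0.62, "CHH": 0.060},
        "LINE": {"CG": 0.77, "CHG": 0.60, "CHH": 0.055},
        "LTR_other": {"CG": 0.78, "CHG": 0.62, "CHH": 0.060},
        "SINE": {"CG": 0.73, "CHG": 0.57, "CHH": 0.075},
        "Helitron": {"CG": 0.71, "CHG": 0.54, "CHH": 0.075},
        "hAT": {"CG": 0.69, "CHG": 0.52, "CHH": 0.080},
        "MITE": {"CG": 0.73, "CHG": 0.57, "CHH": 0.105},
        "Stowaway": {"CG": 0.67, "CHG": 0.52, "CHH": 0.085},
        "Harbinger": {"CG": 0.67, "CHG": 0.52, "CHH": 0.080},
        "other": {"CG": 0.70, "CHG": 0.54, "CHH": 0.065},
    }


def _default_body_amplitude() -> dict[str, dict[str, float]]:
    # multiplicative body shape relative to the stratum baseline
    return {
        "PCG": {"CG": 1.60, "CHG": 0.25, "CHH": 0.30},
        "lncRNA": {"CG": 1.15, "CHG": 1.10, "CHH": 1.20},
    }


@dataclass
class SimulationConfig:
    """All tunable parameters of the generator.

    Lengths in bp, depths in reads, probabilities in [0, 1]. Baseline
    levels and body amplitudes are per context; ``te_levels`` is keyed
    by TE order.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    gc_fraction: float = 0.36

    pcgs_per_mb: float = 55.0
    pcg_length_log_mean: float = 7.85   # lognormal of body length, ~2.6 kb median
    pcg_length_log_sd: float = 0.55
    pcg_length_min: int = 500
    pcg_length_max: int = 12_000

    lncrnas_per_mb: float = 22.0
    lncrna_length_log_mean: float = 6.8  # ~900 bp median
    lncrna_length_log_sd: float = 0.5
    lncrna_length_min: int = 300
    lncrna_length_max: int = 4_000
    lincrna_min_gene_distance: int = 2_000

    te_fraction: float = 0.60
    te_length_log_mean: float = 7.1     # ~1.2 kb median
    te_length_log_sd: float = 0.8
    te_length_min: int = 150
    te_length_max: int = 12_000
    te_gene_overlap_prob: float = 0.30
    te_order_weights: dict[str, float] = field(default_factory=_default_te_order_weights)

    levels: dict[str, dict[str, float]] = field(default_factory=_default_levels)
    te_levels: dict[str, dict[str, float]] = field(default_factory=_default_te_levels)
    body_amplitude: dict[str, dict[str, float]] = field(default_factory=_default_body_amplitude)
    gene_flank: int = 2_000
    ramp_fraction: float = 0.15
    activity_coupling: dict[str, float] = field(
        default_factory=lambda: {"PCG": -1.0, "lncRNA": 1.0})

    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    error_rate: float = 0.005
    replicates: int = 3

    # expression model (log10 FPKM)
    expr_intercept: dict[str, float] = field(
        default_factory=lambda: {"PCG": 1.1, "lncRNA": 0.4})
    expr_slope_proximity: dict[str, float] = field(
        default_factory=lambda: {"PCG": -1.5, "lncRNA": 1.5})
    expr_slope_count: dict[str, float] = field(
        default_factory=lambda: {"PCG": -0.08, "lncRNA": 0.08})
    expr_proximity_tau: float = 1_000.0
    expr_activity_scale: float = 0.8
    expr_noise_sd: float = 0.45
    expr_replicate_sd: float = 0.05
    expr_none_fraction: dict[str, float] = field(
        default_factory=lambda: {"PCG": 0.25, "lncRNA": 0.35})

    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        for name, ctx_levels in list(self.levels.items()) + list(self.te_levels.items()):
            for ctx, p in ctx_levels.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"level {name}/{ctx} = {p} outside [0, 1]")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class SimulationTruth:
    """Planted parameters needed to score recovered results.

    ``p_true[cytotype][chrom]`` holds (pos, strand, context, p) arrays
    aligned with the simulated cytosine records; ``planted_dmrs`` has
    the interval, context, 2x base probability, signed delta, and
    direction of every planted DMR; ``expression_coefs`` echoes the
    expression-model coefficients.
    """

    planted_dmrs: pd.DataFrame
    p_true: dict[str, dict[str, dict[str, np.ndarray]]] = field(default_factory=dict)
    expression_coefs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "planted_dmrs": self.planted_dmrs.to_dict(orient="records"),
            "expression_coefs": self.expression_coefs,
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=key)))


# ---------------------------------------------------------------------------
# genome and features


def _sample_lengths(rng, n, log_mean, log_sd, lo, hi):
    return np.clip(rng.lognormal(log_mean, log_sd, size=n).astype(np.int64), lo, hi)


def _place_nonoverlapping(rng, length, lengths, occupied: list[tuple[int, int]],
                          max_tries: int = 200) -> list[tuple[int, int]]:
    """Place intervals uniformly without overlapping ``occupied`` or
    each other; raises if the density cannot be met."""
    placed = []
    for L in lengths:
        ok = False
        for _ in range(max_tries):
            start = int(rng.integers(0, max(1, length - L)))
            end = start + int(L)
            if all(end <= s or e <= start for s, e in occupied):
                occupied.append((start, end))
                placed.append((start, end))
                ok = True
                break
        if not ok:
            raise ValueError(
                "could not place features at the requested density without overlap")
    return placed


def simulate_genome(config: SimulationConfig,
                    seed: int | None = None) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate a random genome and its feature annotation.

    PCG and lncRNA bodies never overlap each other; TEs are placed
    until their union covers ``te_fraction`` of each chromosome and may
    overlap gene bodies with probability ``te_gene_overlap_prob``.
    lncRNAs farther than ``lincrna_min_gene_distance`` from every PCG
    are flagged lincRNA. Reproducible: the same seed yields
    byte-identical output.
    """
    if seed is None:
        seed = config.seed
    genome: dict[str, str] = {}
    rows = []
    counters = {"PCG": 0, "lncRNA": 0, "TE": 0}
    orders = [o for o in TE_ORDERS if config.te_order_weights.get(o, 0) > 0]
    weights = np.array([config.te_order_weights[o] for o in orders], dtype=float)
    if weights.size:
        weights = weights / weights.sum()

    for ci, chrom in enumerate(config.chrom_names()):
        rng = _rng(seed, 0, ci)
        L = config.chrom_length
        gc = config.gc_fraction
        seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=L,
                         p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        genome[chrom] = seq.tobytes().decode("ascii")

        occupied: list[tuple[int, int]] = []
        n_pcg = int(round(config.pcgs_per_mb * L / 1e6))
        pcg_iv = _place_nonoverlapping(
            rng, L, _sample_lengths(rng, n_pcg, config.pcg_length_log_mean,
                                    config.pcg_length_log_sd,
                                    config.pcg_length_min, config.pcg_length_max),
            occupied)
        n_lnc = int(round(config.lncrnas_per_mb * L / 1e6))
        lnc_iv = _place_nonoverlapping(
            rng, L, _sample_lengths(rng, n_lnc, config.lncrna_length_log_mean,
                                    config.lncrna_length_log_sd,
                                    config.lncrna_length_min, config.lncrna_length_max),
            occupied)

        for start, end in pcg_iv:
            counters["PCG"] += 1
            strand = "+" if rng.random() < 0.5 else "-"
            activity = float(rng.normal())
            rows.append((f"PCG{counters['PCG']:05d}", chrom, start, end, strand,
                         "PCG", "", "", "", activity))
        pcg_sorted = sorted(pcg_iv)
        for start, end in lnc_iv:
            counters["lncRNA"] += 1
            strand = "+" if rng.random() < 0.5 else "-"
            activity = float(rng.normal())
            dist = min((max(0, max(ps - end, start - pe)) for ps, pe in pcg_sorted),
                       default=config.lincrna_min_gene_distance)
            subkind = "lincRNA" if dist >= config.lincrna_min_gene_distance else "other"
            rows.append((f"lncRNA{counters['lncRNA']:05d}", chrom, start, end, strand,
                         "lncRNA", subkind, "", "", activity))

        if config.te_fraction > 0 and weights.size:
            covered = np.zeros(L, dtype=bool)
            target = config.te_fraction * L
            attempts = 0
            max_attempts = 200_000
            while covered.sum() < target and attempts < max_attempts:
                attempts += 1
                tl = int(_sample_lengths(rng, 1, config.te_length_log_mean,
                                         config.te_length_log_sd,
                                         config.te_length_min, config.te_length_max)[0])
                start = int(rng.integers(0, max(1, L - tl)))
                end = start + tl
                hits_gene = any(start < e and s < end for s, e in pcg_iv)
                if hits_gene and rng.random() >= config.te_gene_overlap_prob:
                    continue
                order = orders[int(rng.choice(len(orders), p=weights))]
                te_class = "I" if order in CLASS_I_ORDERS and order != "other" else (
                    "II" if order != "other" else ("I" if rng.random() < 0.5 else "II"))
                covered[start:end] = True
                counters["TE"] += 1
                rows.append((f"TE{counters['TE']:06d}", chrom, start, end, ".",
                             "TE", "", te_class, order, 0.0))
            if covered.sum() < target * 0.9:
                raise ValueError("TE placement could not reach the target fraction")

    features = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS) + ["activity"])
    features = features.sort_values(["chrom", "start", "id"], kind="mergesort").reset_index(drop=True)
    return genome, features


def te_bp_fraction(features: pd.DataFrame, config: SimulationConfig) -> float:
    """Realized fraction of the genome covered by the TE union."""
    total = config.n_chroms * config.chrom_length
    covered = 0
    for chrom, grp in features[features["kind"] == "TE"].groupby("chrom"):
        mask = np.zeros(config.chrom_length, dtype=bool)
        for s, e in zip(grp["start"], grp["end"]):
            mask[s:e] = True
        covered += int(mask.sum())
    return covered / total


# ---------------------------------------------------------------------------
# planted DMRs


def plant_dmrs(genome: dict[str, str], features: pd.DataFrame,
               context: str = "CG", n: int = 20, delta: float = 0.4,
               length: int = 1000, min_sites: int = 10,
               p_base: float | None = None, direction: str = "hyper",
               seed: int = 0, avoid: pd.DataFrame | None = None) -> pd.DataFrame:
    """Choose non-overlapping intervals to plant as DMRs.

    Each interval contains at least ``min_sites`` cytosines of the
    requested context, so every planted DMR is detectable in
    principle. Inside a planted interval the true probability becomes
    ``p_base`` in 2x and ``p_base + signed delta`` in 4x for that
    context. ``p_base`` defaults to a value keeping both group means
    well inside [0, 1].
    """
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}")
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    signed = delta if direction == "hyper" else -delta
    if p_base is None:
        p_base = 0.25 if direction == "hyper" else 0.75
    if not (0 <= p_base <= 1 and 0 <= p_base + signed <= 1):
        raise ValueError("p_base and p_base + delta must stay in [0, 1]")

    site_pos = {chrom: genome_cytosines(seq) for chrom, seq in genome.items()}
    chroms = list(genome.keys())
    rng = _rng(seed, 9)
    taken: list[tuple[str, int, int]] = []
    if avoid is not None:
        taken += [(r.chrom, int(r.start), int(r.end)) for r in avoid.itertuples(index=False)]
    rows = []
    tries = 0
    while len(rows) < n and tries < 50_000:
        tries += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        L = len(genome[chrom])
        start = int(rng.integers(0, L - length))
        end = start + length
        if any(c == chrom and start < e and s < end for c, s, e in taken):
            continue
        pos, _strand, ctx = site_pos[chrom]
        in_win = (pos >= start) & (pos < end) & (ctx == context)
        if int(in_win.sum()) < min_sites:
            continue
        taken.append((chrom, start, end))
        rows.append((chrom, start, end, context, p_base, signed, direction))
    if len(rows) < n:
        raise ValueError(f"could only place {len(rows)}/{n} DMRs")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "context",
                                     "p_base", "delta", "direction"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# methylome


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _body_shape(length: int, amp: float, ramp_fraction: float) -> np.ndarray:
    """Multiplier curve over a feature body: cosine ramps 1 -> amp at
    both edges, flat amp in the middle."""
    x = (np.arange(length) + 0.5) / length
    r = max(ramp_fraction, 1e-9)
    mult = np.full(length, amp)
    left = x < r
    mult[left] = 1 + (amp - 1) * 0.5 * (1 - np.cos(np.pi * x[left] / r))
    right = x > 1 - r
    mult[right] = 1 + (amp - 1) * 0.5 * (1 - np.cos(np.pi * (1 - x[right]) / r))
    return mult


def true_probabilities(genome: dict[str, str], features: pd.DataFrame,
                       config: SimulationConfig, cytotype: str,
                       planted_dmrs: pd.DataFrame | None = None
                       ) -> dict[str, dict[str, np.ndarray]]:
    """Per-cytosine true methylation probability for one cytotype.

    Returns ``{chrom: {"pos", "strand", "context", "p"}}`` covering
    every context-callable cytosine on both strands.
    """
    if cytotype not in _CYTOTYPES:
        raise ValueError(f"cytotype must be one of {_CYTOTYPES}, got {cytotype!r}")
    orders = list(config.te_levels.keys())
    order_code = {o: 3 + i for i, o in enumerate(orders)}
    baseline = np.zeros((3 + len(orders), 3))
    for code, name in ((0, "intergenic"), (1, "pcg"), (2, "lncrna")):
        for ctx in CONTEXTS:
            baseline[code, _CTX_CODE[ctx]] = config.levels[name][ctx]
    for o in orders:
        for ctx in CONTEXTS:
            baseline[order_code[o], _CTX_CODE[ctx]] = config.te_levels[o][ctx]

    has_activity = "activity" in features.columns
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, seq in genome.items():
        L = len(seq)
        stratum = np.zeros(L, dtype=np.int16)
        shape = np.ones((3, L), dtype=np.float64)
        # per-gene silencing factor over body CHG/CHH; applies to every
        # body cytosine including TE-derived sequence, which carries
        # most of the gene-body non-CG signal
        act = np.ones(L, dtype=np.float64)
        feats = features[features["chrom"] == chrom]
        # paint in increasing precedence: lncRNA region, PCG region, TE body
        for kind, code in (("lncRNA", 2), ("PCG", 1)):
            amps = config.body_amplitude[kind]
            coupling = config.activity_coupling.get(kind, 0.0)
            for row in feats[feats["kind"] == kind].itertuples(index=False):
                lo = max(0, row.start - config.gene_flank)
                hi = min(L, row.end + config.gene_flank)
                stratum[lo:hi] = code
                shape[:, lo:hi] = 1.0
                act[lo:hi] = 1.0
                body_len = row.end - row.start
                activity = getattr(row, "activity", 0.0) if has_activity else 0.0
                act[row.start:row.end] = 0.4 + 1.2 * _sigmoid(coupling * activity)
                for ctx in CONTEXTS:
                    shape[_CTX_CODE[ctx], row.start:row.end] = _body_shape(
                        body_len, amps[ctx], config.ramp_fraction)
        for row in feats[feats["kind"] == "TE"].itertuples(index=False):
            code = order_code.get(row.te_order)
            if code is None:
                raise ValueError(f"no level configured for TE order {row.te_order!r}")
            stratum[row.start:row.end] = code
            shape[:, row.start:row.end] = 1.0  # act is kept: TEs in bodies share it

        pos, strand, context = genome_cytosines(seq)
        ctx_code = np.select([context == "CG", context == "CHG"], [0, 1], default=2)
        p = baseline[stratum[pos], ctx_code] * shape[ctx_code, pos]
        non_cg = ctx_code > 0
        p[non_cg] *= act[pos[non_cg]]
        p = np.clip(p, 0.0, 1.0)

        if planted_dmrs is not None and not planted_dmrs.empty:
            for d in planted_dmrs[planted_dmrs["chrom"] == chrom].itertuples(index=False):
                m = (pos >= d.start) & (pos < d.end) & (context == d.context)
                p[m] = d.p_base + (d.delta if cytotype == "4x" else 0.0)
        out[chrom] = {"pos": pos, "strand": strand, "context": context, "p": p}
    return out


def simulate_methylome(genome: dict[str, str], features: pd.DataFrame,
                       config: SimulationConfig, cytotype: str,
                       replicate: int = 1, seed: int | None = None,
                       planted_dmrs: pd.DataFrame | None = None,
                       p_true: dict | None = None) -> pd.DataFrame:
    """Simulate one replicate's per-cytosine bisulfite counts.

    Depth is negative-binomial (``depth_mean``, ``depth_dispersion``);
    uncovered cytosines are emitted with ``n_total = 0``. Observed
    methylated counts are Binomial(depth, p(1-ε) + (1-p)ε). The
    substream is keyed by (cytotype, replicate, chromosome), so every
    sample is independently reproducible.
    """
    if cytotype not in _CYTOTYPES:
        raise ValueError(f"cytotype must be one of {_CYTOTYPES}, got {cytotype!r}")
    if seed is None:
        seed = config.seed
    if p_true is None:
        p_true = true_probabilities(genome, features, config, cytotype, planted_dmrs)
    eps = config.error_rate
    cyto_key = _CYTOTYPES.index(cytotype)
    frames = []
    for ci, chrom in enumerate(genome.keys()):
        entry = p_true[chrom]
        rng = _rng(seed, 1, cyto_key, replicate, ci)
        n = entry["pos"].size
        k = config.depth_dispersion
        m = config.depth_mean
        depth = rng.negative_binomial(k, k / (k + m), size=n)
        p_obs = entry["p"] * (1 - eps) + (1 - entry["p"]) * eps
        n_meth = rng.binomial(depth, p_obs)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": entry["pos"], "strand": entry["strand"],
            "context": entry["context"],
            "n_meth": n_meth.astype(np.int64), "n_total": depth.astype(np.int64),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(features: pd.DataFrame, tes: pd.DataFrame | None,
                        config: SimulationConfig, seed: int | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """Simulate FPKM per (feature, cytotype, replicate).

    log10 FPKM = intercept + slope_proximity * exp(-d/tau)
    + slope_count * (TEs in 4-kb flanks) + activity_scale * activity
    + noise; the configured lowest-activity fraction per kind is set
    to FPKM 0 ("none"-expressed). PCG slopes are negative (TE
    proximity and abundance suppress), lncRNA slopes positive.
    """
    if seed is None:
        seed = config.seed
    genes = features[features["kind"].isin(["PCG", "lncRNA"])].reset_index(drop=True)
    if genes.empty:
        raise ValueError("no PCG/lncRNA features to simulate expression for")
    slopes_used = any(config.expr_slope_proximity[k] != 0 or config.expr_slope_count[k] != 0
                      for k in ("PCG", "lncRNA"))
    if (tes is None or tes.empty) and slopes_used:
        raise ValueError("TE set required when proximity/abundance slopes are nonzero")

    if tes is not None and not tes.empty:
        from ploidymeth.association import count_flank_tes, nearest_te
        near = nearest_te(genes, tes).set_index("feature_id")
        dist = near["distance"].reindex(genes["id"]).to_numpy()
        dist = np.where(np.isfinite(dist), dist, 1e9)
        counts = count_flank_tes(genes, tes, flank=4000).reindex(genes["id"]).to_numpy()
    else:
        dist = np.full(len(genes), 1e9)
        counts = np.zeros(len(genes))

    rng = _rng(seed, 2)
    activity = genes["activity"].to_numpy() if "activity" in genes.columns \
        else np.zeros(len(genes))
    kinds = genes["kind"].to_numpy()
    log10 = np.empty(len(genes))
    none_mask = np.zeros(len(genes), dtype=bool)
    for kind in ("PCG", "lncRNA"):
        sel = kinds == kind
        if not sel.any():
            continue
        log10[sel] = (config.expr_intercept[kind]
                      + config.expr_slope_proximity[kind]
                      * np.exp(-dist[sel] / config.expr_proximity_tau)
                      + config.expr_slope_count[kind] * counts[sel]
                      + config.expr_activity_scale * activity[sel]
                      + rng.normal(0, config.expr_noise_sd, size=int(sel.sum())))
        # "none"-expressed features are those with the lowest latent
        # expression, so silenced genes coincide with TE-dense,
        # low-activity ones
        n_none = int(round(config.expr_none_fraction[kind] * sel.sum()))
        if n_none > 0:
            idx = np.flatnonzero(sel)
            order = np.lexsort((genes["id"].to_numpy()[idx], log10[idx]))
            none_mask[idx[order[:n_none]]] = True

    rows = []
    for cytotype in _CYTOTYPES:
        for rep in range(1, config.replicates + 1):
            noise = rng.normal(0, config.expr_replicate_sd, size=len(genes))
            fpkm = np.where(none_mask, 0.0, 10.0 ** (log10 + noise))
            for fid, value in zip(genes["id"], fpkm):
                rows.append((fid, cytotype, rep, float(value)))
    expr = pd.DataFrame(rows, columns=["feature_id", "cytotype", "replicate", "fpkm"])
    coefs = {
        "intercept": dict(config.expr_intercept),
        "slope_proximity": dict(config.expr_slope_proximity),
        "slope_count": dict(config.expr_slope_count),
        "proximity_tau": config.expr_proximity_tau,
        "activity_scale": config.expr_activity_scale,
        "none_fraction": dict(config.expr_none_fraction),
    }
    return expr, coefs


def build_truth(genome: dict[str, str], features: pd.DataFrame,
                config: SimulationConfig,
                planted_dmrs: pd.DataFrame | None = None,
                expression_coefs: dict | None = None) -> SimulationTruth:
    """Assemble the full truth record for recovery scoring."""
    if planted_dmrs is None:
        planted_dmrs = pd.DataFrame(
            columns=["chrom", "start", "end", "context", "p_base", "delta", "direction"])
    p_true = {cyt: true_probabilities(genome, features, config, cyt, planted_dmrs)
              for cyt in _CYTOTYPES}
    return SimulationTruth(planted_dmrs=planted_dmrs, p_true=p_true,
                           expression_coefs=expression_coefs or {})
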
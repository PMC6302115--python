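"""Historical effective population size from binned LD.

The estimator inverts the drift expectation of linkage disequilibrium at
recombination distance c,

    E[r2_adj | c] = 1 / (4 f(c) N_t + alpha),

into

    N_t = (1 / (4 f(c))) * (1 / E[r2_adj | c] - alpha),      t = 1 / (2 c),

the Corbin et al. (2012) formula also used by SNeP: LD between loosely linked
loci reflects recent population size, LD between tightly linked loci reflects
ancient size.  ``alpha`` is the mutation adjustment (2 when mutation is
assumed to occur, 1 otherwise); ``f`` is a mapping function of the physical
distance expressed in Morgans (identity by default, with Haldane and
Sved-Feldman alternatives); ``r2_adj`` is r² adjusted for the finite sample of
genotyped individuals.

`HistoricalNe` is the model object (built from an LD pair table); its
``fit()`` produces :class:`HistoricalNeResults` holding the trajectory,
per-chromosome harmonic-mean summaries and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAPPING_FUNCTIONS = ("identity", "haldane", "sved_feldman")
ADJUSTMENT_SCHEMES = ("one_over_n", "one_over_2n", "none")


@dataclass(frozen=True)
class NeConfig:
    """Settings for the LD-to-Ne inversion.

    alpha : mutation adjustment in E[r²] = 1/(4Nc + alpha); 2 assumes mutation
        occurs, 1 assumes none.
    min/max_distance_bp : physical-distance window from which pairs are taken.
    bin_width_bp, n_bins : geometry of the distance bins (defaults: 30 bins of
        50 kb starting at ``min_distance_bp``; pairs beyond the binned span but
        inside ``max_distance_bp`` are counted and ignored).
    recomb_rate_cM_per_Mb : constant physical-to-genetic scaling.
    mapping_function : 'identity' (c proportional to distance), 'haldane', or
        'sved_feldman'.
    sample_size_adjustment : 'one_over_n' (r² - 1/n, the convention matching
        dosage-correlation r²), 'one_over_2n', or 'none'.
    """

    alpha: float = 2.0
    min_distance_bp: int = 0
    max_distance_bp: int = 5_000_000
    bin_width_bp: int = 50_000
    n_bins: int = 30
    recomb_rate_cM_per_Mb: float = 1.0
    mapping_function: str = "identity"
    sample_size_adjustment: str = "one_over_n"

    def __post_init__(self):
        if self.alpha not in (1, 2, 1.0, 2.0) and not (0 <= self.alpha <= 2):
            raise ValueError("alpha conventionally 1 or 2")
        if self.mapping_function not in MAPPING_FUNCTIONS:
            raise ValueError(f"mapping_function must be one of {MAPPING_FUNCTIONS}")
        if self.sample_size_adjustment not in ADJUSTMENT_SCHEMES:
            raise ValueError(f"sample_size_adjustment must be one of {ADJUSTMENT_SCHEMES}")
        if self.bin_width_bp <= 0 or self.n_bins <= 0:
            raise ValueError("bin geometry must be positive")
        if self.min_distance_bp < 0 or self.max_distance_bp <= self.min_distance_bp:
            raise ValueError("distance range must be non-negative and non-empty")


def physical_to_c(distance_bp, recomb_rate_cM_per_Mb: float = 1.0,
                  mapping_function: str = "identity"):
    """Convert physical distance to recombination fraction (Morgans).

    ``d = distance_bp * rate * 1e-8`` Morgans, then the mapping function:
    identity c = d; Haldane c = (1 - exp(-2d))/2; Sved-Feldman c = d/(1+2d).
    """
    d = np.asarray(distance_bp, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    d = d * recomb_rate_cM_per_Mb * 1e-8
    if mapping_function == "identity":
        c = d
    elif mapping_function == "haldane":
        c = (1.0 - np.exp(-2.0 * d)) / 2.0
    elif mapping_function == "sved_feldman":
        c = d / (1.0 + 2.0 * d)
    else:
        raise ValueError(f"unknown mapping function {mapping_function!r}")
    return c if c.ndim else float(c)


class AdjustedR2(NamedTuple):
    value: float
    floored: bool


def adjust_r2(r2: float, n_used: int, scheme: str = "one_over_n") -> AdjustedR2:
    """Sample-size adjustment of an r² value, floored at zero with a flag."""
    if scheme == "one_over_n":
        v = r2 - 1.0 / n_used
    elif scheme == "one_over_2n":
        v = r2 - 1.0 / (2.0 * n_used)
    elif scheme == "none":
        v = r2
    else:
        raise ValueError(f"unknown adjustment scheme {scheme!r}")
    if v < 0:
        return AdjustedR2(0.0, True)
    return AdjustedR2(float(v), False)


def harmonic_mean_ne(values) -> float:
    """Harmonic mean k / sum(1/Ne_i); the natural average for Ne over time."""
    v = np.asarray(list(values), dtype=np.float64)
    if v.size == 0:
        raise ValueError("harmonic mean of empty list")
    if np.any(v <= 0) or np.any(~np.isfinite(v)):
        raise ValueError("harmonic mean requires positive finite values")
    return float(v.size / np.sum(1.0 / v))


def _trajectory_from_pairs(pairs: pd.DataFrame, config: NeConfig) -> pd.DataFrame:
    """Per-bin Ne estimates from an LD pair table (chromosome-agnostic)."""
    dist = pairs["distance_bp"].to_numpy(dtype=np.float64)
    r2 = pairs["r2"].to_numpy(dtype=np.float64)
    n_used = pairs["n_used"].to_numpy(dtype=np.float64)

    span_end = config.min_distance_bp + config.n_bins * config.bin_width_bp
    inrange = (dist > config.min_distance_bp) & (dist <= config.max_distance_bp)
    n_beyond = int(np.sum(inrange & (dist > span_end)))
    if n_beyond:
        logger.info("estimate_ne_trajectory: %d pair(s) beyond the binned span "
                    "(%d bp) ignored", n_beyond, span_end)
    use = inrange & (dist <= span_end)
    if not use.any():
        raise ValueError("no pairs inside the binned distance range")
    dist, r2, n_used = dist[use], r2[use], n_used[use]

    if config.sample_size_adjustment == "one_over_n":
        adj = r2 - 1.0 / n_used
    elif config.sample_size_adjustment == "one_over_2n":
        adj = r2 - 1.0 / (2.0 * n_used)
    else:
        adj = r2.copy()
    floored = adj < 0
    adj[floored] = 0.0

    idx = np.minimum(((dist - config.min_distance_bp - 1) // config.bin_width_bp),
                     config.n_bins - 1).astype(np.int64)
    counts = np.bincount(idx, minlength=config.n_bins)
    mean_adj = np.full(config.n_bins, np.nan)
    mean_d = np.full(config.n_bins, np.nan)
    nz = counts > 0
    mean_adj[nz] = np.bincount(idx, weights=adj, minlength=config.n_bins)[nz] / counts[nz]
    mean_d[nz] = np.bincount(idx, weights=dist, minlength=config.n_bins)[nz] / counts[nz]

    c = np.full(config.n_bins, np.nan)
    c[nz] = physical_to_c(mean_d[nz], config.recomb_rate_cM_per_Mb,
                          config.mapping_function)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = 1.0 / (2.0 * c)
        inv = 1.0 / mean_adj
        ne = (1.0 / (4.0 * c)) * (inv - config.alpha)
    well_posed = nz & (mean_adj > 0) & (inv > config.alpha) & (c > 0)
    ne[~well_posed] = np.nan

    out = pd.DataFrame({
        "bin": np.arange(config.n_bins),
        "mean_distance_bp": mean_d,
        "c": c,
        "generations_ago": t,
        "mean_r2_adj": mean_adj,
        "n_pairs": counts,
        "ne": ne,
        "well_posed": well_posed,
    })
    return out[counts > 0].reset_index(drop=True)


def estimate_ne_trajectory(pairs: pd.DataFrame, config: NeConfig = NeConfig()) -> pd.DataFrame:
    """Historical Ne trajectory from an LD pair table.

    One row per non-empty distance bin: mean adjusted r², mean distance, the
    corresponding recombination fraction c, generations ago t = 1/(2c), and
    N_t = (1/(4 f(c))) (1/E[r²_adj] - alpha).  Bins whose mean adjusted r² is
    too large for the formula (1/E <= alpha) are flagged ``well_posed=False``
    with NaN Ne rather than dropped.
    """
    if len(pairs) == 0:
        raise ValueError("empty LD pair table")
    return _trajectory_from_pairs(pairs, config)


@dataclass
class HistoricalNeResults:
    """Fitted historical-Ne trajectory.

    Attributes
    ----------
    trajectory : DataFrame
        Genome-wide per-bin estimates (see :func:`estimate_ne_trajectory`).
    by_chromosome : DataFrame or None
        Harmonic-mean Ne per chromosome with the realised t-range.
    config : NeConfig
    """

    trajectory: pd.DataFrame
    config: NeConfig
    by_chromosome: pd.DataFrame | None = None

    def harmonic_mean(self, t_max: float | None = None) -> float:
        """Harmonic-mean Ne over well-posed bins, optionally restricted to
        bins informative about the last ``t_max`` generations."""
        t = self.trajectory
        sel = t[t["well_posed"]]
        if t_max is not None:
            sel = sel[sel["generations_ago"] <= t_max]
        return harmonic_mean_ne(sel["ne"])

    def summary(self) -> str:
        lines = ["Historical Ne (LD inversion)",
                 f"  alpha={self.config.alpha}, mapping={self.config.mapping_function}, "
                 f"adjustment={self.config.sample_size_adjustment}",
                 f"  bins: {self.config.n_bins} x {self.config.bin_width_bp} bp, "
                 f"pairs to {self.config.max_distance_bp} bp",
                 f"  {'t (gen ago)':>12} {'Ne':>10} {'E[r2_adj]':>10} {'pairs':>8}"]
        for _, row in self.trajectory.iterrows():
            ne = f"{row['ne']:.6g}" if row["well_posed"] else "ill-posed"
            lines.append(f"  {row['generations_ago']:>12.6g} {ne:>10} "
                         f"{row['mean_r2_adj']:>10.6g} {int(row['n_pairs']):>8}")
        try:
            lines.append(f"  harmonic-mean Ne (all bins): {self.harmonic_mean():.6g}")
        except ValueError:
            lines.append("  harmonic-mean Ne: undefined (no well-posed bin)")
        return "\n".join(lines)


class HistoricalNe:
    """Historical-Ne model over an LD pair table.

    Parameters
    ----------
    pairs : DataFrame
        Output of :func:`ldpopsize.ld.pairwise_ld` (needs ``distance_bp``,
        ``r2``, ``n_used``; ``chromosome`` enables per-chromosome summaries).
    config : NeConfig
    """

    def __init__(self, pairs: pd.DataFrame, config: NeConfig = NeConfig()):
        if len(pairs) == 0:
            raise ValueError("empty LD pair table")
        self.pairs = pairs
        self.config = config

    def fit(self) -> HistoricalNeResults:
        traj = estimate_ne_trajectory(self.pairs, self.config)
        by_chrom = None
        if "chromosome" in self.pairs.columns:
            rows = []
            for chrom, sub in self.pairs.groupby("chromosome", sort=False):
                try:
                    ct = estimate_ne_trajectory(sub, self.config)
                except ValueError:
                    continue
                ok = ct[ct["well_posed"]]
                if len(ok) == 0:
                    continue
                rows.append({
                    "chromosome": chrom,
                    "ne_harmonic": harmonic_mean_ne(ok["ne"]),
                    "t_min": float(ok["generations_ago"].min()),
                    "t_max": float(ok["generations_ago"].max()),
                    "n_bins": len(ok),
                })
            if rows:
                by_chrom = pd.DataFrame(rows)
        return HistoricalNeResults(trajectory=traj, config=self.config,
                                   by_chromosome=by_chrom)
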
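"""Contemporary effective population size by the LD method, plus relatedness.

The single-point LD method (Hill 1981; Waples 2006; Waples & Do 2008, as
implemented in NeEstimator v2) measures the mean squared dosage correlation r²
across marker pairs, subtracts the expected contribution of the finite sample
of S individuals using Waples' empirically calibrated expectations, and
inverts the remaining drift component through a mating-model-specific
quadratic:

    random mating:   E[r²_drift] = 1/(3Ne) - 0.69/Ne²   (S >= 30 branch)
    monogamy:        E[r²_drift] = 2/(3Ne) - 1.80/Ne²

Alleles rarer than the screening threshold ``pcrit`` are excluded before pair
formation.  Unlike the within-chromosome LD-decay machinery, pairs spanning
different chromosomes ARE included here (as in the reference tool); a minimum
same-chromosome pair distance can additionally be imposed.

Also provided: a method-of-moments genome-wide IBD-sharing relatedness
estimate per sample pair (the PLINK PI_HAT convention,
PI_HAT = P(IBD=2) + P(IBD=1)/2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel
from .qc import _maf_array

logger = logging.getLogger(__name__)

#: Waples (2006) / NeEstimator v2 bias-correction and inversion constants.
#: For each (mating model, sample-size branch): the expected sample-induced r²
#: E(r²|S) as polynomial coefficients in 1/S, and the quadratic inversion
#: Ne = (b + sqrt(b² - 4a r²')) / (2 r²') written via (b, a).
WAPLES_CONSTANTS = {
    # E(r²|S) = c0 + c1/S + c2/S²
    ("random", "large"): {"bias": (0.0, 1.0, 3.19), "b": 1.0 / 3.0, "a": 0.69},
    ("random", "small"): {"bias": (0.0018, 0.907, 4.44), "b": 0.308, "a": 0.52},
    ("monogamy", "large"): {"bias": (0.0, 1.0, 3.19), "b": 2.0 / 3.0, "a": 1.80},
    ("monogamy", "small"): {"bias": (0.0018, 0.907, 4.44), "b": 0.618, "a": 1.31},
}


@dataclass(frozen=True)
class LDNeConfig:
    """Settings for the LD-based contemporary Ne estimate.

    pcrit : exclude markers whose minor allele frequency (within the analysed
        sample) is below this screening value.
    mating_model : 'random' or 'monogamy' (lifetime monogamy roughly doubles
        the drift LD for a given Ne).
    min_pair_distance : same-chromosome pairs closer than this many bp are
        dropped (0 keeps all); cross-chromosome pairs are always kept.
    """

    pcrit: float = 0.05
    mating_model: str = "monogamy"
    min_pair_distance: int = 0

    def __post_init__(self):
        if not (0.0 <= self.pcrit < 0.5):
            raise ValueError("pcrit must be in [0, 0.5)")
        if self.mating_model not in ("random", "monogamy"):
            raise ValueError("mating_model must be 'random' or 'monogamy'")


def expected_sample_r2(S: float, mating_model: str = "random") -> float:
    """Waples' expected r² among unlinked loci from sampling S individuals."""
    branch = "large" if S >= 30 else "small"
    c0, c1, c2 = WAPLES_CONSTANTS[(mating_model, branch)]["bias"]
    return c0 + c1 / S + c2 / (S * S)


def invert_r2_drift(r2_drift: float, S: float, mating_model: str = "random") -> float:
    """Solve the Waples quadratic for Ne given the drift component of r².

    Returns ``inf`` when ``r2_drift <= 0`` (no detectable drift signal).
    """
    if r2_drift <= 0:
        return math.inf
    branch = "large" if S >= 30 else "small"
    k = WAPLES_CONSTANTS[(mating_model, branch)]
    disc = k["b"] ** 2 - 4.0 * k["a"] * r2_drift
    if disc < 0:
        disc = 0.0     # r² beyond the parabola's vertex: smallest expressible Ne
    ne = (k["b"] + math.sqrt(disc)) / (2.0 * r2_drift)
    return float(ne)


def _mean_pairwise_r2(panel: GenotypePanel, config: LDNeConfig,
                      chunk: int = 512):
    """Mean Burrows-composite r̂² over all retained marker pairs.

    The composite disequilibrium Δ̂ (Burrows), bias-corrected by S/(S-1), is
    squared and divided by Weir's denominators (p(1-p) + D_hw) at each locus
    — the estimator the Waples (2006) bias expectations were calibrated for;
    a plain Pearson dosage correlation has a different (smaller) sampling
    expectation and would make the published constants overcorrect.  Missing
    data are handled pairwise-complete via masked matrix products, chunked
    over the left marker block.  Returns (mean_r2, harmonic-mean S, n_pairs).
    """
    maf = _maf_array(panel)
    keep = np.nan_to_num(maf, nan=0.0) >= config.pcrit
    if keep.sum() < 2:
        raise ValueError("fewer than two markers pass the pcrit screen")
    sub = panel.subset_markers(np.nonzero(keep)[0])
    d = sub.dosages_float()
    mm = sub.markers
    m = d.shape[1]
    mask = ~np.isnan(d)
    x0 = np.where(mask, d, 0.0)
    hom = np.where(mask, (d == 2.0).astype(np.float64), 0.0)
    maskf = mask.astype(np.float64)

    chrom = np.asarray([str(c) for c in mm.chromosome], dtype=object)
    pos = mm.position_bp.astype(np.int64)

    tot_r2 = 0.0
    tot_inv_n = 0.0
    n_pairs = 0
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        n = maskf[:, lo:hi].T @ maskf              # pairwise-complete S
        sx = x0[:, lo:hi].T @ maskf                # sum of left dosages
        sy = maskf[:, lo:hi].T @ x0
        hx = hom[:, lo:hi].T @ maskf               # left hom-alt counts
        hy = maskf[:, lo:hi].T @ hom
        sxy = x0[:, lo:hi].T @ x0
        with np.errstate(invalid="ignore", divide="ignore"):
            pa = sx / (2.0 * n)
            pb = sy / (2.0 * n)
            # Burrows composite with the S/(S-1) bias factor
            delta = (n / (n - 1.0)) * (sxy / (2.0 * n) - 2.0 * pa * pb)
            da = hx / n - pa * pa                  # within-locus HW disequilibria
            db = hy / n - pb * pb
            denom = (pa * (1 - pa) + da) * (pb * (1 - pb) + db)
            r2 = (delta * delta) / denom
        # upper-triangle pairs only (j > global i)
        jj = np.arange(m)[None, :]
        ii = np.arange(lo, hi)[:, None]
        sel = (jj > ii) & (n >= 2) & (denom > 0) & np.isfinite(r2)
        if config.min_pair_distance > 0:
            same = chrom[lo:hi, None] == chrom[None, :]
            near = np.abs(pos[lo:hi, None] - pos[None, :]) < config.min_pair_distance
            sel &= ~(same & near)
        tot_r2 += float(r2[sel].sum())
        tot_inv_n += float((1.0 / n[sel]).sum())
        n_pairs += int(sel.sum())
    if n_pairs == 0:
        raise ValueError("no marker pairs after screening")
    return tot_r2 / n_pairs, n_pairs / tot_inv_n, n_pairs


@dataclass
class ContemporaryNeResults:
    """Point estimate of contemporary Ne with its ingredients."""

    ne: float
    mean_r2: float
    expected_sample_r2: float
    r2_drift: float
    harmonic_S: float
    n_pairs: int
    n_markers_used: int
    config: LDNeConfig

    def summary(self) -> str:
        ne = "infinite" if math.isinf(self.ne) else f"{self.ne:.6g}"
        return "\n".join([
            "Contemporary Ne (LD method)",
            f"  mating model: {self.config.mating_model}, pcrit: {self.config.pcrit}",
            f"  markers used: {self.n_markers_used}, pairs: {self.n_pairs}",
            f"  mean r2: {self.mean_r2:.6g}  E[r2|S]: {self.expected_sample_r2:.6g}"
            f"  drift r2: {self.r2_drift:.6g}",
            f"  harmonic mean S: {self.harmonic_S:.6g}",
            f"  Ne estimate: {ne}",
        ])


class ContemporaryNe:
    """LD-method contemporary-Ne model over one genotype panel."""

    def __init__(self, panel: GenotypePanel, config: LDNeConfig = LDNeConfig()):
        self.panel = panel
        self.config = config

    def fit(self) -> ContemporaryNeResults:
        maf = _maf_array(self.panel)
        n_used_markers = int(np.sum(np.nan_to_num(maf, nan=0.0) >= self.config.pcrit))
        mean_r2, S, n_pairs = _mean_pairwise_r2(self.panel, self.config)
        exp_r2 = expected_sample_r2(S, self.config.mating_model)
        r2_drift = mean_r2 - exp_r2
        ne = invert_r2_drift(r2_drift, S, self.config.mating_model)
        return ContemporaryNeResults(
            ne=ne, mean_r2=mean_r2, expected_sample_r2=exp_r2,
            r2_drift=r2_drift, harmonic_S=S, n_pairs=n_pairs,
            n_markers_used=n_used_markers, config=self.config,
        )


def ld_ne_point_estimate(panel: GenotypePanel, config: LDNeConfig = LDNeConfig()) -> float:
    """Contemporary Ne point estimate (positive real, or inf when the mean r²
    does not exceed the sampling expectation)."""
    return ContemporaryNe(panel, config).fit().ne


# ---------------------------------------------------------------------------
# Method-of-moments relatedness (PI_HAT)
# ---------------------------------------------------------------------------

def _unbiased_moments(x: np.ndarray, a: np.ndarray):
    """Unbiased estimators of allele-frequency products from allele counts.

    ``x`` alt-allele count, ``a`` total allele count per marker.  Returns the
    minimum-variance unbiased estimates of (p²q², p³q, pq³, p³, q³, p²q, pq²)
    via factorial moments, e.g. E[x(x-1)(a-x)(a-x-1)] = a(a-1)(a-2)(a-3) p²q².
    Plugging raw sample frequencies into these 3rd/4th-order products biases
    the IBS expectations (and hence PI_HAT) upward, badly so for rare alleles.
    """
    y = a - x
    d2 = a * (a - 1)
    d3 = d2 * (a - 2)
    d4 = d3 * (a - 3)
    p2q2 = x * (x - 1) * y * (y - 1) / d4
    p3q = x * (x - 1) * (x - 2) * y / d4
    pq3 = x * y * (y - 1) * (y - 2) / d4
    p3 = x * (x - 1) * (x - 2) / d3
    q3 = y * (y - 1) * (y - 2) / d3
    p2q = x * (x - 1) * y / d3
    pq2 = x * y * (y - 1) / d3
    return p2q2, p3q, pq3, p3, q3, p2q, pq2


def estimate_pairwise_relatedness(panel: GenotypePanel) -> np.ndarray:
    """Pairwise PI_HAT relatedness matrix (method of moments on IBS counts).

    For each sample pair the observed identical-by-state counts (IBS 0/1/2 over
    jointly called markers) are compared with their expectations under IBD
    state 0/1/2 given sample allele frequencies (unbiased factorial-moment
    estimates, the package's equivalent of PLINK's finite-sample correction
    factors), yielding moment estimates of P(IBD=k);
    PI_HAT = P(IBD=2) + P(IBD=1)/2, clipped to [0, 1].  Diagonal is 1.
    Monomorphic markers are ignored.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least two samples")
    maf = _maf_array(panel)
    poly = np.nan_to_num(maf, nan=0.0) > 0
    if poly.sum() < 100:
        logger.warning("estimate_pairwise_relatedness: only %d informative "
                       "markers; estimates may be unstable", int(poly.sum()))
    sub = panel.subset_markers(np.nonzero(poly)[0])
    d = sub.dosages_float()
    n, m = d.shape
    mask = ~np.isnan(d)
    a_tot = 2.0 * mask.sum(axis=0)
    x_alt = np.nansum(d, axis=0)
    usable = a_tot >= 4
    d, mask = d[:, usable], mask[:, usable]
    p2q2, p3q, pq3, p3, q3, p2q, pq2 = _unbiased_moments(x_alt[usable], a_tot[usable])

    # per-marker expected IBS probabilities given IBD state
    e_ibs0_ibd0 = 2 * p2q2
    e_ibs1_ibd0 = 4 * p3q + 4 * pq3
    e_ibs2_ibd0 = 1.0 - e_ibs0_ibd0 - e_ibs1_ibd0
    e_ibs1_ibd1 = 2 * p2q + 2 * pq2
    e_ibs2_ibd1 = 1.0 - e_ibs1_ibd1

    pihat = np.eye(n)
    g = np.where(mask, d, np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            ok = mask[i] & mask[j]
            if ok.sum() == 0:
                pihat[i, j] = pihat[j, i] = np.nan
                continue
            diff = np.abs(g[i, ok] - g[j, ok])
            ibs0 = float(np.sum(diff == 2))
            ibs2 = float(np.sum(diff == 0))
            ibs1 = float(ok.sum()) - ibs0 - ibs2
            E0_0, E1_0, E2_0 = (e_ibs0_ibd0[ok].sum(), e_ibs1_ibd0[ok].sum(),
                                e_ibs2_ibd0[ok].sum())
            E1_1, E2_1 = e_ibs1_ibd1[ok].sum(), e_ibs2_ibd1[ok].sum()
            N = float(ok.sum())
            p0 = ibs0 / E0_0 if E0_0 > 0 else 0.0
            p1 = (ibs1 - p0 * E1_0) / E1_1 if E1_1 > 0 else 0.0
            p2 = (ibs2 - p0 * E2_0 - p1 * E2_1) / N
            # clip to the probability simplex
            p0, p1, p2 = (max(p0, 0.0), max(p1, 0.0), max(p2, 0.0))
            s = p0 + p1 + p2
            if s > 0:
                p0, p1, p2 = p0 / s, p1 / s, p2 / s
            val = min(max(p2 + 0.5 * p1, 0.0), 1.0)
            pihat[i, j] = pihat[j, i] = val
    return pihat


def mean_relatedness(panel: GenotypePanel):
    """Population mean and sd of off-diagonal PI_HAT values."""
    r = estimate_pairwise_relatedness(panel)
    iu = np.triu_indices(r.shape[0], k=1)
    vals = r[iu]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
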
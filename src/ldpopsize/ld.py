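"""Pairwise linkage disequilibrium and LD-decay summaries.

Two r-squared estimators are provided:

* ``genotypic`` — squared Pearson correlation of 0/1/2 dosage vectors over
  pairwise-complete individuals (the PLINK ``--r2`` default);
* ``em`` — the haplotypic r² = D² / (pA pa pB pb) of Hill & Robertson, with
  haplotype frequencies recovered from unphased genotypes by EM over the
  double-heterozygote ambiguity.

Pairs are formed within chromosomes up to a maximum physical distance, then
summarised as adjacent-marker means, 100-kb binned decay curves, and the
distance at which mean r² first decays through a threshold (0.2 by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel, MarkerMap

logger = logging.getLogger(__name__)

_EM_TOL = 1e-10
_EM_MAX_ITER = 1000


# ---------------------------------------------------------------------------
# Single-pair estimators
# ---------------------------------------------------------------------------

def r2_genotypic(dosages_i, dosages_j) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Uses pairwise-complete observations; raises if fewer than two remain or if
    either column is monomorphic among them (r² undefined).
    """
    x = np.asarray(dosages_i, dtype=np.float64)
    y = np.asarray(dosages_j, dtype=np.float64)
    ok = (np.asarray(dosages_i) != MISSING) & (np.asarray(dosages_j) != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ValueError("need >= 2 pairwise-complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("r2 undefined: monomorphic column among complete pairs")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _em_loglik(c: np.ndarray, f: np.ndarray) -> float:
    """Log-likelihood of a 3x3 genotype-pair table given haplotype freqs."""
    fAB, fAb, faB, fab = np.maximum(f, 1e-300)
    cell = np.array([
        [fab * fab, 2 * faB * fab, faB * faB],
        [2 * fAb * fab, 2 * (fAB * fab + fAb * faB), 2 * fAB * faB],
        [fAb * fAb, 2 * fAB * fAb, fAB * fAB],
    ])
    with np.errstate(divide="ignore"):
        ll = np.where(c > 0, c * np.log(np.maximum(cell, 1e-300)), 0.0)
    return float(ll.sum())


def _haplotype_em(counts3x3: np.ndarray):
    """EM haplotype-frequency estimate from a 3x3 genotype-pair count table.

    ``counts3x3[gi, gj]`` counts individuals with dosage gi at locus A and gj
    at locus B.  Returns (pAB, pAb, paB, pab, converged) where allele 'A'/'B'
    denote the dosage-counted allele at each locus.  Only the double
    heterozygote is phase-ambiguous; all other cells contribute fixed
    haplotype counts.  EM is run from three starting resolutions of the
    double heterozygotes (balanced, cis-heavy, trans-heavy) and the highest
    log-likelihood solution is kept — the balanced start alone can sit on a
    symmetric saddle point when the unambiguous counts are balanced.
    """
    c = np.asarray(counts3x3, dtype=np.float64)
    n = c.sum()
    # fixed haplotype contributions (counts of each haplotype from unambiguous cells)
    # locus dosage g contributes g copies of the counted allele over 2 slots.
    nAB = 2 * c[2, 2] + c[2, 1] + c[1, 2]
    nAb = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    naB = 2 * c[0, 2] + c[0, 1] + c[1, 2]
    nab = 2 * c[0, 0] + c[0, 1] + c[1, 0]
    ndh = c[1, 1]                      # double heterozygotes: AB/ab or Ab/aB
    total = 2.0 * n
    fixed = np.array([nAB, nAb, naB, nab], dtype=np.float64)
    if ndh == 0:
        return (*(fixed / total), True)

    best_f, best_ll, best_conv = None, -np.inf, False
    for w0 in (0.5, 0.95, 0.05):
        f = (fixed + ndh * np.array([w0, 1 - w0, 1 - w0, w0])) / total
        converged = False
        for _ in range(_EM_MAX_ITER):
            cis = f[0] * f[3]          # AB * ab
            trans = f[1] * f[2]        # Ab * aB
            denom = cis + trans
            w = 0.5 if denom <= 0 else cis / denom
            new = (fixed + ndh * np.array([w, 1 - w, 1 - w, w])) / total
            if np.max(np.abs(new - f)) < _EM_TOL:
                f = new
                converged = True
                break
            f = new
        ll = _em_loglik(c, f)
        if ll > best_ll + 1e-12 or best_f is None:
            best_f, best_ll, best_conv = f, ll, converged
    return (*best_f, best_conv)


def r2_em(dosages_i, dosages_j) -> float:
    """Hill-Robertson haplotypic r² from unphased dosages via EM.

    r² = D² / (pA pa pB pb) with D = pAB - pA pB, haplotype frequencies
    estimated by EM (tolerance 1e-10, max 1000 iterations; non-convergence is
    logged and the last iterate used).
    """
    gi = np.asarray(dosages_i)
    gj = np.asarray(dosages_j)
    ok = (gi != MISSING) & (gj != MISSING)
    gi, gj = gi[ok], gj[ok]
    if gi.size < 2:
        raise ValueError("need >= 2 pairwise-complete observations")
    counts = np.zeros((3, 3))
    for a, b in zip(gi, gj):
        counts[a, b] += 1
    pAB, pAb, paB, pab, conv = _haplotype_em(counts)
    if not conv:
        logger.warning("r2_em: EM did not converge; using last iterate")
    pA, pB = pAB + pAb, pAB + paB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        raise ValueError("r2 undefined: monomorphic column among complete pairs")
    D = pAB - pA * pB
    return float(min(D * D / denom, 1.0))


# ---------------------------------------------------------------------------
# All-pairs computation
# ---------------------------------------------------------------------------

def _pairwise_complete_r2(d: np.ndarray, left: np.ndarray, right_lo: np.ndarray,
                          right_hi: np.ndarray):
    """Vectorised pairwise-complete squared correlation for banded pairs.

    ``d`` is the (n x m) float dosage matrix with NaN for missing.  For each
    left index ``i`` pairs are formed with columns ``right_lo[i]..right_hi[i]-1``.
    Closed-form Pearson moments via masked matrix products make the result
    independent of chunking.
    """
    mask = ~np.isnan(d)
    x0 = np.where(mask, d, 0.0)
    m = d.shape[1]
    out_i, out_j, out_r2, out_n = [], [], [], []
    x0sq = x0 * x0
    for i, lo, hi in zip(left, right_lo, right_hi):
        if hi <= lo:
            continue
        cols = slice(lo, hi)
        mi = mask[:, i]
        xi = x0[:, i]
        n = mi @ mask[:, cols].astype(np.float64)
        sx = xi @ mask[:, cols]
        sy = mi @ x0[:, cols]
        sxx = x0sq[:, i] @ mask[:, cols]
        syy = mi @ x0sq[:, cols]
        sxy = xi @ x0[:, cols]
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = n * sxy - sx * sy
            varx = n * sxx - sx * sx
            vary = n * syy - sy * sy
            r2 = (cov * cov) / (varx * vary)
        valid = (n >= 2) & (varx > 0) & (vary > 0)
        js = np.arange(lo, hi)[valid]
        out_i.append(np.full(js.size, i))
        out_j.append(js)
        out_r2.append(r2[valid])
        out_n.append(n[valid].astype(np.int64))
    if not out_i:
        empty = np.array([], dtype=np.int64)
        return empty, empty, np.array([]), empty
    return (np.concatenate(out_i), np.concatenate(out_j),
            np.concatenate(out_r2), np.concatenate(out_n))


def pairwise_ld(panel: GenotypePanel, max_distance_bp: int = 10_000_000,
                estimator: str = "genotypic") -> pd.DataFrame:
    """All within-chromosome marker pairs up to ``max_distance_bp``.

    Returns a DataFrame with columns ``chromosome, idx_i, idx_j, marker_i,
    marker_j, distance_bp, r2, n_used`` in deterministic (chromosome, pos_i,
    pos_j) order.  ``idx_*`` are positions in the panel's marker map.  Pairs
    whose r² is undefined (monomorphic among complete observations) are
    skipped with a logged count.
    """
    if estimator not in ("genotypic", "em"):
        raise ValueError(f"unknown estimator {estimator!r}")
    mm = panel.markers
    d = panel.dosages_float()
    frames = []
    n_skipped = 0
    for chrom in mm.chromosomes():
        cidx = np.nonzero(mm.chromosome == chrom)[0]
        if cidx.size < 2:
            continue
        pos = mm.position_bp[cidx].astype(np.int64)
        sub = d[:, cidx]
        hi = np.searchsorted(pos, pos + max_distance_bp, side="right")
        left = np.arange(cidx.size)
        if estimator == "genotypic":
            ii, jj, r2, n_used = _pairwise_complete_r2(sub, left,
                                                       np.minimum(left + 1, cidx.size),
                                                       hi)
        else:
            ii, jj, r2v, nv = [], [], [], []
            gi = panel.dosages[:, cidx]
            for a in range(cidx.size):
                for b in range(a + 1, int(hi[a])):
                    try:
                        val = r2_em(gi[:, a], gi[:, b])
                    except ValueError:
                        n_skipped += 1
                        continue
                    ok = (gi[:, a] != MISSING) & (gi[:, b] != MISSING)
                    ii.append(a); jj.append(b); r2v.append(val); nv.append(int(ok.sum()))
            ii, jj = np.asarray(ii, dtype=np.int64), np.asarray(jj, dtype=np.int64)
            r2, n_used = np.asarray(r2v), np.asarray(nv, dtype=np.int64)
        if ii.size == 0:
            continue
        frames.append(pd.DataFrame({
            "chromosome": chrom,
            "idx_i": cidx[ii], "idx_j": cidx[jj],
            "marker_i": mm.marker_id[cidx[ii]],
            "marker_j": mm.marker_id[cidx[jj]],
            "distance_bp": pos[jj] - pos[ii],
            "r2": r2, "n_used": n_used,
        }))
    if n_skipped:
        logger.info("pairwise_ld: skipped %d undefined pair(s)", n_skipped)
    if not frames:
        return pd.DataFrame(columns=["chromosome", "idx_i", "idx_j", "marker_i",
                                     "marker_j", "distance_bp", "r2", "n_used"])
    return pd.concat(frames, ignore_index=True)


def adjacent_ld_summary(pairs: pd.DataFrame, marker_map: MarkerMap) -> pd.DataFrame:
    """Mean +/- sd of r² between physically adjacent markers, per chromosome.

    Only consecutive-in-map pairs are used.  A final ``genome`` row pools all
    adjacent pairs.  Chromosomes with fewer than two markers are omitted with
    a warning.
    """
    adj = pairs[pairs["idx_j"] == pairs["idx_i"] + 1]
    rows = []
    for chrom in marker_map.chromosomes():
        n_markers = int((marker_map.chromosome == chrom).sum())
        if n_markers < 2:
            logger.warning("adjacent_ld_summary: chromosome %s has <2 markers; omitted", chrom)
            continue
        sub = adj[adj["chromosome"] == chrom]["r2"]
        rows.append({"chromosome": chrom, "n_pairs": len(sub),
                     "mean_r2": sub.mean() if len(sub) else np.nan,
                     "sd_r2": sub.std(ddof=1) if len(sub) > 1 else np.nan})
    allr = adj["r2"]
    rows.append({"chromosome": "genome", "n_pairs": len(allr),
                 "mean_r2": allr.mean() if len(allr) else np.nan,
                 "sd_r2": allr.std(ddof=1) if len(allr) > 1 else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decay curve
# ---------------------------------------------------------------------------

@dataclass
class LDDecayCurve:
    """Binned LD-decay summary: contiguous distance bins with mean r²."""

    bin_width_bp: int
    max_bp: int
    table: pd.DataFrame   # bin_start, bin_end, mean_distance_bp, mean_r2, n_pairs

    def nonempty(self) -> pd.DataFrame:
        return self.table[self.table["n_pairs"] > 0]


def bin_ld(pairs: pd.DataFrame, bin_width_bp: int = 100_000,
           max_bp: int = 10_000_000) -> LDDecayCurve:
    """Group pairs into contiguous distance bins and average r² per bin.

    Bins are [0, w), [w, 2w), ..., with the final bin right-inclusive at
    ``max_bp``.  Empty bins carry count 0 and NaN means.  Pair counts are
    conserved: the bin counts sum to the number of pairs with distance <=
    ``max_bp``.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs to bin")
    n_bins = int(np.ceil(max_bp / bin_width_bp))
    dist = pairs["distance_bp"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    inrange = dist <= max_bp
    dist, r2 = dist[inrange], r2[inrange]
    idx = np.minimum(dist // bin_width_bp, n_bins - 1).astype(np.int64)
    counts = np.bincount(idx, minlength=n_bins)
    sum_r2 = np.bincount(idx, weights=r2, minlength=n_bins)
    sum_d = np.bincount(idx, weights=dist.astype(np.float64), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sum_r2 / counts, np.nan)
        mean_d = np.where(counts > 0, sum_d / counts, np.nan)
    table = pd.DataFrame({
        "bin_start": np.arange(n_bins) * bin_width_bp,
        "bin_end": np.minimum((np.arange(n_bins) + 1) * bin_width_bp, max_bp),
        "mean_distance_bp": mean_d,
        "mean_r2": mean_r2,
        "n_pairs": counts,
    })
    return LDDecayCurve(bin_width_bp, max_bp, table)


def r2_at_distances(curve: LDDecayCurve, distances_bp) -> pd.DataFrame:
    """Mean r² of the bin containing each requested distance.

    Reported alongside that bin's realised mean distance, for fixed-distance
    tables (e.g. r² at 0.1 / 0.5 / 1 / 5 / 10 Mb).
    """
    rows = []
    t = curve.table
    for dd in distances_bp:
        k = min(int(dd // curve.bin_width_bp), len(t) - 1)
        rows.append({"requested_bp": int(dd),
                     "bin_mean_distance_bp": t["mean_distance_bp"].iloc[k],
                     "mean_r2": t["mean_r2"].iloc[k],
                     "n_pairs": int(t["n_pairs"].iloc[k])})
    return pd.DataFrame(rows)


def decay_threshold_distance(curve: LDDecayCurve, r2_threshold: float = 0.2):
    """Distance at which the decay curve first falls through ``r2_threshold``.

    Linear interpolation between the mean distances of the two non-empty bins
    bracketing the first downward crossing.  Returns ``None`` when the curve
    starts below the threshold or never crosses it (explicit no-crossing
    result, not an exception).
    """
    t = curve.nonempty()
    if len(t) < 2:
        raise ValueError("need at least two non-empty bins")
    r = t["mean_r2"].to_numpy()
    dmean = t["mean_distance_bp"].to_numpy()
    if r[0] < r2_threshold:
        return None
    for k in range(len(r) - 1):
        if r[k] >= r2_threshold and r[k + 1] < r2_threshold:
            frac = (r[k] - r2_threshold) / (r[k] - r[k + 1])
            return float(dmean[k] + frac * (dmean[k + 1] - dmean[k]))
    return None
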
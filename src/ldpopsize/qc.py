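"""Per-population genotype quality control.

Implements the QC ladder used for SNP-array population panels: sample
missingness, SNP call rate, an exact Hardy-Weinberg equilibrium test, and a
minor-allele-frequency floor, with a per-criterion exclusion report and the
MAF spectrum of the retained loci.

The HWE test is the exact conditional test on the observed allele counts
(Wigginton, Cutler & Abecasis 2005 style): the two-sided p-value sums, over
every heterozygote count consistent with the allele totals, the probabilities
no larger than that of the observed configuration.  The standard (not mid-p)
tail is used, matching PLINK's default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

# Relative tolerance when comparing configuration probabilities for tail
# inclusion; absorbs float round-off on mathematically exact ties.
_TIE_REL = 1e-12


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the QC ladder (all fractions in [0, 1]).

    Defaults are the array-QC conventions used throughout this package:
    SNP call rate >= 95%, sample missingness <= 5%, MAF >= 5%,
    HWE exact p >= 1e-6.  Boundaries are strict: a SNP is excluded only when
    it is strictly below (call rate, MAF) or strictly below alpha (HWE p).
    """

    min_snp_call_rate: float = 0.95
    max_sample_missing: float = 0.05
    min_maf: float = 0.05
    hwe_alpha: float = 1e-6

    def __post_init__(self):
        for name in ("min_snp_call_rate", "max_sample_missing", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Exclusion bookkeeping for one population.

    SNP counts are mutually exclusive: each SNP is attributed to the first
    criterion that removed it, in the order call rate -> HWE -> MAF, so
    ``n_snps_in - excluded_by_call_rate - excluded_by_hwe - excluded_by_maf
    == n_snps_final``.
    """

    population_name: str
    n_samples_in: int
    n_samples_out: int
    n_snps_in: int
    excluded_by_call_rate: int
    excluded_by_hwe: int
    excluded_by_maf: int
    n_snps_final: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def compute_maf(dosage_column) -> float:
    """Minor allele frequency of one dosage column (missing = -1 ignored).

    MAF = min(p, 1-p) with p = (sum of dosages) / (2 * n_nonmissing).
    """
    col = np.asarray(dosage_column)
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    p = float(obs.sum()) / (2.0 * obs.size)
    return min(p, 1.0 - p)


def _maf_array(panel: GenotypePanel) -> np.ndarray:
    """Vectorized per-marker MAF; NaN for all-missing columns."""
    d = panel.dosages_float()
    n_obs = np.sum(~np.isnan(d), axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * n_obs)
    p[n_obs == 0] = np.nan
    return np.minimum(p, 1.0 - p)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and enumerates every heterozygote
    count of the same parity; the p-value is the total probability of
    configurations no more likely than the observed one.  Probabilities are
    computed by the stable ratio recurrence

        P(het = h + 2) / P(het = h) = (nA - h)(na - h) / ((h + 2)(h + 1) ... )

    normalised at the end, so the result is exact to float precision.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het   # rare-allele count
    if n_rare == 0:
        return 1.0

    # enumerate het counts h = n_rare % 2, +2, ..., min(n_rare, 2n - n_rare)
    h_max = min(n_rare, 2 * n - n_rare)
    h_min = n_rare % 2
    hs = np.arange(h_min, h_max + 1, 2)
    probs = np.empty(hs.size, dtype=np.float64)
    probs[0] = 1.0
    for k in range(hs.size - 1):
        h = hs[k]
        hom_r = (n_rare - h) // 2            # rare homozygotes at this h
        hom_c = n - h - hom_r                # common homozygotes
        # moving h -> h+2 converts one rare + one common homozygote into 2 hets
        probs[k + 1] = probs[k] * (4.0 * hom_r * hom_c) / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    obs = probs[(n_het - h_min) // 2]
    p = float(probs[probs <= obs * (1.0 + _TIE_REL)].sum())
    return min(p, 1.0)


def genotype_counts(panel: GenotypePanel) -> np.ndarray:
    """Per-marker (hom_ref, het, hom_alt) counts, shape (n_markers, 3)."""
    d = panel.dosages
    return np.stack([(d == k).sum(axis=0) for k in (0, 1, 2)], axis=1)


def apply_qc(panel: GenotypePanel, config: QCConfig = QCConfig()):
    """Run the QC ladder on one population panel.

    Order: (1) drop samples with missing fraction > ``max_sample_missing``;
    then drop SNPs sequentially by (2) call rate < ``min_snp_call_rate``,
    (3) HWE exact p < ``hwe_alpha``, (4) MAF < ``min_maf``.  Each SNP is
    counted under the first criterion that removed it.

    Returns
    -------
    (GenotypePanel, QCReport)
        The filtered panel (with its marker map filtered in lockstep) and the
        exclusion report.

    Raises
    ------
    ValueError
        If every sample or every SNP would be removed.
    """
    n_samples_in, n_snps_in = panel.n_samples, panel.n_markers

    miss_frac = panel.missing_mask().mean(axis=1)
    keep_samples = np.nonzero(miss_frac <= config.max_sample_missing)[0]
    if keep_samples.size == 0:
        raise ValueError("QC removed every sample (sample-missingness filter)")
    p = panel.subset_samples(keep_samples)

    call_rate = 1.0 - p.missing_mask().mean(axis=0)
    fail_cr = call_rate < config.min_snp_call_rate

    counts = genotype_counts(p)
    hwe_p = np.ones(p.n_markers)
    todo = np.nonzero(~fail_cr)[0]
    for j in todo:
        hom_r, het, hom_a = counts[j]
        if hom_r + het + hom_a > 0:
            hwe_p[j] = hwe_exact_test(int(hom_r), int(het), int(hom_a))
    fail_hwe = (hwe_p < config.hwe_alpha) & ~fail_cr

    maf = _maf_array(p)
    fail_maf = np.zeros(p.n_markers, dtype=bool)
    with np.errstate(invalid="ignore"):
        fail_maf = (np.nan_to_num(maf, nan=0.0) < config.min_maf) & ~fail_cr & ~fail_hwe

    keep = ~(fail_cr | fail_hwe | fail_maf)
    if not keep.any():
        raise ValueError("QC removed every SNP")
    filtered = p.subset_markers(np.nonzero(keep)[0])
    report = QCReport(
        population_name=panel.population_name,
        n_samples_in=n_samples_in,
        n_samples_out=p.n_samples,
        n_snps_in=n_snps_in,
        excluded_by_call_rate=int(fail_cr.sum()),
        excluded_by_hwe=int(fail_hwe.sum()),
        excluded_by_maf=int(fail_maf.sum()),
        n_snps_final=int(keep.sum()),
    )
    logger.info("QC %s: samples %d->%d, SNPs %d->%d (call rate %d, HWE %d, MAF %d)",
                report.population_name, n_samples_in, report.n_samples_out,
                n_snps_in, report.n_snps_final, report.excluded_by_call_rate,
                report.excluded_by_hwe, report.excluded_by_maf)
    return filtered, report


def maf_spectrum(panel: GenotypePanel, bin_width: float = 0.05) -> pd.DataFrame:
    """Proportion of retained loci per MAF bin.

    Bins are [0, w), [w, 2w), ... up to 0.5 (last bin right-inclusive);
    proportions sum to 1 over loci with a defined MAF.
    """
    maf = _maf_array(panel)
    maf = maf[~np.isnan(maf)]
    if maf.size == 0:
        raise ValueError("no loci with defined MAF")
    n_bins = int(np.ceil(0.5 / bin_width))
    # small epsilon so exact bin boundaries (e.g. MAF 0.30 / width 0.05) are
    # not pushed down a bin by float round-off
    idx = np.minimum((maf / bin_width + 1e-9).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    lo = np.arange(n_bins) * bin_width
    return pd.DataFrame({
        "maf_low": lo,
        "maf_high": np.minimum(lo + bin_width, 0.5),
        "n_loci": counts,
        "proportion": counts / maf.size,
    })
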
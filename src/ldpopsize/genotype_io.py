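"""Genotype panels, marker maps, and text-format I/O.

The two containers used throughout the package are :class:`MarkerMap` (per-marker
chromosome / base-pair position / allele pair, sorted along the genome) and
:class:`GenotypePanel` (an individuals x markers matrix of allele dosages for one
population, carrying its map).  Dosage coding follows the SNP-array convention:
0/1/2 copies of the non-reference allele, with ``-1`` as the missing sentinel.

Readers are provided for PLINK text PED/MAP, VCF (via cyvcf2) and a plain TSV
dosage matrix; writers round-trip losslessly.  ``intersect_markers`` builds the
common-marker subset shared by several post-QC populations, the backbone of any
cross-population comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing dosage in the int8 genotype matrix.
MISSING = np.int8(-1)


class FormatError(ValueError):
    """Malformed genotype input (wrong column counts, >2 alleles, ...)."""


def _chrom_sort_key(chrom: str):
    """Numeric chromosomes before lexical ones, each group in natural order."""
    s = str(chrom)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


@dataclass(frozen=True)
class MarkerMap:
    """Sorted physical map of biallelic markers.

    Parameters
    ----------
    marker_id : array of str
        Unique marker identifiers.
    chromosome : array of str
        Chromosome labels.
    position_bp : array of int
        1-based physical positions; strictly increasing within a chromosome.
    allele_ref, allele_alt : array of str
        The reference (dosage-0) and alternate (counted) allele.  For a
        monomorphic marker ``allele_alt`` may be ``"0"`` (unknown).
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_ref: np.ndarray
    allele_alt: np.ndarray

    def __post_init__(self):
        n = len(self.marker_id)
        for name in ("chromosome", "position_bp", "allele_ref", "allele_alt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MarkerMap field {name!r} length mismatch")
        if len(set(self.marker_id)) != n:
            raise ValueError("marker_id values must be unique")
        if np.any(np.asarray(self.position_bp) < 1):
            raise ValueError("positions are 1-based and must be >= 1")
        # sortedness + strict monotonicity within chromosome
        prev_key = None
        for c, p in zip(self.chromosome, self.position_bp):
            key = (_chrom_sort_key(c), int(p))
            if prev_key is not None:
                if key[0] < prev_key[0]:
                    raise ValueError("MarkerMap not sorted by chromosome")
                if key[0] == prev_key[0] and key[1] <= prev_key[1]:
                    raise ValueError(
                        "positions must strictly increase within a chromosome "
                        f"(duplicate/unsorted at {c}:{p})"
                    )
            prev_key = key

    def __len__(self) -> int:
        return len(self.marker_id)

    @classmethod
    def from_arrays(cls, marker_id, chromosome, position_bp, allele_ref=None,
                    allele_alt=None, sort: bool = True) -> "MarkerMap":
        """Build a map, sorting by (chromosome, position) unless ``sort=False``."""
        marker_id = np.asarray(marker_id, dtype=object)
        chromosome = np.asarray([str(c) for c in chromosome], dtype=object)
        position_bp = np.asarray(position_bp, dtype=np.int64)
        n = len(marker_id)
        if allele_ref is None:
            allele_ref = np.full(n, "0", dtype=object)
        if allele_alt is None:
            allele_alt = np.full(n, "0", dtype=object)
        allele_ref = np.asarray(allele_ref, dtype=object)
        allele_alt = np.asarray(allele_alt, dtype=object)
        order = np.arange(n)
        if sort:
            keys = [( _chrom_sort_key(c), int(p)) for c, p in zip(chromosome, position_bp)]
            order = np.array(sorted(range(n), key=lambda i: keys[i]), dtype=np.int64)
        return cls(marker_id[order], chromosome[order], position_bp[order],
                   allele_ref[order], allele_alt[order]), order

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_id,
            "chromosome": self.chromosome,
            "position_bp": self.position_bp,
            "allele_ref": self.allele_ref,
            "allele_alt": self.allele_alt,
        })

    def keys(self) -> list:
        """Marker identity keys: (chromosome, position, unordered allele pair)."""
        return [
            (c, int(p), frozenset((a, b)))
            for c, p, a, b in zip(self.chromosome, self.position_bp,
                                  self.allele_ref, self.allele_alt)
        ]

    def subset(self, idx) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(self.marker_id[idx], self.chromosome[idx],
                         self.position_bp[idx], self.allele_ref[idx],
                         self.allele_alt[idx])

    def chromosomes(self) -> list:
        """Chromosome labels in map order (first-occurrence order)."""
        seen, out = set(), []
        for c in self.chromosome:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out


@dataclass
class GenotypePanel:
    """Dosage matrix for one population, aligned to a :class:`MarkerMap`.

    ``dosages`` is an ``(n_samples, n_markers)`` int8 array over ``{0, 1, 2}``
    with :data:`MISSING` (-1) for no-calls.
    """

    population_name: str
    sample_ids: list
    dosages: np.ndarray
    markers: MarkerMap

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x markers)")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("row count != number of sample ids")
        if self.dosages.shape[0] < 1:
            raise ValueError("panel must contain at least one individual")
        if self.dosages.shape[1] != len(self.markers):
            raise ValueError("column count != marker map length")
        bad = ~np.isin(self.dosages, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def dosages_float(self) -> np.ndarray:
        """Dosages as float64 with NaN for missing calls."""
        x = self.dosages.astype(np.float64)
        x[self.dosages == MISSING] = np.nan
        return x

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def subset_markers(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(self.population_name, list(self.sample_ids),
                             self.dosages[:, idx], self.markers.subset(idx))

    def subset_samples(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(self.population_name,
                             [self.sample_ids[i] for i in idx],
                             self.dosages[idx, :], self.markers)


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path, population_name: str | None = None) -> GenotypePanel:
    """Read a whitespace-delimited PLINK text fileset.

    The MAP file supplies chromosome/position; alleles are inferred from the PED
    body with the first-seen allele per marker taken as the reference (PED does
    not designate one; all downstream statistics are invariant to the choice).
    ``0`` is the missing-allele code; a pair containing it becomes a missing
    dosage.  Markers are re-sorted by (chromosome, position).

    Raises
    ------
    FormatError
        On a marker with more than two alleles, or on PED/MAP column-count
        mismatch.
    """
    map_df = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str,
                         comment="#")
    if map_df.shape[1] == 3:       # chrom, id, bp  (no genetic distance column)
        map_df.columns = ["chromosome", "marker_id", "position_bp"]
    elif map_df.shape[1] >= 4:
        map_df = map_df.iloc[:, :4]
        map_df.columns = ["chromosome", "marker_id", "cm", "position_bp"]
    else:
        raise FormatError(f"MAP file {map_path} has {map_df.shape[1]} columns; expected 3 or 4")
    m = len(map_df)

    sample_ids = []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"PED line {lineno}: {len(parts)} fields, expected {6 + 2 * m} "
                    f"for {m} MAP markers"
                )
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])
    if not allele_rows:
        raise FormatError(f"PED file {ped_path} contains no individuals")
    alleles = np.asarray(allele_rows, dtype=object).reshape(len(sample_ids), m, 2)

    dosages = np.full((len(sample_ids), m), MISSING, dtype=np.int8)
    ref = np.full(m, "0", dtype=object)
    alt = np.full(m, "0", dtype=object)
    for j in range(m):
        col = alleles[:, j, :]
        flat = col.ravel()
        observed = [a for a in flat if a != "0"]
        uniq = []
        for a in observed:
            if a not in uniq:
                uniq.append(a)
        if len(uniq) > 2:
            raise FormatError(
                f"marker {map_df['marker_id'].iloc[j]!r} has more than two alleles: {uniq}"
            )
        if uniq:
            ref[j] = uniq[0]
            if len(uniq) > 1:
                alt[j] = uniq[1]
        called = (col[:, 0] != "0") & (col[:, 1] != "0")
        d = (col[:, 0] != ref[j]).astype(np.int8) + (col[:, 1] != ref[j]).astype(np.int8)
        dosages[called, j] = d[called]

    marker_map, order = MarkerMap.from_arrays(
        map_df["marker_id"].to_numpy(dtype=object),
        map_df["chromosome"].to_numpy(dtype=object),
        map_df["position_bp"].astype(np.int64).to_numpy(),
        ref, alt,
    )
    name = population_name or Path(ped_path).stem
    return GenotypePanel(name, sample_ids, dosages[:, order], marker_map)


def write_plink_text(panel: GenotypePanel, ped_path, map_path) -> None:
    """Write a panel as PLINK text PED/MAP (lossless dosage round trip).

    Heterozygotes are written ``ref alt`` so that re-reading (first-seen
    reference convention) reproduces the same dosage matrix whenever the panel
    itself originated from :func:`read_plink_text`.
    """
    mm = panel.markers
    with open(map_path, "w") as fh:
        for c, mid, p in zip(mm.chromosome, mm.marker_id, mm.position_bp):
            fh.write(f"{c}\t{mid}\t0\t{p}\n")
    ref = np.asarray(mm.allele_ref, dtype=object)
    alt = np.asarray(mm.allele_alt, dtype=object)
    # A monomorphic marker has no observed alt; emit a placeholder distinct
    # from ref so dosage-2 (impossible there anyway) would not alias ref.
    alt = np.where(alt == "0", np.where(ref == "A", "B", "A"), alt)
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            fields = [panel.population_name, str(sid), "0", "0", "0", "-9"]
            row = panel.dosages[i]
            for j, d in enumerate(row):
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [ref[j], ref[j]]
                elif d == 1:
                    fields += [ref[j], alt[j]]
                else:
                    fields += [alt[j], alt[j]]
            fh.write(" ".join(map(str, fields)) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path, population_name: str | None = None) -> GenotypePanel:
    """Read biallelic SNP records from a VCF (GT field) into a panel.

    Dosage = ALT-allele count; phasing is ignored; ``./.`` becomes missing.
    Multiallelic records are skipped (not split) with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    sample_ids = list(vcf.samples)
    ids, chroms, poss, refs, alts, cols = [], [], [], [], [], []
    n_skipped = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gt = np.asarray(var.gt_types)          # gts012: 0/1/2 dosage, 3 missing
        col = gt.astype(np.int8)
        col[gt == 3] = MISSING
        cols.append(col)
    vcf.close()
    if n_skipped:
        logger.warning("read_vcf: skipped %d multiallelic record(s)", n_skipped)
    if not cols:
        raise FormatError(f"no biallelic SNP records in {vcf_path}")
    dosages = np.stack(cols, axis=1)
    marker_map, order = MarkerMap.from_arrays(ids, chroms, poss, refs, alts)
    name = population_name or Path(vcf_path).stem
    return GenotypePanel(name, sample_ids, dosages[:, order], marker_map)


# ---------------------------------------------------------------------------
# TSV dosage matrix
# ---------------------------------------------------------------------------

def write_tsv_matrix(panel: GenotypePanel, matrix_path, map_path=None) -> None:
    """Write the dosage matrix as TSV (samples x markers, header = marker ids).

    Missing dosages are written as ``NA``.  If ``map_path`` is given the marker
    map is written alongside so the fileset is self-contained.
    """
    df = pd.DataFrame(panel.dosages.astype(object),
                      index=list(panel.sample_ids),
                      columns=list(panel.markers.marker_id))
    df = df.mask(df == int(MISSING), "NA")
    df.to_csv(matrix_path, sep="\t", index_label="sample_id")
    if map_path is not None:
        panel.markers.to_dataframe().to_csv(map_path, sep="\t", index=False)


def read_tsv_matrix(matrix_path, map_path, population_name: str | None = None) -> GenotypePanel:
    """Read a TSV dosage matrix plus its marker-map TSV."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    mdf = pd.read_csv(map_path, sep="\t", dtype={"chromosome": str})
    marker_map, order = MarkerMap.from_arrays(
        mdf["marker_id"].to_numpy(dtype=object),
        mdf["chromosome"].to_numpy(dtype=object),
        mdf["position_bp"].to_numpy(np.int64),
        mdf["allele_ref"].astype(str).to_numpy(dtype=object),
        mdf["allele_alt"].astype(str).to_numpy(dtype=object),
    )
    df = df[list(np.asarray(mdf["marker_id"], dtype=object)[order])]
    dos = df.replace("NA", "-1").to_numpy(dtype=np.float64).astype(np.int8)
    name = population_name or Path(matrix_path).stem
    return GenotypePanel(name, [str(s) for s in df.index], dos, marker_map)


# ---------------------------------------------------------------------------
# Cross-population marker intersection
# ---------------------------------------------------------------------------

class EmptyIntersectionError(ValueError):
    """No marker is shared by all input panels."""


def intersect_markers(panels: Sequence[GenotypePanel]) -> list:
    """Restrict each panel to the markers present in every input panel.

    Marker identity is (chromosome, position, unordered allele pair); marker
    order follows the first panel's map.  Typically applied after per-population
    QC so that downstream cross-population comparisons use a common SNP set.
    """
    if len(panels) < 2:
        raise ValueError("need at least two panels to intersect")
    key_sets = [set(p.markers.keys()) for p in panels]
    common = set.intersection(*key_sets)
    if not common:
        raise EmptyIntersectionError("panels share no common markers")
    out = []
    for p in panels:
        keys = p.markers.keys()
        idx = [i for i, k in enumerate(keys) if k in common]
        out.append(p.subset_markers(idx))
    logger.info("intersect_markers: %d common markers across %d panels",
                len(common), len(panels))
    return out


def concat_panels(panels: Sequence[GenotypePanel], name: str = "combined"):
    """Stack panels sharing an identical marker map into one panel.

    Returns the combined panel and the per-sample population labels.
    """
    ref_keys = panels[0].markers.keys()
    for p in panels[1:]:
        if p.markers.keys() != ref_keys:
            raise ValueError("panels must share an identical marker map; "
                             "run intersect_markers first")
    dosages = np.vstack([p.dosages for p in panels])
    sample_ids, labels = [], []
    for p in panels:
        for s in p.sample_ids:
            sample_ids.append(f"{p.population_name}:{s}")
            labels.append(p.population_name)
    return GenotypePanel(name, sample_ids, dosages, panels[0].markers), labels
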
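"""End-to-end pipeline: QC -> common-SNP intersection -> LD -> decay ->
historical Ne -> contemporary Ne -> PCA, from one flat YAML config.

Emits per-stage TSV/JSON artifacts (QC report, adjacent-marker LD and
per-chromosome Ne, decay curve and r²-at-distance table, Ne trajectory,
contemporary Ne, PCA coordinates, MAF spectrum) plus a run manifest with
settings, versions, the seed, and per-stage counts.  Output formatting is
fixed at six significant digits so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype_io import (GenotypePanel, concat_panels, intersect_markers,
                          read_plink_text, read_tsv_matrix, read_vcf)
from .ld import (adjacent_ld_summary, bin_ld, decay_threshold_distance,
                 pairwise_ld, r2_at_distances)
from .ne_contemporary import ContemporaryNe, LDNeConfig
from .ne_historical import HistoricalNe, NeConfig
from .pca import pca
from .qc import QCConfig, apply_qc, maf_spectrum
from .simulate import SimConfig, simulate_split, simulate_wf

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Flat pipeline settings; defaults reproduce the package's reference
    analysis settings (QC 95%/5%/5%/1e-6, 100-kb decay bins to 10 Mb,
    Eq.-inversion with alpha=2 over 30 x 50-kb bins, pcrit=0.05 monogamy,
    PCA k=10)."""

    populations: dict = field(default_factory=dict)   # name -> {format, paths...}
    simulate: dict | None = None                      # alternative to file inputs
    out_dir: str = "ldpopsize_out"
    seed: int = 0
    estimator: str = "genotypic"
    qc: QCConfig = field(default_factory=QCConfig)
    ld_max_distance_bp: int = 10_000_000
    ld_bin_width_bp: int = 100_000
    r2_threshold: float = 0.2
    table_distances_bp: tuple = (100_000, 500_000, 1_000_000, 5_000_000, 10_000_000)
    ne_hist: NeConfig = field(default_factory=NeConfig)
    ne_ld: LDNeConfig = field(default_factory=LDNeConfig)
    pca_k: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("populations", "simulate", "out_dir", "seed", "estimator",
                    "ld_max_distance_bp", "ld_bin_width_bp", "r2_threshold",
                    "pca_k"):
            if key in raw:
                kwargs[key] = raw[key]
        if "table_distances_bp" in raw:
            kwargs["table_distances_bp"] = tuple(raw["table_distances_bp"])
        if "qc" in raw:
            kwargs["qc"] = QCConfig(**raw["qc"])
        if "ne_hist" in raw:
            kwargs["ne_hist"] = NeConfig(**raw["ne_hist"])
        if "ne_ld" in raw:
            kwargs["ne_ld"] = LDNeConfig(**raw["ne_ld"])
        cfg = cls(**kwargs)
        for name, spec in cfg.populations.items():
            for k, v in spec.items():
                if k.endswith("_path") and not Path(v).exists():
                    raise FileNotFoundError(f"population {name}: missing {k}={v}")
        return cfg


def _load_panels(config: PipelineConfig):
    panels = []
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        if "ne_trajectory" in sim_kwargs:
            sim_kwargs["ne_trajectory"] = tuple(
                tuple(p) for p in sim_kwargs["ne_trajectory"])
        sc = SimConfig(**sim_kwargs)
        if sc.split_times:
            panels, _ = simulate_split(sc)
        else:
            panel, _ = simulate_wf(sc)
            panels = [panel]
        return panels
    for name, spec in config.populations.items():
        fmt = spec.get("format", "ped")
        if fmt == "ped":
            panels.append(read_plink_text(spec["ped_path"], spec["map_path"], name))
        elif fmt == "vcf":
            panels.append(read_vcf(spec["vcf_path"], name))
        elif fmt == "tsv":
            panels.append(read_tsv_matrix(spec["matrix_path"], spec["map_path"], name))
        else:
            raise ValueError(f"unknown input format {fmt!r} for population {name}")
    if not panels:
        raise ValueError("no input populations configured")
    return panels


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written as JSON).

    A fatal stage error aborts with the stage named; previously written
    artifacts are retained alongside a ``FAILED`` marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "estimator": config.estimator,
        "settings": {
            "qc": dataclasses.asdict(config.qc),
            "ld": {"max_distance_bp": config.ld_max_distance_bp,
                   "bin_width_bp": config.ld_bin_width_bp},
            "ne_hist": dataclasses.asdict(config.ne_hist),
            "ne_ld": dataclasses.asdict(config.ne_ld),
            "pca_k": config.pca_k,
        },
        "stages": {},
        "populations": {},
    }
    stage = "load"
    try:
        t0 = time.perf_counter()
        panels = _load_panels(config)
        manifest["stages"]["load"] = {
            "populations": [p.population_name for p in panels],
            "n_samples": {p.population_name: p.n_samples for p in panels},
            "n_markers": {p.population_name: p.n_markers for p in panels},
        }
        logger.info("load: %d population(s) in %.2fs", len(panels),
                    time.perf_counter() - t0)

        stage = "qc"
        qc_rows = []
        qc_panels = []
        for p in panels:
            fp, rep = apply_qc(p, config.qc)
            qc_panels.append(fp)
            qc_rows.append(rep.__dict__)
        qc_df = pd.DataFrame(qc_rows)
        _write_tsv(qc_df, out / "qc_report.tsv")
        manifest["stages"]["qc"] = {r["population_name"]:
                                    {k: v for k, v in r.items() if k != "population_name"}
                                    for r in qc_rows}

        stage = "intersect"
        if len(qc_panels) >= 2:
            common = intersect_markers(qc_panels)
        else:
            common = qc_panels
        manifest["stages"]["intersect"] = {"n_common_markers": common[0].n_markers}

        stage = "maf_spectrum"
        spec_frames = []
        for p in common:
            s = maf_spectrum(p)
            s.insert(0, "population", p.population_name)
            spec_frames.append(s)
        _write_tsv(pd.concat(spec_frames, ignore_index=True), out / "maf_spectrum.tsv")

        stage = "ld"
        decay_rows, adj_frames, table_frames = [], [], []
        ne_traj_frames, ne_chrom_frames, ne_point = [], [], {}
        for p in common:
            pairs = pairwise_ld(p, config.ld_max_distance_bp, config.estimator)
            adj = adjacent_ld_summary(pairs, p.markers)
            adj.insert(0, "population", p.population_name)
            adj_frames.append(adj)
            curve = bin_ld(pairs, config.ld_bin_width_bp, config.ld_max_distance_bp)
            ct = curve.table.copy()
            ct.insert(0, "population", p.population_name)
            decay_rows.append(ct)
            tab = r2_at_distances(curve, config.table_distances_bp)
            tab.insert(0, "population", p.population_name)
            table_frames.append(tab)
            thr = decay_threshold_distance(curve, config.r2_threshold)
            manifest["populations"].setdefault(p.population_name, {})[
                "threshold_distance_bp"] = thr
            manifest["populations"][p.population_name]["n_ld_pairs"] = len(pairs)

            stage = "ne_historical"
            res = HistoricalNe(pairs, config.ne_hist).fit()
            tr = res.trajectory.copy()
            tr.insert(0, "population", p.population_name)
            ne_traj_frames.append(tr)
            if res.by_chromosome is not None:
                bc = res.by_chromosome.copy()
                bc.insert(0, "population", p.population_name)
                ne_chrom_frames.append(bc)

            stage = "ne_contemporary"
            cres = ContemporaryNe(p, config.ne_ld).fit()
            ne_point[p.population_name] = {
                "ne": cres.ne if np.isfinite(cres.ne) else "infinity",
                "mean_r2": cres.mean_r2,
                "harmonic_S": cres.harmonic_S,
                "n_pairs": cres.n_pairs,
                "mating_model": config.ne_ld.mating_model,
                "pcrit": config.ne_ld.pcrit,
            }
            stage = "ld"
        _write_tsv(pd.concat(adj_frames, ignore_index=True), out / "adjacent_ld.tsv")
        _write_tsv(pd.concat(decay_rows, ignore_index=True), out / "ld_decay.tsv")
        _write_tsv(pd.concat(table_frames, ignore_index=True),
                   out / "r2_at_distance.tsv")
        _write_tsv(pd.concat(ne_traj_frames, ignore_index=True),
                   out / "ne_trajectory.tsv")
        if ne_chrom_frames:
            _write_tsv(pd.concat(ne_chrom_frames, ignore_index=True),
                       out / "ne_per_chromosome.tsv")
        with open(out / "ne_point.json", "w") as fh:
            json.dump(ne_point, fh, indent=2, default=float)

        stage = "pca"
        if len(common) >= 2:
            combined, labels = concat_panels(common)
        else:
            combined, labels = common[0], [common[0].population_name] * common[0].n_samples
        pres = pca(combined, config.pca_k, population_labels=labels)
        _write_tsv(pres.to_frame(), out / "pca.tsv")
        eig = pd.DataFrame({
            "component": np.arange(1, pres.pct_variance.size + 1),
            "eigenvalue": pres.eigenvalues[:pres.pct_variance.size],
            "pct_variance": pres.pct_variance,
        })
        _write_tsv(eig, out / "pca_eigen.tsv")
        manifest["stages"]["pca"] = {
            "pct_variance_pc1": float(pres.pct_variance[0]),
            "pct_variance_pc2": float(pres.pct_variance[1])
            if pres.pct_variance.size > 1 else None,
        }

        manifest["stages"]["ne_point"] = ne_point
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
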
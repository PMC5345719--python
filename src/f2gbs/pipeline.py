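"""End-to-end orchestration and graphical-genotype export."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abh import CorrectionParams, encode_abh, merge_populations, postprocess
from .filtering import filter_pipeline
from .io import (read_phenotype_csv, read_site_matrix, write_abh_csv,
                 write_map_tsv)
from .linkage import estimate_map
from .model import ABHMatrix
from .qtl import scan

log = logging.getLogger("f2gbs")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (filter -> ... -> scan).

    All paths are validated before any stage executes.  Coordinates in
    every output are 1-based inclusive.
    """

    genotypes: str = ""
    format: str = "vcf"
    roles: str = ""
    phenotype: str = ""
    out_dir: str = "f2gbs_out"
    maf_threshold: float = 0.25
    min_depth: int = 7
    thin_bp: int = 64
    max_missing: float = 0.75
    het_run_max: int = 4
    stretch_run_max: int = 1
    map_function: str = "haldane"
    step_cM: float = 1.0
    n_draws: int = 16
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    stages: tuple[str, ...] = ("filter", "encode", "correct", "map", "scan")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def validate(self) -> None:
        for path, label in ((self.genotypes, "genotypes"), (self.roles, "roles")):
            if path and not os.path.exists(path):
                raise ValueError(f"{label} file does not exist: {path}")
        if self.phenotype and not os.path.exists(self.phenotype):
            raise ValueError(f"phenotype file does not exist: {self.phenotype}")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        valid_stages = {"filter", "encode", "correct", "map", "scan"}
        bad = set(self.stages) - valid_stages
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stage prefix, persisting per-stage outputs.

    Returns a provenance record (stage outputs, counts, config hash, seed,
    package version) that is also written to ``<out_dir>/provenance.json``.
    Stage failures abort with the stage name; earlier outputs remain.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    record: dict = {
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    abh = None
    gmap = None
    stage = "init"
    try:
        if "filter" in config.stages:
            stage = "filter"
            m = read_site_matrix(config.genotypes, config.format, config.roles)
            m, report = filter_pipeline(
                m, maf_threshold=config.maf_threshold, min_depth=config.min_depth,
                thin_bp=config.thin_bp, max_missing=config.max_missing)
            path = os.path.join(config.out_dir, "filter_report.json")
            with open(path, "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            record["stages"]["filter"] = {
                "sites_out": m.n_sites, "report": path}
            log.info("filter: %d sites retained", m.n_sites)
        if "encode" in config.stages:
            stage = "encode"
            abh = encode_abh(m)
            path = os.path.join(config.out_dir, "genotypes_raw.abh.csv")
            write_abh_csv(abh, path)
            record["stages"]["encode"] = {"path": path,
                                          "individuals": abh.n_individuals,
                                          "markers": abh.n_markers}
        if "correct" in config.stages and abh is not None:
            stage = "correct"
            params = CorrectionParams(het_run_max=config.het_run_max,
                                      stretch_run_max=config.stretch_run_max)
            abh, stats = postprocess(abh, params)
            path = os.path.join(config.out_dir, "genotypes_corrected.abh.csv")
            write_abh_csv(abh, path)
            record["stages"]["correct"] = {"path": path, **stats.to_dict()}
            log.info("correct: N %.2f%% -> %.2f%%",
                     100 * stats.composition_before["N"],
                     100 * stats.composition_after["N"])
        if "map" in config.stages and abh is not None:
            stage = "map"
            gmap = estimate_map(abh, map_function=config.map_function)
            path = os.path.join(config.out_dir, "map.tsv")
            write_map_tsv(gmap, path)
            record["stages"]["map"] = {"path": path,
                                       "total_cM": gmap.total_length_cM()}
            log.info("map: total length %.1f cM", gmap.total_length_cM())
        if "scan" in config.stages and abh is not None and gmap is not None \
                and config.phenotype:
            stage = "scan"
            pheno = read_phenotype_csv(config.phenotype)
            result = scan(abh, gmap, pheno, step_cM=config.step_cM,
                          n_draws=config.n_draws, n_perm=config.n_perm,
                          alpha=config.alpha, seed=config.seed)
            scan_path = os.path.join(config.out_dir, "scan.tsv")
            pd.DataFrame({
                "chromosome": result.grid_chrom,
                "position_cM": result.grid_cM,
                "lod": result.lod,
            }).to_csv(scan_path, sep="\t", index=False)
            peaks_path = os.path.join(config.out_dir, "peaks.json")
            with open(peaks_path, "w") as fh:
                json.dump({
                    "threshold": result.threshold,
                    "alpha": result.alpha,
                    "peaks": [{
                        "chromosome": p.chromosome,
                        "position_cM": p.position_cM,
                        "lod": p.lod,
                        "interval_cM": list(p.interval_cM),
                        "percent_variance": p.percent_variance,
                        "additive_effect": p.additive_effect,
                        "dominance_effect": p.dominance_effect,
                    } for p in result.peaks],
                }, fh, indent=2)
            record["stages"]["scan"] = {"scan": scan_path, "peaks": peaks_path,
                                        "threshold": result.threshold,
                                        "n_peaks": len(result.peaks)}
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    with open(os.path.join(config.out_dir, "provenance.json"), "w") as fh:
        json.dump(record, fh, indent=2)
    return record


# ---------------------------------------------------------------------------
# graphical genotypes

ABH_COLORS = {"A": "#d95f02", "B": "#1b9e77", "H": "#7570b3", "N": "#dddddd"}


def export_graphical_genotypes(g: ABHMatrix, out_prefix: str,
                               render_png: bool = True) -> str:
    """Export per-individual genotype tracks.

    Writes a long-format TSV (individual, marker, chromosome, position,
    code) at ``<out_prefix>.tsv`` and, optionally, a PNG rendering with one
    horizontal track per individual and markers in genome order, coloured
    by code.  Returns the TSV path.
    """
    tsv_path = out_prefix + ".tsv"
    n_ind, n_mark = g.codes.shape
    frame = pd.DataFrame({
        "individual": np.repeat(g.individuals, n_mark),
        "marker": np.tile(g.marker_ids, n_ind),
        "chromosome": np.tile(g.chromosomes, n_ind),
        "position": np.tile(g.positions, n_ind),
        "code": g.codes.ravel(),
    })
    frame.to_csv(tsv_path, sep="\t", index=False)
    if render_png:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        lookup = {c: i for i, c in enumerate("ABHN")}
        img = np.vectorize(lookup.get)(g.codes) if g.codes.size else np.zeros((1, 1), int)
        fig, ax = plt.subplots(figsize=(10, max(2, 0.05 * n_ind)))
        ax.imshow(img, aspect="auto", interpolation="nearest",
                  cmap=ListedColormap([ABH_COLORS[c] for c in "ABHN"]),
                  vmin=0, vmax=3)
        ax.set_xlabel("marker index (genome order)")
        ax.set_ylabel("individual")
        fig.savefig(out_prefix + ".png", dpi=120)
        plt.close(fig)
    return tsv_path


def genotype_diff(before: ABHMatrix, after: ABHMatrix) -> pd.DataFrame:
    """Long-format table of exactly the cells that differ between matrices."""
    if before.codes.shape != after.codes.shape:
        raise ValueError("matrices must have identical dimensions")
    rows, cols = np.nonzero(before.codes != after.codes)
    return pd.DataFrame({
        "individual": [before.individuals[i] for i in rows],
        "marker": [before.marker_ids[j] for j in cols],
        "before": before.codes[rows, cols],
        "after": after.codes[rows, cols],
    })
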
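"""Readers, writers, configuration and the reproducible pipeline driver.

Conventions: all tables are UTF-8 tab-separated with a header row and ``NA``
for missing values; genomic coordinates are 1-based inclusive (VCF
convention); heterozygous sites travel as a minimal VCF whose INFO field
carries the gene id (``GENE=``) and, when known, the double allele
(``DA=ref|alt``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from . import ase as ase_mod
from . import dosage as dosage_mod
from .classifier import classify_mosaic
from .doublets import detect_doublets, x_profiles, XHaplotypeDoubletDetector
from .simulate import AlleleCounts, SimConfig, SimResult, simulate_population

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_sites",
    "write_sites",
    "read_counts",
    "write_counts",
    "read_expression",
    "write_expression",
    "write_truth",
    "run_pipeline",
]

_NA = "NA"


# ---- heterozygous sites (VCF) -------------------------------------------------

def write_sites(sites: pd.DataFrame, path, double_allele: pd.Series | None = None
                ) -> None:
    """Write sites as a minimal VCF (CHROM, POS 1-based, ID, REF, ALT)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##INFO=<ID=DA,Number=1,Type=String,'
                 'Description="Double allele (ref or alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in sites.itertuples(index=False):
            info = f"GENE={row.gene_id}"
            if double_allele is not None and row.site_id in double_allele.index:
                info += f";DA={double_allele[row.site_id]}"
            fh.write(f"{row.chrom}\t{row.pos}\t{row.site_id}\t{row.ref}\t"
                     f"{row.alt}\t.\t.\t{info}\n")


def read_sites(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read heterozygous sites from a VCF.

    Biallelic SNVs only: indels and multi-allelic records are skipped with a
    logged count; a duplicated (chrom, pos) is an error.  Returns the site
    table and the (possibly empty) double-allele map found in INFO/DA.
    """
    rows, da = [], {}
    seen: set[tuple[str, int]] = set()
    n_skipped = 0
    for i, rec in enumerate(VCF(str(path))):
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        key = (rec.CHROM, rec.POS)
        if key in seen:
            raise ValueError(f"duplicate site at record {i + 1}: "
                             f"{rec.CHROM}:{rec.POS}")
        seen.add(key)
        site_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        gene = rec.INFO.get("GENE") or site_id
        rows.append((site_id, rec.CHROM, rec.POS, rec.REF, alts[0], gene))
        if rec.INFO.get("DA") is not None:
            da[site_id] = rec.INFO.get("DA")
    if n_skipped:
        logger.info("skipped %d non-SNV/multi-allelic VCF records", n_skipped)
    sites = pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "ref",
                                        "alt", "gene_id"])
    return sites, pd.Series(da, name="double_allele", dtype=object)


# ---- count and expression tables ---------------------------------------------

def write_counts(table: AlleleCounts, counts_path, totals_path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index=False, na_rep=_NA)
    table.total_reads.rename("total_reads").to_frame().to_csv(
        totals_path, sep="\t", index_label="cell_id", na_rep=_NA)


def read_counts(counts_path, totals_path, sites: pd.DataFrame | None = None
                ) -> AlleleCounts:
    counts = pd.read_csv(counts_path, sep="\t")
    required = {"cell_id", "site_id", "ref_reads", "alt_reads"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if counts.empty:
        counts = counts.astype({"ref_reads": np.int64, "alt_reads": np.int64})
    for col in ("ref_reads", "alt_reads"):
        if not np.issubdtype(counts[col].dtype, np.number):
            raise ValueError(f"non-numeric values in column {col}")
        if (counts[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    totals = pd.read_csv(totals_path, sep="\t", index_col="cell_id")["total_reads"]
    unknown_cells = set(counts["cell_id"]) - set(totals.index)
    if unknown_cells:
        raise ValueError(f"counts reference unknown cells: "
                         f"{sorted(unknown_cells)[:5]}")
    if sites is not None:
        unknown_sites = set(counts["site_id"]) - set(sites["site_id"])
        if unknown_sites:
            raise ValueError(f"counts reference unknown sites: "
                             f"{sorted(unknown_sites)[:5]}")
    if counts.empty:
        logger.warning("counts table is empty")
    return AlleleCounts(counts=counts, total_reads=totals)


def write_expression(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="cell_id", na_rep=_NA)


def read_expression(path) -> pd.DataFrame:
    """Expression matrix from TSV (cells x genes) or MatrixMarket triplet.

    A MatrixMarket file ``X.mtx`` expects companion index files ``X.rows``
    (cell ids) and ``X.cols`` (gene ids), one id per line.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread
        mat = mmread(path).toarray()
        cells = Path(str(path.with_suffix("")) + ".rows").read_text().split()
        genes = Path(str(path.with_suffix("")) + ".cols").read_text().split()
        return pd.DataFrame(mat, index=pd.Index(cells, name="cell_id"),
                            columns=genes)
    return pd.read_csv(path, sep="\t", index_col="cell_id")


def write_truth(truth, path) -> None:
    truth.cell_labels.rename("label").to_frame().to_csv(
        path, sep="\t", index_label="cell_id", na_rep=_NA)


# ---- configuration ------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved pipeline thresholds; every default is the published one."""

    counts_path: str = ""
    totals_path: str = ""
    sites_path: str = ""
    expression_path: str = ""
    output_dir: str = "trisect_out"
    supernumerary_chromosome: str = "chr21"
    mosaic: bool = True
    mode: str = "c1"                       # or "droplet"
    min_coverage: int = 16
    min_rpsm: float = 20.0
    ase_low: float = 0.1
    ase_high: float = 0.9
    mep_low: float = 0.2
    mep_high: float = 0.8
    expression_bounds: tuple[float, float] = (3.0, 15.0)
    dosage_band: tuple[float, float] = (0.8, 1.2)
    min_expressing_cells: int = 10
    min_total_reads: float = 1e6
    min_expressed_fraction: float = 0.10
    doublet_band: tuple[float, float] = (0.0, 0.75)
    escapee_genes: tuple = ()
    max_iter: int = 100
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(d[f.name], list):
                d[f.name] = tuple(d[f.name])
        return cls(**d)


# ---- pipeline -----------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """QC -> doublet screen -> (mosaic classification) -> ASE -> dosage.

    Writes per-stage TSV outputs, a JSON report and a resolved copy of the
    configuration to ``config.output_dir``; identical configurations produce
    identical outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}

    def stage(name, **info):
        logger.info("stage %s: %s", name, info)
        report["stages"].append({"name": name, **info})

    sites, da_from_file = read_sites(config.sites_path)
    table = read_counts(config.counts_path, config.totals_path, sites)
    expression = read_expression(config.expression_path)
    stage("load", cells=len(table.cells()), sites=len(sites),
          genes=expression.shape[1])

    qc = ase_mod.qc_cells(expression, table.total_reads,
                          config.min_total_reads, config.min_expressed_fraction)
    keep = qc[qc].index
    table = table.subset_cells(keep)
    expression = expression.loc[keep]
    stage("qc", cells_in=len(qc), cells_out=len(keep))

    prof = x_profiles(table, sites, escapee_genes=config.escapee_genes)
    if prof.shape[1] > 0:
        det = XHaplotypeDoubletDetector(band=config.doublet_band)
        flags = det.fit_predict(prof)
        singlets = flags[~flags].index
        table = table.subset_cells(singlets)
        expression = expression.loc[singlets]
        flags.rename("is_doublet").to_frame().to_csv(
            out / "doublets.tsv", sep="\t", index_label="cell_id")
        stage("doublets", flagged=int(flags.sum()), cells_out=len(singlets))
    else:
        stage("doublets", skipped=True)

    if config.mosaic:
        clf = classify_mosaic(table, expression, sites,
                              config.supernumerary_chromosome,
                              max_iter=config.max_iter, seed=config.seed)
        labels = clf.labels_
        da_map = clf.double_allele_map_
        labels.to_frame().to_csv(out / "cell_labels.tsv", sep="\t",
                                 index_label="cell_id")
        da_map.rename("double_allele").to_frame().to_csv(
            out / "double_allele_map.tsv", sep="\t", index_label="site_id")
        stage("classify", converged=bool(clf.converged_), n_iter=clf.n_iter_,
              trisomic=int((labels == "trisomic").sum()),
              separable=bool(clf.separable_))
    else:
        labels = pd.Series("diploid", index=expression.index, name="label")
        da_map = da_from_file
        stage("classify", skipped=True)

    obs = ase_mod.compute_observations(
        table, sites, double_allele=da_map if len(da_map) else None,
        supernumerary_chromosome=(config.supernumerary_chromosome
                                  if len(da_map) else None),
        trisomic_cells=labels[labels == "trisomic"].index)
    obs_f = ase_mod.filter_observations(obs, config.min_coverage, config.min_rpsm)
    obs_f.to_csv(out / "ase_observations.tsv", sep="\t", index=False, na_rep=_NA)
    mep = ase_mod.compute_mep(obs_f, sites)
    mep.to_csv(out / "gene_mep.tsv", sep="\t", index=False, na_rep=_NA)
    stage("ase", observations_in=len(obs), observations_out=len(obs_f),
          genes_with_mep=len(mep))

    if (labels == "trisomic").any() and (labels == "diploid").any():
        summary = dosage_mod.decompose_genes(
            expression, labels,
            genes=[g for g in expression.columns
                   if g in set(sites.loc[sites["chrom"] ==
                               config.supernumerary_chromosome, "gene_id"])],
            mep_classes=mep.set_index("gene_id")["mep_class"] if len(mep) else None,
            min_cells=config.min_expressing_cells)
        summary.to_csv(out / "gene_dosage_summary.tsv", sep="\t", index=False,
                       na_rep=_NA)
        stage("dosage", genes=len(summary))
        report["dosage_medians"] = {
            "fc_bulk": float(summary["fc_bulk"].median()),
            "fc_sc": float(summary["fc_sc"].median()),
            "r_ratio": float(summary["r_ratio"].median()),
        } if len(summary) else {}
    else:
        stage("dosage", skipped=True)

    config.to_yaml(out / "resolved_config.yaml")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def simulate_to_dir(config: SimConfig, outdir) -> SimResult:
    """Run the simulator and write all tables (the `simulate` subcommand)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = simulate_population(config)
    write_counts(res.counts, outdir / "allele_counts.tsv", outdir / "cell_totals.tsv")
    write_sites(res.sites, outdir / "sites.vcf", double_allele=res.truth.double_allele)
    write_expression(res.expression, outdir / "expression.tsv")
    write_truth(res.truth, outdir / "truth.tsv")
    cfg = {f.name: getattr(config, f.name) for f in dataclasses.fields(config)}
    for k, v in cfg.items():
        if isinstance(v, tuple):
            cfg[k] = list(v)
    (outdir / "sim_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    return res
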
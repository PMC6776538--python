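"""Per-cell allele-specific expression (ASE), coverage filters and MEP classes.

ASE at a heterozygous site is the fraction of reads supporting a designated
allele: the REF allele in diploid regions, and the double allele (the allele
present in two copies, DA) on the supernumerary chromosome of trisomic cells.
Observations are guarded against allele dropout by requiring a minimum site
coverage (default 16 reads) and a minimum RPSM — reads per site per million
mapped reads — of 20.  ASE <= 0.1 is called monoallelic for the ALT/single
allele, ASE >= 0.9 monoallelic for the REF/double allele, and everything
strictly in between biallelic.

A gene's monoallelic expression prevalence (MEP) is the fraction of cells
with a monoallelic call at the gene's most-observed heterozygous site; genes
are classed monoallelic (MEP > 0.8), intermediate (0.2-0.8) or biallelic
(MEP < 0.2).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import AlleleCounts

logger = logging.getLogger(__name__)

__all__ = [
    "compute_rpsm",
    "ase_diploid",
    "ase_trisomic",
    "classify_ase",
    "compute_observations",
    "filter_observations",
    "compute_mep",
    "classify_gene_mep",
    "ase_histogram_summary",
    "qc_cells",
]

ASE_LOW = 0.1
ASE_HIGH = 0.9


def compute_rpsm(site_reads, total_mapped_reads):
    """Reads per site per million mapped reads: ``reads / total * 1e6``."""
    site_reads = np.asarray(site_reads, dtype=float)
    total = np.asarray(total_mapped_reads, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total mapped reads must be > 0")
    return site_reads / total * 1e6


def _ratio(num, den_other, what):
    num = np.asarray(num, dtype=float)
    den_other = np.asarray(den_other, dtype=float)
    tot = num + den_other
    if np.any(tot <= 0):
        raise ValueError(f"{what}: site has zero total reads; observation must be "
                         "dropped, not scored")
    return num / tot


def ase_diploid(ref_reads, alt_reads):
    """Diploid-fraction ASE: reference reads over total reads."""
    return _ratio(ref_reads, alt_reads, "ase_diploid")


def ase_trisomic(da_reads, sa_reads):
    """Trisomic-fraction ASE: double-allele reads over total reads."""
    return _ratio(da_reads, sa_reads, "ase_trisomic")


def classify_ase(ase):
    """Partition ASE values into monoallelic_low / biallelic / monoallelic_high.

    Boundaries are inclusive for the monoallelic calls (ASE <= 0.1 and
    ASE >= 0.9); the biallelic class is the open interval between them.
    """
    a = np.asarray(ase, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("ASE values must lie in [0, 1]")
    out = np.where(a <= ASE_LOW, "monoallelic_low",
                   np.where(a >= ASE_HIGH, "monoallelic_high", "biallelic"))
    if np.isscalar(ase):
        return str(out)
    return out


def compute_observations(table: AlleleCounts, sites: pd.DataFrame,
                         double_allele: pd.Series | None = None,
                         supernumerary_chromosome: str | None = None,
                         trisomic_cells=None) -> pd.DataFrame:
    """Build the per cell x site ASE observation table.

    Sites on ``supernumerary_chromosome`` observed in ``trisomic_cells`` are
    oriented to the double allele given by ``double_allele`` (site_id ->
    {"ref", "alt"}); all other observations use the reference-allele
    orientation.  Zero-coverage pairs are absent from the input by
    construction and never imputed.
    """
    obs = table.counts.merge(sites[["site_id", "chrom", "gene_id"]], on="site_id",
                             how="left", validate="many_to_one")
    if obs["chrom"].isna().any():
        unknown = obs.loc[obs["chrom"].isna(), "site_id"].unique()[:5]
        raise ValueError(f"counts reference unknown site ids, e.g. {list(unknown)}")
    cov = obs["ref_reads"] + obs["alt_reads"]
    obs = obs.loc[cov > 0].copy()
    cov = obs["ref_reads"] + obs["alt_reads"]

    ref_frac = obs["ref_reads"] / cov
    ase = ref_frac.to_numpy().copy()
    if supernumerary_chromosome is not None and double_allele is not None:
        on_super = (obs["chrom"] == supernumerary_chromosome).to_numpy()
        if trisomic_cells is not None:
            on_super &= obs["cell_id"].isin(pd.Index(trisomic_cells)).to_numpy()
        da = obs["site_id"].map(double_allele)
        known = da.notna().to_numpy()
        flip = on_super & known & (da == "alt").to_numpy()
        ase[flip] = 1.0 - ase[flip]
        missing = on_super & ~known
        if missing.any():
            raise ValueError("double allele unknown for supernumerary site(s) "
                             f"{sorted(obs.loc[missing, 'site_id'].unique())[:5]}")

    totals = obs["cell_id"].map(table.total_reads)
    out = pd.DataFrame({
        "cell_id": obs["cell_id"].to_numpy(),
        "site_id": obs["site_id"].to_numpy(),
        "gene_id": obs["gene_id"].to_numpy(),
        "chrom": obs["chrom"].to_numpy(),
        "ase": ase,
        "coverage": cov.to_numpy(),
        "rpsm": compute_rpsm(cov.to_numpy(), totals.to_numpy()),
    })
    return out.reset_index(drop=True)


def filter_observations(obs: pd.DataFrame, min_coverage: int = 16,
                        min_rpsm: float = 20.0) -> pd.DataFrame:
    """Keep observations with coverage >= min_coverage and RPSM >= min_rpsm."""
    keep = (obs["coverage"] >= min_coverage) & (obs["rpsm"] >= min_rpsm)
    return obs.loc[keep].reset_index(drop=True)


def compute_mep(obs: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Per-gene monoallelic expression prevalence at the most-observed site.

    For every gene the heterozygous site with the highest number of cellular
    ASE observations is chosen (ties broken to the lowest genomic position);
    MEP is the fraction of that site's cells whose ASE is monoallelic.
    Genes with no qualifying site are skipped with a logged reason.
    """
    if obs.empty:
        return pd.DataFrame(columns=["gene_id", "mep", "n_cells_observed",
                                     "mep_class", "chosen_site"])
    pos = sites.set_index("site_id")["pos"]
    per_site = (obs.groupby(["gene_id", "site_id"], sort=False)
                .size().rename("n_obs").reset_index())
    per_site["pos"] = per_site["site_id"].map(pos)
    per_site = per_site.sort_values(["gene_id", "n_obs", "pos"],
                                    ascending=[True, False, True])
    chosen = per_site.drop_duplicates("gene_id", keep="first")

    mono = (obs["ase"] <= ASE_LOW) | (obs["ase"] >= ASE_HIGH)
    rows = []
    for gene, site in zip(chosen["gene_id"], chosen["site_id"]):
        m = (obs["gene_id"] == gene) & (obs["site_id"] == site)
        n = int(m.sum())
        if n == 0:                      # pragma: no cover - guarded upstream
            logger.info("gene %s skipped: no qualifying site", gene)
            continue
        mep = float(mono[m].mean())
        rows.append((gene, mep, n, classify_gene_mep(mep), site))
    return pd.DataFrame(rows, columns=["gene_id", "mep", "n_cells_observed",
                                       "mep_class", "chosen_site"])


def classify_gene_mep(mep: float) -> str:
    """MEP > 0.8 -> monoallelic; MEP < 0.2 -> biallelic; else intermediate."""
    if not (0.0 <= mep <= 1.0):
        raise ValueError(f"MEP must be in [0, 1], got {mep}")
    if mep > 0.8:
        return "monoallelic"
    if mep < 0.2:
        return "biallelic"
    return "intermediate"


def ase_histogram_summary(obs: pd.DataFrame) -> dict:
    """Summary of an ASE observation histogram.

    Returns the monoallelic fraction and its split into the high band
    (ASE >= 0.9: REF/double allele only) and low band (ASE <= 0.1: ALT/single
    allele only), plus the mean of the biallelic observations
    (0.1 < ASE < 0.9; ``None`` when there are none).
    """
    if obs.empty:
        raise ValueError("no ASE observations to summarise")
    a = obs["ase"].to_numpy()
    hi = a >= ASE_HIGH
    lo = a <= ASE_LOW
    bi = ~hi & ~lo
    return {
        "n_observations": int(a.size),
        "fraction_monoallelic": float((hi | lo).mean()),
        "fraction_da_monoallelic": float(hi.mean()),
        "fraction_sa_monoallelic": float(lo.mean()),
        "mean_biallelic_ase": float(a[bi].mean()) if bi.any() else None,
    }


def qc_cells(expression: pd.DataFrame, total_reads: pd.Series,
             min_total_reads: float = 1e6,
             min_expressed_fraction: float = 0.10) -> pd.Series:
    """Cell-level QC: enough mapped reads and enough expressed genes.

    Returns a boolean Series over cells; a cell passes when its total mapped
    reads reach ``min_total_reads`` and at least ``min_expressed_fraction``
    of the gene panel has nonzero expression.
    """
    frac_expressed = (expression > 0).mean(axis=1)
    total = total_reads.reindex(expression.index)
    passed = (total >= min_total_reads) & (frac_expressed >= min_expressed_fraction)
    n_fail = int((~passed).sum())
    if n_fail:
        logger.info("cell QC removed %d of %d cells", n_fail, len(passed))
    return passed.rename("qc_pass")
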
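"""Doublet detection from X-chromosome haplotype expression (female samples).

In female cells X inactivation makes each cell express one X haplotype
essentially exclusively, so the per-cell vector of reference-allele ratios at
heterozygous X sites (outside the pseudoautosomal regions and known escapee
genes) is close to one of two complementary binary patterns.  Two singlets
therefore correlate near +1 (same haplotype) or -1 (opposite haplotype),
while a chamber that captured two cells of opposite haplotype mixes both
patterns and its profile decorrelates from both haplotype groups.  Cells
whose median absolute correlation to both groups falls below the singlet
level are flagged as doublets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .simulate import AlleleCounts

logger = logging.getLogger(__name__)

__all__ = [
    "PAR1",
    "PAR2",
    "x_profiles",
    "XHaplotypeDoubletDetector",
    "detect_doublets",
]

# GRCh37 pseudoautosomal regions (1-based inclusive).
PAR1 = (60_001, 2_699_520)
PAR2 = (154_931_044, 155_260_560)


def x_profiles(table: AlleleCounts, sites: pd.DataFrame,
               escapee_genes=(), par_regions=(PAR1, PAR2),
               x_chromosome: str = "chrX") -> pd.DataFrame:
    """Per-cell X-haplotype expression profiles (cells x sites, ref fraction).

    Pseudoautosomal sites and sites in escapee genes are excluded a priori;
    uncovered sites are missing (NaN), never imputed.  Returns an empty frame
    when the sample has no informative X sites (male or X-homozygous sample).
    """
    x = sites[sites["chrom"] == x_chromosome].copy()
    for lo, hi in par_regions:
        x = x[(x["pos"] < lo) | (x["pos"] > hi)]
    if escapee_genes:
        x = x[~x["gene_id"].isin(set(escapee_genes))]
    if x.empty:
        logger.info("no informative X sites: doublet screen is a no-op")
        return pd.DataFrame(index=table.cells())
    c = table.counts
    sub = c[c["site_id"].isin(x["site_id"])].copy()
    cov = sub["ref_reads"] + sub["alt_reads"]
    sub = sub[cov > 0]
    sub["ratio"] = sub["ref_reads"] / (sub["ref_reads"] + sub["alt_reads"])
    prof = sub.pivot_table(index="cell_id", columns="site_id", values="ratio")
    return prof.reindex(table.cells())


class XHaplotypeDoubletDetector(BaseEstimator):
    """Flag doublets by pairwise correlation of X-haplotype profiles.

    Pairwise Pearson correlations are computed on shared covered sites (at
    least ``min_shared_sites`` per pair), the cells are split into the two
    haplotype groups by average-linkage hierarchical clustering on
    correlation distance, and a cell is flagged when its median absolute
    correlation to *both* groups lies inside ``band`` (singlets sit near 1 to
    both groups, so the default band is everything at or below 0.75).

    Attributes (after ``fit``)
    --------------------------
    flags_ : boolean Series over cells (True = doublet).
    correlations_ : cells x cells Pearson correlation DataFrame.
    groups_ : Series assigning each cell to haplotype group 1 or 2.
    informative_ : boolean Series, False for cells excluded from the screen.
    """

    def __init__(self, band: tuple[float, float] = (0.0, 0.75),
                 min_shared_sites: int = 10):
        self.band = band
        self.min_shared_sites = min_shared_sites

    def fit(self, profiles: pd.DataFrame, y=None):
        cells = profiles.index
        self.flags_ = pd.Series(False, index=cells, name="is_doublet")
        n_sites_per_cell = profiles.notna().sum(axis=1) if profiles.shape[1] else \
            pd.Series(0, index=cells)
        self.informative_ = n_sites_per_cell > 0
        if profiles.shape[1] == 0 or len(cells) < 3:
            logger.info("doublet screen skipped (needs X sites and >= 3 cells)")
            self.groups_ = pd.Series(0, index=cells, name="haplotype_group")
            self.correlations_ = pd.DataFrame(np.nan, index=cells, columns=cells)
            return self
        if (~self.informative_).any():
            logger.warning("%d cells lack informative X sites and are excluded "
                           "from the doublet screen",
                           int((~self.informative_).sum()))

        P = profiles.to_numpy(dtype=float)
        n = len(cells)
        C = np.full((n, n), np.nan)
        valid = ~np.isnan(P)
        for i in range(n):
            for j in range(i + 1, n):
                m = valid[i] & valid[j]
                if m.sum() < self.min_shared_sites:
                    continue
                xi, xj = P[i, m], P[j, m]
                if xi.std() == 0 or xj.std() == 0:
                    continue
                C[i, j] = C[j, i] = np.corrcoef(xi, xj)[0, 1]
        self.correlations_ = pd.DataFrame(C, index=cells, columns=cells)

        # correlation-distance average-linkage split into the 2 haplotype groups
        D = 1.0 - np.where(np.isnan(C), 0.0, C)
        np.fill_diagonal(D, 0.0)
        D = (D + D.T) / 2.0
        Z = linkage(squareform(D, checks=False), method="average")
        groups = fcluster(Z, t=2, criterion="maxclust")
        self.groups_ = pd.Series(groups, index=cells, name="haplotype_group")
        if len(np.unique(groups)) < 2:
            logger.info("profiles form a single cluster; no doublets flagged")
            return self

        lo, hi = self.band
        absC = np.abs(C)
        for i in range(n):
            if not self.informative_.iloc[i]:
                continue
            meds = []
            for g in (1, 2):
                mask = (groups == g)
                mask[i] = False
                vals = absC[i, mask]
                vals = vals[~np.isnan(vals)]
                if vals.size == 0:
                    break
                meds.append(np.median(vals))
            if len(meds) == 2 and all(lo <= m <= hi for m in meds):
                self.flags_.iloc[i] = True
        return self

    def fit_predict(self, profiles: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(profiles).flags_


def detect_doublets(table: AlleleCounts, sites: pd.DataFrame, escapee_genes=(),
                    band: tuple[float, float] = (0.0, 0.75),
                    min_shared_sites: int = 10) -> pd.Series:
    """Convenience wrapper: build X profiles and flag doublets."""
    prof = x_profiles(table, sites, escapee_genes=escapee_genes)
    det = XHaplotypeDoubletDetector(band=band, min_shared_sites=min_shared_sites)
    return det.fit_predict(prof)
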
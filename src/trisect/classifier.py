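"""Diploid/trisomic cell classification in mosaic populations.

Cells are clustered by iterated 2-means on two per-cell features measured on
the supernumerary chromosome only: the mean min-max-normalised gene
expression, and the mean ASE.  The double allele at each heterozygous site is
unknown at the start, so the first ASE feature uses the folded magnitude
``0.5 + |ASE_ref - 0.5|``; after every clustering round the double allele of
each site is re-estimated as the allele with the larger summed read count
across currently-trisomic cells, the ASE feature is re-oriented to it, and
the cells are re-clustered.  The loop stops when no cell changes label (or an
exact period-2 oscillation is detected).  The cluster whose centroid has the
larger feature sum is called trisomic, which makes the assignment invariant
to cluster-id permutation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold

from . import ase as ase_mod
from .simulate import AlleleCounts

logger = logging.getLogger(__name__)

__all__ = [
    "MosaicTrisomyClassifier",
    "estimate_double_allele",
    "classify_mosaic",
    "cross_validate",
]


def estimate_double_allele(table: AlleleCounts, sites: pd.DataFrame,
                           trisomic_cells, supernumerary_chromosome: str,
                           previous: pd.Series | None = None) -> pd.Series:
    """Per-site double-allele estimate from currently-trisomic cells.

    The allele with the greater summed read count across trisomic-labelled
    cells is taken as doubled; exact ties keep the previous assignment (ref
    if there is none), and sites with zero reads in trisomic cells keep their
    previous/unknown state.
    """
    trisomic_cells = pd.Index(trisomic_cells)
    if len(trisomic_cells) == 0:
        raise ValueError("double-allele estimation requires >= 1 trisomic cell")
    super_sites = sites.loc[sites["chrom"] == supernumerary_chromosome, "site_id"]
    c = table.counts
    sub = c[c["cell_id"].isin(trisomic_cells) & c["site_id"].isin(super_sites)]
    sums = sub.groupby("site_id")[["ref_reads", "alt_reads"]].sum()

    out = {}
    for site in super_sites:
        prev = previous.get(site) if previous is not None else None
        if site not in sums.index or sums.loc[site].sum() == 0:
            if prev is not None:
                out[site] = prev
            continue
        r, a = sums.loc[site, "ref_reads"], sums.loc[site, "alt_reads"]
        if r > a:
            out[site] = "ref"
        elif a > r:
            out[site] = "alt"
        else:
            out[site] = prev if prev is not None else "ref"
    return pd.Series(out, name="double_allele", dtype=object)


class MosaicTrisomyClassifier(BaseEstimator, ClassifierMixin):
    """Iterated 2-means classifier of diploid vs trisomic cells.

    Parameters
    ----------
    supernumerary_chromosome : str
        Chromosome whose genes/sites provide the features.
    max_iter : int
        Maximum alternations of clustering and double-allele estimation.
    min_coverage, min_rpsm : thresholds for the ASE observations feeding the
        ASE feature (allele-dropout guard).
    min_separation : float
        Minimum Euclidean distance between the two cluster centroids in
        z-scored feature space; below it the population is declared
        non-separable and every cell is left diploid.  A forced 2-means
        split of a single (unstructured) Gaussian cloud yields a centroid
        distance of about 2*sqrt(2/pi) ~ 1.6 along the dominant axis, so
        the default of 2.0 rejects clusterings no stronger than noise.
    random_state : int
        Seed for k-means++ initialisation (deterministic fit).

    Attributes (after ``fit``)
    --------------------------
    labels_ : pd.Series mapping cell_id to {"diploid", "trisomic"}.
    double_allele_map_ : pd.Series mapping supernumerary site_id to {"ref","alt"}.
    converged_, n_iter_, separable_ : convergence diagnostics.
    feature_matrix_ : per-cell (expr_feature, ase_feature) DataFrame.
    label_changes_ : list of per-iteration label-change counts.
    """

    def __init__(self, supernumerary_chromosome: str = "chr21", max_iter: int = 100,
                 min_coverage: int = 16, min_rpsm: float = 20.0,
                 min_separation: float = 2.0, random_state: int = 0):
        self.supernumerary_chromosome = supernumerary_chromosome
        self.max_iter = max_iter
        self.min_coverage = min_coverage
        self.min_rpsm = min_rpsm
        self.min_separation = min_separation
        self.random_state = random_state

    # ---- feature construction -------------------------------------------------

    def _super_genes(self, sites: pd.DataFrame) -> pd.Index:
        g = sites.loc[sites["chrom"] == self.supernumerary_chromosome, "gene_id"]
        return pd.Index(g.unique())

    def _expression_feature(self, expression: pd.DataFrame, genes: pd.Index,
                            fit_range: bool) -> pd.Series:
        sub = expression[genes.intersection(expression.columns)]
        if fit_range:
            self.gene_min_ = sub.min(axis=0)
            self.gene_max_ = sub.max(axis=0)
        rng_ = (self.gene_max_ - self.gene_min_).replace(0, np.nan)
        norm = ((sub - self.gene_min_) / rng_).clip(0.0, 1.0)
        return norm.mean(axis=1, skipna=True).fillna(0.0)

    def _ase_feature(self, obs: pd.DataFrame, cells: pd.Index,
                     da_map: pd.Series | None) -> pd.Series:
        sup = obs[obs["chrom"] == self.supernumerary_chromosome]
        if da_map is None:
            val = 0.5 + (sup["ase"] - 0.5).abs()   # orientation-free magnitude
        else:
            da = sup["site_id"].map(da_map)
            val = sup["ase"].where(da != "alt", 1.0 - sup["ase"])
            val = val[da.notna()]
            sup = sup.loc[val.index]
        feat = val.groupby(sup["cell_id"]).mean()
        feat = feat.reindex(cells)
        self.ase_fallback_cells_ = pd.Index(feat.index[feat.isna()])
        if len(self.ase_fallback_cells_) == len(cells):
            raise ValueError("no supernumerary ASE data for any cell")
        return feat.fillna(feat.mean())

    def _features(self, table, expression, obs, cells, genes, da_map,
                  fit_range: bool) -> pd.DataFrame:
        f1 = self._expression_feature(expression.loc[cells], genes, fit_range)
        f2 = self._ase_feature(obs[obs["cell_id"].isin(cells)], cells, da_map)
        return pd.DataFrame({"expr_feature": f1, "ase_feature": f2}, index=cells)

    # ---- fitting --------------------------------------------------------------

    def fit(self, table: AlleleCounts, expression: pd.DataFrame,
            sites: pd.DataFrame, y=None):
        cells = expression.index
        if len(cells) < 2:
            raise ValueError("need at least 2 cells")
        genes = self._super_genes(sites)
        if len(genes.intersection(expression.columns)) == 0:
            raise ValueError("no supernumerary genes with expression data")
        obs = ase_mod.compute_observations(table, sites)
        obs = ase_mod.filter_observations(obs, self.min_coverage, self.min_rpsm)

        km = KMeans(n_clusters=2, n_init=10, random_state=self.random_state)
        da_map: pd.Series | None = None
        labels = None
        history: list[tuple] = []
        self.label_changes_ = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            feats = self._features(table, expression, obs, cells, genes, da_map,
                                   fit_range=(it == 1))
            # z-score both features so neither scale dominates the metric
            mu = feats.mean(axis=0).to_numpy()
            sd = feats.std(axis=0).replace(0, 1.0).to_numpy()
            self.feature_center_, self.feature_scale_ = mu, sd
            X = (feats.to_numpy() - mu) / sd
            assign = km.fit_predict(X)
            centroids = km.cluster_centers_
            trisomic_cluster = int(np.argmax(centroids.sum(axis=1)))
            self.feature_matrix_ = feats
            self.centroids_ = centroids
            self._trisomic_cluster = trisomic_cluster
            new_labels = pd.Series(
                np.where(assign == trisomic_cluster, "trisomic", "diploid"),
                index=cells)
            if labels is not None:
                changes = int((new_labels != labels).sum())
                self.label_changes_.append(changes)
                if changes == 0:
                    labels = new_labels
                    converged = True
                    break
            key = tuple(new_labels.to_numpy())
            if len(history) >= 2 and key == history[-2]:
                labels = new_labels          # period-2 oscillation guard
                converged = True
                logger.warning("label oscillation with period 2; stopping")
                break
            history.append(key)
            labels = new_labels
            tri_cells = cells[labels == "trisomic"]
            if len(tri_cells) == 0:
                converged = True
                break
            da_map = estimate_double_allele(table, sites, tri_cells,
                                            self.supernumerary_chromosome,
                                            previous=da_map)
        else:
            logger.warning("no label stability within max_iter=%d", self.max_iter)

        self.n_iter_ = it
        self.converged_ = converged
        separation = float(np.linalg.norm(self.centroids_[0] - self.centroids_[1]))
        self.separation_ = separation
        self.separable_ = separation >= self.min_separation
        if not self.separable_:
            logger.warning("centroid separation %.4f below %.4f: population "
                           "declared non-separable; all cells kept diploid",
                           separation, self.min_separation)
            labels = pd.Series("diploid", index=cells)
        self.labels_ = labels.rename("label")
        if da_map is None:
            da_map = pd.Series(dtype=object, name="double_allele")
        self.double_allele_map_ = da_map
        self.sites_ = sites
        return self

    def fit_predict(self, table, expression, sites, y=None) -> pd.Series:
        return self.fit(table, expression, sites).labels_

    def predict(self, table: AlleleCounts, expression: pd.DataFrame) -> pd.Series:
        """Label new cells by nearest fitted centroid.

        Features are built with the training min-max ranges and the fitted
        double-allele map, so held-out cells never influence the model.
        """
        if not hasattr(self, "centroids_"):
            raise ValueError("classifier is not fitted")
        cells = expression.index
        genes = self._super_genes(self.sites_)
        obs = ase_mod.compute_observations(table, self.sites_)
        obs = ase_mod.filter_observations(obs, self.min_coverage, self.min_rpsm)
        da = self.double_allele_map_ if len(self.double_allele_map_) else None
        feats = self._features(table, expression, obs, cells, genes, da,
                               fit_range=False)
        X = (feats.to_numpy() - self.feature_center_) / self.feature_scale_
        d = ((X[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        assign = d.argmin(axis=1)
        return pd.Series(np.where(assign == self._trisomic_cluster,
                                  "trisomic", "diploid"),
                         index=cells, name="label")


def classify_mosaic(table: AlleleCounts, expression: pd.DataFrame,
                    sites: pd.DataFrame, supernumerary_chromosome: str = "chr21",
                    max_iter: int = 100, seed: int = 0) -> MosaicTrisomyClassifier:
    """Fit and return a :class:`MosaicTrisomyClassifier` on one population."""
    clf = MosaicTrisomyClassifier(
        supernumerary_chromosome=supernumerary_chromosome,
        max_iter=max_iter, random_state=seed)
    return clf.fit(table, expression, sites)


def cross_validate(table: AlleleCounts, expression: pd.DataFrame,
                   sites: pd.DataFrame, truth_labels: pd.Series,
                   supernumerary_chromosome: str = "chr21",
                   n_folds: int = 5, seed: int = 0) -> float:
    """Mean held-out accuracy of the mosaic classifier under stratified CV.

    Per fold the classifier is fitted on the training cells only (the
    double-allele map and feature ranges are estimated there) and applied to
    the held-out cells; accuracy is measured against the provided truth.
    """
    cells = expression.index
    y = truth_labels.reindex(cells)
    if y.isna().any():
        raise ValueError("truth labels missing for some cells")
    if y.value_counts().min() < n_folds:
        raise ValueError("each class needs at least n_folds cells for "
                         "stratified folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(np.zeros(len(cells)), y.to_numpy()):
        train_cells, test_cells = cells[train_idx], cells[test_idx]
        clf = MosaicTrisomyClassifier(
            supernumerary_chromosome=supernumerary_chromosome, random_state=seed)
        clf.fit(table.subset_cells(train_cells), expression.loc[train_cells], sites)
        pred = clf.predict(table.subset_cells(test_cells),
                           expression.loc[test_cells])
        accs.append(float((pred == y.loc[test_cells]).mean()))
    return float(np.mean(accs))
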
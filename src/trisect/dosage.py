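"""Decomposition of gene dosage imbalance into its single-cell components.

For a gene with ``k`` copies the population mean expression factorises as
``E(s_k) = R_k * sbar_k`` where ``R_k`` is the fraction of cells expressing
the gene and ``sbar_k`` the zero-truncated mean among expressing cells.  The
bulk fold change of a triplicated gene therefore obeys

    fc_bulk = E(s_3)/E(s_2) = (R_3/R_2) * (sbar_3/sbar_2) = 3/2,

an exact bookkeeping identity per gene and, under independent bursty alleles,
an expectation of 1.5 for the bulk ratio.  Low-expressed genes realise the
imbalance mostly through the fraction of expressing cells (R_3/R_2 > 1,
fc_sc ~ 1) while highly expressed genes realise it per cell
(fc_sc ~ 1.5, R_3/R_2 ~ 1); the two ratios are inversely related along the
hyperbola r_ratio = 1.5 / fc_sc.

Closed forms used as oracles throughout: with per-allele zero probability
``p0 = (1/(1+b))**f``, ``R_k = 1 - p0**k`` and ``sbar_k = k*f*b / (1-p0**k)``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "expected_zero_probability",
    "expected_fraction_expressing",
    "expected_truncated_mean",
    "is_expressed",
    "fraction_expressing",
    "fold_changes",
    "classify_dosage",
    "classify_expression_level",
    "decompose_genes",
    "compare_fractions",
    "hyperbola_fit",
    "stratify_by_expression",
]

EXPRESSION_CLASS_BOUNDS = (3.0, 15.0)     # FPKM-scale low/medium/high boundaries
DOSAGE_SENSITIVE_FC = 1.2
DOSAGE_INSENSITIVE_BAND = (0.8, 1.2)


# ---- closed-form oracles ------------------------------------------------------

def expected_zero_probability(f: float, b: float) -> float:
    """Per-allele zero probability ``(1/(1+b))**f`` of the NB burst law."""
    return (1.0 / (1.0 + b)) ** f


def expected_fraction_expressing(f: float, b: float, k: int) -> float:
    """``R_k = 1 - p0**k`` for a gene with k independent alleles."""
    return 1.0 - expected_zero_probability(f, b) ** k


def expected_truncated_mean(f: float, b: float, k: int) -> float:
    """Zero-truncated mean ``sbar_k = k*f*b / (1 - p0**k)``."""
    return k * f * b / expected_fraction_expressing(f, b, k)


# ---- expressing-cell bookkeeping ---------------------------------------------

def is_expressed(obs: pd.DataFrame, min_cells: int = 10, min_rpsm: float = 20.0,
                 mode: str = "c1", min_reads: int = 5, min_cells_droplet: int = 50
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cell expressing flags and per-gene usability from ASE observations.

    ``mode="c1"`` (deep full-length data): a cell expresses the gene when its
    site observation has RPSM >= ``min_rpsm``; the gene is usable when at
    least ``min_cells`` cells express it.  ``mode="droplet"``: a cell counts
    with more than ``min_reads`` reads and a gene needs more than
    ``min_cells_droplet`` expressing cells.
    """
    if mode == "c1":
        flags = obs.loc[obs["rpsm"] >= min_rpsm, ["cell_id", "gene_id"]]
        need = min_cells
        cmp_ge = True
    elif mode == "droplet":
        flags = obs.loc[obs["coverage"] > min_reads, ["cell_id", "gene_id"]]
        need = min_cells_droplet
        cmp_ge = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    flags = flags.drop_duplicates()
    n_per_gene = flags.groupby("gene_id").size()
    usable = n_per_gene >= need if cmp_ge else n_per_gene > need
    return flags, usable.rename("usable")


def fraction_expressing(expressing: np.ndarray) -> float:
    """R_k: expressing cells over all QC-passed cells of one ploidy."""
    expressing = np.asarray(expressing, dtype=bool)
    if expressing.size == 0:
        raise ValueError("no cells of this ploidy")
    return float(expressing.mean())


def _gene_stats(values: np.ndarray, expressing: np.ndarray):
    """(mean over all cells, R, zero-truncated mean) with values outside the
    expressing mask treated as not expressed (zeroed)."""
    v = np.where(expressing, values, 0.0)
    r = fraction_expressing(expressing)
    mean_all = float(v.mean())
    sbar = float(v[expressing].mean()) if expressing.any() else np.nan
    return mean_all, r, sbar


def fold_changes(diploid_values, trisomic_values, diploid_expressing=None,
                 trisomic_expressing=None) -> dict:
    """Bulk and single-cell fold changes plus R_2, R_3 for one gene.

    ``fc_bulk`` is the ratio of means over *all* cells (zeros included);
    ``fc_sc`` the ratio of zero-truncated means over expressing cells only.
    The expressing masks default to ``value > 0``; values outside the mask
    are treated as noise and excluded from both numerators, which makes the
    identity ``fc_bulk = (R_3/R_2) * fc_sc`` exact.
    """
    d = np.asarray(diploid_values, dtype=float)
    t = np.asarray(trisomic_values, dtype=float)
    de = d > 0 if diploid_expressing is None else np.asarray(diploid_expressing, bool)
    te = t > 0 if trisomic_expressing is None else np.asarray(trisomic_expressing, bool)
    mean2, r2, sbar2 = _gene_stats(d, de)
    mean3, r3, sbar3 = _gene_stats(t, te)
    if mean2 == 0 or not de.any():
        return {"fc_bulk": np.nan, "fc_sc": np.nan, "r2": r2, "r3": r3,
                "r_ratio": np.nan, "diploid_mean": mean2, "trisomic_mean": mean3,
                "flagged": True}
    return {
        "fc_bulk": mean3 / mean2,
        "fc_sc": sbar3 / sbar2 if te.any() else np.nan,
        "r2": r2,
        "r3": r3,
        "r_ratio": r3 / r2,
        "diploid_mean": mean2,
        "trisomic_mean": mean3,
        "flagged": False,
    }


def classify_dosage(fc: float, sensitive_threshold: float = DOSAGE_SENSITIVE_FC,
                    insensitive_band: tuple[float, float] = DOSAGE_INSENSITIVE_BAND
                    ) -> str:
    """fc > 1.2 -> sensitive; 0.8 < fc < 1.2 -> insensitive; else other."""
    if not (fc > 0):
        raise ValueError(f"fold change must be > 0, got {fc}")
    if fc > sensitive_threshold:
        return "sensitive"
    lo, hi = insensitive_band
    if lo < fc < hi:
        return "insensitive"
    return "other"


def classify_expression_level(mean_expression: float,
                              bounds: tuple[float, float] = EXPRESSION_CLASS_BOUNDS
                              ) -> str:
    lo, hi = bounds
    if mean_expression < lo:
        return "low"
    if mean_expression > hi:
        return "high"
    return "medium"


def decompose_genes(expression: pd.DataFrame, labels: pd.Series,
                    genes=None, expressing: pd.DataFrame | None = None,
                    mep_classes: pd.Series | None = None,
                    min_cells: int = 10) -> pd.DataFrame:
    """Per-gene dosage summary table over a labelled cell population.

    Parameters
    ----------
    expression : cells x genes matrix (counts, FPKM or normalised UMIs).
    labels : per-cell {"diploid", "trisomic"}.
    expressing : optional boolean cells x genes mask overriding the default
        value > 0 rule (e.g. the RPSM-based site rule).
    mep_classes : optional gene -> MEP class mapping carried into the output.
    min_cells : minimum expressing cells (both ploidies pooled) for a gene to
        be usable.
    """
    labels = labels.reindex(expression.index)
    dip = labels == "diploid"
    tri = labels == "trisomic"
    if not dip.any() or not tri.any():
        raise ValueError("need both diploid and trisomic cells")
    gene_list = list(genes) if genes is not None else list(expression.columns)
    rows = []
    for g in gene_list:
        v = expression[g].to_numpy(dtype=float)
        mask = (expression[g] > 0).to_numpy() if expressing is None \
            else expressing[g].reindex(expression.index).fillna(False).to_numpy()
        n_expr = int(mask.sum())
        if n_expr < min_cells:
            logger.debug("gene %s excluded: %d expressing cells", g, n_expr)
            continue
        res = fold_changes(v[dip.to_numpy()], v[tri.to_numpy()],
                           mask[dip.to_numpy()], mask[tri.to_numpy()])
        dmean = v[dip.to_numpy()].mean()
        row = {"gene_id": g, **res,
               "expression_class": classify_expression_level(dmean),
               "dosage_class": (classify_dosage(res["fc_sc"])
                                if np.isfinite(res.get("fc_sc", np.nan)) and
                                res["fc_sc"] > 0 else "other"),
               "n_expressing": n_expr}
        if mep_classes is not None:
            row["mep_class"] = mep_classes.get(g)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_fractions(r2, r3) -> dict:
    """Paired two-sided Wilcoxon signed-rank test on per-gene (R2, R3).

    Exact null distribution for n <= 25 pairs (after the standard discard of
    zero differences), normal approximation with continuity correction above.
    All-zero differences return p = 1 with a warning.
    """
    r2 = np.asarray(r2, dtype=float)
    r3 = np.asarray(r3, dtype=float)
    if r2.shape != r3.shape:
        raise ValueError("R2 and R3 must be paired")
    if r2.size < 6:
        raise ValueError("need at least 6 gene pairs")
    diffs = r3 - r2
    nonzero = diffs != 0
    n = int(nonzero.sum())
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return {"statistic": 0.0, "pvalue": 1.0, "n": 0}
    method = "exact" if n <= 25 else "approx"
    res = stats.wilcoxon(r3, r2, zero_method="wilcox", correction=(method == "approx"),
                         alternative="two-sided", method=method)
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue), "n": n}


def hyperbola_fit(summary: pd.DataFrame, k: int = 3) -> dict:
    """Spearman association of log(R3/R2) with log(fc_sc) and the model curve.

    The model predicts ``r_ratio = (k/2) / fc_sc``; the returned dict carries
    the Spearman rho and p-value on the log scale plus the predicted
    ``r_ratio`` for every gene's observed ``fc_sc``.
    """
    sub = summary.dropna(subset=["r_ratio", "fc_sc"])
    sub = sub[(sub["r_ratio"] > 0) & (sub["fc_sc"] > 0)]
    if len(sub) < 10:
        raise ValueError("need >= 10 usable genes for the hyperbola fit")
    x = np.log(sub["fc_sc"].to_numpy())
    y = np.log(sub["r_ratio"].to_numpy())
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("degenerate (constant) fold-change input")
    rho, p = stats.spearmanr(x, y)
    return {
        "rho": float(rho),
        "pvalue": float(p),
        "n": int(len(sub)),
        "predicted_r_ratio": (k / 2.0) / sub["fc_sc"],
    }


def stratify_by_expression(summary: pd.DataFrame) -> dict:
    """Medians of r_ratio and fc_sc per expression class + pairwise tests.

    Classes use the diploid-mean boundaries (<3 low, 3-15 medium, >15 high);
    pairwise comparisons are two-sided Mann-Whitney U on r_ratio.  Empty
    classes are reported absent.
    """
    out: dict = {"classes": {}, "tests": {}}
    groups = {}
    for cls in ("low", "medium", "high"):
        sub = summary[summary["expression_class"] == cls].dropna(subset=["r_ratio"])
        if sub.empty:
            continue
        groups[cls] = sub
        out["classes"][cls] = {
            "n": int(len(sub)),
            "median_r_ratio": float(sub["r_ratio"].median()),
            "median_fc_sc": float(sub["fc_sc"].median()),
        }
    names = list(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, bname = names[i], names[j]
            u = stats.mannwhitneyu(groups[a]["r_ratio"], groups[bname]["r_ratio"],
                                   alternative="two-sided")
            out["tests"][f"{a}_vs_{bname}"] = {"U": float(u.statistic),
                                               "pvalue": float(u.pvalue)}
    return out
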
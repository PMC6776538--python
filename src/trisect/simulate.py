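"""Synthetic single-cell allele-level count data with known ground truth.

The generator emulates the statistical structure that the downstream analysis
assumes: every allele of a gene transcribes independently in bursts, so that
steady-state transcript counts per allele follow a negative binomial with
shape equal to the burst frequency ``f`` (bursts per mRNA lifetime) and mean
``f*b`` where ``b`` is the mean burst size.  A gene on the supernumerary
chromosome of a trisomic cell carries three such alleles, two of which are
copies of the same parental allele (the "double allele"); everywhere else a
cell carries two.  Sequencing is emulated as per-transcript Bernoulli capture
followed by multinomial allocation of site reads, which keeps every
population-level quantity analytically tractable (a thinned negative binomial
is again negative binomial).

All randomness flows from ``SimConfig.rng_seed`` through a fixed
``numpy.random.SeedSequence`` spawning scheme (one child stream per stage:
gene parameters, transcript counts, read sampling, X haplotypes, doublets),
so identical configurations reproduce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BurstParams",
    "SimConfig",
    "TruthTable",
    "AlleleCounts",
    "SimResult",
    "simulate_allele_counts",
    "simulate_site_reads",
    "simulate_population",
    "inject_doublets",
]

# Non-pseudoautosomal window used when placing synthetic X sites (GRCh37).
_X_SAFE_START = 3_000_000
_X_SAFE_STEP = 1_000_000


@dataclass(frozen=True)
class BurstParams:
    """Two-state promoter parameters in the non-overlapping-burst regime.

    Parameters
    ----------
    burst_frequency : float
        Bursts per mRNA lifetime (``f``), > 0.
    burst_size : float
        Mean transcripts produced per burst (``b``), > 0.

    In this regime per-allele transcript counts are negative binomial with
    shape ``f`` and mean ``f*b``; the per-allele probability of observing
    zero transcripts is ``p0 = (1/(1+b))**f``.
    """

    burst_frequency: float
    burst_size: float

    def __post_init__(self) -> None:
        if not (self.burst_frequency > 0):
            raise ValueError(f"burst_frequency must be > 0, got {self.burst_frequency}")
        if not (self.burst_size > 0):
            raise ValueError(f"burst_size must be > 0, got {self.burst_size}")

    @property
    def mean_expression(self) -> float:
        """Expected transcripts per allele, ``f*b``."""
        return self.burst_frequency * self.burst_size

    @property
    def zero_probability(self) -> float:
        """Per-allele probability of zero transcripts, ``(1/(1+b))**f``."""
        return (1.0 / (1.0 + self.burst_size)) ** self.burst_frequency


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic mosaic population.

    ``burst_frequency_range`` / ``burst_size_range`` parameterise the
    log-uniform sampler used to draw per-gene ``(f, b)``; defaults span the
    low-to-high expression spectrum.  ``depth_dispersion`` is the log-normal
    sigma of the per-cell sequencing-depth factor (library-size variability).
    """

    n_genes: int = 100
    n_cells_diploid: int = 158
    n_cells_trisomic: int = 158
    supernumerary_chromosome: str = "chr21"
    n_genes_control: int = 0
    control_chromosome: str = "chr1"
    n_sites_x: int = 0
    burst_frequency_range: tuple[float, float] = (0.05, 5.0)
    burst_size_range: tuple[float, float] = (2.0, 50.0)
    mean_site_depth: float = 30.0
    capture_efficiency: float = 0.3
    depth_dispersion: float = 0.5
    doublet_rate: float = 0.0
    total_mapped_reads: int = 1_000_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells_diploid", "n_cells_trisomic",
                     "n_genes_control", "n_sites_x"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.capture_efficiency <= 1.0):
            raise ValueError("capture_efficiency must be in (0, 1]")
        if not (0.0 <= self.doublet_rate < 1.0):
            raise ValueError("doublet_rate must be in [0, 1)")
        if self.n_genes == 0:
            raise ValueError("gene panel is empty (n_genes == 0)")


@dataclass
class TruthTable:
    """Ground truth for every simulated cell and supernumerary site."""

    cell_labels: pd.Series          # cell_id -> {"diploid", "trisomic", "doublet"}
    double_allele: pd.Series        # site_id -> {"ref", "alt"} (supernumerary sites)
    x_haplotype: pd.Series          # cell_id -> {"A", "B"} (singlets only)
    doublet_parents: dict[str, tuple[str, str]] = field(default_factory=dict)


@dataclass
class AlleleCounts:
    """Per (cell, site) allele-supporting read counts.

    ``counts`` has columns ``cell_id, site_id, ref_reads, alt_reads`` with one
    row per covered cell x site; ``total_reads`` maps each cell to its total
    mapped read count (the RPSM denominator).
    """

    counts: pd.DataFrame
    total_reads: pd.Series

    def cells(self) -> pd.Index:
        return self.total_reads.index

    def subset_cells(self, cell_ids) -> "AlleleCounts":
        cell_ids = pd.Index(cell_ids)
        mask = self.counts["cell_id"].isin(cell_ids)
        return AlleleCounts(
            counts=self.counts.loc[mask].reset_index(drop=True),
            total_reads=self.total_reads.loc[cell_ids],
        )


@dataclass
class SimResult:
    counts: AlleleCounts
    expression: pd.DataFrame        # cells x genes, transcript totals
    sites: pd.DataFrame             # site_id, chrom, pos, ref, alt, gene_id
    truth: TruthTable
    gene_params: pd.DataFrame       # gene_id, burst_frequency, burst_size


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_allele_counts(params: BurstParams, n_alleles: int, n_cells: int,
                           seed) -> np.ndarray:
    """Independent per-allele negative-binomial transcript counts.

    Returns an ``(n_cells, n_alleles)`` integer array; every allele is an
    independent draw from NB(shape=f, mean=f*b), so the expected cell total is
    ``n_alleles * f * b``.
    """
    if n_alleles not in (1, 2, 3):
        raise ValueError(f"n_alleles must be 1, 2 or 3, got {n_alleles}")
    rng = _as_rng(seed)
    p = 1.0 / (1.0 + params.burst_size)
    return rng.negative_binomial(params.burst_frequency, p,
                                 size=(n_cells, n_alleles))


def simulate_site_reads(allele_transcripts: np.ndarray, depth, capture_efficiency: float,
                        seed) -> np.ndarray:
    """Sample per-allele reads at one heterozygous site.

    Each transcript is retained independently with ``capture_efficiency``
    (allele dropout); the site's total read count is Poisson with the given
    expected ``depth`` (scalar or per-cell array) whenever at least one
    transcript survives, and reads are allocated to alleles multinomially in
    proportion to retained transcript counts.
    """
    rng = _as_rng(seed)
    t = np.atleast_2d(np.asarray(allele_transcripts, dtype=np.int64))
    if np.any(np.asarray(depth) < 0):
        raise ValueError("depth must be >= 0")
    retained = rng.binomial(t, capture_efficiency)
    tot = retained.sum(axis=1)
    expressed = tot > 0
    n_reads = np.where(expressed, rng.poisson(np.broadcast_to(depth, tot.shape)), 0)
    reads = _multinomial_rows(rng, n_reads, retained, tot)
    if np.asarray(allele_transcripts).ndim == 1:
        return reads[0]
    return reads


def _multinomial_rows(rng: np.random.Generator, n: np.ndarray, weights: np.ndarray,
                      wsum: np.ndarray) -> np.ndarray:
    """Row-wise multinomial via sequential conditional binomials (vectorised)."""
    n_rows, k = weights.shape
    out = np.zeros((n_rows, k), dtype=np.int64)
    remaining_n = n.astype(np.int64).copy()
    remaining_w = wsum.astype(np.float64).copy()
    for j in range(k - 1):
        w = weights[:, j].astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(remaining_w > 0, w / remaining_w, 0.0)
        draw = rng.binomial(remaining_n, np.clip(p, 0.0, 1.0))
        out[:, j] = draw
        remaining_n -= draw
        remaining_w -= w
    out[:, k - 1] = remaining_n
    return out


def _sample_gene_params(rng: np.random.Generator, n: int,
                        f_range: tuple[float, float],
                        b_range: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    f = np.exp(rng.uniform(np.log(f_range[0]), np.log(f_range[1]), n))
    b = np.exp(rng.uniform(np.log(b_range[0]), np.log(b_range[1]), n))
    return f, b


def simulate_population(config: SimConfig) -> SimResult:
    """Simulate a mosaic diploid/trisomic population with ground truth.

    Trisomic cells carry three alleles for every gene on the supernumerary
    chromosome (the doubled allele chosen uniformly per site and recorded in
    the truth table) and two alleles elsewhere; diploid cells carry two
    alleles everywhere.  Optional X-chromosome sites give every singlet a
    consistent monoallelically expressed X haplotype (female X inactivation),
    which is what the doublet screen keys on.  Doublets, if requested, are
    injected with :func:`inject_doublets`.
    """
    ss = np.random.SeedSequence(config.rng_seed)
    (ss_params, ss_counts, ss_reads, ss_x, ss_doublets) = ss.spawn(5)
    rng_params = np.random.default_rng(ss_params)
    rng_counts = np.random.default_rng(ss_counts)
    rng_reads = np.random.default_rng(ss_reads)
    rng_x = np.random.default_rng(ss_x)

    n_cells = config.n_cells_diploid + config.n_cells_trisomic
    cells = pd.Index([f"cell{i:04d}" for i in range(n_cells)], name="cell_id")
    ploidy = np.array(["diploid"] * config.n_cells_diploid +
                      ["trisomic"] * config.n_cells_trisomic)
    trisomic = ploidy == "trisomic"

    # --- gene panel (one heterozygous site per gene) ---
    n_main = config.n_genes + config.n_genes_control
    f, b = _sample_gene_params(rng_params, n_main, config.burst_frequency_range,
                               config.burst_size_range)
    gene_ids, chroms, positions = [], [], []
    for i in range(config.n_genes):
        gene_ids.append(f"g{config.supernumerary_chromosome.lstrip('chr')}_{i:04d}")
        chroms.append(config.supernumerary_chromosome)
        positions.append(1_000_000 + 10_000 * i)
    for i in range(config.n_genes_control):
        gene_ids.append(f"g{config.control_chromosome.lstrip('chr')}_{i:04d}")
        chroms.append(config.control_chromosome)
        positions.append(1_000_000 + 10_000 * i)

    bases = np.array(list("ACGT"))
    ref_idx = rng_params.integers(0, 4, n_main)
    alt_idx = (ref_idx + rng_params.integers(1, 4, n_main)) % 4
    sites = pd.DataFrame({
        "site_id": [f"s{i:04d}" for i in range(n_main)],
        "chrom": chroms,
        "pos": positions,
        "ref": bases[ref_idx],
        "alt": bases[alt_idx],
        "gene_id": gene_ids,
    })
    on_super = sites["chrom"].to_numpy() == config.supernumerary_chromosome
    double_is_ref = rng_params.random(n_main) < 0.5  # meaningful on supernumerary only

    depth_factor = np.exp(rng_reads.normal(0.0, config.depth_dispersion, n_cells))
    depth = config.mean_site_depth * depth_factor

    expr = np.zeros((n_cells, n_main), dtype=np.int64)
    rows_cell, rows_site, rows_ref, rows_alt = [], [], [], []
    cell_codes = np.arange(n_cells)

    for g in range(n_main):
        # transcripts: columns = (ref allele, alt allele, extra copy of DA)
        base = rng_counts.negative_binomial(f[g], 1.0 / (1.0 + b[g]), size=(n_cells, 3))
        if on_super[g]:
            base[~trisomic, 2] = 0      # diploid cells lack the third allele
        else:
            base[:, 2] = 0
        if double_is_ref[g]:
            t_ref = base[:, 0] + base[:, 2]
            t_alt = base[:, 1]
        else:
            t_ref = base[:, 0]
            t_alt = base[:, 1] + base[:, 2]
        expr[:, g] = t_ref + t_alt
        reads = simulate_site_reads(np.column_stack([t_ref, t_alt]), depth,
                                    config.capture_efficiency, rng_reads)
        covered = reads.sum(axis=1) > 0
        rows_cell.append(cell_codes[covered])
        rows_site.append(np.full(covered.sum(), g))
        rows_ref.append(reads[covered, 0])
        rows_alt.append(reads[covered, 1])

    # --- X-haplotype sites for the doublet screen ---
    x_hap = pd.Series(np.where(rng_x.random(n_cells) < 0.5, "A", "B"), index=cells)
    x_sites = None
    if config.n_sites_x > 0:
        nx = config.n_sites_x
        fx, bx = _sample_gene_params(rng_x, nx, config.burst_frequency_range,
                                     config.burst_size_range)
        phase_a_ref = rng_x.random(nx) < 0.5   # hapA carries the REF allele at site
        xref = rng_x.integers(0, 4, nx)
        xalt = (xref + rng_x.integers(1, 4, nx)) % 4
        x_sites = pd.DataFrame({
            "site_id": [f"x{i:04d}" for i in range(nx)],
            "chrom": "chrX",
            "pos": [_X_SAFE_START + _X_SAFE_STEP * i for i in range(nx)],
            "ref": bases[xref],
            "alt": bases[xalt],
            "gene_id": [f"gX_{i:04d}" for i in range(nx)],
        })
        hap_a = (x_hap.to_numpy() == "A")
        for s in range(nx):
            # only the active haplotype's allele transcribes
            t = rng_x.negative_binomial(fx[s], 1.0 / (1.0 + bx[s]), n_cells)
            active_is_ref = np.where(hap_a, phase_a_ref[s], ~phase_a_ref[s])
            t_ref = np.where(active_is_ref, t, 0)
            t_alt = np.where(active_is_ref, 0, t)
            reads = simulate_site_reads(np.column_stack([t_ref, t_alt]), depth,
                                        config.capture_efficiency, rng_reads)
            covered = reads.sum(axis=1) > 0
            rows_cell.append(cell_codes[covered])
            rows_site.append(np.full(covered.sum(), n_main + s))
            rows_ref.append(reads[covered, 0])
            rows_alt.append(reads[covered, 1])

    if x_sites is not None:
        sites = pd.concat([sites, x_sites], ignore_index=True)

    site_index = sites["site_id"].to_numpy()
    counts = pd.DataFrame({
        "cell_id": cells.to_numpy()[np.concatenate(rows_cell)],
        "site_id": site_index[np.concatenate(rows_site)],
        "ref_reads": np.concatenate(rows_ref),
        "alt_reads": np.concatenate(rows_alt),
    })

    total_reads = pd.Series(
        np.round(config.total_mapped_reads * depth_factor).astype(np.int64),
        index=cells, name="total_reads")

    truth = TruthTable(
        cell_labels=pd.Series(ploidy, index=cells, name="label"),
        double_allele=pd.Series(
            np.where(double_is_ref[on_super], "ref", "alt"),
            index=pd.Index(site_index[:n_main][on_super], name="site_id"),
            name="double_allele"),
        x_haplotype=x_hap.rename("x_haplotype"),
    )

    expression = pd.DataFrame(expr, index=cells, columns=gene_ids)
    table = AlleleCounts(counts=counts, total_reads=total_reads)
    gene_params = pd.DataFrame({"gene_id": gene_ids,
                                "burst_frequency": f, "burst_size": b})

    result = SimResult(counts=table, expression=expression, sites=sites,
                       truth=truth, gene_params=gene_params)
    if config.doublet_rate > 0:
        table2, truth2, expression2 = inject_doublets(
            result.counts, result.truth, config.doublet_rate,
            np.random.default_rng(ss_doublets), expression=result.expression)
        result = replace(result, counts=table2, truth=truth2, expression=expression2)
    return result


def inject_doublets(table: AlleleCounts, truth: TruthTable, rate: float, seed,
                    expression: pd.DataFrame | None = None):
    """Replace pairs of discordant-X-haplotype singlets by summed doublets.

    ``rate`` is the fraction of the final library that should be doublets.
    Each doublet's counts are the site-wise sum of two randomly chosen
    singlets with opposite X haplotypes; the two parents are consumed and the
    truth table updated (parents recorded for testing).
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"doublet rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return (table, truth, expression) if expression is not None else (table, truth)
    rng = _as_rng(seed)
    singlets = truth.cell_labels.index[truth.cell_labels != "doublet"]
    # n doublets such that doublets / (singlets - n) ~= rate
    n_doublets = int(round(rate * len(singlets) / (1.0 + 2.0 * rate)))
    hap = truth.x_haplotype
    pool_a = list(rng.permutation(singlets[hap.loc[singlets] == "A"]))
    pool_b = list(rng.permutation(singlets[hap.loc[singlets] == "B"]))
    n_doublets = min(n_doublets, len(pool_a), len(pool_b))

    counts = table.counts
    new_rows = []
    labels = truth.cell_labels.copy()
    total_reads = table.total_reads.copy()
    expr = expression.copy() if expression is not None else None
    parents: dict[str, tuple[str, str]] = dict(truth.doublet_parents)
    consumed = []
    for i in range(n_doublets):
        ca, cb = pool_a.pop(), pool_b.pop()
        did = f"doublet{i:03d}"
        pair = counts[counts["cell_id"].isin([ca, cb])]
        merged = (pair.groupby("site_id", as_index=False)[["ref_reads", "alt_reads"]]
                  .sum())
        merged.insert(0, "cell_id", did)
        new_rows.append(merged)
        total_reads[did] = table.total_reads[ca] + table.total_reads[cb]
        labels[did] = "doublet"
        parents[did] = (ca, cb)
        if expr is not None:
            expr.loc[did] = expr.loc[ca] + expr.loc[cb]
        consumed.extend([ca, cb])

    keep = ~counts["cell_id"].isin(consumed)
    counts = pd.concat([counts[keep]] + new_rows, ignore_index=True)
    labels = labels.drop(consumed)
    total_reads = total_reads.drop(consumed)
    x_hap = truth.x_haplotype.drop(consumed, errors="ignore")
    if expr is not None:
        expr = expr.drop(index=consumed)

    new_table = AlleleCounts(counts=counts, total_reads=total_reads)
    new_truth = TruthTable(cell_labels=labels, double_allele=truth.double_allele,
                           x_haplotype=x_hap, doublet_parents=parents)
    if expression is not None:
        return new_table, new_truth, expr
    return new_table, new_truth
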
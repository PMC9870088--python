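"""Best-SNP gene scoring and gene-set enrichment of GWAS associations.

The procedure follows the MAGENTA shape: every gene is scored by the most
significant SNP in a strand-oriented window around it (110 kb upstream /
40 kb downstream by default), the score is regressed on confounders that
mechanically inflate it (gene size, SNP count) and replaced by the residual
plus the grand mean, and a candidate gene set is tested for over-representation
above a percentile cutoff of the adjusted scores with both a hypergeometric
and a permutation p-value. LD- and recombination-based confounders of the
original method need external maps and are not modelled.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def map_snps_to_genes(
    gwas: pd.DataFrame,
    genome: pd.DataFrame,
    upstream_bp: int = 110_000,
    downstream_bp: int = 40_000,
) -> pd.DataFrame:
    """Long table (gene_id, snp_id, pos, pvalue) of SNPs in each gene's window.

    A SNP belongs to gene g iff it lies in [start − upstream, end + downstream)
    on the + strand and [start − downstream, end + upstream) on the − strand.
    A SNP may belong to several genes; no arbitration is applied.
    """
    pieces = []
    for chrom, snps in gwas.groupby("chrom"):
        genes = genome[genome["chrom"] == chrom]
        if genes.empty:
            continue
        snps = snps.sort_values("pos", kind="stable")
        pos = snps["pos"].to_numpy(np.int64)
        plus = genes["strand"].to_numpy() == "+"
        lo = np.where(plus, genes["start"] - upstream_bp, genes["start"] - downstream_bp)
        hi = np.where(plus, genes["end"] + downstream_bp, genes["end"] + upstream_bp)
        first = np.searchsorted(pos, lo, side="left")
        last = np.searchsorted(pos, hi, side="left")
        n_each = last - first
        if n_each.sum() == 0:
            continue
        take = np.concatenate([np.arange(f, l) for f, l in zip(first, last)])
        piece = snps.iloc[take][["snp_id", "pos", "pvalue"]].reset_index(drop=True)
        piece.insert(0, "gene_id", np.repeat(genes["gene_id"].to_numpy(), n_each))
        pieces.append(piece)
    if not pieces:
        return pd.DataFrame(columns=["gene_id", "snp_id", "pos", "pvalue"])
    return pd.concat(pieces, ignore_index=True)


def gene_score(snp_map: pd.DataFrame, genome: pd.DataFrame) -> pd.DataFrame:
    """Raw per-gene score: −log10 of the best (minimum) SNP p-value.

    Genes with no SNP in their window are absent from the table. Records the
    confounders used downstream: SNP count and gene size (end − start).
    """
    if snp_map.empty:
        raise ValueError("no SNP maps to any gene")
    grouped = snp_map.groupby("gene_id")["pvalue"]
    table = pd.DataFrame({"raw_score": -np.log10(grouped.min()), "n_snps": grouped.size()})
    sizes = genome.set_index("gene_id").eval("end - start")
    table["gene_size"] = sizes.reindex(table.index)
    return table


def adjust_scores(table: pd.DataFrame) -> pd.DataFrame:
    """OLS of raw_score on log10 gene size and log10 SNP count.

    adjusted_score = residual + grand mean, so the mean is preserved.
    Constant covariates are dropped (degenerate designs fall back gracefully);
    with no usable covariate the adjusted score equals the raw score.
    """
    table = table.copy()
    y = table["raw_score"].to_numpy(dtype=float)
    covs = [np.log10(table["gene_size"].to_numpy(dtype=float)), np.log10(table["n_snps"].to_numpy(dtype=float))]
    cols = [c for c in covs if np.ptp(c) > 1e-12]
    if not cols:
        table["adjusted_score"] = y
        return table
    X = np.column_stack([np.ones_like(y)] + cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    table["adjusted_score"] = resid + y.mean()
    return table


@dataclasses.dataclass
class EnrichmentResult:
    cutoff_percentile: float
    cutoff: float
    n_scored: int
    n_above: int
    n_set_scored: int
    observed_above: int
    expected_above: float
    hypergeom_p: float
    permutation_p: float | None
    leading_edge: list

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def enrichment_test(
    table: pd.DataFrame,
    gene_set,
    cutoff_percentile: float = 95.0,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Over-representation of ``gene_set`` above a percentile of adjusted scores.

    The cutoff is the ``cutoff_percentile``-th percentile (linear
    interpolation) of all adjusted scores; membership above the cutoff is
    strict (>). The hypergeometric p is the exact upper tail P(X >=
    observed); the permutation p draws random same-size gene sets from the
    scored genes with the add-one estimator. ``n_perm = 0`` skips the
    permutation (permutation_p = None).
    """
    if not 0 < cutoff_percentile < 100:
        raise ValueError("cutoff_percentile must be in (0, 100)")
    scores = table["adjusted_score"]
    in_set = scores.index.isin(set(gene_set))
    n_set = int(in_set.sum())
    if n_set == 0:
        raise ValueError("gene set has no overlap with scored genes")
    cutoff = float(np.percentile(scores.to_numpy(), cutoff_percentile))
    above = (scores.to_numpy() > cutoff)
    n_above = int(above.sum())
    observed = int((above & in_set).sum())
    m = len(scores)
    hyp_p = float(stats.hypergeom.sf(observed - 1, m, n_above, n_set))
    expected = n_set * n_above / m

    perm_p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            draw = rng.choice(m, size=n_set, replace=False)
            if int(above[draw].sum()) >= observed:
                hits += 1
        perm_p = (1 + hits) / (1 + n_perm)

    le = scores[above & in_set]
    leading_edge = sorted(le.index, key=lambda g: (-le[g], g))
    return EnrichmentResult(
        cutoff_percentile=float(cutoff_percentile),
        cutoff=cutoff,
        n_scored=m,
        n_above=n_above,
        n_set_scored=n_set,
        observed_above=observed,
        expected_above=float(expected),
        hypergeom_p=hyp_p,
        permutation_p=perm_p,
        leading_edge=leading_edge,
    )


def gene_level_fdr(table: pd.DataFrame, gene_set, fdr: float = 0.05):
    """Per-gene empirical p within the genome-wide score distribution, BH in the set.

    The empirical p of gene g is (1 + the number of scored genes *outside*
    the set with adjusted score >= g's) / N_scored — the upper-tail rank
    probability against the genome-wide null; a set gene holding the single
    highest score among N scored genes gets 1/N. Counting set members in
    their own tail would floor the i-th best set gene's p at i/N and make
    q < K/N unattainable for a K-gene set, so the reference tail is the
    complement. Benjamini–Hochberg is applied within the gene set only and
    the genes with q < ``fdr`` are returned sorted by ascending q then
    descending score.
    """
    scores = table["adjusted_score"]
    in_set = [g for g in scores.index if g in set(gene_set)]
    if not in_set:
        raise ValueError("gene set has no overlap with scored genes")
    n = len(scores)
    outside = np.sort(scores.drop(index=in_set).to_numpy())
    set_scores = scores.loc[in_set].to_numpy()
    # count of non-set scores >= s, via position in the ascending sort
    emp_p = (1 + len(outside) - np.searchsorted(outside, set_scores, side="left")) / n
    qvals = multipletests(emp_p, method="fdr_bh")[1]
    out = pd.DataFrame({"gene_id": in_set, "empirical_p": emp_p, "qvalue": qvals,
                        "adjusted_score": set_scores})
    out = out.sort_values(["qvalue", "adjusted_score", "gene_id"],
                          ascending=[True, False, True], kind="stable").reset_index(drop=True)
    passing = out.loc[out["qvalue"] < fdr, "gene_id"].tolist()
    return out, passing


def score_genes(gwas: pd.DataFrame, genome: pd.DataFrame,
                upstream_bp: int = 110_000, downstream_bp: int = 40_000) -> pd.DataFrame:
    """Convenience: map SNPs, score, adjust — the full gene-scoring path."""
    snp_map = map_snps_to_genes(gwas, genome, upstream_bp=upstream_bp, downstream_bp=downstream_bp)
    return adjust_scores(gene_score(snp_map, genome))
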
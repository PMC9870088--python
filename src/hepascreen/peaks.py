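"""Reproducible peaks, differential occupancy, and TSS-anchored gene assignment.

Coordinates are 0-based half-open. The pseudoreplicate filter keeps a peak of
the full set only if it overlaps a peak in *each* pseudoreplicate.
Differential occupancy is a documented negative-binomial exact test
(median-of-ratios normalization, moment dispersion shrunk toward the common
value, conditional two-sided test by doubling the smaller tail) — an
edgeR-style analysis without shelling out to R. Peaks are tied to the gene
with the nearest TSS within a radius, anchored at the summit when present and
at the interval midpoint otherwise.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def _check_sorted(peaks: pd.DataFrame, label: str) -> None:
    key = peaks[["chrom", "start"]]
    if not key.equals(key.sort_values(["chrom", "start"], kind="stable")):
        raise ValueError(f"peak set '{label}' is not sorted by (chrom, start)")


def _overlaps_any(
    starts: np.ndarray, ends: np.ndarray, other: pd.DataFrame, min_overlap_bp: int, reciprocal: float
) -> np.ndarray:
    """Boolean per query interval: overlaps >= threshold with any interval in `other`."""
    os, oe = other["start"].to_numpy(), other["end"].to_numpy()
    hit = np.zeros(len(starts), dtype=bool)
    chunk = max(1, 4_000_000 // max(1, len(os)))
    for lo in range(0, len(starts), chunk):
        s = starts[lo : lo + chunk, None]
        e = ends[lo : lo + chunk, None]
        ov = np.minimum(e, oe[None, :]) - np.maximum(s, os[None, :])
        ok = ov >= min_overlap_bp
        if reciprocal > 0:
            ok &= (ov >= reciprocal * (e - s)) & (ov >= reciprocal * (oe - os)[None, :])
        hit[lo : lo + chunk] = ok.any(axis=1)
    return hit


def reproducible_peaks(
    full: pd.DataFrame,
    pseudo_a: pd.DataFrame,
    pseudo_b: pd.DataFrame,
    min_overlap_bp: int = 1,
    reciprocal: float = 0.0,
) -> pd.DataFrame:
    """Peaks of ``full`` present (>= min_overlap_bp overlap) in both pseudoreplicates.

    Returns the qualifying rows of ``full`` with their original coordinates and
    order. ``reciprocal`` > 0 additionally requires that fraction of both peak
    lengths to overlap (off by default).
    """
    for df, label in [(full, "full"), (pseudo_a, "pseudo_a"), (pseudo_b, "pseudo_b")]:
        _check_sorted(df, label)
    keep = np.zeros(len(full), dtype=bool)
    for chrom, idx in full.groupby("chrom").indices.items():
        starts = full["start"].to_numpy()[idx]
        ends = full["end"].to_numpy()[idx]
        ok = np.ones(len(idx), dtype=bool)
        for pseudo in (pseudo_a, pseudo_b):
            sub = pseudo[pseudo["chrom"] == chrom]
            if sub.empty:
                ok[:] = False
                break
            ok &= _overlaps_any(starts, ends, sub, min_overlap_bp, reciprocal)
        keep[idx] = ok
    return full[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# differential occupancy


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over rows positive in every sample.

    Normalized by the median factor: rescaling one column then rescales every
    row's geometric mean by a common power, which the median cancels, so the
    normalized counts (and hence the exact test) are invariant to library-size
    changes of individual samples.
    """
    mat = counts.to_numpy(dtype=float)
    pos = (mat > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no peak has positive counts in every sample")
    logmat = np.log(mat[pos])
    logratio = logmat - logmat.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logratio, axis=0))
    sf /= np.median(sf)
    return pd.Series(sf, index=counts.columns)


def _group_sum_logpmf(j: np.ndarray, mean, group_dispersion) -> np.ndarray:
    """log pmf of a sum of NB counts: NB(mean, dispersion/n) -> Poisson as disp -> 0."""
    if np.ndim(group_dispersion) == 0:
        if group_dispersion < 1e-10:
            return stats.poisson.logpmf(j, mean)
        size = 1.0 / group_dispersion
        return stats.nbinom.logpmf(j, size, size / (size + mean))
    disp = np.maximum(np.asarray(group_dispersion, dtype=float), 1e-10)
    size = 1.0 / disp
    return stats.nbinom.logpmf(j, size, size / (size + mean))


def nb_exact_test(k_a, k_b, n_a: int, n_b: int, dispersion) -> np.ndarray:
    """Two-sided NB exact test of equal per-sample means, conditional on k_a + k_b.

    ``k_a``/``k_b`` are the (rounded, normalized) group total counts;
    ``dispersion`` is the per-sample NB dispersion (scalar or per-peak array).
    The sum of n iid NB(mu, phi) is NB(n·mu, phi/n); conditioning on the total
    gives the reference distribution, and the p-value doubles the smaller tail
    (capped at 1), the convention of edgeR's exact test.
    """
    k_a = np.atleast_1d(np.asarray(k_a, dtype=np.int64))
    k_b = np.atleast_1d(np.asarray(k_b, dtype=np.int64))
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), k_a.shape).copy()
    total = k_a + k_b
    f_a = n_a / (n_a + n_b)
    pvals = np.ones(len(k_a))
    nonzero = total > 0
    if not nonzero.any():
        return pvals
    t_max = int(total[nonzero].max())
    j = np.arange(t_max + 1)
    mu_a = (total[:, None] * f_a).astype(float)
    mu_b = (total[:, None] * (1 - f_a)).astype(float)
    logw = _group_sum_logpmf(j[None, :], mu_a, (disp / n_a)[:, None]) + _group_sum_logpmf(
        total[:, None] - j[None, :], mu_b, (disp / n_b)[:, None]
    )
    logw[j[None, :] > total[:, None]] = -np.inf
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    csum = np.cumsum(w, axis=1)
    rows = np.arange(len(k_a))
    lower = csum[rows, k_a]
    upper = 1.0 - np.where(k_a > 0, csum[rows, np.maximum(k_a - 1, 0)], 0.0)
    pvals = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    pvals[~nonzero] = 1.0
    return pvals


def differential_occupancy(
    counts: pd.DataFrame,
    conditions: pd.Series,
    fdr_threshold: float = 0.20,
) -> pd.DataFrame:
    """Per-peak differential occupancy between two conditions.

    Returns a table (peak, log2FC, pvalue, qvalue, significant). All-zero
    rows get p = 1 and log2FC = 0 by convention; q-values are
    Benjamini–Hochberg; significant means q < fdr_threshold.
    """
    conditions = conditions.reindex(counts.columns)
    if conditions.isna().any():
        raise ValueError("condition map does not cover all samples")
    groups = conditions.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 conditions, got {list(groups)}")
    cols_a = conditions.index[conditions == groups[0]]
    cols_b = conditions.index[conditions == groups[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each condition needs at least 2 samples")
    mat = counts.to_numpy()
    if not np.issubdtype(mat.dtype, np.integer):
        if not np.allclose(mat, np.rint(mat)):
            raise ValueError("counts must be integers")
        mat = np.rint(mat).astype(np.int64)

    sf = size_factors(counts)
    norm = mat / sf.to_numpy()[None, :]

    # moment dispersion from within-condition variation (so the estimate is not
    # inflated by the very group difference under test), shrunk 50/50 to the
    # common value
    ia = counts.columns.get_indexer(cols_a)
    ib = counts.columns.get_indexer(cols_b)
    mu = norm.mean(axis=1)
    ss_within = ((norm[:, ia] - norm[:, ia].mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (norm[:, ib] - norm[:, ib].mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    var_within = ss_within / (len(ia) + len(ib) - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mu > 0, np.maximum(0.0, (var_within - mu) / mu**2), 0.0)
    common = phi[mu > 0].mean() if (mu > 0).any() else 0.0
    # floor at the common value: with so few residual df the moment estimate
    # cannot establish below-ensemble dispersion, and letting it drop below
    # common manufactures far-tail false positives
    phi = np.maximum(1e-8, np.maximum(common, 0.5 * phi + 0.5 * common))

    k_a = np.rint(norm[:, ia].sum(axis=1)).astype(np.int64)
    k_b = np.rint(norm[:, ib].sum(axis=1)).astype(np.int64)
    pvals = nb_exact_test(k_a, k_b, len(ia), len(ib), phi)

    mean_a = norm[:, ia].mean(axis=1)
    mean_b = norm[:, ib].mean(axis=1)
    log2fc = np.log2(mean_b + 0.5) - np.log2(mean_a + 0.5)
    zero = mat.sum(axis=1) == 0
    pvals[zero] = 1.0
    log2fc[zero] = 0.0

    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "peak": counts.index,
            "log2FC": log2fc,
            "pvalue": pvals,
            "qvalue": qvals,
            "significant": qvals < fdr_threshold,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# peak -> gene assignment


def _tie_break_gene(tss: np.ndarray, gene_ids: np.ndarray, anchor: int, dist: int) -> int:
    """Index of the lexicographically smallest gene at exactly |anchor - tss| == dist."""
    cand = []
    for pos in {anchor - dist, anchor + dist}:
        lo = np.searchsorted(tss, pos, side="left")
        hi = np.searchsorted(tss, pos, side="right")
        cand.extend(range(lo, hi))
    return min(cand, key=lambda i: gene_ids[i])


def assign_peaks_to_genes(
    peaks: pd.DataFrame, genome: pd.DataFrame, radius_bp: int = 200_000
) -> pd.DataFrame:
    """Assign each peak to the gene with the nearest TSS within ``radius_bp``.

    The anchor is the summit when present, otherwise the interval midpoint
    (floor). Distances are strand-oriented: positive means the anchor lies
    downstream of the TSS in the gene's reading direction. ``edge_distance``
    is the minimum distance from any base of the peak interval to the TSS
    (0 when the TSS falls inside the peak) and is what the downstream
    candidate-gene window uses. Ties on |anchor − TSS| go to the
    lexicographically smallest gene id; peaks beyond the radius or on
    chromosomes absent from the annotation are dropped (counted in the log).
    """
    if "summit" in peaks.columns:
        anchors = peaks["summit"].where(peaks["summit"].notna(), (peaks["start"] + peaks["end"]) // 2)
    else:
        anchors = (peaks["start"] + peaks["end"]) // 2
    anchors = anchors.astype(np.int64)

    by_chrom = {}
    for chrom, sub in genome.groupby("chrom"):
        sub = sub.sort_values(["tss", "gene_id"], kind="stable")
        by_chrom[chrom] = (
            sub["tss"].to_numpy(np.int64),
            sub["gene_id"].to_numpy(),
            sub["strand"].to_numpy(),
        )

    rows = []
    n_unassigned = 0
    for peak, chrom, start, end, anchor in zip(
        peaks["name"], peaks["chrom"], peaks["start"], peaks["end"], anchors
    ):
        entry = by_chrom.get(chrom)
        if entry is None:
            n_unassigned += 1
            continue
        tss, gene_ids, strands = entry
        i = np.searchsorted(tss, anchor)
        best, best_dist = -1, None
        for cand in (i - 1, i):
            if 0 <= cand < len(tss):
                d = abs(int(anchor) - int(tss[cand]))
                if best_dist is None or d < best_dist:
                    best, best_dist = cand, d
        if best_dist is None or best_dist > radius_bp:
            n_unassigned += 1
            continue
        best = _tie_break_gene(tss, gene_ids, int(anchor), best_dist)
        t = int(tss[best])
        signed = int(anchor) - t
        if strands[best] == "-":
            signed = -signed
        if start <= t < end:
            edge = 0
        else:
            edge = min(abs(start - t), abs((end - 1) - t))
        rows.append(
            {
                "peak": peak,
                "gene_id": gene_ids[best],
                "distance": signed,
                "abs_distance": best_dist,
                "edge_distance": int(edge),
            }
        )
    if n_unassigned:
        logger.info("assign_peaks_to_genes: %d peaks unassigned", n_unassigned)
    return pd.DataFrame(rows, columns=["peak", "gene_id", "distance", "abs_distance", "edge_distance"])


def tss_distance_histogram(assignments: pd.DataFrame, bin_edges_bp) -> pd.Series:
    """Counts of |anchor − TSS| per left-closed right-open bin.

    Distances at or beyond the last edge are dropped (logged); with covering
    edges the counts sum to the number of assignments.
    """
    edges = np.asarray(bin_edges_bp, dtype=np.int64)
    if len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be increasing with at least two values")
    d = assignments["abs_distance"].to_numpy(np.int64) if len(assignments) else np.array([], dtype=np.int64)
    idx = np.searchsorted(edges, d, side="right") - 1
    inside = (idx >= 0) & (d < edges[-1])
    dropped = int((~inside).sum())
    if dropped:
        logger.info("tss_distance_histogram: %d distances outside bin range", dropped)
    counts = np.bincount(idx[inside], minlength=len(edges) - 1)[: len(edges) - 1]
    labels = [f"[{edges[i]},{edges[i + 1]})" for i in range(len(edges) - 1)]
    return pd.Series(counts, index=labels, name="count")


def candidate_gene_set(assignments: pd.DataFrame, tss_window_bp: int = 20_000) -> set:
    """Genes whose assigned peak interval comes within ``tss_window_bp`` of the TSS.

    Uses the peak-edge-to-TSS distance, so a wide peak whose edge reaches the
    window qualifies even when its anchor does not.
    """
    if len(assignments) == 0:
        return set()
    hit = assignments["edge_distance"] <= tss_window_bp
    return set(assignments.loc[hit, "gene_id"])


def map_orthologs(gene_set, ortholog_table: pd.DataFrame | dict | None = None) -> set:
    """Map a gene set into the target namespace.

    With a two-column table (source, target) unmapped genes are dropped and
    counted in the log; without a table, identity mapping up to upper-casing
    of symbols. Many-to-one mappings collapse to unique target ids.
    """
    gene_set = set(gene_set)
    if ortholog_table is None:
        return {str(g).upper() for g in gene_set}
    if isinstance(ortholog_table, pd.DataFrame):
        src, dst = ortholog_table.columns[:2]
        mapping = dict(zip(ortholog_table[src].astype(str), ortholog_table[dst].astype(str)))
    else:
        mapping = {str(k): str(v) for k, v in ortholog_table.items()}
    mapped = {mapping[g] for g in gene_set if g in mapping}
    n_lost = sum(g not in mapping for g in gene_set)
    if n_lost:
        logger.warning("map_orthologs: %d of %d genes had no ortholog", n_lost, len(gene_set))
    return mapped
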
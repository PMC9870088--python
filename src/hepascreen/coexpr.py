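"""Composite TF-activity scoring, correlation screen, and set enrichment.

The pipeline mirrors the human-liver corroboration step of the screen: keep
genes with mean raw expression strictly above a floor, log-transform
(ln(x + 1)) and z-score each gene across samples (population s.d.), average
the z-rows of a marker panel of validated TF targets into a composite
activity vector, correlate every gene with it, take the top fraction, and
test gene-set libraries on that query with Fisher's exact (hypergeometric)
p-values combined with a rank-deviation z into ``combined_score =
ln(p) × z`` — the Enrichr convention. Enrichr's precomputed rank lookup
tables are replaced by a seeded Monte-Carlo null of random same-size queries.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def preprocess(matrix: pd.DataFrame, expression_floor: float = 20.0) -> pd.DataFrame:
    """Filtered, log-transformed, row-z-scored expression matrix.

    Keeps genes whose raw row mean is strictly greater than
    ``expression_floor``, transforms kept rows by ln(x + 1), and z-scores each
    row with the population standard deviation. Zero-variance rows are dropped
    (counted in the log).
    """
    if matrix.empty:
        raise ValueError("expression matrix is empty")
    raw = matrix.to_numpy(dtype=float)
    keep = raw.mean(axis=1) > expression_floor
    if not keep.any():
        raise ValueError(f"no gene has mean expression > {expression_floor}")
    logx = np.log1p(raw[keep])
    mean = logx.mean(axis=1, keepdims=True)
    sd = logx.std(axis=1, ddof=0, keepdims=True)
    nonconst = sd[:, 0] > 0
    n_const = int((~nonconst).sum())
    if n_const:
        logger.info("preprocess: dropped %d zero-variance genes", n_const)
    z = (logx[nonconst] - mean[nonconst]) / sd[nonconst]
    return pd.DataFrame(z, index=matrix.index[keep][nonconst], columns=matrix.columns)


def composite_vector(z_matrix: pd.DataFrame, markers) -> pd.Series:
    """Per-sample mean of the marker genes' z-rows (the activity proxy)."""
    markers = list(markers)
    present = [m for m in markers if m in z_matrix.index]
    missing = [m for m in markers if m not in z_matrix.index]
    if missing:
        logger.warning("composite_vector: %d markers absent after filtering: %s",
                       len(missing), ",".join(missing))
    if not present:
        raise ValueError("no marker gene present in the filtered matrix")
    vec = z_matrix.loc[present].mean(axis=0)
    vec.attrs["markers_used"] = present
    return vec


def correlation_screen(z_matrix: pd.DataFrame, reference) -> pd.DataFrame:
    """Pearson r (and r²) of every gene's z-row against a reference.

    ``reference`` is either a per-sample vector (e.g. the composite) or a gene
    id, in which case that gene's own z-row is the reference and the gene is
    excluded from its own screen. Rows of ``z_matrix`` are already zero-mean
    unit-s.d., so r is an inner product with the standardized reference.
    """
    if z_matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation screen")
    exclude = None
    if isinstance(reference, str):
        if reference not in z_matrix.index:
            raise KeyError(f"reference gene {reference!r} not in matrix")
        exclude = reference
        ref = z_matrix.loc[reference].to_numpy(dtype=float)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (z_matrix.shape[1],):
            raise ValueError("reference length does not match sample count")
    ref = ref - ref.mean()
    sd = ref.std(ddof=0)
    if sd == 0:
        raise ValueError("reference vector is constant")
    ref = ref / sd
    r = z_matrix.to_numpy() @ ref / z_matrix.shape[1]
    out = pd.DataFrame({"r": r, "r2": r**2}, index=z_matrix.index)
    if exclude is not None:
        out = out.drop(index=exclude)
    return out


def top_fraction(screen_result: pd.DataFrame, fraction: float = 0.05) -> list:
    """The ceil(fraction × n) genes with the highest correlation.

    Ranks by descending r with ties broken by gene id, so the returned list is
    deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_take = math.ceil(fraction * len(screen_result))
    order = sorted(screen_result.index, key=lambda g: (-screen_result.at[g, "r"], g))
    return order[:n_take]


def _hypergeom_sf(overlap, n_bg: int, set_sizes, n_query: int):
    return stats.hypergeom.sf(np.asarray(overlap) - 1, n_bg, np.asarray(set_sizes), n_query)


def set_enrichment(
    query,
    library: dict,
    background,
    n_rank_null: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Library enrichment rows sorted by descending combined score.

    fisher_p is the exact upper-tail hypergeometric probability of the
    query/set overlap in the background universe; adjusted_p is BH across the
    library; rank_z is the deviation of the set's observed rank (by fisher_p,
    average ranks on ties) from its expected rank under ``n_rank_null`` random
    same-size queries, in null-s.d. units. combined_score = ln(fisher_p) ×
    rank_z, positive when a set is both enriched (ln p < 0) and ranked better
    than expected (rank_z < 0). Sets with no background overlap are omitted
    (logged); a degenerate null (zero rank s.d.) yields rank_z = 0.
    """
    background = sorted(set(background))
    bg_index = {g: i for i, g in enumerate(background)}
    query = set(query)
    if not query:
        raise ValueError("query gene set is empty")
    if not query <= set(background):
        raise ValueError("query must be a subset of the background universe")

    names, sets = [], []
    for name in library:
        inter = set(library[name]) & set(background)
        if not inter:
            logger.info("set_enrichment: %s has no background overlap, omitted", name)
            continue
        names.append(name)
        sets.append(inter)
    if not names:
        raise ValueError("no library set overlaps the background")

    n_bg, n_query = len(background), len(query)
    member = np.zeros((len(names), n_bg), dtype=np.int64)
    for i, s in enumerate(sets):
        member[i, [bg_index[g] for g in s]] = 1
    set_sizes = member.sum(axis=1)

    q_ind = np.zeros(n_bg, dtype=np.int64)
    q_ind[[bg_index[g] for g in query]] = 1
    overlap = member @ q_ind
    fisher_p = _hypergeom_sf(overlap, n_bg, set_sizes, n_query)
    adjusted_p = multipletests(fisher_p, method="fdr_bh")[1]
    obs_rank = stats.rankdata(fisher_p, method="average")

    rank_z = np.zeros(len(names))
    if n_rank_null > 0:
        rng = np.random.default_rng(seed)
        null_ranks = np.empty((n_rank_null, len(names)))
        for b in range(n_rank_null):
            draw = rng.choice(n_bg, size=n_query, replace=False)
            ind = np.zeros(n_bg, dtype=np.int64)
            ind[draw] = 1
            p_null = _hypergeom_sf(member @ ind, n_bg, set_sizes, n_query)
            null_ranks[b] = stats.rankdata(p_null, method="average")
        mu = null_ranks.mean(axis=0)
        sd = null_ranks.std(axis=0, ddof=0)
        ok = sd > 0
        rank_z[ok] = (obs_rank[ok] - mu[ok]) / sd[ok]

    # floor under the log: sf can underflow to exactly 0 for extreme overlaps
    combined = np.log(np.maximum(fisher_p, 1e-300)) * rank_z
    out = pd.DataFrame(
        {
            "set": names,
            "overlap": overlap.astype(int),
            "set_size": set_sizes.astype(int),
            "fisher_p": fisher_p,
            "adjusted_p": adjusted_p,
            "rank_z": rank_z,
            "combined_score": combined,
        }
    )
    return out.sort_values(["combined_score", "fisher_p", "set"],
                           ascending=[False, True, True], kind="stable").reset_index(drop=True)
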
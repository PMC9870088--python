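"""Synthetic multi-omic inputs with a planted, recoverable ground truth.

The generators emulate the statistical structure the hepatokine screen
assumes: replicate ChIP peak sets concentrated near the TSSs of a designated
target-gene set, GWAS summary statistics that are uniform-null except for an
association boost planted in that target set, an expression matrix driven by
a latent transcription-factor "activity" factor, and a secretome flag table
containing the planted gene. Every generator is a pure function of its
parameters and seed: repeated calls are byte-identical, and one global seed
fans out to fixed per-generator child streams so adding a generator never
perturbs earlier ones.

Defaults describe a desk-scale world: 2,000 genes on five 20-Mb chromosomes
(gene density comparable to a mammalian genome), a 100-gene target set with
one planted secreted hepatokine analog, ~2 background peaks per Mb (the
density implied by a few thousand genome-wide binding sites), 200 expression
samples, and log-scale expression noise of 0.5.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio

logger = logging.getLogger(__name__)

# fixed spawn keys: adding a generator appends a key, never renumbers
_STREAMS = {
    "genome": 0,
    "truth": 1,
    "peaks": 2,
    "gwas": 3,
    "expression": 4,
    "secretome": 5,
    "library": 6,
    "counts": 7,
}

# five 60-Mb chromosomes: 2,000 genes -> ~150 kb per gene, the human gene
# density the downstream SNP-to-gene windows are calibrated for
DEFAULT_CHROM_SIZES = {f"chr{i}": 60_000_000 for i in range(1, 6)}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-generator stream derived from one global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


class CapacityError(ValueError):
    """Requested genes do not fit on the given chromosomes."""


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth recorded alongside generated data.

    ``marker_loadings`` maps every gene with a nonzero expression loading to
    that loading; ``markers`` lists the genes used as the composite activity
    proxy (the analog of the validated TF target panel).
    """

    target_gene_set: set
    planted_hepatokine: str
    gwas_effect: float
    latent_activity: np.ndarray
    marker_loadings: dict
    markers: list
    seed: int

    def __post_init__(self):
        if self.planted_hepatokine not in self.target_gene_set:
            raise ValueError("planted hepatokine must belong to the target gene set")
        if self.gwas_effect < 0:
            raise ValueError("gwas_effect must be non-negative")
        self.latent_activity = np.asarray(self.latent_activity, dtype=float)
        self.latent_activity = self.latent_activity - self.latent_activity.mean()

    def to_dict(self) -> dict:
        return {
            "target_gene_set": sorted(self.target_gene_set),
            "planted_hepatokine": self.planted_hepatokine,
            "gwas_effect": self.gwas_effect,
            "latent_activity": self.latent_activity.tolist(),
            "marker_loadings": dict(sorted(self.marker_loadings.items())),
            "markers": list(self.markers),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            target_gene_set=set(d["target_gene_set"]),
            planted_hepatokine=d["planted_hepatokine"],
            gwas_effect=float(d["gwas_effect"]),
            latent_activity=np.asarray(d["latent_activity"], dtype=float),
            marker_loadings=dict(d["marker_loadings"]),
            markers=list(d["markers"]),
            seed=int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# genome


def generate_genome(
    n_genes: int = 2000,
    chrom_sizes: dict | None = None,
    min_gene_bp: int = 2_000,
    max_gene_bp: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Place ``n_genes`` non-overlapping genes uniformly on the chromosomes.

    Genes are allocated to chromosomes proportionally to size, lengths drawn
    uniformly in [min_gene_bp, max_gene_bp], strands Bernoulli(0.5). The TSS
    is ``start`` on the + strand and ``end - 1`` on the − strand.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if min_gene_bp < 1 or max_gene_bp < min_gene_bp:
        raise ValueError("need 1 <= min_gene_bp <= max_gene_bp")
    chrom_sizes = dict(chrom_sizes or DEFAULT_CHROM_SIZES)
    rng = child_rng(seed, "genome")

    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    # largest-remainder apportionment, deterministic
    quota = n_genes * sizes / sizes.sum()
    counts = np.floor(quota).astype(int)
    order = np.argsort(-(quota - counts), kind="stable")
    for i in order[: n_genes - counts.sum()]:
        counts[i] += 1

    records = []
    gid = 0
    width = max(4, len(str(n_genes)))
    for chrom, n_here in zip(chroms, counts):
        if n_here == 0:
            continue
        size = chrom_sizes[chrom]
        lengths = rng.integers(min_gene_bp, max_gene_bp + 1, size=n_here)
        free = size - int(lengths.sum())
        if free < 0:
            raise CapacityError(
                f"{chrom} ({size} bp) cannot hold {n_here} genes totalling {lengths.sum()} bp"
            )
        gaps = np.sort(rng.integers(0, free + 1, size=n_here))
        starts = gaps + np.concatenate([[0], np.cumsum(lengths[:-1])])
        strands = np.where(rng.random(n_here) < 0.5, "+", "-")
        for s, length, strand in zip(starts, lengths, strands):
            gid += 1
            start, end = int(s), int(s + length)
            records.append(
                {
                    "gene_id": f"G{gid:0{width}d}",
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "tss": start if strand == "+" else end - 1,
                }
            )
    genome = pd.DataFrame.from_records(records)
    genome.attrs["chrom_sizes"] = chrom_sizes
    return genome


def chrom_sizes_of(genome: pd.DataFrame) -> dict:
    sizes = genome.attrs.get("chrom_sizes")
    if sizes:
        return dict(sizes)
    return {c: int(g["end"].max()) + 50_000 for c, g in genome.groupby("chrom")}


# ---------------------------------------------------------------------------
# truth


def make_truth(
    genome: pd.DataFrame,
    n_target_genes: int = 100,
    n_markers: int = 5,
    n_coexpressed: int = 100,
    gwas_effect: float = 3.0,
    n_samples: int = 200,
    marker_loading: float = 1.0,
    hepatokine_loading: float = 0.8,
    coexpressed_loading: float = 0.6,
    seed: int = 0,
) -> SyntheticTruth:
    """Choose the target set, the planted hepatokine, markers and loadings.

    Markers are drawn from the target set (the real marker panel consists of
    validated TF targets); the planted hepatokine is a target-set member with
    a positive expression loading and a secreted flag downstream.
    """
    if n_target_genes < n_markers + 1:
        raise ValueError("target set must hold the markers plus the planted gene")
    rng = child_rng(seed, "truth")
    genes = genome["gene_id"].to_numpy()
    if n_target_genes > len(genes):
        raise ValueError("more target genes requested than genes in the genome")
    target = rng.choice(genes, size=n_target_genes, replace=False)
    planted = str(target[0])
    markers = [str(g) for g in target[1 : n_markers + 1]]
    rest = np.setdiff1d(genes, target, assume_unique=False)
    n_co = min(n_coexpressed, len(rest))
    coexpressed = rng.choice(rest, size=n_co, replace=False)

    loadings = {m: marker_loading for m in markers}
    loadings[planted] = hepatokine_loading
    loadings.update({str(g): coexpressed_loading for g in coexpressed})

    activity = rng.standard_normal(n_samples)
    return SyntheticTruth(
        target_gene_set=set(map(str, target)),
        planted_hepatokine=planted,
        gwas_effect=float(gwas_effect),
        latent_activity=activity,
        marker_loadings=loadings,
        markers=markers,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# peaks


@dataclasses.dataclass
class ReplicatePeaks:
    full: pd.DataFrame
    pseudo_a: pd.DataFrame
    pseudo_b: pd.DataFrame


@dataclasses.dataclass
class PeakSimulation:
    replicates: list
    consensus: pd.DataFrame  # union of per-replicate pseudoreplicate-reproducible peaks
    counts: pd.DataFrame  # consensus peaks x samples
    conditions: pd.Series  # sample -> condition


def _sort_peaks(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end", "name"], kind="stable").reset_index(drop=True)


def generate_peaks(
    genome: pd.DataFrame,
    truth: SyntheticTruth,
    n_replicates: int = 2,
    peak_width_bp: int = 400,
    near_tss_sd_bp: int = 100,
    background_rate: float = 2.0,
    dropout: float = 0.1,
    count_mean: float = 50.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> PeakSimulation:
    """Replicate peak sets with target-TSS peaks plus Poisson background.

    Each replicate gets one peak per target gene centered Normal(TSS,
    near_tss_sd_bp) plus background peaks at ``background_rate`` per Mb.
    Pseudoreplicates are copies of the replicate with independent Bernoulli
    dropout. Per-peak read counts (negative binomial, condition-independent
    means — a true null for the differential test) are generated over the
    union of per-replicate reproducible peaks, one water and one fructose
    sample per replicate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    from . import peaks as pk  # deferred: peaks does not import synthdata

    rng = child_rng(seed, "peaks")
    sizes = chrom_sizes_of(genome)
    targets = genome[genome["gene_id"].isin(truth.target_gene_set)]

    replicates = []
    for _ in range(n_replicates):
        rows = []
        centers = np.rint(rng.normal(targets["tss"].to_numpy(), near_tss_sd_bp)).astype(int)
        for chrom, center in zip(targets["chrom"], centers):
            start = max(0, int(center) - peak_width_bp // 2)
            rows.append((chrom, start, start + peak_width_bp, int(center)))
        for chrom, size in sizes.items():
            n_bg = rng.poisson(background_rate * size / 1e6)
            starts = rng.integers(0, max(1, size - peak_width_bp), size=n_bg)
            for s in starts:
                rows.append((chrom, int(s), int(s) + peak_width_bp, int(s) + peak_width_bp // 2))
        full = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit"])
        full["score"] = 0
        full["strand"] = "."
        full["name"] = ""
        full = _sort_peaks(full)
        full["name"] = [f"peak_{i + 1:06d}" for i in range(len(full))]
        full = full[["chrom", "start", "end", "name", "score", "strand", "summit"]]
        keep_a = rng.random(len(full)) >= dropout
        keep_b = rng.random(len(full)) >= dropout
        replicates.append(
            ReplicatePeaks(
                full=full,
                pseudo_a=full[keep_a].reset_index(drop=True),
                pseudo_b=full[keep_b].reset_index(drop=True),
            )
        )

    reproducible = [
        pk.reproducible_peaks(rep.full, rep.pseudo_a, rep.pseudo_b) for rep in replicates
    ]
    consensus = (
        pd.concat(reproducible, ignore_index=True)
        .drop_duplicates(subset=["chrom", "start", "end"])
        .pipe(_sort_peaks)
    )
    consensus["name"] = [f"cpeak_{i + 1:06d}" for i in range(len(consensus))]

    counts, conditions = generate_null_counts(
        n_peaks=len(consensus),
        n_per_condition=n_replicates,
        count_mean=count_mean,
        dispersion=dispersion,
        seed=seed,
        peak_names=consensus["name"].tolist(),
    )
    return PeakSimulation(replicates=replicates, consensus=consensus, counts=counts, conditions=conditions)


def generate_null_counts(
    n_peaks: int,
    n_per_condition: int = 2,
    count_mean: float = 50.0,
    dispersion: float = 0.1,
    seed: int = 0,
    peak_names: list | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """NB counts with condition-independent per-peak means (global null).

    Per-peak mean is log-normal around ``count_mean``; every sample of both
    conditions draws from the same NB(mean, dispersion), so any differential
    call is a false positive.
    """
    rng = child_rng(seed, "counts")
    if peak_names is None:
        peak_names = [f"peak_{i + 1:06d}" for i in range(n_peaks)]
    samples = [f"water_{r + 1}" for r in range(n_per_condition)] + [
        f"fructose_{r + 1}" for r in range(n_per_condition)
    ]
    mu = np.exp(rng.normal(np.log(count_mean), 0.5, size=n_peaks))
    size = 1.0 / dispersion if dispersion > 0 else None
    cols = {}
    for s in samples:
        if size is None:
            cols[s] = rng.poisson(mu)
        else:
            cols[s] = rng.negative_binomial(size, size / (size + mu))
    counts = pd.DataFrame(cols, index=pd.Index(peak_names, name="peak"))
    conditions = pd.Series(
        ["water"] * n_per_condition + ["fructose"] * n_per_condition,
        index=pd.Index(samples, name="sample"),
        name="condition",
    )
    return counts, conditions


# ---------------------------------------------------------------------------
# GWAS


def generate_gwas(
    genome: pd.DataFrame,
    truth: SyntheticTruth,
    snps_per_gene_mean: float = 3.0,
    flank_bp: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """SNPs scattered in and around genes, uniform-null p-values.

    SNP counts are Poisson with mean proportional to the gene's flanked span,
    so SNP count and gene size are genuine confounders of the best-SNP score.
    Each target gene's best SNP gets a −log10 p boost drawn Exp(mean =
    ``truth.gwas_effect``); the planted hepatokine's boost is deterministic at
    2 × gwas_effect so that ground-truth recovery measures the pipeline, not
    one exponential draw. At gwas_effect = 0 both boosts vanish and the table
    is exactly null.
    """
    if snps_per_gene_mean <= 0:
        raise ValueError("snps_per_gene_mean must be > 0")
    rng = child_rng(seed, "gwas")
    spans = (genome["end"] - genome["start"]).to_numpy() + 2 * flank_bp
    lam = snps_per_gene_mean * spans / spans.mean()
    n_snps = rng.poisson(lam)

    rows = []
    for (_, gene), k in zip(genome.iterrows(), n_snps):
        if gene["gene_id"] == truth.planted_hepatokine:
            # the planted locus must be genotyped to be a recoverable truth
            k = max(1, k)
        if k == 0:
            continue
        lo = max(0, gene["start"] - flank_bp)
        hi = gene["end"] + flank_bp
        pos = rng.integers(lo, hi, size=k)
        pval = 1.0 - rng.random(k)  # in (0, 1]
        if truth.gwas_effect > 0 and gene["gene_id"] in truth.target_gene_set:
            if gene["gene_id"] == truth.planted_hepatokine:
                boost = 2.0 * truth.gwas_effect
            else:
                boost = rng.exponential(truth.gwas_effect)
            best = int(np.argmin(pval))
            pval[best] = 10.0 ** (np.log10(pval[best]) - boost)
        for p, q in zip(pos, pval):
            rows.append((gene["chrom"], int(p), float(q)))

    gwas = pd.DataFrame(rows, columns=["chrom", "pos", "pvalue"])
    gwas = gwas.sort_values(["chrom", "pos", "pvalue"], kind="stable").reset_index(drop=True)
    gwas.insert(0, "snp_id", [f"snp_{i + 1:07d}" for i in range(len(gwas))])
    return gwas


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    genome: pd.DataFrame,
    truth: SyntheticTruth,
    n_samples: int = 200,
    noise_sd: float = 0.5,
    loaded_log_baseline: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Counts = round(exp(baseline + loading · activity + noise)).

    Genes with a loading in ``truth.marker_loadings`` share a high baseline
    (e^5 ≈ 148 counts, safely above the mean > 20 filter); all other genes get
    a log-uniform baseline spanning the filter threshold so the filter is
    exercised. The latent activity vector is the one stored in ``truth``.
    """
    if n_samples != len(truth.latent_activity):
        raise ValueError(
            f"n_samples={n_samples} does not match truth.latent_activity "
            f"(length {len(truth.latent_activity)})"
        )
    rng = child_rng(seed, "expression")
    genes = genome["gene_id"].to_numpy()
    loadings = np.array([truth.marker_loadings.get(g, 0.0) for g in genes])
    baseline = rng.uniform(np.log(2.0), np.log(400.0), size=len(genes))
    baseline[loadings != 0] = loaded_log_baseline
    log_mu = (
        baseline[:, None]
        + loadings[:, None] * truth.latent_activity[None, :]
        + rng.normal(0.0, noise_sd, size=(len(genes), n_samples))
    )
    counts = np.rint(np.exp(log_mu)).astype(np.int64)
    samples = [f"S{j + 1:04d}" for j in range(n_samples)]
    return pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)


# ---------------------------------------------------------------------------
# secretome


def generate_secretome(
    genome: pd.DataFrame,
    truth: SyntheticTruth,
    secreted_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag table: the planted hepatokine is secreted; others Bernoulli."""
    if not 0 <= secreted_fraction <= 1:
        raise ValueError("secreted_fraction must be in [0, 1]")
    rng = child_rng(seed, "secretome")
    genes = genome["gene_id"].to_numpy()
    flags = rng.random(len(genes)) < secreted_fraction
    table = pd.DataFrame({"gene_id": genes, "secreted": flags})
    table.loc[table["gene_id"] == truth.planted_hepatokine, "secreted"] = True
    return table


# ---------------------------------------------------------------------------
# gene-set library for the coexpression enrichment


def make_gene_set_library(
    genome: pd.DataFrame,
    truth: SyntheticTruth,
    n_decoys: int = 50,
    decoy_size: int = 100,
    seed: int = 0,
) -> dict:
    """One true activity-driven set plus random decoy sets of similar size."""
    rng = child_rng(seed, "library")
    true_set = set(truth.marker_loadings)  # markers + planted + coexpressed
    genes = genome["gene_id"].to_numpy()
    decoy_size = min(decoy_size, len(genes))
    library = {"activity_driven": true_set}
    for i in range(n_decoys):
        library[f"decoy_{i + 1:03d}"] = set(rng.choice(genes, size=decoy_size, replace=False))
    return library


# ---------------------------------------------------------------------------
# whole workspace


def simulate_workspace(
    outdir,
    seed: int = 0,
    n_genes: int = 2000,
    chrom_sizes: dict | None = None,
    n_target_genes: int = 100,
    gwas_effect: float = 3.0,
    n_samples: int = 200,
    noise_sd: float = 0.5,
    n_replicates: int = 2,
    background_rate: float = 2.0,
    secreted_fraction: float = 0.1,
    snps_per_gene_mean: float = 3.0,
    n_perm: int = 10_000,
) -> dict:
    """Generate every screen input under ``outdir`` plus a ready config.

    Returns a dict of the written paths. The truth sidecar makes the planted
    ground truth recoverable by tests and demos.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(n_genes=n_genes, chrom_sizes=chrom_sizes, seed=seed)
    truth = make_truth(
        genome, n_target_genes=n_target_genes, gwas_effect=gwas_effect, n_samples=n_samples, seed=seed
    )
    sim = generate_peaks(
        genome, truth, n_replicates=n_replicates, background_rate=background_rate, seed=seed
    )
    gwas = generate_gwas(genome, truth, snps_per_gene_mean=snps_per_gene_mean, seed=seed)
    expr = generate_expression(genome, truth, n_samples=n_samples, noise_sd=noise_sd, seed=seed)
    secretome = generate_secretome(genome, truth, secreted_fraction=secreted_fraction, seed=seed)
    library = make_gene_set_library(genome, truth, seed=seed)

    paths = {"genome": outdir / "genome.tsv", "truth": outdir / "truth.json"}
    hio.write_gene_annotation(genome, paths["genome"])
    hio.write_json(truth.to_dict(), paths["truth"])
    replicates = []
    rel_replicates = []  # config paths relative to the workspace for portability
    for i, rep in enumerate(sim.replicates, start=1):
        entry, rel_entry = {}, {}
        for tag, df in [("full", rep.full), ("pseudo_a", rep.pseudo_a), ("pseudo_b", rep.pseudo_b)]:
            p = outdir / f"peaks_rep{i}_{tag}.bed"
            hio.write_bed(df, p)
            entry[tag] = str(p)
            rel_entry[tag] = p.name
        replicates.append(entry)
        rel_replicates.append(rel_entry)
    paths["counts"] = outdir / "peak_counts.tsv"
    paths["conditions"] = outdir / "peak_conditions.tsv"
    hio.write_counts(sim.counts, sim.conditions, paths["counts"], paths["conditions"])
    paths["gwas"] = outdir / "gwas.tsv"
    hio.write_gwas(gwas, paths["gwas"])
    paths["expression"] = outdir / "expression.tsv"
    hio.write_expression(expr, paths["expression"])
    paths["secretome"] = outdir / "secretome.tsv"
    hio.write_secretome(secretome, paths["secretome"])
    paths["library"] = outdir / "library.gmt"
    hio.write_gmt(library, paths["library"])

    config = {
        "genome": Path(paths["genome"]).name,
        "replicates": rel_replicates,
        "counts": Path(paths["counts"]).name,
        "conditions": Path(paths["conditions"]).name,
        "gwas": Path(paths["gwas"]).name,
        "expression": Path(paths["expression"]).name,
        "secretome": Path(paths["secretome"]).name,
        "markers": list(truth.markers),
        "seed": int(seed),
        "n_perm": int(n_perm),
    }
    paths["config"] = outdir / "screen.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    paths = {k: str(v) for k, v in paths.items()}
    paths["replicates"] = replicates
    logger.info("workspace written to %s (%d genes, %d consensus peaks)", outdir, n_genes, len(sim.consensus))
    return paths
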
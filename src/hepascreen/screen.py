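"""End-to-end hepatokine screen: peaks → candidates → GWAS enrichment →
secretome filter → coexpression corroboration.

One config drives the whole run: pseudoreplicate-reproducible peaks are
pooled across replicates, tied to the nearest TSS within 200 kb, genes with a
peak edge within 20 kb of the TSS form the candidate set, candidates are
mapped into the GWAS namespace, tested MAGENTA-style for enrichment of
best-SNP associations, the FDR-passing leading edge is intersected with the
secretome, and each secreted candidate's rank in the genome-wide correlation
screen against the composite activity vector is reported. The report carries
enough provenance (config hash, seed, version) to re-execute the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import coexpr, io as hio, peaks as pk, vgsea

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ScreenConfig:
    """Paths and thresholds for one screen run (defaults from the protocol)."""

    genome: str
    replicates: list  # dicts with keys full / pseudo_a / pseudo_b
    gwas: str
    expression: str
    secretome: str
    markers: list
    counts: str | None = None
    conditions: str | None = None
    ortholog_table: str | None = None
    radius_bp: int = 200_000
    tss_window_bp: int = 20_000
    min_overlap_bp: int = 1
    upstream_bp: int = 110_000
    downstream_bp: int = 40_000
    cutoff_percentile: float = 95.0
    n_perm: int = 10_000
    fdr: float = 0.05
    diff_fdr: float = 0.20
    top_fraction: float = 0.05
    expression_floor: float = 20.0
    seed: int = 0

    def __post_init__(self):
        for field in ("radius_bp", "tss_window_bp", "n_perm", "fdr", "diff_fdr",
                      "top_fraction", "expression_floor"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be non-negative")
        if not self.replicates:
            raise ValueError("at least one replicate (full/pseudo_a/pseudo_b) is required")

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        """Load a config; relative paths resolve against the config's directory."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = Path(path).resolve().parent

        def resolve(p):
            return str(base / p) if p and not Path(p).is_absolute() else p

        for key in ("genome", "gwas", "expression", "secretome", "counts",
                    "conditions", "ortholog_table"):
            if raw.get(key):
                raw[key] = resolve(raw[key])
        raw["replicates"] = [
            {k: resolve(v) for k, v in rep.items()} for rep in raw.get("replicates", [])
        ]
        return cls(**raw)

    def hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclasses.dataclass
class ScreenReport:
    n_reproducible_peaks: int
    n_assigned_peaks: int
    n_candidate_genes: int
    enrichment: dict
    leading_edge: list  # per-gene dicts: gene_id, qvalue, adjusted_score, secreted
    fdr_passing: list  # leading-edge subset with gene-level BH q < fdr
    secreted_candidates: list  # per-gene dicts incl. coexpression rank and r
    differential: dict | None
    empty_stage: str | None
    provenance: dict
    timestamp: str | None = None

    def to_dict(self, canonical: bool = True) -> dict:
        d = dataclasses.asdict(self)
        if canonical:
            d.pop("timestamp")
        return d

    def to_json(self, canonical: bool = True) -> str:
        return hio.dumps_canonical(self.to_dict(canonical=canonical))


def filter_secreted(genes, secretome_table: pd.DataFrame) -> list:
    """Subset of ``genes`` flagged secreted; absent genes count as not secreted."""
    genes = list(genes)
    flags = dict(zip(secretome_table["gene_id"], secretome_table["secreted"].astype(bool)))
    missing = sum(g not in flags for g in genes)
    if missing:
        logger.warning("filter_secreted: %d of %d genes absent from the secretome table",
                       missing, len(genes))
    if not flags:
        logger.warning("filter_secreted: secretome table is empty")
    return [g for g in genes if flags.get(g, False)]


class _Stage:
    """Stage timer that names the failing stage on error."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            logger.error("stage %s failed: %s", self.name, exc)
            raise RuntimeError(f"screen stage '{self.name}' failed: {exc}") from exc
        logger.info("stage %-22s %.2fs", self.name, time.perf_counter() - self.t0)


def run_screen_frames(
    genome: pd.DataFrame,
    replicates: list,
    gwas: pd.DataFrame,
    expression: pd.DataFrame,
    secretome: pd.DataFrame,
    markers,
    counts: pd.DataFrame | None = None,
    conditions: pd.Series | None = None,
    ortholog_table: pd.DataFrame | None = None,
    config: ScreenConfig | None = None,
    radius_bp: int = 200_000,
    tss_window_bp: int = 20_000,
    min_overlap_bp: int = 1,
    upstream_bp: int = 110_000,
    downstream_bp: int = 40_000,
    cutoff_percentile: float = 95.0,
    n_perm: int = 10_000,
    fdr: float = 0.05,
    diff_fdr: float = 0.20,
    expression_floor: float = 20.0,
    seed: int = 0,
) -> ScreenReport:
    """The screen on in-memory inputs; ``run_screen`` is the file-path wrapper.

    ``replicates`` is a list of (full, pseudo_a, pseudo_b) peak DataFrames (or
    objects with those attributes). An empty candidate set at any stage ends
    the run with ``empty_stage`` set instead of raising.
    """
    if config is not None:
        radius_bp, tss_window_bp = config.radius_bp, config.tss_window_bp
        min_overlap_bp = config.min_overlap_bp
        upstream_bp, downstream_bp = config.upstream_bp, config.downstream_bp
        cutoff_percentile, n_perm, fdr = config.cutoff_percentile, config.n_perm, config.fdr
        diff_fdr, expression_floor, seed = config.diff_fdr, config.expression_floor, config.seed

    provenance = {
        "config_hash": config.hash() if config is not None else None,
        "seed": int(seed),
        "version": _version(),
        "n_genes": int(len(genome)),
        "n_replicates": len(replicates),
        "parameters": {
            "radius_bp": radius_bp, "tss_window_bp": tss_window_bp,
            "min_overlap_bp": min_overlap_bp,
            "upstream_bp": upstream_bp, "downstream_bp": downstream_bp,
            "cutoff_percentile": cutoff_percentile, "n_perm": n_perm, "fdr": fdr,
            "diff_fdr": diff_fdr, "expression_floor": expression_floor,
        },
    }

    def _empty(stage: str, **partial) -> ScreenReport:
        logger.warning("screen ended early: stage '%s' produced an empty result", stage)
        base = dict(
            n_reproducible_peaks=0, n_assigned_peaks=0, n_candidate_genes=0,
            enrichment={}, leading_edge=[], fdr_passing=[], secreted_candidates=[],
            differential=None, provenance=provenance,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )
        base.update(partial)
        return ScreenReport(empty_stage=stage, **base)

    with _Stage("reproducible_peaks"):
        pooled = []
        for rep in replicates:
            full, pa, pb = (
                (rep["full"], rep["pseudo_a"], rep["pseudo_b"])
                if isinstance(rep, dict)
                else (rep.full, rep.pseudo_a, rep.pseudo_b)
            )
            pooled.append(pk.reproducible_peaks(full, pa, pb, min_overlap_bp=min_overlap_bp))
        reproducible = (
            pd.concat(pooled, ignore_index=True)
            .drop_duplicates(subset=["chrom", "start", "end"])
            .sort_values(["chrom", "start", "end"], kind="stable")
            .reset_index(drop=True)
        )
        reproducible["name"] = [f"cpeak_{i + 1:06d}" for i in range(len(reproducible))]
    if reproducible.empty:
        return _empty("reproducible_peaks")

    with _Stage("assign_peaks_to_genes"):
        assignments = pk.assign_peaks_to_genes(reproducible, genome, radius_bp=radius_bp)

    with _Stage("candidate_gene_set"):
        candidates = pk.candidate_gene_set(assignments, tss_window_bp=tss_window_bp)
    if not candidates:
        return _empty("candidate_gene_set",
                      n_reproducible_peaks=len(reproducible),
                      n_assigned_peaks=len(assignments))

    with _Stage("map_orthologs"):
        mapped = pk.map_orthologs(candidates, ortholog_table)
    if not mapped:
        return _empty("map_orthologs",
                      n_reproducible_peaks=len(reproducible),
                      n_assigned_peaks=len(assignments),
                      n_candidate_genes=len(candidates))

    with _Stage("gwas_gene_scores"):
        table = vgsea.score_genes(gwas, genome, upstream_bp=upstream_bp,
                                  downstream_bp=downstream_bp)

    with _Stage("enrichment_test"):
        result = vgsea.enrichment_test(table, mapped, cutoff_percentile=cutoff_percentile,
                                       n_perm=n_perm, seed=seed)
        fdr_table, passing = vgsea.gene_level_fdr(table, mapped, fdr=fdr)

    with _Stage("filter_secreted"):
        # the leading edge is the set genes above the enrichment cutoff (the
        # genes "contributing to the enrichment"); gene-level BH q-values are
        # attached as annotation and the q < fdr subset reported separately
        secreted = filter_secreted(result.leading_edge, secretome)

    with _Stage("coexpression"):
        z = coexpr.preprocess(expression, expression_floor=expression_floor)
        composite = coexpr.composite_vector(z, markers)
        screen_table = coexpr.correlation_screen(z, composite)
        ranked = screen_table.sort_values("r", ascending=False, kind="stable")
        rank_of = {g: i + 1 for i, g in enumerate(ranked.index)}

    differential = None
    if counts is not None and conditions is not None:
        with _Stage("differential_occupancy"):
            diff = pk.differential_occupancy(counts, conditions, fdr_threshold=diff_fdr)
            differential = {
                "n_peaks": int(len(diff)),
                "n_significant": int(diff["significant"].sum()),
                "fdr_threshold": diff_fdr,
            }

    qmap = dict(zip(fdr_table["gene_id"], fdr_table["qvalue"]))
    smap = dict(zip(fdr_table["gene_id"], fdr_table["adjusted_score"]))
    secreted_set = set(secreted)
    leading_edge = [
        {"gene_id": g, "qvalue": float(qmap[g]), "adjusted_score": float(smap[g]),
         "secreted": g in secreted_set}
        for g in result.leading_edge
    ]
    secreted_candidates = [
        {"gene_id": g, "qvalue": float(qmap[g]),
         "coexpression_rank": rank_of.get(g),
         "coexpression_r": float(screen_table.at[g, "r"]) if g in screen_table.index else None}
        for g in secreted
    ]

    # containment invariant of the report
    assert secreted_set <= set(result.leading_edge) <= set(mapped)

    return ScreenReport(
        n_reproducible_peaks=int(len(reproducible)),
        n_assigned_peaks=int(len(assignments)),
        n_candidate_genes=int(len(candidates)),
        enrichment=result.to_dict(),
        leading_edge=leading_edge,
        fdr_passing=[g for g in passing if g in set(result.leading_edge)],
        secreted_candidates=secreted_candidates,
        differential=differential,
        empty_stage=None,
        provenance=provenance,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


def run_screen(config: ScreenConfig, report_path=None, canonical: bool = True) -> ScreenReport:
    """Load every input named in ``config``, run the screen, optionally write JSON."""
    with _Stage("load_inputs"):
        genome = hio.read_gene_annotation(config.genome)
        replicates = [
            {k: hio.read_bed(rep[k]) for k in ("full", "pseudo_a", "pseudo_b")}
            for rep in config.replicates
        ]
        gwas = hio.read_gwas(config.gwas)
        expression = hio.read_expression(config.expression)
        secretome = hio.read_secretome(config.secretome)
        counts = conditions = None
        if config.counts and config.conditions:
            counts, conditions = hio.read_counts(config.counts, config.conditions)
        ortho = pd.read_csv(config.ortholog_table, sep="\t") if config.ortholog_table else None

    report = run_screen_frames(
        genome, replicates, gwas, expression, secretome, config.markers,
        counts=counts, conditions=conditions, ortholog_table=ortho, config=config,
    )
    if report_path is not None:
        Path(report_path).write_text(report.to_json(canonical=canonical))
        logger.info("report written to %s", report_path)
    return report


def _version() -> str:
    from . import __version__

    return __version__
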
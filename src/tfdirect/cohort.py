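"""Patient-cohort analytics and the end-to-end pipeline runner.

Given single-sample metagene scores and a biopsy design table (patient id,
ordinal histologic grade, progression status, batch, TIN), this module
fits the grade-trend random-intercept models, builds progression rank lists
(regressive vs progressive/persistent, per-gene mixed models), tests target
sets for progression enrichment by preranked GSEA, and scores immune
cell-type sets against a designated gene and the metagene scores.

:func:`run_pipeline` chains every stage — simulate, interval consensus and
cross-factor overlap, proximal/distal target assignment, tri-knockdown DE,
concordance classification, and the cohort analytics — and writes result
tables plus a manifest that suffices to reproduce every number.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import (
    CountMatrix,
    DEResult,
    MixedLMResult,
    NormalizedMatrix,
    RankList,
    fit_de,
    fit_random_intercept,
    filter_low_info_genes,
    log_cpm,
    rank_by_t,
)
from .intervals import consensus_across_replicates, filter_fold_change, overlap_sets
from .signatures import (
    EnrichmentResult,
    GeneSet,
    ScoreMatrix,
    correlation_with_fdr,
    gsea_preranked,
    ssgsea_score,
    write_gmt,
)
from .simulate import SimulationConfig, simulate_cohort, simulate_genome, \
    simulate_knockdown_counts, simulate_peaks
from .targets import (
    Thresholds,
    assign_distal,
    assign_proximal,
    classify_direct_targets,
    filter_interactions,
    merge_assignments,
)

__all__ = [
    "PipelineConfig",
    "AssociationResult",
    "grade_trend",
    "progression_ranklist",
    "progression_enrichment",
    "immune_association",
    "knockdown_de",
    "run_pipeline",
]


@dataclass
class AssociationResult:
    """Per-score association slopes from the grade or progression models."""

    table: pd.DataFrame  # rows: score names; cols: slope, se, t, p, model
    covariates: list[str] = field(default_factory=list)

    def __getitem__(self, score: str) -> pd.Series:
        return self.table.loc[score]


def _assoc_table(rows: dict[str, dict]) -> pd.DataFrame:
    table = pd.DataFrame(rows).T
    for c in ("slope", "se", "t", "p"):
        table[c] = table[c].astype(float)
    return table


def _design_frame(design: pd.DataFrame, main: pd.Series,
                  covariates: list[str] | None) -> pd.DataFrame:
    """Numeric fixed-effect frame: main variable first, then covariates.

    Categorical covariates are dummy-coded (first level dropped); numeric
    ones enter linearly.
    """
    cols = {main.name: main.astype(float)}
    for cov in covariates or []:
        v = design[cov]
        if pd.api.types.is_numeric_dtype(v):
            cols[cov] = v.astype(float)
        else:
            dummies = pd.get_dummies(v, prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
    return pd.DataFrame(cols, index=design.index)


def grade_trend(
    scores: ScoreMatrix,
    design: pd.DataFrame,
    covariates: list[str] | None = None,
) -> AssociationResult:
    """Grade-trend association per score row, patient as random intercept.

    Grade enters as a continuous ordinal covariate; each score row is fit
    with :func:`fit_random_intercept` (OLS fallback when patients have a
    single biopsy each).
    """
    if design["grade"].nunique() < 2:
        raise ValueError("no grade variation in the design")
    X = _design_frame(design, design["grade"].rename("grade"), covariates)
    rows = {}
    for name in scores.sets:
        y = scores.scores.loc[name, design.index].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_random_intercept(y, X, design["patient"], coef="grade")
        rows[name] = {
            "slope": fit.slope, "se": fit.slope_se,
            "t": float(fit.tvalues["grade"]), "p": float(fit.pvalues["grade"]),
            "model": fit.model,
        }
    return AssociationResult(table=_assoc_table(rows),
                             covariates=list(covariates or []))


def _regressive_indicator(design: pd.DataFrame) -> pd.Series:
    """1 for regressive lesions, 0 for progressive/persistent, NaN otherwise."""
    prog = design["progression"].astype(str)
    x = pd.Series(np.nan, index=design.index, name="regressive")
    x[prog == "regressive"] = 1.0
    x[prog.str.startswith("progressive")] = 0.0
    x[prog == "persistent"] = 0.0
    return x


def progression_ranklist(
    nm: NormalizedMatrix,
    design: pd.DataFrame,
    subtype_filter: str | None = None,
    covariates: list[str] | None = None,
) -> RankList:
    """Gene rank list by t for regressive vs progressive/persistent status.

    Positive t means higher expression in regressive lesions.  Each gene is
    fit with the random-intercept model (patient grouping; OLS fallback).
    ``subtype_filter`` restricts to samples of one molecular subtype label.
    """
    design = design.loc[nm.logcpm.columns]
    if subtype_filter is not None:
        design = design[design["subtype"] == subtype_filter]
    x = _regressive_indicator(design)
    design = design[x.notna()]
    x = x[x.notna()]
    if x.nunique() < 2:
        raise ValueError("need both progression classes after filtering")
    X = _design_frame(design, x, covariates)
    expr = nm.logcpm[design.index]
    groups = design["patient"]
    t_stats = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in expr.index:
            fit = fit_random_intercept(
                expr.loc[g].to_numpy(dtype=float), X, groups, coef="regressive"
            )
            t_stats[g] = float(fit.tvalues["regressive"])
    return RankList.from_stats(pd.Series(t_stats))


def progression_enrichment(
    ranklist: RankList,
    target_sets: list[GeneSet],
    nperm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA of each target set on the progression rank list.

    With the regressive-up coding, a positive enrichment score means the
    set is elevated in regressive lesions.
    """
    if not target_sets:
        raise ValueError("no target sets supplied")
    rows = []
    for s in target_sets:
        res = gsea_preranked(ranklist, s, nperm=nperm, seed=seed)
        rows.append(
            {
                "set": s.name, "es": res.es, "nes": res.nes, "p": res.p_value,
                "n_hits": res.n_hits,
                "enriched_in": "regressive" if res.es > 0
                else "progressive/persistent",
                "leading_edge": ",".join(res.leading_edge),
            }
        )
    return pd.DataFrame(rows).set_index("set")


@dataclass
class ImmuneAssociation:
    scores: ScoreMatrix
    gene_correlations: pd.DataFrame      # immune set vs designated gene
    metagene_correlations: pd.DataFrame  # immune set vs metagene scores
    progression: AssociationResult


def immune_association(
    nm: NormalizedMatrix,
    design: pd.DataFrame,
    immune_sets: list[GeneSet],
    designated_gene: str,
    metagene_scores: ScoreMatrix | None = None,
) -> ImmuneAssociation:
    """Immune cell-type scores and their correlates.

    Scores each immune set per sample (ssGSEA), correlates every immune
    score with the designated gene's expression (and with the supplied
    metagene scores), and fits the progression model per immune score.
    """
    scores = ssgsea_score(nm.logcpm, immune_sets)
    if designated_gene not in nm.logcpm.index:
        raise ValueError(f"designated gene {designated_gene!r} not in the matrix")
    gene_expr = nm.logcpm.loc[[designated_gene]]
    gene_corr = correlation_with_fdr(scores.scores, gene_expr)
    gene_corr = gene_corr.sort_values("r", ascending=False).reset_index(drop=True)
    if metagene_scores is not None:
        meta_corr = correlation_with_fdr(scores.scores, metagene_scores.scores)
    else:
        meta_corr = pd.DataFrame(columns=["x", "y", "r", "p", "fdr"])

    x = _regressive_indicator(design)
    keep = x.notna()
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in scores.sets:
            y = scores.scores.loc[name, design.index[keep]].to_numpy(dtype=float)
            X = pd.DataFrame({"regressive": x[keep].astype(float)})
            fit = fit_random_intercept(y, X, design["patient"][keep],
                                       coef="regressive")
            rows[name] = {
                "slope": fit.slope, "se": fit.slope_se,
                "t": float(fit.tvalues["regressive"]),
                "p": float(fit.pvalues["regressive"]), "model": fit.model,
            }
    return ImmuneAssociation(
        scores=scores,
        gene_correlations=gene_corr,
        metagene_correlations=meta_corr,
        progression=AssociationResult(table=_assoc_table(rows)),
    )


# ---------------------------------------------------------------------------
# knockdown DE + full pipeline


def knockdown_de(kd: CountMatrix) -> list[DEResult]:
    """Per-arm differential expression against the shared controls.

    Each knockdown arm is analysed separately: subset to arm + control
    samples, drop uninformative genes, recompute TMM factors, transform to
    log2-CPM, and fit the moderated linear model with treatment as the main
    variable and cell line as a covariate.
    """
    arms = [t for t in kd.meta["treatment"].unique() if t != "control"]
    if not arms or "control" not in set(kd.meta["treatment"]):
        raise ValueError("metadata must contain 'control' and knockdown arms")
    results = []
    for arm in arms:
        keep = kd.meta["treatment"].isin(["control", arm])
        sub = CountMatrix(kd.counts.loc[:, keep.to_numpy()], kd.meta[keep])
        sub = filter_low_info_genes(sub)
        nm = log_cpm(sub)
        design = _design_frame(
            sub.meta,
            (sub.meta["treatment"] == arm).astype(float).rename("treatment"),
            ["cell_line"] if sub.meta["cell_line"].nunique() > 1 else None,
        )
        results.append(fit_de(nm, design, coef="treatment", contrast=arm))
    return results


@dataclass
class PipelineConfig:
    """One structured configuration for the end-to-end run."""

    outdir: str = "tfdirect_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_fold_change: float = 2.0
    nperm: int = 999
    run_cohort: bool = True
    subtype_filter: str | None = "Proliferative"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = dict(raw.get("simulation", {}))
        sim_raw.setdefault("seed", raw.get("seed", 0))
        if "peak_width_bp" in sim_raw:
            sim_raw["peak_width_bp"] = tuple(sim_raw["peak_width_bp"])
        sim = SimulationConfig(**sim_raw)
        th = Thresholds(**raw.get("thresholds", {}))
        kwargs = {k: v for k, v in raw.items()
                  if k not in ("simulation", "thresholds")}
        return cls(simulation=sim, thresholds=th, **kwargs)

    def to_yaml(self, path) -> None:
        obj = asdict(self)
        obj["simulation"]["peak_width_bp"] = list(obj["simulation"]["peak_width_bp"])
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


@dataclass
class PipelineResult:
    """Everything the end-to-end run computed, plus where it was written."""

    outdir: Path
    cobound_regions: object
    direct_targets: object
    de_results: list[DEResult]
    grade: AssociationResult | None
    progression: pd.DataFrame | None
    recovery: dict[str, float]


def _recovery_metrics(found: set[str], truth: set[str]) -> tuple[float, float]:
    tp = len(found & truth)
    sens = tp / len(truth) if truth else np.nan
    prec = tp / len(found) if found else np.nan
    return sens, prec


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Simulate, infer direct targets, and run the cohort analytics.

    Stages: synthetic genome/peaks/counts -> fold-change filter ->
    replicate consensus per factor -> cross-factor overlap regions ->
    proximal + distal gene assignment -> tri-knockdown DE -> concordance
    classification -> metagene scoring, grade trend and progression GSEA on
    the synthetic cohort.  Writes result tables and a manifest under
    ``cfg.outdir``; identical configs give identical outputs.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = cfg.simulation
    genes = simulate_genome(sim_cfg)
    peaks = simulate_peaks(sim_cfg, genes)
    truth = peaks.truth

    consensus = {}
    for factor in sim_cfg.factors:
        reps = [
            filter_fold_change(ps, cfg.min_fold_change)
            for (f, _), ps in peaks.peaksets.items()
            if f == factor
        ]
        consensus[factor] = consensus_across_replicates(reps)
    overlap = overlap_sets(list(consensus.values()))
    from .intervals import PeakSet  # local to avoid a cycle at import time
    regions = PeakSet(factor="cobound", replicate="consensus",
                      intervals=overlap.merged)

    th = cfg.thresholds
    prox = assign_proximal(regions, genes, th)
    inter = filter_interactions(peaks.interactions, genes, th)
    dist = assign_distal(regions, genes, inter, th)
    universe = merge_assignments(prox, dist)

    kd = simulate_knockdown_counts(sim_cfg, genes, truth)
    de_results = knockdown_de(kd)
    direct = classify_direct_targets(universe, de_results, th)

    sens, prec = _recovery_metrics(direct.induced | direct.repressed,
                                   truth.all_targets)
    recovery = {
        "sensitivity": sens,
        "precision": prec,
        "n_induced_found": len(direct.induced),
        "n_repressed_found": len(direct.repressed),
        "n_cobound_regions": len(regions),
        "n_universe": len(universe),
    }

    target_sets = []
    if direct.induced:
        target_sets.append(GeneSet("induced_targets", frozenset(direct.induced)))
    if direct.repressed:
        target_sets.append(GeneSet("repressed_targets", frozenset(direct.repressed)))
    write_gmt(target_sets, outdir / "direct_targets.gmt")
    direct.to_frame().to_csv(outdir / "direct_targets.tsv", sep="\t", index=False)

    grade_res = None
    prog_res = None
    if cfg.run_cohort and target_sets:
        cohort = simulate_cohort(sim_cfg, genes, truth)
        ccm = filter_low_info_genes(cohort.counts)
        nm = log_cpm(ccm)
        nm.meta = cohort.design
        scores = ssgsea_score(nm.logcpm, target_sets)
        grade_res = grade_trend(scores, cohort.design)
        grade_res.table.to_csv(outdir / "grade_trend.tsv", sep="\t")
        ranklist = progression_ranklist(nm, cohort.design,
                                        subtype_filter=cfg.subtype_filter)
        prog_res = progression_enrichment(ranklist, target_sets,
                                          nperm=cfg.nperm, seed=cfg.seed)
        prog_res.to_csv(outdir / "progression_gsea.tsv", sep="\t")
        scores.scores.to_csv(outdir / "metagene_scores.tsv", sep="\t")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "simulation": asdict(sim_cfg),
        "thresholds": asdict(th),
        "nperm": cfg.nperm,
        "recovery": recovery,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return PipelineResult(
        outdir=outdir,
        cobound_regions=regions,
        direct_targets=direct,
        de_results=de_results,
        grade=grade_res,
        progression=prog_res,
        recovery=recovery,
    )
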
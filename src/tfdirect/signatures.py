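"""Gene-set analytics: single-sample scores, preranked GSEA, overlap tests.

Single-sample "metagene" scores summarise a gene set's relative expression
within each sample.  Two rank-based variants are provided:

* :func:`ssgsea_score` — the weighted-ECDF running-sum statistic of
  single-sample GSEA (exponent ``tau``), range-normalised so scores are
  comparable across set sizes.
* :func:`aucell_score` — area under the top-k recovery curve, the AUCell
  statistic used for sparse per-cell expression.

Both depend on expression only through within-sample ranks, so they are
invariant to any strictly monotone per-sample transform.

Preranked GSEA (:func:`gsea_preranked`) computes the classic weighted
Kolmogorov-Smirnov running-sum enrichment score on a t-statistic rank list,
with a gene-label permutation null (random same-size sets), sign-conditional
NES normalisation, and an exhaustive enumeration mode for small problems.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .expression import RankList, bh_fdr

__all__ = [
    "GeneSet",
    "ScoreMatrix",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "ssgsea_score",
    "aucell_score",
    "gsea_preranked",
    "fisher_overlap",
    "correlation_with_fdr",
    "hypergeometric_pathway_enrichment",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ScoreMatrix:
    """Gene-set x sample single-sample scores."""

    scores: pd.DataFrame
    method: str

    @property
    def sets(self) -> pd.Index:
        return self.scores.index

    @property
    def samples(self) -> pd.Index:
        return self.scores.columns


@dataclass
class EnrichmentResult:
    """Preranked-GSEA outcome for one gene set."""

    set_name: str
    es: float
    nes: float
    p_value: float
    fdr: float = np.nan
    leading_edge: list[str] = field(default_factory=list)
    n_hits: int = 0


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            genes = frozenset(g for g in parts[2:] if g)
            sets.append(GeneSet(name=parts[0], description=parts[1], genes=genes))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na",
                                *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# single-sample scores


def _ssgsea_raw(order: np.ndarray, rank_values: np.ndarray,
                in_set: np.ndarray, tau: float) -> float:
    """Running-sum ssGSEA statistic for one sample.

    ``order`` lists gene indices from highest to lowest expression;
    ``rank_values`` are descending rank scores (ties averaged);
    ``in_set`` is a boolean mask over genes.
    """
    hits = in_set[order]
    w = np.where(hits, rank_values[order] ** tau, 0.0)
    wsum = w.sum()
    if wsum == 0:
        w = hits.astype(float)
        wsum = w.sum()
    n_out = len(order) - hits.sum()
    pin = np.cumsum(w) / wsum
    pout = np.cumsum(~hits) / max(n_out, 1)
    return float(np.sum(pin - pout))


def _ssgsea_range(n_genes: int, set_size: int, tau: float) -> float:
    """Max minus min attainable raw statistic for this geometry."""
    rank_values = np.arange(n_genes, 0, -1, dtype=float)
    order = np.arange(n_genes)
    top = np.zeros(n_genes, dtype=bool)
    top[:set_size] = True
    bottom = np.zeros(n_genes, dtype=bool)
    bottom[n_genes - set_size:] = True
    hi = _ssgsea_raw(order, rank_values, top, tau)
    lo = _ssgsea_raw(order, rank_values, bottom, tau)
    return hi - lo


def ssgsea_score(values: pd.DataFrame, sets: list[GeneSet],
                 tau: float = 0.25) -> ScoreMatrix:
    """Rank-based single-sample enrichment score per set per sample.

    Genes are ranked within each sample (descending, average ranks for
    ties); the score is the sum over list positions of the weighted in-set
    ECDF minus the out-set ECDF, with in-set weights rank^tau, divided by
    the maximum-minus-minimum attainable for that set size and gene count.
    Sets with under half their members in the matrix are scored on the
    intersection with a warning; an empty intersection is an error.
    """
    gene_index = values.index
    n_genes = len(gene_index)
    masks: dict[str, np.ndarray] = {}
    for s in sets:
        present = gene_index.isin(s.genes)
        n_present = int(present.sum())
        if n_present == 0:
            raise ValueError(f"gene set {s.name!r} shares no genes with the matrix")
        if n_present < int(np.ceil(len(s) / 2)):
            warnings.warn(
                f"gene set {s.name!r}: only {n_present}/{len(s)} members in "
                "the matrix; scoring the intersection",
                stacklevel=2,
            )
        masks[s.name] = present
    vals = values.to_numpy(dtype=float)
    gene_ids = gene_index.to_numpy()
    id_order = np.argsort(gene_ids)  # deterministic tie-break by gene id
    out = np.empty((len(sets), values.shape[1]))
    ranges = {
        s.name: _ssgsea_range(n_genes, int(masks[s.name].sum()), tau)
        for s in sets
    }
    for j in range(values.shape[1]):
        col = vals[:, j]
        # order: descending value, gene id ascending within ties
        order = id_order[np.argsort(-col[id_order], kind="stable")]
        # rank score: top gene ~ N, bottom ~ 1, ties averaged
        rank_values = stats.rankdata(col, method="average")
        for i, s in enumerate(sets):
            raw = _ssgsea_raw(order, rank_values, masks[s.name], tau)
            out[i, j] = raw / ranges[s.name]
    frame = pd.DataFrame(out, index=[s.name for s in sets], columns=values.columns)
    return ScoreMatrix(scores=frame, method="ssgsea")


def aucell_score(values: pd.DataFrame, sets: list[GeneSet],
                 top_fraction: float = 0.05, seed: int = 0) -> ScoreMatrix:
    """Area under the top-k recovery curve per set per cell.

    For each cell, genes are ranked by descending value (ties broken by a
    seeded shuffle); the recovery curve counts set genes among the top k for
    k up to ceil(top_fraction * n_genes), and the score is its area divided
    by the maximal attainable area.
    """
    rng = np.random.default_rng(seed)
    gene_index = values.index
    n_genes = len(gene_index)
    k_max = int(np.ceil(top_fraction * n_genes))
    masks = {}
    for s in sets:
        present = gene_index.isin(s.genes)
        if not present.any():
            raise ValueError(f"gene set {s.name!r} shares no genes with the matrix")
        masks[s.name] = present
    vals = values.to_numpy(dtype=float)
    out = np.empty((len(sets), values.shape[1]))
    for j in range(values.shape[1]):
        col = vals[:, j]
        jitter = rng.permutation(n_genes)  # random tie-break
        order = np.lexsort((jitter, -col))
        top = order[:k_max]
        for i, s in enumerate(sets):
            hits = masks[s.name][top]
            set_size = int(masks[s.name].sum())
            curve = np.cumsum(hits)
            max_curve = np.minimum(np.arange(1, k_max + 1), set_size)
            out[i, j] = curve.sum() / max_curve.sum()
    frame = pd.DataFrame(out, index=[s.name for s in sets], columns=values.columns)
    return ScoreMatrix(scores=frame, method="aucell")


# ---------------------------------------------------------------------------
# preranked GSEA


def _running_es(hit_mask: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    """Weighted KS enrichment score and extremum position (0-based).

    Hit steps are |t|^w normalised over set hits; miss steps are
    1/(N - n_hits).  Returns the running-sum value of largest magnitude.
    """
    n = len(hit_mask)
    n_hits = int(hit_mask.sum())
    w = np.where(hit_mask, weights, 0.0)
    wsum = w.sum()
    if wsum <= 0:
        w = hit_mask.astype(float)
        wsum = float(n_hits)
    step = np.where(hit_mask, w / wsum, -1.0 / (n - n_hits))
    running = np.cumsum(step)
    imax = int(np.argmax(running))
    imin = int(np.argmin(running))
    if abs(running[imax]) >= abs(running[imin]):
        return float(running[imax]), imax
    return float(running[imin]), imin


def gsea_preranked(
    ranks: RankList,
    gene_set: GeneSet,
    weight_exponent: float = 1.0,
    nperm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> EnrichmentResult:
    """Preranked GSEA with a random-gene-set null.

    ES is the maximum deviation of the weighted running sum over the ranked
    list.  The null re-draws same-size gene sets uniformly (positions on the
    list); with ``exhaustive`` and C(N, |S|) <= 1e5, all placements are
    enumerated instead.  NES divides ES by the mean |null ES| of the same
    sign, and p = (1 + #{same-sign null as or more extreme}) /
    (#same-sign null + 1).
    """
    n = len(ranks)
    positions = np.arange(n)
    hit_mask = np.array([g in gene_set.genes for g in ranks.gene_ids])
    n_hits = int(hit_mask.sum())
    if n_hits < 2:
        raise ValueError(
            f"gene set {gene_set.name!r}: only {n_hits} members on the rank "
            "list (need >= 2)"
        )
    if n_hits == n:
        raise ValueError(f"gene set {gene_set.name!r} covers the whole list")
    weights = np.abs(ranks.t_stats) ** weight_exponent
    es, ipeak = _running_es(hit_mask, weights)

    if exhaustive:
        n_comb = special.comb(n, n_hits, exact=True)
        if n_comb > 10**5:
            raise ValueError(
                f"C({n},{n_hits}) = {n_comb} placements exceed the "
                "exhaustive-mode limit of 1e5"
            )
        null_es = np.empty(n_comb)
        for k, combo in enumerate(itertools.combinations(range(n), n_hits)):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            null_es[k], _ = _running_es(mask, weights)
    else:
        if nperm < 1:
            raise ValueError("nperm must be >= 1 unless exhaustive")
        rng = np.random.default_rng(seed)
        null_es = np.empty(nperm)
        for k in range(nperm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(positions, size=n_hits, replace=False)] = True
            null_es[k], _ = _running_es(mask, weights)

    same_sign = null_es * np.sign(es) > 0 if es != 0 else np.ones(len(null_es), bool)
    n_same = int(same_sign.sum())
    extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
    p = (1 + extreme) / (n_same + 1)
    mean_mag = float(np.mean(np.abs(null_es[same_sign]))) if n_same else np.nan
    nes = es / mean_mag if (mean_mag and np.isfinite(mean_mag)) else np.nan

    if es >= 0:
        leading = [g for g, h in zip(ranks.gene_ids[: ipeak + 1], hit_mask) if h]
    else:
        leading = [
            g for g, h in zip(ranks.gene_ids[ipeak:], hit_mask[ipeak:]) if h
        ]
    return EnrichmentResult(
        set_name=gene_set.name, es=es, nes=nes, p_value=p,
        leading_edge=leading, n_hits=n_hits,
    )


# ---------------------------------------------------------------------------
# overlap and correlation tests


def fisher_overlap(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[np.ndarray, float, float]:
    """Fisher's exact test of set overlap within a universe.

    Table rows index membership in A, columns membership in B.  Returns
    (2x2 table, odds ratio, two-sided p).  The odds ratio is ad/bc with a
    Haldane 0.5 correction (and a warning) when any cell is zero.
    """
    a_set, b_set = set(set_a) & universe, set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise ValueError("sets must be subsets of the universe")
    n11 = len(a_set & b_set)
    n12 = len(a_set - b_set)
    n21 = len(b_set - a_set)
    n22 = len(universe) - n11 - n12 - n21
    table = np.array([[n11, n12], [n21, n22]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        warnings.warn("zero cell: odds ratio uses Haldane 0.5 correction",
                      stacklevel=2)
        t = table + 0.5
    else:
        t = table.astype(float)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return table, float(odds), float(p)


def correlation_with_fdr(
    x_matrix: pd.DataFrame, y_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of every x row against every y row, with BH FDR.

    Rows are variables, columns are shared samples.  Pairs involving a
    constant vector are reported with NaN statistics and excluded from the
    FDR adjustment.
    """
    common = x_matrix.columns.intersection(y_matrix.columns)
    if len(common) < 3:
        raise ValueError("need at least 3 paired samples")
    xm = x_matrix[common]
    ym = y_matrix[common]
    rows = []
    for xi in xm.index:
        xv = xm.loc[xi].to_numpy(dtype=float)
        for yi in ym.index:
            yv = ym.loc[yi].to_numpy(dtype=float)
            if np.std(xv) == 0 or np.std(yv) == 0:
                rows.append((xi, yi, np.nan, np.nan))
                continue
            r, p = stats.pearsonr(xv, yv)
            rows.append((xi, yi, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["x", "y", "r", "p"])
    out["fdr"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "fdr"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out


def hypergeometric_pathway_enrichment(
    targets: set[str], pathway_sets: list[GeneSet], universe: set[str]
) -> pd.DataFrame:
    """One-sided over-representation test of targets in each pathway set."""
    targ = set(targets) & universe
    n_univ, n_targ = len(universe), len(targ)
    rows = []
    for s in pathway_sets:
        members = s.genes & universe
        k = len(targ & members)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_targ))
        rows.append((s.name, k, len(members), p))
    out = pd.DataFrame(rows, columns=["set", "n_overlap", "n_set", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy()) if len(out) else np.nan
    return out.sort_values("p", kind="stable").reset_index(drop=True)
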
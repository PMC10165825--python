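"""Peak-to-gene assignment and direct-target classification.

A gene is a candidate direct target of a co-bound region if either

* proximal rule — its TSS lies within ``tss_window_bp`` (default 50 kb) of
  the region (gap to the nearest covered base, half-open arithmetic), or
* distal rule — a retained chromatin interaction (promoter-capture Hi-C
  style fragment pair, p <= ``interaction_p_max``) has one fragment
  containing the gene's TSS and the other fragment overlapping the region.

Candidates are then classified by knockdown concordance: a gene is a
repressed target if it is significantly up-regulated (fdr < ``de_fdr_max``
and logFC > ``de_abs_logfc_min``, strict) in *every* knockdown contrast,
and an induced target if significantly down-regulated in every contrast.
Induced and repressed sets are disjoint by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .expression import DEResult
from .intervals import GenomicInterval, PeakSet

__all__ = [
    "Thresholds",
    "TargetAssignment",
    "DirectTargetSet",
    "assign_proximal",
    "filter_interactions",
    "assign_distal",
    "classify_direct_targets",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """The pipeline's classification constants.

    tss_window_bp: proximal-assignment window around co-bound regions.
    interaction_p_max: retention cutoff for chromatin interactions
    (inclusive).  de_fdr_max / de_abs_logfc_min: strict significance and
    effect-size bounds applied per knockdown contrast.
    """

    tss_window_bp: int = 50_000
    interaction_p_max: float = 0.05
    de_fdr_max: float = 0.05
    de_abs_logfc_min: float = 0.5

    def __post_init__(self) -> None:
        if self.tss_window_bp < 0 or self.interaction_p_max <= 0 \
                or self.de_fdr_max <= 0 or self.de_abs_logfc_min < 0:
            raise ValueError("invalid thresholds")


@dataclass
class TargetAssignment:
    gene_id: str
    evidence: str  # proximal | distal | both
    supporting_region_ids: set[str] = field(default_factory=set)


@dataclass
class DirectTargetSet:
    """Concordance-classified direct targets with per-gene evidence."""

    induced: set[str]
    repressed: set[str]
    evidence: dict[str, TargetAssignment]
    stats: pd.DataFrame  # gene x (contrast, logFC/fdr) for classified genes

    def __post_init__(self) -> None:
        if self.induced & self.repressed:
            raise ValueError("induced and repressed sets overlap")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, members in (("induced", self.induced), ("repressed", self.repressed)):
            for g in sorted(members):
                ev = self.evidence[g]
                rows.append(
                    (g, cls, ev.evidence, ",".join(sorted(ev.supporting_region_ids)))
                )
        return pd.DataFrame(rows, columns=["gene_id", "class", "evidence", "regions"])


def _gap_to_region(tss: int, start: int, end: int) -> int:
    """Distance from a TSS to a half-open region; 0 if inside."""
    if start <= tss < end:
        return 0
    if tss < start:
        return start - tss
    return tss - (end - 1)


def assign_proximal(
    regions: PeakSet, genes: pd.DataFrame, th: Thresholds = Thresholds()
) -> dict[str, TargetAssignment]:
    """Genes whose TSS lies within the window of any co-bound region."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: dict[str, TargetAssignment] = {}
    for row in genes.itertuples():
        support = {
            iv.id
            for iv in by_chrom.get(row.chrom, [])
            if _gap_to_region(int(row.tss), iv.start, iv.end) <= th.tss_window_bp
        }
        if support:
            out[row.gene_id] = TargetAssignment(row.gene_id, "proximal", support)
    return out


def filter_interactions(
    records: pd.DataFrame, genes: pd.DataFrame, th: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Retain interactions with p <= cutoff and label their kind.

    ``records`` columns: chrom_a, start_a, end_a, chrom_b, start_b, end_b,
    p_value.  A fragment is promoter-containing if it covers >= 1 TSS of any
    gene; kind is promoter-promoter when both fragments do, else
    promoter-other.
    """
    kept = records[records["p_value"] <= th.interaction_p_max].copy()
    tss_by_chrom = {
        str(c): sub["tss"].to_numpy() for c, sub in genes.groupby("chrom")
    }

    def has_tss(chrom: str, start: int, end: int) -> bool:
        tss = tss_by_chrom.get(chrom)
        return tss is not None and bool(((tss >= start) & (tss < end)).any())

    kinds = []
    for row in kept.itertuples():
        a = has_tss(row.chrom_a, row.start_a, row.end_a)
        b = has_tss(row.chrom_b, row.start_b, row.end_b)
        kinds.append("promoter-promoter" if (a and b) else "promoter-other")
    kept["kind"] = kinds
    return kept


def assign_distal(
    regions: PeakSet,
    genes: pd.DataFrame,
    interactions: pd.DataFrame,
    th: Thresholds = Thresholds(),
) -> dict[str, TargetAssignment]:
    """Genes linked to a co-bound region by a retained fragment pair.

    A gene qualifies if its TSS falls in one fragment of a retained record
    and the partner fragment overlaps (>= 1 bp) a region, in either
    orientation.  ``interactions`` should already be p-filtered
    (:func:`filter_interactions`); any p_value column present is re-checked
    defensively.
    """
    if "p_value" in interactions.columns:
        interactions = interactions[interactions["p_value"] <= th.interaction_p_max]
    regs_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        regs_by_chrom.setdefault(iv.chrom, []).append(iv)

    def overlapping_regions(chrom: str, start: int, end: int) -> set[str]:
        return {
            iv.id
            for iv in regs_by_chrom.get(chrom, [])
            if min(iv.end, end) - max(iv.start, start) >= 1
        }

    out: dict[str, TargetAssignment] = {}
    for row in interactions.itertuples():
        frags = (
            (row.chrom_a, row.start_a, row.end_a, row.chrom_b, row.start_b, row.end_b),
            (row.chrom_b, row.start_b, row.end_b, row.chrom_a, row.start_a, row.end_a),
        )
        for pc, ps, pe, oc, os_, oe in frags:
            support = overlapping_regions(oc, os_, oe)
            if not support:
                continue
            sub = genes[genes["chrom"] == pc]
            hit = sub[(sub["tss"] >= ps) & (sub["tss"] < pe)]
            for g in hit["gene_id"]:
                if g in out:
                    out[g].supporting_region_ids |= support
                else:
                    out[g] = TargetAssignment(g, "distal", set(support))
    return out


def merge_assignments(
    proximal: dict[str, TargetAssignment], distal: dict[str, TargetAssignment]
) -> dict[str, TargetAssignment]:
    """Union of the two rules, with evidence upgraded to "both" on overlap."""
    out = {g: TargetAssignment(g, a.evidence, set(a.supporting_region_ids))
           for g, a in proximal.items()}
    for g, a in distal.items():
        if g in out:
            out[g].evidence = "both"
            out[g].supporting_region_ids |= a.supporting_region_ids
        else:
            out[g] = TargetAssignment(g, "distal", set(a.supporting_region_ids))
    return out


def classify_direct_targets(
    universe: dict[str, TargetAssignment],
    de_results: list[DEResult],
    th: Thresholds = Thresholds(),
) -> DirectTargetSet:
    """Tri-knockdown concordance classification of assigned genes.

    Repressed targets rise (logFC > +min, strict) with fdr < max in every
    contrast; induced targets fall (logFC < -min) in every contrast.  Genes
    absent from any contrast are excluded (count logged).
    """
    if not de_results:
        raise ValueError("no DE results supplied")
    induced, repressed = set(), set()
    rows = []
    n_missing = 0
    for g in universe:
        per = []
        for de in de_results:
            if g not in de.table.index:
                per = None
                break
            r = de.table.loc[g]
            per.append((float(r["logFC"]), float(r["fdr"])))
        if per is None:
            n_missing += 1
            continue
        sig = all(fdr < th.de_fdr_max for _, fdr in per)
        up = sig and all(lfc > th.de_abs_logfc_min for lfc, _ in per)
        down = sig and all(lfc < -th.de_abs_logfc_min for lfc, _ in per)
        if up:
            repressed.add(g)
        elif down:
            induced.add(g)
        if up or down:
            for de, (lfc, fdr) in zip(de_results, per):
                rows.append((g, de.contrast, lfc, fdr))
    if n_missing:
        logger.info("%d assigned genes absent from a DE table; excluded", n_missing)
    stats = pd.DataFrame(rows, columns=["gene_id", "contrast", "logFC", "fdr"])
    return DirectTargetSet(
        induced=induced,
        repressed=repressed,
        evidence={g: universe[g] for g in induced | repressed},
        stats=stats,
    )
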
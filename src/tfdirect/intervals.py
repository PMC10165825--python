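"""Genomic-interval engine for ChIP-seq peak analysis.

Parses narrowPeak/BED peak files, derives replicate-consensus and
cross-factor overlap regions, applies the summit fold-change and blacklist
filters, annotates peak-to-TSS distances, and tests overlap significance by
a width-preserving permutation null.

All coordinates are 0-based half-open internally (the native narrowPeak/BED
convention), so two intervals that merely abut ([100,200) and [200,300)) do
NOT overlap.  "Overlap" means >= ``min_overlap_bp`` shared bases (default 1).
Cross-set overlap clusters are connected components of the pairwise-overlap
graph; the merged region of a cluster is its union span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "OverlapResult",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_chrom_sizes",
    "overlap_sets",
    "consensus_across_replicates",
    "filter_fold_change",
    "subtract_blacklist",
    "annotate_tss_distance",
    "overlap_significance",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with optional peak metadata.

    ``fold_change`` is the peak caller's signal enrichment at the summit
    (narrowPeak column 7); ``summit_offset`` is the summit position relative
    to ``start`` (narrowPeak column 10; -1 in the file means absent).
    """

    chrom: str
    start: int
    end: int
    id: str
    fold_change: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.id}: start {self.start} >= end {self.end}"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"interval {self.id}: summit offset {self.summit_offset} "
                f"outside [0, {self.end - self.start})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def anchor(self) -> int:
        """Summit position if present, else the floor midpoint."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PeakSet:
    """An ordered collection of peaks for one factor and replicate.

    Intervals are kept sorted by (chrom, start, end); ids must be unique
    within the set.  ``replicate`` is "consensus" for replicate-merged sets.
    """

    factor: str
    replicate: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        ids = [iv.id for iv in self.intervals]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate interval ids in PeakSet {self.factor}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "id": [iv.id for iv in self.intervals],
                "fold_change": [iv.fold_change for iv in self.intervals],
                "summit_offset": [iv.summit_offset for iv in self.intervals],
            }
        )


@dataclass
class OverlapResult:
    """Clusters of mutually overlapping intervals across several peak sets.

    ``merged`` holds one union-span interval per qualifying cluster (one
    contributor from every input set); ``membership[i]`` maps each input-set
    label to the contributing interval ids of cluster i.  ``remainder`` maps
    set labels to ids that ended up in non-qualifying clusters.
    """

    merged: list[GenomicInterval]
    membership: list[dict[str, list[str]]]
    remainder: dict[str, list[str]]


# ---------------------------------------------------------------------------
# narrowPeak / BED I/O


def read_narrowpeak(path) -> PeakSet:
    """Read a narrowPeak (BED6+4) or plain BED file into a PeakSet.

    Column 7 (signalValue) populates ``fold_change`` and column 10 (peak
    summit offset) populates ``summit_offset``; a summit of -1 means absent.
    Raises ValueError with the 1-based line number on malformed lines.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{lineno}"
                fc = float(fields[6]) if len(fields) > 6 else None
                summit = int(fields[9]) if len(fields) > 9 else None
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            if summit is not None and summit < 0:
                summit = None
            intervals.append(
                GenomicInterval(chrom, start, end, name, fc, summit)
            )
    return PeakSet(factor="", replicate="", intervals=intervals)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    """Write a PeakSet as narrowPeak (BED6+4); absent summit written as -1."""
    with open(path, "w") as fh:
        for iv in peaks:
            fc = iv.fold_change if iv.fold_change is not None else 0.0
            summit = iv.summit_offset if iv.summit_offset is not None else -1
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t.\t"
                f"{fc!r}\t-1\t-1\t{summit}\n"
            )


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split("\t")[:2]
            sizes[name] = int(length)
    return sizes


# ---------------------------------------------------------------------------
# overlap machinery


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> int:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri
        return ri


def _cluster_sweep(
    items: list[tuple[GenomicInterval, int]], min_overlap_bp: int
) -> list[list[tuple[GenomicInterval, int]]]:
    """Connected components of the >=min_overlap_bp overlap graph.

    Sweep per chromosome over start-sorted intervals with a union-find.  An
    edge a~b (a.start <= b.start) needs min(a.end, b.end) - b.start >= mo,
    i.e. both ends must reach b.start + mo.  Actives whose end falls short of
    that threshold can never connect to anything later (starts only grow), so
    they are retired; every surviving active connects to b, and the whole
    merged component can be collapsed to its max-end representative.
    """
    mo = min_overlap_bp
    n = len(items)
    uf = _UnionFind(n)
    by_chrom: dict[str, list[int]] = {}
    for k, (iv, _) in enumerate(items):
        by_chrom.setdefault(iv.chrom, []).append(k)
    for chrom in sorted(by_chrom):
        order = sorted(by_chrom[chrom], key=lambda k: (items[k][0].start, items[k][0].end))
        active: list[tuple[int, int]] = []  # (end, node) of component reps
        for k in order:
            iv = items[k][0]
            threshold = iv.start + mo
            active = [(e, node) for e, node in active if e >= threshold]
            if iv.end >= threshold:  # width >= mo: can form edges
                root = k
                max_end = iv.end
                for e, node in active:
                    root = uf.union(root, node)
                    max_end = max(max_end, e)
                active = [(max_end, root)]
            # width < mo: permanent singleton, never pushed
    groups: dict[int, list[tuple[GenomicInterval, int]]] = {}
    for k, item in enumerate(items):
        groups.setdefault(uf.find(k), []).append(item)
    clusters = sorted(
        groups.values(),
        key=lambda g: (g[0][0].chrom, min(iv.start for iv, _ in g)),
    )
    return [
        sorted(g, key=lambda t: (t[0].start, t[0].end, t[1])) for g in clusters
    ]


def overlap_sets(sets: list[PeakSet], min_overlap_bp: int = 1) -> OverlapResult:
    """Find clusters with >=1 contributor from EVERY input set.

    A cluster is a connected component of the pairwise-overlap graph over the
    pooled intervals (edges require >= ``min_overlap_bp`` shared bases).  The
    merged interval of a qualifying cluster is the union span.  Empty input
    sets simply yield an empty result.
    """
    if len(sets) < 2:
        raise ValueError("overlap_sets needs at least two peak sets")
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    labels = [ps.factor or f"set{i}" for i, ps in enumerate(sets)]
    if len(set(labels)) != len(labels):
        labels = [f"{lab}#{i}" for i, lab in enumerate(labels)]
    pooled = [(iv, i) for i, ps in enumerate(sets) for iv in ps]
    clusters = _cluster_sweep(pooled, min_overlap_bp)

    merged: list[GenomicInterval] = []
    membership: list[dict[str, list[str]]] = []
    remainder: dict[str, list[str]] = {lab: [] for lab in labels}
    for cluster in clusters:
        present = {src for _, src in cluster}
        if present == set(range(len(sets))):
            start = min(iv.start for iv, _ in cluster)
            end = max(iv.end for iv, _ in cluster)
            merged.append(
                GenomicInterval(
                    cluster[0][0].chrom, start, end, f"merged_{len(merged) + 1}"
                )
            )
            members: dict[str, list[str]] = {lab: [] for lab in labels}
            for iv, src in cluster:
                members[labels[src]].append(iv.id)
            membership.append(members)
        else:
            for iv, src in cluster:
                remainder[labels[src]].append(iv.id)
    return OverlapResult(merged=merged, membership=membership, remainder=remainder)


def consensus_across_replicates(replicates: list[PeakSet]) -> PeakSet:
    """Peaks supported by every replicate of one factor.

    Returns the union span of each cluster that contains at least one peak
    from every replicate, labelled replicate="consensus".  A single replicate
    is returned unchanged with a warning.
    """
    factors = {ps.factor for ps in replicates}
    if len(factors) != 1:
        raise ValueError(f"replicates span multiple factors: {sorted(factors)}")
    factor = factors.pop()
    if len(replicates) == 1:
        warnings.warn(
            f"single replicate for {factor!r}: consensus equals the input",
            stacklevel=2,
        )
        return PeakSet(factor=factor, replicate="consensus",
                       intervals=list(replicates[0].intervals))
    tagged = [
        PeakSet(factor=f"rep{i}", replicate=ps.replicate, intervals=list(ps.intervals))
        for i, ps in enumerate(replicates)
    ]
    result = overlap_sets(tagged)
    out = [
        replace(iv, id=f"{factor}_consensus_{k + 1}")
        for k, iv in enumerate(result.merged)
    ]
    return PeakSet(factor=factor, replicate="consensus", intervals=out)


def filter_fold_change(peaks: PeakSet, min_fc: float = 2.0) -> PeakSet:
    """Keep peaks with summit fold-change strictly greater than ``min_fc``.

    Peaks lacking a fold-change value are dropped; the count of such peaks is
    reported via a warning so silently-missing signal columns are visible.
    """
    kept, missing = [], 0
    for iv in peaks:
        if iv.fold_change is None:
            missing += 1
        elif iv.fold_change > min_fc:
            kept.append(iv)
    if missing:
        warnings.warn(
            f"{missing} peaks lacked a fold-change value and were dropped",
            stacklevel=2,
        )
    return PeakSet(factor=peaks.factor, replicate=peaks.replicate, intervals=kept)


def subtract_blacklist(peaks: PeakSet, blacklist: PeakSet) -> PeakSet:
    """Remove (whole, never trimmed) any peak overlapping a blacklist region."""
    black = sorted(blacklist.intervals, key=lambda iv: (iv.chrom, iv.start))
    kept = []
    for iv in peaks:
        hit = any(iv.overlap_bp(b) >= 1 for b in black)
        if not hit:
            kept.append(iv)
    return PeakSet(factor=peaks.factor, replicate=peaks.replicate, intervals=kept)


def annotate_tss_distance(peaks: PeakSet, genes: pd.DataFrame) -> pd.DataFrame:
    """Distance from each peak anchor to the nearest gene TSS.

    ``genes`` needs columns gene_id, chrom, strand, tss.  The anchor is the
    summit when present, else the floor midpoint.  The sign is positive when
    the anchor lies downstream of the TSS in the gene's orientation (anchor >
    tss on +, anchor < tss on -).  Absolute-distance ties resolve to the
    lexicographically smallest gene_id.
    """
    out = []
    gene_by_chrom: dict[str, pd.DataFrame] = {
        str(chrom): sub.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        for chrom, sub in genes.groupby("chrom")
    }
    for iv in peaks:
        sub = gene_by_chrom.get(iv.chrom)
        if sub is None or len(sub) == 0:
            out.append((iv.id, None, None))
            continue
        anchor = iv.anchor
        dist = (sub["tss"].to_numpy() - anchor)
        absdist = np.abs(dist)
        best = np.flatnonzero(absdist == absdist.min())
        gidx = best[np.argmin(sub["gene_id"].to_numpy()[best])] if len(best) > 1 else best[0]
        row = sub.iloc[int(gidx)]
        magnitude = int(abs(anchor - row["tss"]))
        downstream = (anchor > row["tss"]) if row["strand"] == "+" else (anchor < row["tss"])
        signed = magnitude if downstream else -magnitude
        if magnitude == 0:
            signed = 0
        out.append((iv.id, row["gene_id"], signed))
    return pd.DataFrame(out, columns=["peak_id", "gene_id", "distance"])


def _count_overlapping(query: list[tuple[str, int, int]],
                       target_by_chrom: dict[str, np.ndarray]) -> int:
    """Number of query intervals overlapping >=1 bp of any target interval."""
    n = 0
    for chrom, start, end in query:
        arr = target_by_chrom.get(chrom)
        if arr is None:
            continue
        # arr is (m, 2) sorted by start
        starts, ends = arr[:, 0], arr[:, 1]
        if np.any((starts < end) & (ends > start)):
            n += 1
    return n


def overlap_significance(
    query: PeakSet,
    target: PeakSet,
    chrom_sizes: dict[str, int],
    nperm: int = 999,
    seed: int = 0,
) -> tuple[int, float]:
    """Permutation test for query/target peak-overlap enrichment.

    The observed statistic is the number of query peaks overlapping any
    target peak.  The null re-places each query peak uniformly within its own
    chromosome, preserving widths (shuffled peaks may overlap one another);
    p = (1 + #{perm >= observed}) / (nperm + 1).
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    for iv in query:
        size = chrom_sizes.get(iv.chrom)
        if size is None:
            raise ValueError(f"no chromosome size for {iv.chrom}")
        if iv.width > size:
            raise ValueError(f"peak {iv.id} wider than chromosome {iv.chrom}")
    target_by_chrom: dict[str, np.ndarray] = {}
    for iv in target:
        target_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    target_by_chrom = {
        c: np.array(sorted(v)) for c, v in target_by_chrom.items()
    }
    observed = _count_overlapping(
        [(iv.chrom, iv.start, iv.end) for iv in query], target_by_chrom
    )
    rng = np.random.default_rng(seed)
    hits = 0
    chroms = [iv.chrom for iv in query]
    widths = np.array([iv.width for iv in query])
    maxstarts = np.array([chrom_sizes[c] - w for c, w in zip(chroms, widths)])
    for _ in range(nperm):
        starts = rng.integers(0, maxstarts + 1)
        placed = list(zip(chroms, starts, starts + widths))
        if _count_overlapping(placed, target_by_chrom) >= observed:
            hits += 1
    p = (1 + hits) / (nperm + 1)
    return observed, p
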
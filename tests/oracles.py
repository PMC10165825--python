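"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — quadratic all-pairs scans, nested
loops, explicit enumeration — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_overlap_clusters(
    sets: list[list[tuple[str, int, int, str]]], min_overlap_bp: int = 1
) -> list[dict]:
    """All-pairs intersection + connected components over pooled intervals.

    Each input set is a list of (chrom, start, end, id).  Returns, for each
    cluster containing members of every set, a dict with the merged span and
    the member ids per set index, sorted by (chrom, start).
    """
    pooled = [
        (chrom, start, end, iid, si)
        for si, s in enumerate(sets)
        for (chrom, start, end, iid) in s
    ]
    n = len(pooled)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pooled[i], pooled[j]
            if a[0] != b[0]:
                continue
            if min(a[2], b[2]) - max(a[1], b[1]) >= min_overlap_bp:
                adj[i][j] = adj[j][i] = True
    seen = [False] * n
    clusters = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            k = stack.pop()
            comp.append(k)
            for j in range(n):
                if adj[k][j] and not seen[j]:
                    seen[j] = True
                    stack.append(j)
        members = [pooled[k] for k in comp]
        if {m[4] for m in members} == set(range(len(sets))):
            clusters.append(
                {
                    "chrom": members[0][0],
                    "start": min(m[1] for m in members),
                    "end": max(m[2] for m in members),
                    "ids": {
                        si: sorted(m[3] for m in members if m[4] == si)
                        for si in range(len(sets))
                    },
                }
            )
    return sorted(clusters, key=lambda c: (c["chrom"], c["start"]))


def brute_subtract(peaks, blacklist):
    """Nested-loop whole-peak blacklist removal; inputs as (chrom,start,end,id)."""
    out = []
    for p in peaks:
        hit = any(
            p[0] == b[0] and min(p[2], b[2]) - max(p[1], b[1]) >= 1
            for b in blacklist
        )
        if not hit:
            out.append(p)
    return out


def brute_nearest_tss(anchor_chrom, anchor_pos, genes):
    """Exhaustive nearest-TSS scan; genes is a DataFrame."""
    sub = genes[genes["chrom"] == anchor_chrom]
    best = None
    for row in sub.itertuples():
        d = abs(int(row.tss) - anchor_pos)
        key = (d, row.gene_id)
        if best is None or key < best[0]:
            down = anchor_pos > row.tss if row.strand == "+" else anchor_pos < row.tss
            signed = 0 if d == 0 else (d if down else -d)
            best = (key, row.gene_id, signed)
    return (best[1], best[2]) if best else (None, None)


def brute_assign_proximal(regions, genes, window):
    """Quadratic gene x region scan; regions as (chrom, start, end, id)."""
    out = {}
    for row in genes.itertuples():
        hits = set()
        for chrom, start, end, rid in regions:
            if chrom != row.chrom:
                continue
            tss = int(row.tss)
            if start <= tss < end:
                gap = 0
            elif tss < start:
                gap = start - tss
            else:
                gap = tss - (end - 1)
            if gap <= window:
                hits.add(rid)
        if hits:
            out[row.gene_id] = hits
    return out


def brute_assign_distal(regions, genes, interactions, p_max):
    """Nested-loop three-way join of gene TSS, fragment pairs, and regions."""
    out = {}
    for rec in interactions.itertuples():
        if rec.p_value > p_max:
            continue
        frag_pairs = [
            ((rec.chrom_a, rec.start_a, rec.end_a), (rec.chrom_b, rec.start_b, rec.end_b)),
            ((rec.chrom_b, rec.start_b, rec.end_b), (rec.chrom_a, rec.start_a, rec.end_a)),
        ]
        for (pc, ps, pe), (oc, os_, oe) in frag_pairs:
            touching = {
                rid
                for chrom, start, end, rid in regions
                if chrom == oc and min(end, oe) - max(start, os_) >= 1
            }
            if not touching:
                continue
            for row in genes.itertuples():
                if row.chrom == pc and ps <= int(row.tss) < pe:
                    out.setdefault(row.gene_id, set()).update(touching)
    return out


def reml_grid_loglik(y, X, groups, lam_grid):
    """Grid evaluation of the restricted log-likelihood over variance ratios.

    Direct dense-matrix REML: V0 = I + lam ZZ', ll = -0.5[(n-p) log s2 +
    log|V0| + log|X'V0^-1 X| + (n-p)], s2 = r'V0^-1 r/(n-p).  Independent of
    the package's blockwise profile implementation.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    n, p = X.shape
    Z = (groups[:, None] == np.unique(groups)[None, :]).astype(float)
    lls = []
    for lam in lam_grid:
        V0 = np.eye(n) + lam * Z @ Z.T
        Vi = np.linalg.inv(V0)
        XtVX = X.T @ Vi @ X
        beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
        r = y - X @ beta
        s2 = (r @ Vi @ r) / (n - p)
        _, ld_v = np.linalg.slogdet(V0)
        _, ld_x = np.linalg.slogdet(XtVX)
        lls.append(-0.5 * ((n - p) * np.log(s2) + ld_v + ld_x + (n - p)))
    return np.array(lls)


def gsea_es_bruteforce(t_stats, hit_positions, exponent=1.0):
    """Step-by-step running-sum ES, written independently of the package."""
    n = len(t_stats)
    hits = set(hit_positions)
    wsum = sum(abs(t_stats[i]) ** exponent for i in hits)
    best, run = 0.0, 0.0
    for i in range(n):
        if i in hits:
            run += (abs(t_stats[i]) ** exponent) / wsum if wsum > 0 else 1.0 / len(hits)
        else:
            run -= 1.0 / (n - len(hits))
        if abs(run) > abs(best):
            best = run
    return best


def gsea_exhaustive_p(t_stats, set_size, observed_es, exponent=1.0):
    """Exact same-sign tail probability over all C(N, k) placements."""
    n = len(t_stats)
    null = [
        gsea_es_bruteforce(t_stats, combo, exponent)
        for combo in itertools.combinations(range(n), set_size)
    ]
    sign = 1.0 if observed_es >= 0 else -1.0
    same = [e for e in null if e * sign > 0]
    extreme = sum(1 for e in same if abs(e) >= abs(observed_es))
    return (1 + extreme) / (len(same) + 1)


def hypergeom_tail_sum(k, n_universe, n_set, n_draw):
    """P(X >= k) by direct summation of hypergeometric point masses."""
    from math import comb

    total = comb(n_universe, n_draw)
    return sum(
        comb(n_set, x) * comb(n_universe - n_set, n_draw - x)
        for x in range(k, min(n_set, n_draw) + 1)
    ) / total


def fisher_two_sided_p(table):
    """Two-sided Fisher p by summation of as-or-less-probable tables."""
    from math import comb

    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    denom = comb(n, col1)

    def prob(x):
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > c + d:
            return 0.0
        return comb(row1, x) * comb(n - row1, col1 - x) / denom

    p_obs = prob(a)
    return sum(p for x in range(0, col1 + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9))
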
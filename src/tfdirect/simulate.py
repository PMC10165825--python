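"""Synthetic-data generator with planted ground truth.

Every input the pipeline consumes can be generated here: replicate ChIP-seq
peak sets for several factors with planted co-binding near a subset of gene
TSSs, fragment-pair interaction tables linking distal peaks to promoters,
negative-binomial knockdown count matrices with planted concordant targets
(shared controls across arms, as in a multi-control siRNA design), and a
multi-patient cohort expression matrix with an ordinal histologic-grade
effect, patient random intercepts, and progression labels.

The generator is the study-design stand-in: planted truth is recorded in a
:class:`GroundTruth` object so recovery can be scored exactly.  Identical
configurations produce bit-identical outputs; each stage draws from its own
seeded substream so stages can be regenerated independently.

What it does NOT emulate: read-level sequencing noise, chromatin-state
structure around peaks, GC/length biases, or single-cell sparsity beyond
what the count model implies.  Conclusions from passing tests are about the
pipeline's logic and statistics, not about properties of any real dataset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .intervals import GenomicInterval, PeakSet, write_narrowpeak
from .signatures import GeneSet, write_gmt

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortSim",
    "simulate_genome",
    "simulate_peaks",
    "simulate_knockdown_counts",
    "simulate_cohort",
    "simulate_grade_response",
    "write_outputs",
    "read_genes",
    "read_interactions",
    "read_counts",
]

_FACTOR_NAMES = ["TF_A", "TF_B", "TF_C", "TF_D", "TF_E", "TF_F"]
_CELL_LINES = ["HBEC1", "HBEC2", "HBEC3"]


@dataclass(frozen=True)
class SimulationConfig:
    """All generator knobs, mirroring the emulated study designs.

    Defaults encode the reference conditions: a 2 x 25 Mb toy genome with
    2,000 genes; 3 factors x 3 replicates of peaks; 90 planted co-bound
    target genes (two-thirds induced) with |log2 fold change| 1.5 and NB
    dispersion 0.1 in triplicate knockdown arms against shared triplicate
    controls; and a 30-patient x 3-biopsy cohort over 7 ordinal grades with
    score slope 0.5 per grade step, patient SD 1.0 and residual SD 0.5.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 25_000_000
    n_genes: int = 2_000
    n_factors: int = 3
    n_replicates: int = 3
    n_cobound_target_genes: int = 90
    frac_induced: float = 2 / 3
    planted_logfc: float = 1.5
    nb_dispersion: float = 0.1
    n_samples_per_arm: int = 3
    peak_width_bp: tuple[int, int] = (200, 400)
    noise_peaks_per_replicate: int = 150
    hic_linked_fraction: float = 0.2
    n_noise_interactions: int = 200
    cohort_n_patients: int = 30
    biopsies_per_patient: int = 3
    grade_levels: int = 7
    grade_slope: float = 0.5
    patient_sd: float = 1.0
    resid_sd: float = 0.5

    def __post_init__(self) -> None:
        counts = (
            self.n_chroms, self.chrom_length_bp, self.n_genes, self.n_factors,
            self.n_replicates, self.n_samples_per_arm, self.cohort_n_patients,
            self.biopsies_per_patient, self.grade_levels,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if not (0 <= self.frac_induced <= 1 and 0 <= self.hic_linked_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.patient_sd < 0 or self.resid_sd <= 0:
            raise ValueError("patient_sd >= 0 and resid_sd > 0 required")
        if self.n_cobound_target_genes > self.n_genes:
            raise ValueError("more planted targets than genes")
        if self.n_factors > len(_FACTOR_NAMES):
            raise ValueError(f"at most {len(_FACTOR_NAMES)} factors supported")

    @property
    def factors(self) -> list[str]:
        return _FACTOR_NAMES[: self.n_factors]

    def _rng(self, stage: int) -> np.random.Generator:
        # independent substream per stage, reproducible from the one seed
        return np.random.default_rng([stage, self.seed])


@dataclass
class GroundTruth:
    """What the generator planted, for exact recovery scoring."""

    induced_gene_ids: set[str] = field(default_factory=set)
    repressed_gene_ids: set[str] = field(default_factory=set)
    cobound_peak_ids: dict[str, list[str]] = field(default_factory=dict)
    distal_linked_gene_ids: set[str] = field(default_factory=set)
    cohort_true_slope: float = np.nan

    def __post_init__(self) -> None:
        if self.induced_gene_ids & self.repressed_gene_ids:
            raise ValueError("induced and repressed truth sets overlap")

    @property
    def all_targets(self) -> set[str]:
        return self.induced_gene_ids | self.repressed_gene_ids

    def to_json(self, path) -> None:
        obj = {
            "induced_gene_ids": sorted(self.induced_gene_ids),
            "repressed_gene_ids": sorted(self.repressed_gene_ids),
            "cobound_peak_ids": {k: sorted(v) for k, v in self.cobound_peak_ids.items()},
            "distal_linked_gene_ids": sorted(self.distal_linked_gene_ids),
            "cohort_true_slope": self.cohort_true_slope,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            induced_gene_ids=set(obj["induced_gene_ids"]),
            repressed_gene_ids=set(obj["repressed_gene_ids"]),
            cobound_peak_ids={k: list(v) for k, v in obj["cobound_peak_ids"].items()},
            distal_linked_gene_ids=set(obj["distal_linked_gene_ids"]),
            cohort_true_slope=obj["cohort_true_slope"],
        )


# ---------------------------------------------------------------------------
# genome


def simulate_genome(cfg: SimulationConfig) -> pd.DataFrame:
    """Gene annotation table: gene_id, chrom, strand, tss.

    TSSs are uniform on each chromosome with a margin from the ends (so
    distal peaks and promoter fragments always fit); collisions are
    re-drawn.  Deterministic under the config seed.
    """
    rng = cfg._rng(1)
    margin = 200_000
    lo, hi = margin, cfg.chrom_length_bp - margin
    if hi - lo < cfg.n_genes:  # cannot place unique positions
        raise ValueError("n_genes exceeds placeable TSS positions")
    chroms = np.array([f"chr{i + 1}" for i in range(cfg.n_chroms)])
    gene_chrom = chroms[rng.integers(0, cfg.n_chroms, size=cfg.n_genes)]
    tss = rng.integers(lo, hi, size=cfg.n_genes)
    # re-draw collisions within a chromosome until all TSS are unique
    for _ in range(100):
        key = pd.MultiIndex.from_arrays([gene_chrom, tss])
        dup = key.duplicated()
        if not dup.any():
            break
        tss[dup] = rng.integers(lo, hi, size=int(dup.sum()))
    else:  # pragma: no cover - would need pathological density
        raise RuntimeError("could not resolve TSS collisions")
    strand = rng.choice(["+", "-"], size=cfg.n_genes)
    width = len(str(cfg.n_genes))
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:0{width}d}" for i in range(cfg.n_genes)],
            "chrom": gene_chrom,
            "strand": strand,
            "tss": tss,
        }
    )
    return genes.sort_values(["chrom", "tss"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# peaks + interactions


@dataclass
class PeakSim:
    """Peak sets per factor/replicate plus the interaction table."""

    peaksets: dict[tuple[str, str], PeakSet]
    interactions: pd.DataFrame
    truth: GroundTruth
    chrom_sizes: dict[str, int]


def simulate_peaks(cfg: SimulationConfig, genes: pd.DataFrame) -> PeakSim:
    """Plant one co-localised peak per factor (all replicates) per target.

    Proximal targets get the peak within 50 kb of their TSS; a
    ``hic_linked_fraction`` of targets instead get it > 50 kb away together
    with a significant promoter-fragment interaction linking it back.
    Noise peaks are unique to single replicates and factors, so they do not
    survive replicate consensus; noise interactions carry uniform p-values.
    """
    rng = cfg._rng(2)
    shuffled = genes["gene_id"].to_numpy().copy()
    rng.shuffle(shuffled)
    planted = list(shuffled[: cfg.n_cobound_target_genes])
    n_induced = int(round(cfg.frac_induced * len(planted)))
    truth = GroundTruth(
        induced_gene_ids=set(planted[:n_induced]),
        repressed_gene_ids=set(planted[n_induced:]),
        cohort_true_slope=cfg.grade_slope,
    )
    gene_rows = genes.set_index("gene_id")
    wlo, whi = cfg.peak_width_bp
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length_bp for i in range(cfg.n_chroms)}

    intervals: dict[tuple[str, str], list[GenomicInterval]] = {
        (f, f"rep{r + 1}"): []
        for f in cfg.factors
        for r in range(cfg.n_replicates)
    }
    truth.cobound_peak_ids = {f: [] for f in cfg.factors}
    inter_rows = []

    for g in planted:
        row = gene_rows.loc[g]
        tss = int(row["tss"])
        distal = rng.random() < cfg.hic_linked_fraction
        if distal:
            offset = int(rng.integers(80_000, 150_000)) * (1 if rng.random() < 0.5 else -1)
            center = tss + offset
            truth.distal_linked_gene_ids.add(g)
            # promoter fragment around the TSS, partner fragment over the peak
            inter_rows.append(
                (row["chrom"], tss - 2_000, tss + 2_000,
                 row["chrom"], center - 5_000, center + 5_000,
                 float(rng.uniform(0.0005, 0.04)))
            )
        else:
            # within the proximal window even after width and jitter
            center = tss + int(rng.integers(-40_000, 40_001))
        for fi, factor in enumerate(cfg.factors):
            f_center = center + int(rng.integers(-50, 51))
            width = int(rng.integers(wlo, whi + 1))
            start0 = f_center - width // 2
            for r in range(cfg.n_replicates):
                jitter = int(rng.integers(-20, 21))
                start = max(0, start0 + jitter)
                pid = f"{factor}_rep{r + 1}_t{g}"
                iv = GenomicInterval(
                    chrom=str(row["chrom"]), start=start, end=start + width,
                    id=pid, fold_change=float(rng.uniform(2.5, 10.0)),
                    summit_offset=width // 2,
                )
                intervals[(factor, f"rep{r + 1}")].append(iv)
                truth.cobound_peak_ids[factor].append(pid)

    for factor in cfg.factors:
        for r in range(cfg.n_replicates):
            for k in range(cfg.noise_peaks_per_replicate):
                chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
                width = int(rng.integers(wlo, whi + 1))
                start = int(rng.integers(0, cfg.chrom_length_bp - width))
                iv = GenomicInterval(
                    chrom=chrom, start=start, end=start + width,
                    id=f"{factor}_rep{r + 1}_n{k + 1}",
                    fold_change=float(rng.uniform(0.5, 8.0)),
                    summit_offset=width // 2,
                )
                intervals[(factor, f"rep{r + 1}")].append(iv)

    for k in range(cfg.n_noise_interactions):
        chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
        a = int(rng.integers(100_000, cfg.chrom_length_bp - 100_000))
        b = a + int(rng.integers(60_000, 400_000))
        inter_rows.append(
            (chrom, a - 2_500, a + 2_500, chrom, b - 2_500, b + 2_500,
             float(rng.uniform(0.0, 1.0)))
        )

    peaksets = {
        key: PeakSet(factor=key[0], replicate=key[1], intervals=ivs)
        for key, ivs in intervals.items()
    }
    interactions = pd.DataFrame(
        inter_rows,
        columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
                 "p_value"],
    )
    return PeakSim(peaksets=peaksets, interactions=interactions, truth=truth,
                   chrom_sizes=chrom_sizes)


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with variance mu + dispersion * mu^2."""
    mean = np.maximum(mean, 1e-8)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def simulate_knockdown_counts(
    cfg: SimulationConfig, genes: pd.DataFrame, truth: GroundTruth
) -> CountMatrix:
    """Knockdown arms (one per factor) against shared control samples.

    Baseline means are log-normal(log 100, 1); induced targets drop by
    ``planted_logfc`` log2 units in every arm, repressed targets rise by the
    same amount, non-targets are unchanged.  Library sizes vary x[0.5, 2]
    and per-gene cell-line offsets are added (samples cycle through the
    cell lines within each arm).
    """
    if cfg.nb_dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = cfg._rng(3)
    gene_ids = genes["gene_id"].to_numpy()
    n_genes = len(gene_ids)
    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)
    cl_offset = rng.normal(0.0, 0.15, size=(n_genes, len(_CELL_LINES)))

    induced = np.isin(gene_ids, list(truth.induced_gene_ids))
    repressed = np.isin(gene_ids, list(truth.repressed_gene_ids))

    arms = ["control"] + [f"si{f}" for f in cfg.factors]
    cols, col_meta = [], []
    for arm in arms:
        effect = np.zeros(n_genes)
        if arm != "control":
            effect = np.where(induced, -cfg.planted_logfc,
                              np.where(repressed, cfg.planted_logfc, 0.0))
        for s in range(cfg.n_samples_per_arm):
            cl = s % len(_CELL_LINES)
            libf = rng.uniform(0.5, 2.0)
            mu = base * 2.0 ** (effect + cl_offset[:, cl]) * libf
            cols.append(_nb_draw(rng, mu, cfg.nb_dispersion))
            col_meta.append(
                {"sample_id": f"{arm}_s{s + 1}", "treatment": arm,
                 "cell_line": _CELL_LINES[cl]}
            )
    counts = pd.DataFrame(
        np.column_stack(cols), index=gene_ids,
        columns=[m["sample_id"] for m in col_meta],
    )
    meta = pd.DataFrame(col_meta).set_index("sample_id")
    return CountMatrix(counts=counts, meta=meta)


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortSim:
    """Cohort counts, design table, planted latent, and immune sets."""

    counts: CountMatrix
    design: pd.DataFrame
    latent: np.ndarray  # per-sample planted score (log2 units)
    immune_sets: list[GeneSet]
    designated_gene: str  # the exemplar repressed target (CIITA analog)
    single_biopsy_warning: bool = False


_IMMUNE_CELL_TYPES = [
    "Th1_cells", "Th2_cells", "Th17_cells", "Treg_cells", "CD8_T_cells",
    "T_helper_cells", "Tgd_cells", "Tcm_cells", "Tem_cells", "NK_cells",
    "NK_CD56bright", "NK_CD56dim", "B_cells", "Cytotoxic_cells", "DC_cells",
    "iDC_cells", "aDC_cells", "pDC_cells", "Macrophages", "Mast_cells",
    "Neutrophils", "Eosinophils", "TFH_cells", "Monocytes",
]


def simulate_cohort(
    cfg: SimulationConfig, genes: pd.DataFrame, truth: GroundTruth
) -> CohortSim:
    """Multi-patient biopsy cohort with an ordinal-grade effect.

    Each sample carries a latent score s = grade_slope * grade + b_patient +
    noise (b ~ N(0, patient_sd^2), noise ~ N(0, resid_sd^2)).  Induced-target
    genes shift by +s log2 units, repressed targets by -s; the progression
    label thresholds s + noise at its median (high latent -> progressive/
    persistent), so repressed targets are up in regressive lesions by
    construction.  One immune set (Th1-like) is planted to co-vary with the
    designated repressed target; the other 23 are neutral gene sets.
    """
    rng = cfg._rng(4)
    gene_ids = genes["gene_id"].to_numpy()
    n_genes = len(gene_ids)
    induced = np.isin(gene_ids, list(truth.induced_gene_ids))
    repressed = np.isin(gene_ids, list(truth.repressed_gene_ids))

    n_samples = cfg.cohort_n_patients * cfg.biopsies_per_patient
    patient = np.repeat(np.arange(cfg.cohort_n_patients), cfg.biopsies_per_patient)
    grade = rng.integers(0, cfg.grade_levels, size=n_samples)
    b_patient = rng.normal(0.0, cfg.patient_sd, size=cfg.cohort_n_patients)
    eps = rng.normal(0.0, cfg.resid_sd, size=n_samples)
    latent = cfg.grade_slope * grade + b_patient[patient] + eps

    warned = cfg.biopsies_per_patient == 1
    if warned:
        warnings.warn(
            "one biopsy per patient: cohort design degenerates to "
            "independent samples",
            stacklevel=2,
        )

    # immune gene sets drawn from non-target genes; set 0 tracks the
    # designated repressed target (negative latent direction)
    non_target = gene_ids[~(induced | repressed)]
    per_set = min(30, len(non_target) // len(_IMMUNE_CELL_TYPES))
    if per_set < 2:
        raise ValueError("too few non-target genes to build immune sets")
    picks = rng.choice(len(non_target), size=len(_IMMUNE_CELL_TYPES) * per_set,
                       replace=False)
    immune_sets = []
    immune_masks = np.zeros((len(_IMMUNE_CELL_TYPES), n_genes), dtype=bool)
    for i, name in enumerate(_IMMUNE_CELL_TYPES):
        members = non_target[picks[i * per_set: (i + 1) * per_set]]
        immune_sets.append(GeneSet(name=name, genes=frozenset(members)))
        immune_masks[i] = np.isin(gene_ids, members)
    designated = sorted(truth.repressed_gene_ids)[0] if truth.repressed_gene_ids \
        else gene_ids[0]

    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)
    shift_sign = np.where(induced, 1.0, np.where(repressed, -1.0, 0.0))
    th1_coupling = np.where(immune_masks[0], -0.8, 0.0)

    cols = []
    prog_noise = rng.normal(0.0, 0.5, size=n_samples)
    for j in range(n_samples):
        libf = rng.uniform(0.5, 2.0)
        mu = base * 2.0 ** ((shift_sign + th1_coupling) * latent[j]) * libf
        cols.append(_nb_draw(rng, mu, cfg.nb_dispersion))
    prog_latent = latent + prog_noise
    progressive = prog_latent > np.median(prog_latent)

    sample_ids = [
        f"pt{p + 1:02d}_b{j % cfg.biopsies_per_patient + 1}"
        for j, p in enumerate(patient)
    ]
    design = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient": [f"pt{p + 1:02d}" for p in patient],
            "grade": grade,
            "progression": np.where(progressive, "progressive/persistent",
                                    "regressive"),
            "subtype": rng.choice(["Proliferative", "Other"], size=n_samples,
                                  p=[2 / 3, 1 / 3]),
            "batch": np.where(np.arange(n_samples) % 2 == 0, "b1", "b2"),
            "tin": np.round(rng.normal(75.0, 5.0, size=n_samples), 2),
        }
    ).set_index("sample_id")
    counts = pd.DataFrame(np.column_stack(cols), index=gene_ids,
                          columns=design.index)
    return CohortSim(
        counts=CountMatrix(counts=counts, meta=design.copy()),
        design=design,
        latent=latent,
        immune_sets=immune_sets,
        designated_gene=designated,
        single_biopsy_warning=warned,
    )


def simulate_grade_response(
    n_patients: int = 30,
    biopsies_per_patient: int = 3,
    slope: float = 0.5,
    patient_sd: float = 1.0,
    resid_sd: float = 0.5,
    grade_levels: int = 7,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Direct draw from the random-intercept model: (y, grade, patient).

    y_ij = slope * grade_ij + b_i + e_ij; the minimal generator for
    mixed-model parameter-recovery experiments.
    """
    rng = np.random.default_rng([5, seed])
    n = n_patients * biopsies_per_patient
    patient = np.repeat(np.arange(n_patients), biopsies_per_patient)
    grade = rng.integers(0, grade_levels, size=n)
    y = (
        slope * grade
        + rng.normal(0.0, patient_sd, size=n_patients)[patient]
        + rng.normal(0.0, resid_sd, size=n)
    )
    return y, grade, patient


# ---------------------------------------------------------------------------
# file I/O (round-trips through the pipeline's own readers)


def write_outputs(cfg: SimulationConfig, outdir) -> Path:
    """Generate everything and write it under one directory.

    Emits narrowPeak files per factor x replicate, the gene table,
    chromosome sizes, the interaction table, knockdown and cohort count and
    metadata TSVs, the immune-set GMT, and the ground-truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = simulate_genome(cfg)
    sim = simulate_peaks(cfg, genes)
    kd = simulate_knockdown_counts(cfg, genes, sim.truth)
    cohort = simulate_cohort(cfg, genes, sim.truth)

    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    with open(outdir / "chrom_sizes.tsv", "w") as fh:
        for chrom, size in sim.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    for (factor, rep), ps in sim.peaksets.items():
        write_narrowpeak(ps, outdir / f"peaks_{factor}_{rep}.narrowPeak")
    sim.interactions.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    kd.counts.to_csv(outdir / "knockdown_counts.tsv", sep="\t")
    kd.meta.to_csv(outdir / "knockdown_meta.tsv", sep="\t")
    cohort.counts.counts.to_csv(outdir / "cohort_counts.tsv", sep="\t")
    cohort.design.to_csv(outdir / "cohort_meta.tsv", sep="\t")
    write_gmt(cohort.immune_sets, outdir / "immune_sets.gmt")
    sim.truth.to_json(outdir / "ground_truth.json")
    manifest = asdict(cfg)
    manifest["designated_gene"] = cohort.designated_gene
    (outdir / "sim_manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def read_genes(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "tss"}
    if not required <= set(genes.columns):
        raise ValueError(f"gene table missing columns {required - set(genes.columns)}")
    return genes


def read_interactions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_counts(counts_path, meta_path=None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path else pd.DataFrame()
    return CountMatrix(counts=counts, meta=meta)
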
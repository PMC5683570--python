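"""Synthetic coupled miRNA/mRNA count data with planted regulatory structure.

The generator emulates the statistical shape of a two-group (tumor versus
normal germinal-center B cell) deep-sequencing study at desk scale:

* a regulatory prior — each miRNA gets a fixed number of random validated
  targets; a subset of genes act as TFs with random out-edges;
* negative-binomial counts over log-normally spread baseline abundances
  and log-normal library sizes (deeper for the mRNA assay than for the
  miRNA assay, mirroring assay depth asymmetry);
* planted driver miRNAs up-regulated in tumors whose validated targets
  are repressed, coupled through a per-sample driver-activity variable so
  that planted pairs are negatively correlated across samples — the
  signal every downstream stage is meant to recover;
* independently planted up/down DE genes, and an optional batch factor
  shifting a random 30% of features in half the samples.

Everything is reproducible bit-for-bit from ``SimConfig.seed``, and the
planted structure is returned as machine-readable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, EdgeList, SampleSheet

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_network",
    "simulate_counts",
    "simulate_study",
    "write_truth",
    "read_truth",
]

#: fraction of features a batch effect touches
BATCH_FRACTION = 0.3


@dataclass
class SimConfig:
    """Study-design and effect-size knobs for the generator.

    Defaults follow the miRNA arm of the emulated design: 17 tumors
    versus 4 normals, planted drivers at log2FC 3, per-driver target
    knockdown of -1.5 log2 units (summed over a gene's up drivers, capped
    at -4), 10% independent DE genes at |log2FC| 3, NB dispersion 0.2.
    """

    n_genes: int = 300
    n_tfs: int = 30
    n_mirnas: int = 55
    targets_per_mirna: int = 10
    genes_per_tf: int = 8
    n_tumor: int = 17
    n_normal: int = 4
    n_drivers: int = 5
    lfc_mirna: float = 3.0
    repression_lfc: float = -1.5
    repression_cap: float = -4.0
    frac_de_genes: float = 0.1
    lfc_gene: float = 3.0
    dispersion: float = 0.2
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    activity_sd: float = 0.5  # per-sample driver-activity noise, log2 units
    mirna_depth: float = 1e6
    mrna_depth: float = 2e7
    depth_log2_sd: float = 0.25
    batch_shift: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.targets_per_mirna > self.n_genes:
            raise ValueError("targets_per_mirna cannot exceed n_genes")
        if self.genes_per_tf > self.n_genes - 1:
            raise ValueError("genes_per_tf cannot exceed n_genes - 1")
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs cannot exceed n_genes")
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need at least 2 samples per group")
        if self.n_drivers > self.n_mirnas:
            raise ValueError("n_drivers cannot exceed n_mirnas")

    @classmethod
    def mrna_arm(cls, **kw) -> "SimConfig":
        """Preset for the mRNA arm of the emulated design (28 vs 5)."""
        kw.setdefault("n_tumor", 28)
        kw.setdefault("n_normal", 5)
        return cls(**kw)


@dataclass
class GroundTruth:
    """Planted structure: drivers, independent DE genes, repression pairs,
    and the batch assignment (empty when no batch effect was simulated)."""

    drivers: pd.DataFrame  # mirna_id, log2fc
    de_genes: pd.DataFrame  # gene_id, log2fc
    pairs: pd.DataFrame  # mirna_id, gene_id
    batch: pd.Series = field(default_factory=lambda: pd.Series(dtype=str))


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-{i + 1:03d}" for i in range(n)]


def simulate_network(cfg: SimConfig) -> tuple[EdgeList, dict[str, list[str]]]:
    """Random regulatory prior: miRNA->target and TF->gene edges.

    Each miRNA receives exactly ``targets_per_mirna`` distinct targets
    drawn uniformly; the first ``n_tfs`` genes act as TFs with exactly
    ``genes_per_tf`` out-edges each (no self-loops). Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    genes = _gene_ids(cfg.n_genes)
    mirnas = _mirna_ids(cfg.n_mirnas)
    tfs = genes[: cfg.n_tfs]
    rows = []
    for m in mirnas:
        picks = rng.choice(cfg.n_genes, size=cfg.targets_per_mirna, replace=False)
        for j in sorted(picks):
            rows.append((m, genes[j], "mirna_target", "simulated"))
    for tf in tfs:
        others = [g for g in genes if g != tf]
        picks = rng.choice(len(others), size=cfg.genes_per_tf, replace=False)
        for j in sorted(picks):
            rows.append((tf, others[j], "tf_gene", "simulated"))
    edges = EdgeList(pd.DataFrame(rows, columns=["source", "target", "edge_type", "evidence"]))
    rosters = {"genes": genes, "tfs": tfs, "mirnas": mirnas}
    return edges, rosters


def simulate_counts(cfg: SimConfig, edges: EdgeList
                    ) -> tuple[CountMatrix, CountMatrix, SampleSheet, GroundTruth]:
    """NB count matrices for both assays plus sample sheet and truth.

    Tumor-group means are multiplied by 2^log2FC for drivers, independent
    DE genes and repressed targets; a per-sample driver-activity variable
    (log2-normal around the group effect) scales each driver's miRNA mean
    up and its targets' means down, so planted pairs anti-correlate across
    samples, not just between groups.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    genes = _gene_ids(cfg.n_genes)
    mirnas = _mirna_ids(cfg.n_mirnas)
    samples = [f"T{i + 1:02d}" for i in range(cfg.n_tumor)] + [
        f"N{i + 1:02d}" for i in range(cfg.n_normal)
    ]
    is_tumor = np.array([s.startswith("T") for s in samples])
    n_samples = len(samples)

    drivers = sorted(rng.choice(cfg.n_mirnas, size=cfg.n_drivers, replace=False))
    driver_ids = [mirnas[i] for i in drivers]
    target_map = {m: edges.targets_of(m) for m in driver_ids}
    pair_rows = [(m, g) for m in driver_ids for g in target_map[m]]
    repressed = sorted({g for _, g in pair_rows})

    # per-sample driver activity, log2 scale: group effect + shared noise
    activity = (
        cfg.lfc_mirna * is_tumor[None, :]
        + rng.normal(0.0, cfg.activity_sd, size=(cfg.n_drivers, n_samples))
    ) if cfg.n_drivers else np.zeros((0, n_samples))

    # log2 multiplier matrices
    mirna_shift = np.zeros((cfg.n_mirnas, n_samples))
    for k, i in enumerate(drivers):
        mirna_shift[i] = activity[k]

    gene_shift = np.zeros((cfg.n_genes, n_samples))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for g in repressed:
        ks = [k for k, m in enumerate(driver_ids) if g in target_map[m]]
        total = cfg.repression_lfc * len(ks)
        scale = 1.0 if total >= cfg.repression_cap else cfg.repression_cap / total
        w = cfg.repression_lfc * scale  # per-driver contribution after capping
        for k in ks:
            if cfg.lfc_mirna != 0:
                gene_shift[gene_idx[g]] += (w / cfg.lfc_mirna) * activity[k]
            else:
                gene_shift[gene_idx[g]] += w * is_tumor

    # independent DE genes among those untouched by drivers
    free = [g for g in genes if g not in set(repressed)]
    n_de = int(round(cfg.frac_de_genes * cfg.n_genes))
    n_de = min(n_de, len(free))
    de_pick = sorted(rng.choice(len(free), size=n_de, replace=False))
    de_gene_rows = []
    for j, idx in enumerate(de_pick):
        lfc = cfg.lfc_gene if j % 2 == 0 else -cfg.lfc_gene
        gene_shift[gene_idx[free[idx]]] += lfc * is_tumor
        de_gene_rows.append((free[idx], lfc))

    # batch effect: half the samples (alternating, spanning both groups)
    batch = pd.Series(dtype=str)
    batch_cols = ["A" if i % 2 == 0 else "B" for i in range(n_samples)]
    if cfg.batch_shift is not None:
        batch = pd.Series(batch_cols, index=samples)
        in_b = np.array([b == "B" for b in batch_cols])
        for shift_mat, n_feat in ((mirna_shift, cfg.n_mirnas), (gene_shift, cfg.n_genes)):
            touched = rng.choice(n_feat, size=int(round(BATCH_FRACTION * n_feat)),
                                 replace=False)
            shift_mat[np.ix_(touched, np.where(in_b)[0])] += cfg.batch_shift

    mirna_counts = _nb_counts(rng, cfg, cfg.n_mirnas, mirna_shift,
                              cfg.mirna_depth, n_samples)
    mrna_counts = _nb_counts(rng, cfg, cfg.n_genes, gene_shift,
                             cfg.mrna_depth, n_samples)

    mirna_mat = CountMatrix(pd.DataFrame(mirna_counts, index=mirnas, columns=samples), "mirna")
    mrna_mat = CountMatrix(pd.DataFrame(mrna_counts, index=genes, columns=samples), "mrna")
    sheet_df = pd.DataFrame(
        {"group": np.where(is_tumor, "tumor", "normal")}, index=pd.Index(samples, name="sample_id")
    )
    if cfg.batch_shift is not None:
        sheet_df["batch"] = batch_cols
    truth = GroundTruth(
        drivers=pd.DataFrame({"mirna_id": driver_ids,
                              "log2fc": [cfg.lfc_mirna] * len(driver_ids)}),
        de_genes=pd.DataFrame(de_gene_rows, columns=["gene_id", "log2fc"]),
        pairs=pd.DataFrame(pair_rows, columns=["mirna_id", "gene_id"]),
        batch=batch,
    )
    return mirna_mat, mrna_mat, SampleSheet(sheet_df), truth


def _nb_counts(rng: np.random.Generator, cfg: SimConfig, n_features: int,
               log2_shift: np.ndarray, depth: float, n_samples: int) -> np.ndarray:
    base = np.exp2(rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                              size=n_features))
    rel = base / base.sum()
    lib = depth * np.exp2(rng.normal(0.0, cfg.depth_log2_sd, size=n_samples))
    mu = rel[:, None] * lib[None, :] * np.exp2(log2_shift)
    if cfg.dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / cfg.dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_study(cfg: SimConfig
                   ) -> tuple[EdgeList, CountMatrix, CountMatrix, SampleSheet, GroundTruth]:
    """Network plus coupled count matrices from a single config."""
    edges, _ = simulate_network(cfg)
    mirna, mrna, sheet, truth = simulate_counts(cfg, edges)
    return edges, mirna, mrna, sheet, truth


# ---------------------------------------------------------------------------
# ground-truth serialization (single long-form TSV, lossless round-trip)
# ---------------------------------------------------------------------------

def write_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = []
    for r in truth.drivers.itertuples(index=False):
        rows.append(("driver", r.mirna_id, "", r.log2fc))
    for r in truth.de_genes.itertuples(index=False):
        rows.append(("de_gene", r.gene_id, "", r.log2fc))
    for r in truth.pairs.itertuples(index=False):
        rows.append(("pair", r.mirna_id, r.gene_id, ""))
    for sample, label in truth.batch.items():
        rows.append(("batch", sample, label, ""))
    pd.DataFrame(rows, columns=["record_type", "id1", "id2", "log2fc"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype={"record_type": str, "id1": str, "id2": str})
    d = df[df["record_type"] == "driver"]
    g = df[df["record_type"] == "de_gene"]
    p = df[df["record_type"] == "pair"]
    b = df[df["record_type"] == "batch"]
    return GroundTruth(
        drivers=pd.DataFrame(
            {"mirna_id": d["id1"].tolist(), "log2fc": d["log2fc"].astype(float).tolist()}
        ),
        de_genes=pd.DataFrame(
            {"gene_id": g["id1"].tolist(), "log2fc": g["log2fc"].astype(float).tolist()}
        ),
        pairs=pd.DataFrame(
            {"mirna_id": p["id1"].tolist(), "gene_id": p["id2"].tolist()}
        ),
        batch=pd.Series(b["id2"].tolist(), index=b["id1"].tolist(), dtype=str),
    )
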
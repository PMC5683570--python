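"""End-to-end orchestration: simulate -> DE -> network propagation -> pairs.

The pipeline mirrors the analysis sequence of a two-group integrative
miRNA/mRNA study: differential expression of both assays, network
propagation to score candidate driver miRNAs against the ranked gene DE
profile, and inverse-correlation pair discovery with permutation
significance. One global seed propagates to every stochastic stage, and a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import datamodel as dm
from .diffexpr import DEConfig, run_de
from .netprop import NetpropConfig, build_network, npes_screen, rank_genes
from .pairing import candidate_pairs, permutation_test, score_pairs
from .simulate import SimConfig, simulate_study, write_truth

__all__ = ["PipelineConfig", "run_pipeline", "table1_report"]

logger = logging.getLogger(__name__)

REPORT_KEYS = [
    "n_de_genes", "n_de_genes_up", "n_de_genes_down",
    "n_de_mirnas", "n_de_mirnas_up", "n_de_mirnas_down",
    "n_enriched_mirnas", "n_candidate_pairs", "n_significant_pairs",
    "global_p", "seed",
]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    de_mirna: DEConfig = field(default_factory=DEConfig)
    de_mrna: DEConfig = field(default_factory=DEConfig)
    netprop: NetpropConfig = field(default_factory=NetpropConfig)
    pair_n_perm: int = 10000
    pair_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        # one global seed drives every stochastic stage
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.netprop = dataclasses.replace(self.netprop, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        """Flat YAML with optional sections sim / de_mirna / de_mrna /
        netprop / pairs, plus a top-level seed."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw: dict = {}
        if "sim" in raw:
            kw["sim"] = SimConfig(**raw["sim"])
        if "de_mirna" in raw:
            kw["de_mirna"] = DEConfig(**raw["de_mirna"])
        if "de_mrna" in raw:
            kw["de_mrna"] = DEConfig(**raw["de_mrna"])
        if "netprop" in raw:
            kw["netprop"] = NetpropConfig(**raw["netprop"])
        pairs = raw.get("pairs", {})
        if "n_perm" in pairs:
            kw["pair_n_perm"] = int(pairs["n_perm"])
        if "alpha" in pairs:
            kw["pair_alpha"] = float(pairs["alpha"])
        kw["seed"] = int(raw.get("seed", 0)) if seed is None else seed
        return cls(**kw)


def _stage(name: str):
    logger.info("stage %s", name)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a simulated study and write all outputs.

    Writes counts, sample sheet, edges and ground truth, both DE tables,
    the NPES table, the pair table, and a key/value report (TSV and a
    human-readable text rendering). Returns the report as a dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    _stage("simulate")
    edges, mirna, mrna, sheet, truth = simulate_study(cfg.sim)
    dm.write_count_matrix(mirna, outdir / "mirna_counts.tsv")
    dm.write_count_matrix(mrna, outdir / "mrna_counts.tsv")
    dm.write_sample_sheet(sheet, outdir / "samples.tsv")
    dm.write_edge_list(edges, outdir / "edges.tsv")
    write_truth(truth, outdir / "truth.tsv")
    logger.info(
        "simulated %d miRNAs x %d samples, %d genes; %d edges; seed %d",
        *mirna.shape, mrna.shape[0], len(edges), cfg.seed,
    )

    _stage("de")
    de_mirna = run_de(mirna, sheet, cfg.de_mirna, apply_cpm_filter=True,
                      latent=cfg.de_mirna.n_latent, seed=cfg.seed)
    de_mrna = run_de(mrna, sheet, cfg.de_mrna, apply_cpm_filter=False,
                     latent=cfg.de_mrna.n_latent, seed=cfg.seed)
    dm.write_de_table(de_mirna, outdir / "de_mirna.tsv")
    dm.write_de_table(de_mrna, outdir / "de_mrna.tsv")

    _stage("netprop")
    network = build_network(edges)
    ranked = rank_genes(de_mrna)
    # orientation needs only the sign of each miRNA's expression change:
    # a rising miRNA is expected to push its targets down the ranking
    directions = {
        f: ("up" if lfc > 0 else "down")
        for f, lfc in zip(de_mirna["feature_id"], de_mirna["log2fc"])
    }
    npes_table = npes_screen(network, ranked, cfg.netprop, directions)
    npes_table.to_csv(outdir / "npes.tsv", sep="\t", index=False)

    _stage("pairs")
    candidates = candidate_pairs(de_mirna, de_mrna, network)
    scored = score_pairs(candidates, mirna, mrna)
    result = permutation_test(scored, mirna, mrna, n_perm=cfg.pair_n_perm,
                              alpha=cfg.pair_alpha, seed=cfg.seed)
    result.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)

    _stage("report")
    report = {
        "n_de_genes": int((de_mrna["direction"] != "ns").sum()),
        "n_de_genes_up": int((de_mrna["direction"] == "up").sum()),
        "n_de_genes_down": int((de_mrna["direction"] == "down").sum()),
        "n_de_mirnas": int((de_mirna["direction"] != "ns").sum()),
        "n_de_mirnas_up": int((de_mirna["direction"] == "up").sum()),
        "n_de_mirnas_down": int((de_mirna["direction"] == "down").sum()),
        "n_enriched_mirnas": int(npes_table["enriched"].sum()) if len(npes_table) else 0,
        "n_candidate_pairs": int(len(candidates)),
        "n_significant_pairs": result.k_obs,
        "global_p": result.global_p,
        "seed": cfg.seed,
    }
    pd.DataFrame(
        {"key": list(report), "value": [report[k] for k in report]}
    ).to_csv(outdir / "report.tsv", sep="\t", index=False)
    (outdir / "report.txt").write_text(_render_report(report))
    return report


def _render_report(report: dict) -> str:
    lines = [
        "Integrative miRNA-mRNA analysis report",
        "=====================================",
        f"DE genes: {report['n_de_genes']} "
        f"({report['n_de_genes_up']} up, {report['n_de_genes_down']} down)",
        f"DE miRNAs: {report['n_de_mirnas']} "
        f"({report['n_de_mirnas_up']} up, {report['n_de_mirnas_down']} down)",
        f"Enriched miRNAs (NPES screen): {report['n_enriched_mirnas']}",
        f"Candidate inverse pairs: {report['n_candidate_pairs']}",
        f"Significant pairs (permutation): {report['n_significant_pairs']}",
        f"Global pair-count p-value: {report['global_p']:.6g}",
        f"Seed: {report['seed']}",
    ]
    return "\n".join(lines) + "\n"


def table1_report() -> dict:
    """Summary of the packaged published DE-miRNA table: total, up and
    down counts, and the number of down-regulated let-7 family members."""
    t = dm.load_table1_fixture()
    let7_down = t[
        t["feature_id"].str.startswith("hsa-let-7") & (t["direction"] == "down")
    ]
    return {
        "n_total": int(len(t)),
        "n_up": int((t["direction"] == "up").sum()),
        "n_down": int((t["direction"] == "down").sum()),
        "n_let7_down": int(len(let7_down)),
    }
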
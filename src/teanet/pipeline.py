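"""End-to-end orchestration: simulate -> qc -> profile -> dam -> network.

Each stage writes its standard text outputs into the run directory and
registers them (with SHA-256 hashes) in a :class:`RunManifest`, so a run is
reproducible from its manifest: same config + seed => byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .corrnet import count_pairs_above, gene_metabolite_network, mutual_rank, pairwise_pcc, build_network
from .differential import dam_test, volcano_table
from .errors import DomainError, TeanetError
from .profiling import assign_groups, run_pca, variability_table
from .qc import qc_stability
from .synthetic import default_config, generate_cohort
from .tables import (
    AbundanceMatrix,
    ExpressionMatrix,
    RunConfig,
    read_expression_table,
    read_feature_table,
    write_expression_table,
    write_feature_table,
    write_network,
)

__all__ = ["RunManifest", "run_pipeline", "report_summary", "identified_fraction"]

log = logging.getLogger("teanet")

_FLOAT_FMT = "%.12g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seed, stage outputs and counts."""

    config: dict
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def add_stage(self, name: str, outputs: dict[str, Path], summary: dict, elapsed: float) -> None:
        self.stages[name] = {
            "outputs": {k: str(v) for k, v in outputs.items()},
            "hashes": {k: _sha256(v) for k, v in outputs.items()},
            "summary": summary,
            "elapsed_s": round(elapsed, 3),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def identified_fraction(identified: int, detected: int) -> float:
    """Share of detected features that were identified, in %, 2 decimals.

    E.g. 251 identified out of 3775 detected features -> 6.65.
    """
    if detected <= 0:
        raise DomainError("detected feature count must be positive")
    if identified < 0 or identified > detected:
        raise DomainError("identified count must lie in [0, detected]")
    return round(100.0 * identified / detected, 2)


def run_pipeline(
    out_dir,
    config: RunConfig | None = None,
    seed: int = 0,
    abundance_path=None,
    meta_path=None,
    feature_meta_path=None,
    expression_path=None,
    pathway_genes=None,
    detected_features: int | None = None,
) -> RunManifest:
    """Run all stages on provided tables, or on a simulated cohort.

    When ``abundance_path`` is None the simulate stage generates the default
    synthetic cohort for ``seed`` (and its planted hub gene becomes the
    pathway gene list unless one is supplied).  ``detected_features`` lets a
    caller state how many raw features the identified table was distilled
    from, for the identified-fraction line of the report.
    """
    cfg = config or RunConfig(seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.to_dict(), seed=seed)

    # --- stage: simulate or load -----------------------------------------
    t0 = time.perf_counter()
    if abundance_path is None:
        syn = default_config(seed=seed)
        metab, expr, truth = generate_cohort(syn)
        paths = {
            "abundance": out / "abundance.tsv",
            "sample_meta": out / "sample_meta.tsv",
            "feature_meta": out / "feature_meta.tsv",
            "expression": out / "expression.tsv",
            "ground_truth": out / "ground_truth.json",
        }
        write_feature_table(metab, paths["abundance"], paths["sample_meta"], paths["feature_meta"])
        write_expression_table(expr, paths["expression"])
        truth.to_json(paths["ground_truth"])
        if pathway_genes is None:
            pathway_genes = list(truth.hub_genes) + list(expr.gene_ids[:20])
        manifest.add_stage(
            "simulate",
            paths,
            {"n_samples": len(metab.sample_ids), "n_features": len(metab.feature_ids),
             "n_genes": len(expr.gene_ids)},
            time.perf_counter() - t0,
        )
    else:
        metab = read_feature_table(abundance_path, meta_path, feature_meta_path)
        expr = read_expression_table(expression_path) if expression_path else None
        manifest.add_stage(
            "load",
            {"abundance": Path(abundance_path)},
            {"n_samples": len(metab.sample_ids), "n_features": len(metab.feature_ids)},
            time.perf_counter() - t0,
        )
    log.info("input: %d samples x %d features", len(metab.sample_ids), len(metab.feature_ids))

    # --- stage: qc ---------------------------------------------------------
    t0 = time.perf_counter()
    if int(metab.is_qc.sum()) >= 2:
        report = qc_stability(metab, threshold=cfg.qc_pcc_threshold)
        qc_path = out / "qc_report.json"
        report.to_json(qc_path)
        manifest.add_stage(
            "qc", {"report": qc_path},
            {"min_pcc": report.min_pcc, "passed": report.passed},
            time.perf_counter() - t0,
        )
        log.info("qc: min pairwise PCC %.4f (%s)", report.min_pcc, "pass" if report.passed else "FAIL")
    else:
        log.info("qc: skipped (<2 QC samples)")

    # --- stage: profile ----------------------------------------------------
    t0 = time.perf_counter()
    var_tab = variability_table(metab)
    pca = run_pca(metab, scaling=cfg.pca_scaling)
    grp = assign_groups(pca, k=cfg.k_groups, n_components=cfg.pca_components, seed=cfg.seed)
    paths = {
        "variability": out / "variability.tsv",
        "pca_scores": out / "pca_scores.tsv",
        "pca_loadings": out / "pca_loadings.tsv",
        "groups": out / "groups.tsv",
    }
    var_tab.to_csv(paths["variability"], sep="\t", index=False, float_format=_FLOAT_FMT)
    pca.scores.to_csv(paths["pca_scores"], sep="\t", float_format=_FLOAT_FMT)
    pca.loadings.to_csv(paths["pca_loadings"], sep="\t", float_format=_FLOAT_FMT)
    grp.labels.to_frame().to_csv(paths["groups"], sep="\t")
    manifest.add_stage(
        "profile", paths,
        {
            "pc_variance_pct": [round(float(v), 2) for v in pca.variance_pct[:5]],
            "group_sizes": grp.labels.value_counts().sort_index().to_dict(),
            "n_over_1000_fold": int((var_tab["tier"] == ">1000").sum()),
        },
        time.perf_counter() - t0,
    )
    log.info("profile: PC1 %.1f%%, PC2 %.1f%%", pca.variance_pct[0], pca.variance_pct[1])

    # --- stage: dam --------------------------------------------------------
    t0 = time.perf_counter()
    paths, dam_counts = {}, {}
    for a, b in grp.pairs():
        dam = dam_test(metab, grp, (a, b), test=cfg.dam_test,
                       fc_gate=cfg.fc_gate, fdr_gate=cfg.fdr_gate)
        path = out / f"volcano_g{a}_vs_g{b}.tsv"
        volcano_table(dam).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        paths[f"volcano_{a}_{b}"] = path
        dam_counts[f"{a}_vs_{b}"] = dam.counts()["n_dam"]
    manifest.add_stage("dam", paths, {"n_dam": dam_counts}, time.perf_counter() - t0)
    log.info("dam: %s", dam_counts)

    # --- stage: network ----------------------------------------------------
    t0 = time.perf_counter()
    corr = pairwise_pcc(metab.biological())
    edges = mutual_rank(corr, mode=cfg.mr_mode)
    net = build_network(
        corr, edges,
        pcc_gate=cfg.pcc_gate_metabolite, fdr_gate=cfg.fdr_gate,
        weight_floor=cfg.weight_floor,
    )
    paths = {
        "met_edges": out / "metabolite_network.tsv",
        "met_sif": out / "metabolite_network.sif",
        "met_graphml": out / "metabolite_network.graphml",
    }
    for dialect, key in (("tsv", "met_edges"), ("sif", "met_sif"), ("graphml", "met_graphml")):
        write_network(net, paths[key], dialect=dialect)
    summary = {
        "metabolite": net.summary(),
        "pairs_abs_pcc_gt_0.8": count_pairs_above(corr, 0.8),
        "pairs_abs_pcc_gt_0.9": count_pairs_above(corr, 0.9),
    }
    if expr is not None and pathway_genes:
        gm = gene_metabolite_network(
            expr, metab, pathway_genes,
            pcc_gate=cfg.pcc_gate_gene, fdr_gate=cfg.fdr_gate,
            weight_floor=cfg.weight_floor, mr_mode=cfg.mr_mode,
        )
        for dialect, name in (("tsv", "gene_metabolite_network.tsv"),
                              ("sif", "gene_metabolite_network.sif"),
                              ("graphml", "gene_metabolite_network.graphml")):
            path = out / name
            write_network(gm, path, dialect=dialect)
            paths[name] = path
        summary["gene_metabolite"] = gm.summary()
    net_summary_path = out / "network_summary.json"
    with open(net_summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    paths["summary"] = net_summary_path
    manifest.add_stage(
        "network", paths,
        {"n_edges": summary["metabolite"]["n_edges"],
         "pairs_abs_pcc_gt_0.8": summary["pairs_abs_pcc_gt_0.8"]},
        time.perf_counter() - t0,
    )
    log.info("network: %d metabolite edges", summary["metabolite"]["n_edges"])

    # --- report ------------------------------------------------------------
    n_feat = len(metab.feature_ids)
    manifest.stages["counts"] = {
        "detected": detected_features if detected_features is not None else n_feat,
        "identified": n_feat,
    }
    manifest.to_json(out / "manifest.json")
    return manifest


_REQUIRED_STAGES = ("profile", "dam", "network", "counts")


def report_summary(manifest: RunManifest) -> dict:
    """Condense a completed manifest into the headline numbers.

    Includes the identified fraction (100 x identified / detected, rounded
    to 2 decimals), per-pair DAM counts, high-correlation pair counts and
    the top hubs of each network.
    """
    stages = manifest.stages
    missing = [s for s in _REQUIRED_STAGES if s not in stages]
    if missing:
        raise TeanetError(f"manifest incomplete; missing stage(s): {missing}")
    counts = stages["counts"]
    out = {
        "detected_features": counts["detected"],
        "identified_features": counts["identified"],
        "identified_fraction_pct": identified_fraction(counts["identified"], counts["detected"]),
        "pc_variance_pct": stages["profile"]["summary"]["pc_variance_pct"],
        "group_sizes": stages["profile"]["summary"]["group_sizes"],
        "dam_counts": stages["dam"]["summary"]["n_dam"],
        "pairs_abs_pcc_gt_0.8": stages["network"]["summary"]["pairs_abs_pcc_gt_0.8"],
        "n_network_edges": stages["network"]["summary"]["n_edges"],
        "seed": manifest.seed,
        "version": manifest.version,
    }
    return out
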
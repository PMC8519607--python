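"""Monte-Carlo recovery studies on planted synthetic cohorts.

Each study generates cohorts under the package's standard study conditions
(68 accessions, lognormal intensities, planted structure), runs the relevant
analysis stage, and measures how reliably the planted truth is recovered:

* a 7-feature correlation module at latent r = 0.9 through the default
  metabolite network gates;
* differential features (log2 effect 2 at 10% within-group CV) and the
  false-discovery behaviour under a global null;
* the pooled-QC correlation band at 1% injection CV;
* a hub gene tracking a 25-metabolite block through the gene-metabolite
  network;
* three latent accession groups through PCA + k-means.

These are the package's calibration evidence; the study sizes default to a
few dozen to a few hundred seeds, enough for stable rates at desk scale.
"""

from __future__ import annotations

import itertools

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .corrnet import build_network, gene_metabolite_network, hubs, mutual_rank, pairwise_pcc
from .differential import dam_test
from .profiling import assign_groups, run_pca
from .qc import qc_stability
from .synthetic import DamSpec, ModuleSpec, SyntheticConfig, default_config, generate_cohort

__all__ = [
    "module_recovery_study",
    "dam_null_study",
    "dam_power_study",
    "qc_band_study",
    "hub_recovery_study",
    "group_recovery_study",
]

_LN10 = np.log(10.0)


def _cv_to_log10_sd(cv: float) -> float:
    """log10-scale sd of a lognormal with raw-scale coefficient of variation ``cv``."""
    return float(np.sqrt(np.log1p(cv**2)) / _LN10)


def module_recovery_study(
    n_seeds: int = 50,
    base_seed: int = 0,
    n_samples: int = 68,
    n_features: int = 100,
    module_size: int = 7,
    target_r: float = 0.9,
    pcc_gate: float = 0.8,
    fdr_gate: float = 0.05,
    weight_floor: float = 0.01,
) -> dict:
    """Edge recovery of one planted module through the default network gates.

    Returns the median within-module edge recall across seeds and the pooled
    between-module false-edge rate (false edges / non-module pairs).
    """
    recalls = []
    false_edges = 0
    possible_false = 0
    for i in range(n_seeds):
        cfg = SyntheticConfig(
            n_accessions=n_samples,
            n_features=n_features,
            n_genes=0,
            seed=base_seed + i,
        )
        members = tuple(cfg.feature_ids[:module_size])
        cfg = SyntheticConfig(
            n_accessions=n_samples,
            n_features=n_features,
            n_genes=0,
            modules=(ModuleSpec(members, target_r),),
            seed=base_seed + i,
        )
        metab, _, _ = generate_cohort(cfg)
        corr = pairwise_pcc(metab.biological())
        net = build_network(
            corr, mutual_rank(corr),
            pcc_gate=pcc_gate, fdr_gate=fdr_gate, weight_floor=weight_floor,
        )
        member_set = set(members)
        within = list(itertools.combinations(sorted(member_set), 2))
        hit = sum(net.graph.has_edge(a, b) for a, b in within)
        recalls.append(hit / len(within))
        n_false = sum(
            1 for a, b in net.graph.edges if not (a in member_set and b in member_set)
        )
        false_edges += n_false
        n_nodes = net.n_nodes
        possible_false += n_nodes * (n_nodes - 1) // 2 - len(within)
    return {
        "median_recall": float(np.median(recalls)),
        "false_edge_rate": false_edges / possible_false,
        "n_seeds": n_seeds,
    }


def _two_group_config(seed: int, cv: float, n_per_group: int, n_features: int, dam_specs=()) -> SyntheticConfig:
    return SyntheticConfig(
        n_accessions=2 * n_per_group,
        n_groups=2,
        n_features=n_features,
        n_genes=0,
        n_qc=0,
        feature_log_sd=_cv_to_log10_sd(cv),
        group_effect_rel=0.0,  # no latent group differences beyond dam_specs
        dam_specs=dam_specs,
        seed=seed,
    )


def dam_null_study(
    n_seeds: int = 200,
    base_seed: int = 0,
    n_features: int = 250,
    n_per_group: int = 20,
    cv: float = 0.10,
    fdr_gate: float = 0.05,
) -> dict:
    """Mean fraction of features with q < ``fdr_gate`` under a global null."""
    fracs = []
    for i in range(n_seeds):
        cfg = _two_group_config(base_seed + i, cv, n_per_group, n_features)
        metab, _, truth = generate_cohort(cfg)
        res = dam_test(metab, truth.group_labels, (1, 2), fdr_gate=fdr_gate)
        fracs.append(float((res.table["q"] < fdr_gate).mean()))
    return {"mean_fraction_q_lt_gate": float(np.mean(fracs)), "n_seeds": n_seeds}


def dam_power_study(
    n_seeds: int = 200,
    base_seed: int = 0,
    n_features: int = 250,
    n_per_group: int = 20,
    cv: float = 0.10,
    log2_effect: float = 2.0,
) -> dict:
    """Detection rate of one planted log2 effect through both DAM gates."""
    hits = 0
    for i in range(n_seeds):
        cfg = _two_group_config(base_seed + i, cv, n_per_group, n_features)
        planted = cfg.feature_ids[0]
        cfg = _two_group_config(
            base_seed + i, cv, n_per_group, n_features,
            dam_specs=(DamSpec(planted, 1, 2, log2_effect),),
        )
        metab, _, truth = generate_cohort(cfg)
        res = dam_test(metab, truth.group_labels, (1, 2))
        hits += bool(res.table.loc[planted, "is_dam"])
    return {"detection_rate": hits / n_seeds, "n_seeds": n_seeds}


def qc_band_study(
    n_seeds: int = 200,
    base_seed: int = 0,
    qc_cv: float = 0.01,
    threshold: float = 0.99,
    n_features: int = 250,
) -> dict:
    """Fraction of cohorts whose minimum pairwise QC PCC clears ``threshold``."""
    passes = 0
    min_pccs = []
    for i in range(n_seeds):
        cfg = SyntheticConfig(
            n_features=n_features, n_genes=0, qc_cv=qc_cv, seed=base_seed + i
        )
        metab, _, _ = generate_cohort(cfg)
        report = qc_stability(metab, threshold=threshold)
        passes += report.passed
        min_pccs.append(report.min_pcc)
    return {
        "pass_rate": passes / n_seeds,
        "median_min_pcc": float(np.median(min_pccs)),
        "n_seeds": n_seeds,
    }


def hub_recovery_study(
    n_seeds: int = 100,
    base_seed: int = 0,
    pcc_gate: float = 0.4,
    fdr_gate: float = 0.05,
) -> dict:
    """How often the planted hub gene tops the gene degree ranking.

    Uses the default study design (25-metabolite block tracked at r = 0.6 by
    one hub gene among 60 background genes) and the gene-metabolite gates.
    """
    wins = 0
    for i in range(n_seeds):
        cfg = default_config(seed=base_seed + i)
        metab, expr, truth = generate_cohort(cfg)
        net = gene_metabolite_network(
            expr, metab, expr.gene_ids, pcc_gate=pcc_gate, fdr_gate=fdr_gate
        )
        gene_rank = hubs(net, top_k=1, kind="gene")
        wins += bool(gene_rank and gene_rank[0][0] in truth.hub_genes)
    return {"top_rank_rate": wins / n_seeds, "n_seeds": n_seeds}


def group_recovery_study(
    n_seeds: int = 100,
    base_seed: int = 0,
    n_features: int = 100,
    min_separation: float = 6.0,
) -> dict:
    """PCA + k-means recovery of the three planted accession groups.

    Also measures the realized centroid-separation-to-within-spread ratio on
    the PC1/PC2 plane, so callers can verify the planted separation regime.
    """
    aris = []
    ratios = []
    for i in range(n_seeds):
        cfg = SyntheticConfig(n_features=n_features, n_genes=0, seed=base_seed + i)
        metab, _, truth = generate_cohort(cfg)
        pca = run_pca(metab)
        scores = pca.scores.loc[pca.fitted_samples, ["PC1", "PC2"]]
        cents = {
            g: scores.loc[truth.group_labels.index[truth.group_labels == g]].mean()
            for g in sorted(truth.group_labels.unique())
        }
        seps = [
            np.linalg.norm(cents[a] - cents[b])
            for a, b in itertools.combinations(sorted(cents), 2)
        ]
        # within-spread: per-coordinate sd on the PC1/PC2 plane, averaged
        # over coordinates and groups
        within = np.mean([
            scores.loc[truth.group_labels.index[truth.group_labels == g]]
            .std(axis=0, ddof=1)
            .mean()
            for g in cents
        ])
        ratios.append(float(np.mean(seps) / within))
        grp = assign_groups(pca, k=3, n_components=2, seed=base_seed + i)
        aris.append(
            adjusted_rand_score(
                truth.group_labels, grp.labels.loc[truth.group_labels.index]
            )
        )
    return {
        "median_ari": float(np.median(aris)),
        "median_separation_ratio": float(np.median(ratios)),
        "n_seeds": n_seeds,
    }
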
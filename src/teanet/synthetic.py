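"""Synthetic tea-shoot cohorts with known structure.

Emulates the design of an untargeted metabolomics survey of a tea-plant
germplasm panel: ~68 accessions profiled for ~250 identified metabolite
features plus interleaved pooled-QC injections, alongside an FPKM-like gene
expression matrix for the same accessions.  Everything downstream (QC
screening, variability tiers, PCA grouping, differential accumulation,
mutual-rank networks) can be validated against the planted ground truth:

* latent accession groups (log-scale mean shifts, strength relative to each
  feature's own spread);
* correlated metabolite "modules" built from a shared latent factor — e.g. a
  7-member procyanidin/caffeine-like block;
* per-pair differential-accumulation effects (log2 shifts between groups);
* hub genes whose expression tracks a whole metabolite module;
* pooled-QC replicates: the grand-mean profile under small multiplicative
  noise.

Intensities are lognormal: all signal is built on the log10 scale and
exponentiated, which keeps abundances strictly positive and makes the
max/min variability statistic span the <3-fold to >1000-fold range seen in
real panels when per-feature spreads are drawn from a narrow "primary-like"
and a wide "secondary-like" regime.

Reproducibility: one global seed feeds a named substream per sub-generator
(feature parameters, latents, noise, QC, genes, ...), so enlarging one part
of the design does not perturb draws elsewhere.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .tables import AbundanceMatrix, ExpressionMatrix

__all__ = [
    "ModuleSpec",
    "DamSpec",
    "HubSpec",
    "SyntheticConfig",
    "GroundTruth",
    "make_correlated_block",
    "generate_cohort",
    "plant_hub_gene",
    "default_config",
]

LOG10_2 = np.log10(2.0)

_VARIETIES = (
    "C. sinensis var. sinensis",
    "C. sinensis var. assamica",
    "C. sinensis var. pubilimba",
    "C. taliensis",
    "C. tachangensis",
)

_CLASSES = (
    "flavan-3-ol",
    "procyanidin",
    "flavonol glycoside",
    "organic acid",
    "amino acid",
    "alkaloid",
    "carbohydrate",
    "phenolic acid",
)


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named deterministic substream derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class ModuleSpec:
    """A block of features sharing one latent factor at correlation ``target_r``."""

    member_features: tuple[str, ...]
    target_r: float
    node_kind: str = "metabolite"

    def __post_init__(self):
        object.__setattr__(self, "member_features", tuple(self.member_features))
        if len(self.member_features) < 2:
            raise ParameterError("a module needs at least 2 member features")
        if not (0.0 < self.target_r < 1.0):
            raise ParameterError(f"target_r must be in (0, 1), got {self.target_r}")
        if self.node_kind not in ("metabolite", "gene"):
            raise ParameterError(f"node_kind must be metabolite or gene, got {self.node_kind!r}")


@dataclass(frozen=True)
class DamSpec:
    """A planted log2 mean shift on one feature between two groups.

    Group A is shifted up and group B down by ``log2_effect / 2`` each, so the
    ratio of group geometric means is ``2**log2_effect``.
    """

    feature: str
    group_a: int
    group_b: int
    log2_effect: float


@dataclass(frozen=True)
class HubSpec:
    """A gene planted to correlate at ``target_r`` with each target feature."""

    gene_id: str
    target_features: tuple[str, ...]
    target_r: float

    def __post_init__(self):
        object.__setattr__(self, "target_features", tuple(self.target_features))


@dataclass
class SyntheticConfig:
    """Design of a synthetic cohort.

    The defaults are the study conditions this package targets: 68 accessions,
    250 identified features, 60 genes, 3 latent groups, 7 pooled-QC
    injections at 1% CV (one QC per ~10 biological injections).
    """

    n_accessions: int = 68
    n_features: int = 250
    n_genes: int = 60
    n_groups: int = 3
    group_sizes: Sequence[int] | None = None
    modules: Sequence[ModuleSpec] = ()
    dam_specs: Sequence[DamSpec] = ()
    hub_specs: Sequence[HubSpec] = ()
    n_qc: int = 7
    qc_cv: float = 0.01
    base_log_mean: float = 5.0  # log10 of a typical relative intensity
    base_log_sd: float = 1.0  # spread of per-feature mean log10 intensities
    primary_fraction: float = 0.15  # share of narrow-spread "primary-like" features
    primary_sd_range: tuple[float, float] = (0.02, 0.09)
    secondary_sd_range: tuple[float, float] = (0.2, 0.9)
    feature_log_sd: float | None = None  # override: one log10 sd for every feature
    group_effect_rel: float = 0.5  # group shift sd as a fraction of feature sd
    gene_log_mean: float = 2.0  # log10 FPKM scale
    gene_log_sd: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.group_sizes is None:
            base, extra = divmod(self.n_accessions, self.n_groups)
            self.group_sizes = [base + (1 if i < extra else 0) for i in range(self.n_groups)]
        self.group_sizes = list(self.group_sizes)
        if sum(self.group_sizes) != self.n_accessions:
            raise ParameterError(
                f"group_sizes {self.group_sizes} must sum to n_accessions={self.n_accessions}"
            )
        if len(self.group_sizes) != self.n_groups:
            raise ParameterError("group_sizes length must equal n_groups")
        if self.qc_cv < 0:
            raise ParameterError("qc_cv must be >= 0")
        if self.seed < 0:
            raise ParameterError("seed must be a non-negative integer")
        self.modules = tuple(self.modules)
        self.dam_specs = tuple(DamSpec(*d) if not isinstance(d, DamSpec) else d for d in self.dam_specs)
        self.hub_specs = tuple(self.hub_specs)
        seen: set[str] = set()
        for mod in self.modules:
            overlap = seen.intersection(mod.member_features)
            if overlap:
                raise ParameterError(f"module feature sets must be disjoint; repeated: {sorted(overlap)}")
            seen.update(mod.member_features)

    @property
    def feature_ids(self) -> list[str]:
        """aa/bb/cc feature ids mirroring standard/literature/database tiers."""
        n = self.n_features
        n_aa = min(84, n)
        n_bb = min(13, max(0, n - n_aa))
        n_cc = max(0, n - n_aa - n_bb)
        ids = [f"aa{i:03d}" for i in range(1, n_aa + 1)]
        ids += [f"bb{i:03d}" for i in range(1, n_bb + 1)]
        ids += [f"cc{i:03d}" for i in range(1, n_cc + 1)]
        return ids

    @property
    def gene_ids(self) -> list[str]:
        return [f"TEA{i:06d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GroundTruth:
    """What was planted: the answer key for downstream recovery tests."""

    group_labels: pd.Series  # biological sample id -> 1..k
    modules: dict[str, list[str]]  # module name -> member feature/gene ids
    dams: list[DamSpec]
    hub_genes: list[str]

    def to_json(self, path) -> None:
        payload = {
            "group_labels": {k: int(v) for k, v in self.group_labels.items()},
            "modules": self.modules,
            "dams": [
                {"feature": d.feature, "group_a": d.group_a, "group_b": d.group_b,
                 "log2_effect": d.log2_effect}
                for d in self.dams
            ],
            "hub_genes": self.hub_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def make_correlated_block(
    n_samples: int, block_size: int, target_r: float, rng_seed: int
) -> np.ndarray:
    """Standardized log-scale block with expected pairwise correlation ``target_r``.

    Each column is ``sqrt(r) * z + sqrt(1-r) * eps`` for a shared standard
    latent ``z`` and independent standard noise ``eps``, so every off-diagonal
    population correlation equals ``target_r`` exactly.
    """
    if not (0.0 < target_r < 1.0):
        raise ParameterError(f"target_r must be in (0, 1), got {target_r}")
    if block_size < 2:
        raise ParameterError("block_size must be >= 2")
    if n_samples < 3:
        raise ParameterError("n_samples must be >= 3")
    rng = np.random.default_rng(rng_seed)
    z = rng.standard_normal(n_samples)
    eps = rng.standard_normal((n_samples, block_size))
    return np.sqrt(target_r) * z[:, None] + np.sqrt(1.0 - target_r) * eps


def _standardize(cols: np.ndarray) -> np.ndarray:
    c = cols - cols.mean(axis=0)
    sd = c.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return c / sd


def _hub_profile(
    log_targets: np.ndarray, target_r: float, rng: np.random.Generator
) -> np.ndarray:
    """Standardized gene profile correlated ~``target_r`` with each target column.

    The shared component is estimated as the standardized row-mean of the
    standardized target profiles; the mixing coefficient is calibrated against
    the realized mean correlation between that component and the targets.  If
    ``target_r`` exceeds what the targets' mutual correlation permits, the
    coefficient saturates near 1 and the achieved correlation falls short —
    a hub tracking 25 mutually independent profiles at r = 0.6 is not
    mathematically possible.
    """
    z = _standardize(log_targets)
    m = z.mean(axis=1)
    m = (m - m.mean()) / m.std(ddof=0)
    rho = float(np.mean(m @ z) / len(m))
    c = target_r / rho if rho > 0 else 1.0
    c = min(max(c, 0.0), 0.999)
    g = c * m + np.sqrt(1.0 - c * c) * rng.standard_normal(len(m))
    return (g - g.mean()) / g.std(ddof=0)


def plant_hub_gene(
    expr: ExpressionMatrix,
    metab: AbundanceMatrix,
    target_features: Sequence[str],
    target_r: float,
    rng_seed: int,
    gene_id: str = "HUB0001",
    gene_log_mean: float = 2.0,
    gene_log_sd: float = 0.8,
) -> ExpressionMatrix:
    """Return a copy of ``expr`` with one gene tracking the given metabolites.

    The gene's log10 expression is a calibrated mix of the targets' shared
    component and fresh noise, so its expected Pearson correlation with each
    target's log10 intensity is close to ``target_r`` (see :func:`_hub_profile`
    for the attainability caveat).
    """
    target_features = list(target_features)
    if not target_features:
        raise ParameterError("target_features must be non-empty")
    unknown = [f for f in target_features if f not in metab.values.columns]
    if unknown:
        raise KeyError(f"unknown feature id(s): {unknown}")
    if not (0.0 < target_r < 1.0):
        raise ParameterError(f"target_r must be in (0, 1), got {target_r}")
    samples = expr.values.index
    if not samples.isin(metab.values.index).all():
        raise ParameterError("every expression sample must exist in the abundance matrix")
    log_targets = np.log10(metab.values.loc[samples, target_features].to_numpy())
    rng = np.random.default_rng(rng_seed)
    g = _hub_profile(log_targets, target_r, rng)
    values = expr.values.copy()
    values[gene_id] = np.power(10.0, gene_log_mean + gene_log_sd * g)
    return ExpressionMatrix(values)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[AbundanceMatrix, ExpressionMatrix, GroundTruth]:
    """Generate abundance + expression matrices and their ground truth.

    The log10 intensity of feature ``f`` in biological sample ``s`` is

    ``mu_f + delta_{g(s),f} + dam shifts + s_f * (sqrt(r_m) z_{m,s} + sqrt(1-r_m) e_{s,f})``

    where ``mu_f`` is the feature's base level, ``delta`` a group shift drawn
    with sd ``group_effect_rel * s_f`` (module members and dam-spec features
    are exempt so planted structure stays exact), and the bracket reduces to
    plain noise for
    features outside any module.  QC rows are the grand-mean biological
    profile under multiplicative lognormal noise with coefficient of
    variation ``qc_cv``.  Identical seeds give byte-identical output.
    """
    cfg = config
    feature_ids = cfg.feature_ids
    gene_ids = cfg.gene_ids
    fid_index = {f: i for i, f in enumerate(feature_ids)}
    gid_index = {g: i for i, g in enumerate(gene_ids)}

    metab_modules = [m for m in cfg.modules if m.node_kind == "metabolite"]
    gene_modules = [m for m in cfg.modules if m.node_kind == "gene"]
    for mod in metab_modules:
        missing = [f for f in mod.member_features if f not in fid_index]
        if missing:
            raise ParameterError(f"module member(s) not in feature set: {missing}")
    for mod in gene_modules:
        missing = [g for g in mod.member_features if g not in gid_index]
        if missing:
            raise ParameterError(f"gene module member(s) not in gene set: {missing}")

    n = cfg.n_accessions
    p = cfg.n_features

    # --- per-feature parameters ------------------------------------------
    rng_feat = _rng(cfg.seed, "feature-params")
    mu = cfg.base_log_mean + cfg.base_log_sd * rng_feat.standard_normal(p)
    if cfg.feature_log_sd is not None:
        sd = np.full(p, float(cfg.feature_log_sd))
        primary_mask = np.zeros(p, dtype=bool)
    else:
        primary_mask = rng_feat.random(p) < cfg.primary_fraction
        sd = np.where(
            primary_mask,
            rng_feat.uniform(*cfg.primary_sd_range, size=p),
            rng_feat.uniform(*cfg.secondary_sd_range, size=p),
        )

    # --- group labels -----------------------------------------------------
    labels = np.repeat(np.arange(1, cfg.n_groups + 1), cfg.group_sizes)
    sample_ids = [f"TS{i:03d}" for i in range(1, n + 1)]
    group_labels = pd.Series(labels, index=sample_ids, name="group")

    # --- signal on the log10 scale ----------------------------------------
    rng_noise = _rng(cfg.seed, "feature-noise")
    eps = rng_noise.standard_normal((n, p))
    signal = np.zeros((n, p))

    module_members: set[int] = set()
    rng_lat = _rng(cfg.seed, "module-latents")
    for mod in metab_modules:
        idx = [fid_index[f] for f in mod.member_features]
        module_members.update(idx)
        z = rng_lat.standard_normal(n)
        r = mod.target_r
        signal[:, idx] = np.sqrt(r) * z[:, None] + np.sqrt(1.0 - r) * eps[:, idx]
    non_module = np.array([i for i in range(p) if i not in module_members], dtype=int)
    signal[:, non_module] = eps[:, non_module]

    log_vals = mu[None, :] + sd[None, :] * signal

    # group shifts; module members and dam-spec features are exempt so the
    # planted correlations and effect sizes stay exact
    rng_grp = _rng(cfg.seed, "group-effects")
    delta = rng_grp.standard_normal((cfg.n_groups, p)) * (cfg.group_effect_rel * sd)[None, :]
    exempt = set(module_members)
    exempt.update(fid_index[d.feature] for d in cfg.dam_specs if d.feature in fid_index)
    if exempt:
        delta[:, sorted(exempt)] = 0.0
    log_vals = log_vals + delta[labels - 1, :]

    # planted differential accumulation
    for dam in cfg.dam_specs:
        if dam.feature not in fid_index:
            raise ParameterError(f"dam feature not in feature set: {dam.feature}")
        j = fid_index[dam.feature]
        half = 0.5 * dam.log2_effect * LOG10_2
        log_vals[labels == dam.group_a, j] += half
        log_vals[labels == dam.group_b, j] -= half

    abundance_bio = np.power(10.0, log_vals)

    # --- pooled QC rows ----------------------------------------------------
    rng_qc = _rng(cfg.seed, "qc-noise")
    grand = abundance_bio.mean(axis=0)
    # exact-CV multiplicative lognormal noise; sigma = 0 when qc_cv = 0
    sigma = np.sqrt(np.log1p(cfg.qc_cv**2))
    qc_rows = grand[None, :] * np.exp(sigma * rng_qc.standard_normal((cfg.n_qc, p)))
    qc_ids = [f"QC{i:02d}" for i in range(1, cfg.n_qc + 1)]

    values = pd.DataFrame(
        np.vstack([abundance_bio, qc_rows]),
        index=sample_ids + qc_ids,
        columns=feature_ids,
    )

    sample_meta = pd.DataFrame(
        {
            "accession_id": [f"ACC{i:03d}" for i in range(1, n + 1)] + ["pooled"] * cfg.n_qc,
            "variety": [_VARIETIES[i % len(_VARIETIES)] for i in range(n)] + ["pooled"] * cfg.n_qc,
            "group": list(labels) + [""] * cfg.n_qc,
            "is_qc": [False] * n + [True] * cfg.n_qc,
        },
        index=pd.Index(sample_ids + qc_ids, name="sample_id"),
    )

    tiers = ["standard-aligned" if f.startswith("aa") else "literature" if f.startswith("bb") else "database" for f in feature_ids]
    feature_meta = pd.DataFrame(
        {
            "tier": tiers,
            "chem_class": [_CLASSES[i % len(_CLASSES)] for i in range(p)],
            "regime": np.where(primary_mask, "primary-like", "secondary-like"),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    metab = AbundanceMatrix(values, sample_meta, feature_meta)

    # --- expression matrix --------------------------------------------------
    rng_gene = _rng(cfg.seed, "gene-noise")
    g_eps = rng_gene.standard_normal((n, cfg.n_genes))
    g_signal = g_eps.copy()
    rng_glat = _rng(cfg.seed, "gene-latents")
    for mod in gene_modules:
        idx = [gid_index[g] for g in mod.member_features]
        z = rng_glat.standard_normal(n)
        r = mod.target_r
        g_signal[:, idx] = np.sqrt(r) * z[:, None] + np.sqrt(1.0 - r) * g_eps[:, idx]
    g_mu = cfg.gene_log_mean + 0.5 * rng_gene.standard_normal(cfg.n_genes)
    expr_vals = np.power(10.0, g_mu[None, :] + cfg.gene_log_sd * g_signal)
    expr = ExpressionMatrix(pd.DataFrame(expr_vals, index=sample_ids, columns=gene_ids))

    hub_genes: list[str] = []
    rng_hub = _rng(cfg.seed, "hub-genes")
    for hub in cfg.hub_specs:
        expr = plant_hub_gene(
            expr,
            metab,
            hub.target_features,
            hub.target_r,
            rng_seed=int(rng_hub.integers(2**31)),
            gene_id=hub.gene_id,
            gene_log_mean=cfg.gene_log_mean,
            gene_log_sd=cfg.gene_log_sd,
        )
        hub_genes.append(hub.gene_id)

    truth = GroundTruth(
        group_labels=group_labels,
        modules={f"module{i + 1}": list(m.member_features) for i, m in enumerate(cfg.modules)},
        dams=list(cfg.dam_specs),
        hub_genes=hub_genes,
    )
    return metab, expr, truth


def default_config(seed: int = 0) -> SyntheticConfig:
    """The default study design: 68 accessions, 250 features, planted structure.

    Plants a tight 7-member procyanidin-like block (latent r = 0.9), a broader
    25-member block (latent r = 0.4) tracked by one hub gene at r = 0.6, and
    three 4-fold differential features between group pairs.
    """
    cfg = SyntheticConfig(seed=seed)
    fids = cfg.feature_ids
    tight = tuple(fids[30:37])  # 7-member, aa031..aa037
    broad = tuple(fids[100:125])  # 25-member
    return SyntheticConfig(
        modules=(
            ModuleSpec(tight, target_r=0.9, node_kind="metabolite"),
            ModuleSpec(broad, target_r=0.4, node_kind="metabolite"),
        ),
        dam_specs=(
            DamSpec(fids[0], 1, 2, 2.0),
            DamSpec(fids[1], 1, 3, 2.0),
            DamSpec(fids[2], 2, 3, -2.0),
        ),
        hub_specs=(HubSpec("HUB0001", broad, 0.6),),
        seed=seed,
    )
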
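"""Synthetic-data generators for every pipeline input.

The generators emulate the statistical structure of a four-condition
(Control, TiO2NPs, UV, UV+TiO2NPs) *C. elegans* nanotoxicology study:
a log2 expression matrix with three biological replicates per condition
and planted differentially expressed genes, a KEGG-style pathway
annotation with overlapping gene sets, binomial dose-response mortality
under a log-normal tolerance model, per-worm offspring counts, a qPCR Ct
table with a constant housekeeping gene, and a metabolite concentration
matrix. A single seed drives per-generator substreams, so identical
configurations yield byte-identical outputs and adding a generator does
not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .deg import ExpressionMatrix
from .errors import ConfigError
from .toxassays import MetaboliteMatrix

CONDITIONS = ("Control", "TiO2NPs", "UV", "UV+TiO2NPs")

# Group means calibrated so that the relative offspring decreases of
# UV+TiO2NPs against Control / TiO2NPs / UV are 37.9%, 29.5% and 24.3%;
# the Control level (230 offspring per worm over 72 h) is a typical
# wild-type brood and only the ratios matter downstream.
_CONTROL_OFFSPRING = 230.0
_UVT_OFFSPRING = _CONTROL_OFFSPRING * (1.0 - 0.379)
DEFAULT_REPRO_MEANS = {
    "Control": _CONTROL_OFFSPRING,
    "TiO2NPs": _UVT_OFFSPRING / (1.0 - 0.295),
    "UV": _UVT_OFFSPRING / (1.0 - 0.243),
    "UV+TiO2NPs": _UVT_OFFSPRING,
}

# Oxidative-stress / xenobiotic response panel with Control fixed at 1.
DEFAULT_CT_PLAN = {
    "gst-4": {"Control": 1.0, "TiO2NPs": 1.2, "UV": 2.0, "UV+TiO2NPs": 3.5},
    "sod-3": {"Control": 1.0, "TiO2NPs": 1.1, "UV": 1.6, "UV+TiO2NPs": 2.4},
    "mtl-1": {"Control": 1.0, "TiO2NPs": 1.3, "UV": 0.8, "UV+TiO2NPs": 0.5},
    "cyp-35a2": {"Control": 1.0, "TiO2NPs": 1.0, "UV": 2.2, "UV+TiO2NPs": 2.9},
}

# Energy-metabolism panel; unspecified condition folds default to 1.
DEFAULT_METAB_PLAN = {
    "succinate": {"UV": 1.6, "UV+TiO2NPs": 2.2},
    "pyruvate": {"UV": 0.7, "UV+TiO2NPs": 0.45},
    "lactate": {"UV+TiO2NPs": 1.8},
    "alanine": {},
    "glycine": {},
    "glutamate": {"UV+TiO2NPs": 0.6},
    "glucose": {},
    "trehalose": {"UV": 1.7, "UV+TiO2NPs": 1.9},
}

_STREAMS = {
    "pathways": 0,
    "expression": 1,
    "dose_response": 2,
    "reproduction": 3,
    "qpcr": 4,
    "metabolites": 5,
}


@dataclass
class SimConfig:
    """Full parameterization of the synthetic study.

    Defaults encode the study design the analysis assumes: three
    biological replicates of each of the four exposure conditions for
    the omics tables, doses 0/2/5/10 mg/L for the lethality assay with
    a true LC50 of 7.9 mg/L and log10-tolerance SD 0.176, and eight
    worms per condition for the reproduction assay with group means
    calibrated to the reported relative decreases.
    """

    seed: int = 0
    n_genes: int = 200
    n_pathways: int = 12
    pathway_size_range: tuple[int, int] = (5, 40)
    n_replicates: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    deg_plan: Mapping[str, Sequence[tuple[str, float]]] = field(default_factory=dict)
    noise_sd_log2: float = 0.25
    baseline_mean_log2: float = 7.0
    baseline_sd_log2: float = 1.5
    lc50_true: float = 7.9
    sigma_log10_true: float = 0.176
    doses: tuple[float, ...] = (0.0, 2.0, 5.0, 10.0)
    n_per_dose: int = 30
    repro_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REPRO_MEANS)
    )
    repro_cv: float = 0.1
    n_worms: int = 8
    ct_plan: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_CT_PLAN.items()}
    )
    ct_noise_sd: float = 0.15
    housekeeping_gene: str = "pmp-3"
    housekeeping_ct: float = 15.0
    metab_plan: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_METAB_PLAN.items()}
    )
    metab_noise_sd_log: float = 0.1

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def validate(self) -> None:
        lo, hi = self.pathway_size_range
        if self.n_genes < 1 or self.n_pathways < 0:
            raise ConfigError("n_genes and n_pathways must be positive")
        if lo < 2 or hi < lo:
            raise ConfigError("pathway_size_range must satisfy 2 <= min <= max")
        if hi > self.n_genes:
            raise ConfigError(
                f"pathway_size_range.max ({hi}) exceeds n_genes ({self.n_genes})"
            )
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("conditions must be unique")
        universe = set(self.gene_ids())
        for cond, plan in self.deg_plan.items():
            if cond not in self.conditions:
                raise ConfigError(f"deg_plan condition {cond!r} not in conditions")
            for gene, _effect in plan:
                if gene not in universe:
                    raise ConfigError(f"planted DEG {gene!r} not in gene universe")
        if self.noise_sd_log2 < 0:
            raise ConfigError("noise_sd_log2 must be >= 0")
        if self.lc50_true <= 0:
            raise ConfigError("lc50_true must be > 0")
        if self.sigma_log10_true <= 0:
            raise ConfigError("sigma_log10_true must be > 0")
        if any(d < 0 for d in self.doses):
            raise ConfigError("doses must be >= 0")
        if len(set(self.doses)) != len(self.doses):
            raise ConfigError("doses must be unique")
        if self.n_per_dose < 1:
            raise ConfigError("n_per_dose must be >= 1")
        missing = [c for c in self.conditions if c not in self.repro_means]
        if missing:
            raise ConfigError(f"repro_means missing conditions: {missing}")
        if any(m <= 0 for m in self.repro_means.values()):
            raise ConfigError("repro_means must be > 0")
        if not 0 <= self.repro_cv < 1:
            raise ConfigError("repro_cv must be in [0, 1)")
        for gene, per_cond in self.ct_plan.items():
            for cond, rel in per_cond.items():
                if cond not in self.conditions:
                    raise ConfigError(f"ct_plan condition {cond!r} unknown")
                if rel <= 0:
                    raise ConfigError(f"ct_plan relative expression for {gene!r} must be > 0")
        for metab, per_cond in self.metab_plan.items():
            for cond, fold in per_cond.items():
                if cond not in self.conditions:
                    raise ConfigError(f"metab_plan condition {cond!r} unknown")
                if fold <= 0:
                    raise ConfigError(f"metab_plan fold for {metab!r} must be > 0")


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    """Independent per-generator substream derived from the global seed."""
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


@dataclass
class PathwayAnnotation:
    """Mapping pathway ID -> (description, member gene set).

    ``universe`` is the declared gene universe the members are drawn
    from; insertion order of ``pathways`` is the canonical pathway
    order used by writers and result tables.
    """

    pathways: dict[str, tuple[str, frozenset]]
    universe: frozenset = frozenset()

    def __post_init__(self) -> None:
        for pid, (_desc, members) in self.pathways.items():
            if not members:
                raise ConfigError(f"pathway {pid!r} has an empty member set")
        if not self.universe:
            self.universe = frozenset().union(
                *(m for _d, m in self.pathways.values())
            ) if self.pathways else frozenset()

    def gene_sets(self) -> dict[str, frozenset]:
        return {pid: members for pid, (_d, members) in self.pathways.items()}

    def pathway_ids(self) -> list[str]:
        return list(self.pathways)


def gen_pathway_annotation(cfg: SimConfig) -> PathwayAnnotation:
    """Draw overlapping pathway gene sets with sizes uniform in the configured range.

    Genes are sampled without replacement within a pathway but freely
    across pathways, so a gene may belong to several pathways — the
    overlaps are what create shared-pathway links downstream. When at
    least two pathways exist the generator guarantees that some gene
    belongs to two of them.
    """
    cfg.validate()
    rng = _rng(cfg, "pathways")
    genes = np.array(cfg.gene_ids())
    lo, hi = cfg.pathway_size_range
    width = len(str(max(cfg.n_pathways, 1)))
    pathways: dict[str, tuple[str, frozenset]] = {}
    for i in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(genes, size=size, replace=False).tolist())
        pid = f"pw{i + 1:0{width}d}"
        pathways[pid] = (f"Synthetic pathway {i + 1}", members)
    if cfg.n_pathways >= 2:
        ids = list(pathways)
        sets = [pathways[p][1] for p in ids]
        if not any(
            sets[i] & sets[j]
            for i in range(len(sets))
            for j in range(i + 1, len(sets))
        ):
            # Force one overlap by swapping a gene of the first pathway
            # into the second; sizes stay within range.
            first = sorted(sets[0])[0]
            second_members = sorted(sets[1])
            desc, _ = pathways[ids[1]]
            replaced = next(g for g in second_members if g != first)
            pathways[ids[1]] = (
                desc,
                frozenset(sets[1] - {replaced} | {first}),
            )
    return PathwayAnnotation(pathways=pathways, universe=frozenset(genes.tolist()))


def gen_expression(cfg: SimConfig, annotation: PathwayAnnotation | None = None) -> ExpressionMatrix:
    """Simulate a genes x samples log2 intensity matrix with planted effects.

    Each gene receives one baseline intensity drawn from a normal
    distribution on the log2 scale; every replicate of a condition is
    baseline + planted log2 effect (zero unless the gene appears in
    ``deg_plan`` for that condition) + additive Gaussian noise. Columns
    are ordered condition-major, replicates within condition.
    """
    cfg.validate()
    del annotation  # membership is not needed; plan genes are validated by cfg
    rng = _rng(cfg, "expression")
    genes = cfg.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(cfg.baseline_mean_log2, cfg.baseline_sd_log2, cfg.n_genes)

    samples = [
        f"{cond}_r{j + 1}" for cond in cfg.conditions for j in range(cfg.n_replicates)
    ]
    effects = np.zeros((cfg.n_genes, len(cfg.conditions)))
    for ci, cond in enumerate(cfg.conditions):
        for gene, eff in cfg.deg_plan.get(cond, ()):
            effects[gene_index[gene], ci] += eff
    values = np.repeat(baseline[:, None], len(samples), axis=1)
    values += np.repeat(effects, cfg.n_replicates, axis=1)
    values += rng.normal(0.0, cfg.noise_sd_log2, values.shape)

    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    design = pd.Series(
        [cond for cond in cfg.conditions for _ in range(cfg.n_replicates)],
        index=pd.Index(samples, name="sample"),
        name="condition",
    )
    return ExpressionMatrix(values=frame, design=design)


def gen_dose_response(cfg: SimConfig) -> pd.DataFrame:
    """Binomial mortality counts under a log10-normal tolerance model.

    Death probability at positive dose d is Phi((log10 d - log10 LC50) /
    sigma); the zero dose produces no deaths (control mortality is not
    modeled). Returns columns dose_mg_per_L, n_exposed, n_dead.
    """
    cfg.validate()
    rng = _rng(cfg, "dose_response")
    rows = []
    mu = np.log10(cfg.lc50_true)
    for dose in cfg.doses:
        if dose > 0:
            p = norm.cdf((np.log10(dose) - mu) / cfg.sigma_log10_true)
            dead = int(rng.binomial(cfg.n_per_dose, p))
        else:
            dead = 0
        rows.append((float(dose), cfg.n_per_dose, dead))
    return pd.DataFrame(rows, columns=["dose_mg_per_L", "n_exposed", "n_dead"])


def gen_reproduction(cfg: SimConfig) -> pd.DataFrame:
    """Per-worm offspring counts: truncated-at-zero, rounded normal draws.

    Each condition gets ``n_worms`` worms with counts drawn from
    Normal(mean, cv * mean). Returns columns condition, worm_id, offspring.
    """
    cfg.validate()
    rng = _rng(cfg, "reproduction")
    rows = []
    for cond in cfg.conditions:
        mean = cfg.repro_means[cond]
        draws = rng.normal(mean, cfg.repro_cv * mean, cfg.n_worms)
        counts = np.rint(np.clip(draws, 0.0, None)).astype(int)
        for i, c in enumerate(counts):
            rows.append((cond, f"{cond}_w{i + 1}", int(c)))
    return pd.DataFrame(rows, columns=["condition", "worm_id", "offspring"])


def gen_qpcr(cfg: SimConfig) -> pd.DataFrame:
    """Ct table for the planted relative-expression plan.

    The housekeeping gene has a constant Ct in every condition and
    replicate by construction. Target-gene Ct is a per-gene baseline
    minus log2 of the planted relative expression plus Gaussian noise,
    so a noiseless table round-trips exactly through the ddCt pipeline.
    Returns columns gene, condition, replicate, ct.
    """
    cfg.validate()
    rng = _rng(cfg, "qpcr")
    genes = sorted(cfg.ct_plan)
    offsets = {g: float(cfg.housekeeping_ct + rng.normal(6.0, 1.5)) for g in genes}
    rows = []
    for cond in cfg.conditions:
        for rep in range(1, cfg.n_replicates + 1):
            rows.append((cfg.housekeeping_gene, cond, rep, cfg.housekeeping_ct))
            for gene in genes:
                rel = cfg.ct_plan[gene].get(cond, 1.0)
                ct = offsets[gene] - np.log2(rel) + rng.normal(0.0, cfg.ct_noise_sd)
                rows.append((gene, cond, rep, float(ct)))
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])


def gen_metabolites(cfg: SimConfig) -> MetaboliteMatrix:
    """Metabolite x sample concentrations with planted condition fold effects.

    Concentration = per-metabolite baseline x planted fold (1 when the
    plan omits the condition) x multiplicative log-normal noise.
    """
    cfg.validate()
    rng = _rng(cfg, "metabolites")
    metabolites = sorted(cfg.metab_plan)
    baseline = {m: float(10.0 ** rng.normal(1.0, 0.4)) for m in metabolites}
    samples = [
        f"{cond}_r{j + 1}" for cond in cfg.conditions for j in range(cfg.n_replicates)
    ]
    values = np.empty((len(metabolites), len(samples)))
    col = 0
    for cond in cfg.conditions:
        for _rep in range(cfg.n_replicates):
            for mi, metab in enumerate(metabolites):
                fold = cfg.metab_plan[metab].get(cond, 1.0)
                noise = np.exp(rng.normal(0.0, cfg.metab_noise_sd_log))
                values[mi, col] = baseline[metab] * fold * noise
            col += 1
    frame = pd.DataFrame(
        values, index=pd.Index(metabolites, name="metabolite"), columns=samples
    )
    design = pd.Series(
        [cond for cond in cfg.conditions for _ in range(cfg.n_replicates)],
        index=pd.Index(samples, name="sample"),
        name="condition",
    )
    return MetaboliteMatrix(values=frame, design=design)


def plant_degs_in_pathway(
    annotation: PathwayAnnotation,
    pathway_id: str,
    n: int,
    effect: float,
    rng: np.random.Generator,
) -> list[tuple[str, float]]:
    """Pick ``n`` member genes of a pathway and assign them a common log2 effect.

    Convenience for building ``deg_plan`` entries concentrated in one
    pathway, the configuration used to demonstrate planted-signal
    recovery by the network scoring stage.
    """
    members = sorted(annotation.pathways[pathway_id][1])
    if n > len(members):
        raise ConfigError(
            f"cannot plant {n} DEGs in pathway {pathway_id!r} of size {len(members)}"
        )
    chosen = rng.choice(np.array(members), size=n, replace=False)
    return [(str(g), effect) for g in chosen]
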
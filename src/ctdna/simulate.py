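"""Synthetic multi-sample read-count cohorts with known truth.

The generator emulates a metastatic patient's cohort: one matched normal,
one or two tumor tissue samples, and a plasma (cfDNA) sample.  Somatic
mutations fall into three clonal sets — trunk (shared by every tumor
lineage), primary-private and metastasis-private.  Tissue samples observe
the clones they contain at VAF ``purity / 2`` (diploid heterozygous sites);
plasma observes each clone at VAF ``tumor_fraction * weight / 2`` where the
weights describe which lineages shed into the blood.  Trunk sites are
carried by every lineage, so their expected plasma VAF is always
``tumor_fraction / 2`` — the quantity the tumor-fraction estimator inverts.

Per-site depths are negative-binomial (overdispersed around the sample
mean); alt counts are binomial in depth at the error-inflated allele
probability; strand splits are fair-coin binomial; the matched normal
carries a small per-read trace-contamination rate.  Null (non-mutant)
candidate sites are included so the specificity of the filter cascade is
measurable.  Everything is reproducible from the scenario seed.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .model import (
    ConfigError,
    MultiSampleVariant,
    SampleObservation,
    VariantAnnotation,
    VariantKey,
    VariantTable,
)

CLONES = ("trunk", "primary_private", "met_private")

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class ScenarioConfig:
    """Truth parameters of a simulated cohort.

    ``plasma_composition`` weights the primary and metastasis lineages'
    contributions to the tumor-derived part of plasma; keys are a subset of
    ``{"primary", "metastasis"}`` and weights sum to 1.
    ``tumor_purity_tissue`` both names the tissue samples present in the
    cohort and gives their tumor purity.  ``depth_model`` maps every sample
    (tissues, ``normal`` and ``plasma``) to a (mean, dispersion) pair of the
    negative-binomial depth distribution (variance = mean + mean^2 /
    dispersion).
    """

    n_trunk: int
    n_primary_private: int
    n_met_private: int
    plasma_composition: dict[str, float]
    tumor_fraction_plasma: float
    tumor_purity_tissue: dict[str, float]
    depth_model: dict[str, tuple[float, float]]
    error_rate: float = 1e-4
    n_null_sites: int = 200
    normal_alt_rate: float = 5e-4
    frac_nonsynonymous: float = 0.8
    seed: int = 0
    primary_marker_gene: str | None = None
    met_marker_gene: str | None = None

    def __post_init__(self) -> None:
        problems = []
        for name in ("n_trunk", "n_primary_private", "n_met_private", "n_null_sites"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        for name in (
            "tumor_fraction_plasma",
            "error_rate",
            "normal_alt_rate",
            "frac_nonsynonymous",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {v}")
        extra = set(self.plasma_composition) - {"primary", "metastasis"}
        if extra:
            problems.append(f"unknown plasma_composition keys {sorted(extra)}")
        total = sum(self.plasma_composition.values())
        if abs(total - 1.0) > 1e-9:
            problems.append(f"plasma_composition weights sum to {total}, not 1")
        if any(w < 0 for w in self.plasma_composition.values()):
            problems.append("plasma_composition weights must be >= 0")
        for sid, purity in self.tumor_purity_tissue.items():
            if not 0.0 <= purity <= 1.0:
                problems.append(f"purity of {sid!r} must be in [0, 1]")
        needed = set(self.tumor_purity_tissue) | {"normal", "plasma"}
        missing = needed - set(self.depth_model)
        if missing:
            problems.append(f"depth_model missing samples {sorted(missing)}")
        for sid, (mean, disp) in self.depth_model.items():
            if mean <= 0 or disp <= 0:
                problems.append(f"depth_model[{sid!r}] mean/dispersion must be > 0")
        if problems:
            raise ConfigError("invalid scenario: " + "; ".join(problems))

    @property
    def sample_ids(self) -> list[str]:
        tissues = [s for s in ("primary", "metastasis") if s in self.tumor_purity_tissue]
        return ["normal"] + tissues + ["plasma"]

    @property
    def sample_roles(self) -> dict[str, str]:
        roles = {"normal": "normal", "plasma": "plasma"}
        if "primary" in self.tumor_purity_tissue:
            roles["primary"] = "tumor"
        if "metastasis" in self.tumor_purity_tissue:
            roles["metastasis"] = "metastasis"
        return roles

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated site."""

    key: VariantKey
    clone: str  # trunk | primary_private | met_private | null
    gene: str
    true_vaf: dict[str, float]


def _clone_weight_in_plasma(clone: str, cfg: ScenarioConfig) -> float:
    w_primary = cfg.plasma_composition.get("primary", 0.0)
    w_met = cfg.plasma_composition.get("metastasis", 0.0)
    if clone == "trunk":
        return 1.0  # carried by every tumor lineage
    if clone == "primary_private":
        return w_primary
    if clone == "met_private":
        return w_met
    return 0.0


def _clone_in_tissue(clone: str, tissue: str) -> bool:
    if clone == "trunk":
        return True
    if clone == "primary_private":
        return tissue == "primary"
    if clone == "met_private":
        return tissue == "metastasis"
    return False


def _true_vaf(clone: str, sample_id: str, cfg: ScenarioConfig) -> float:
    if clone == "null" or sample_id == "normal":
        return 0.0
    if sample_id == "plasma":
        return (
            cfg.tumor_fraction_plasma * _clone_weight_in_plasma(clone, cfg) / 2.0
        )
    purity = cfg.tumor_purity_tissue[sample_id]
    return purity / 2.0 if _clone_in_tissue(clone, sample_id) else 0.0


def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _draw_observation(
    rng: np.random.Generator,
    depth_mean: float,
    dispersion: float,
    alt_prob: float,
) -> SampleObservation:
    depth = _draw_depth(rng, depth_mean, dispersion)
    alt = int(rng.binomial(depth, alt_prob)) if depth > 0 else 0
    fwd = int(rng.binomial(alt, 0.5)) if alt > 0 else 0
    return SampleObservation(depth=depth, alt_count=alt, alt_fwd=fwd, alt_rev=alt - fwd)


def simulate_cohort(
    cfg: ScenarioConfig,
) -> tuple[VariantTable, list[TruthRecord]]:
    """Draw one cohort (variant table + truth records) from ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    clones = (
        ["trunk"] * cfg.n_trunk
        + ["primary_private"] * cfg.n_primary_private
        + ["met_private"] * cfg.n_met_private
        + ["null"] * cfg.n_null_sites
    )
    sample_ids = cfg.sample_ids
    roles = cfg.sample_roles
    variants: list[MultiSampleVariant] = []
    truth: list[TruthRecord] = []
    first_primary_private = clones.index("primary_private") if cfg.n_primary_private else -1
    first_met_private = clones.index("met_private") if cfg.n_met_private else -1
    for i, clone in enumerate(clones):
        chrom = str(1 + i % 22)
        pos = 10_000 + 1_000 * i
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(3))) % 4]
        gene = f"G{i:04d}"
        is_marker = False
        if i == first_primary_private and cfg.primary_marker_gene:
            gene, is_marker = cfg.primary_marker_gene, True
        if i == first_met_private and cfg.met_marker_gene:
            gene, is_marker = cfg.met_marker_gene, True
        nonsyn = bool(is_marker or rng.random() < cfg.frac_nonsynonymous)
        annotation = VariantAnnotation(
            in_dbsnp=is_marker,  # hotspot markers exercise the COSMIC rescue
            in_cosmic=is_marker,
            nonsynonymous=nonsyn,
            gene=gene,
        )
        obs: dict[str, SampleObservation] = {}
        vafs: dict[str, float] = {}
        for sid in sample_ids:
            mean, disp = cfg.depth_model[sid]
            tv = _true_vaf(clone, sid, cfg)
            vafs[sid] = tv
            if sid == "normal":
                alt_prob = cfg.normal_alt_rate
            else:
                alt_prob = tv + (1.0 - tv) * cfg.error_rate
            obs[sid] = _draw_observation(rng, mean, disp, alt_prob)
        v = MultiSampleVariant(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            annotation=annotation,
            observations=obs,
            sample_roles=dict(roles),
        )
        variants.append(v)
        truth.append(
            TruthRecord(key=v.key, clone=clone, gene=gene, true_vaf=vafs)
        )
    table = VariantTable(
        variants=variants, sample_ids=list(sample_ids), sample_roles=dict(roles)
    )
    return table, truth


def preset_scenario(name: str) -> ScenarioConfig:
    """Named cohort scenarios emulating the two study patients.

    ``patient1`` — metastatic sarcoma: 48 trunk mutations, plasma tumor
    fraction 0.074, plasma depth mean 524×, tissue/normal depths 118–226×.
    Eleven metastasis-private mutations come from an unsampled lesion that
    sheds into plasma (no metastasis tissue sample exists), reproducing the
    cfDNA-only mutation class.

    ``patient2`` — metastatic breast cancer: 30 trunk + 10 primary-private
    + 8 metastasis-private mutations (48 total across tissues), plasma is
    the metastasis lineage at tumor fraction 0.28, plasma depth mean 309×.
    The first primary-private site is a clonal activating hotspot absent
    from metastasis and plasma (PIK3CA-like); the first metastasis-private
    site is an endocrine-resistance hotspot shared by metastasis and plasma
    (ESR1-like).
    """
    if name == "patient1":
        return ScenarioConfig(
            n_trunk=48,
            n_primary_private=1,
            n_met_private=11,
            plasma_composition={"primary": 0.55, "metastasis": 0.45},
            tumor_fraction_plasma=0.074,
            tumor_purity_tissue={"primary": 0.6},
            depth_model={
                "normal": (226.0, 12.0),
                "primary": (118.0, 12.0),
                "plasma": (524.0, 12.0),
            },
            error_rate=1e-4,
            n_null_sites=200,
            normal_alt_rate=5e-4,
            frac_nonsynonymous=0.8,
            seed=0,
        )
    if name == "patient2":
        return ScenarioConfig(
            n_trunk=30,
            n_primary_private=10,
            n_met_private=8,
            plasma_composition={"metastasis": 1.0},
            tumor_fraction_plasma=0.28,
            tumor_purity_tissue={"primary": 0.6, "metastasis": 0.6},
            depth_model={
                "normal": (201.0, 12.0),
                "primary": (118.0, 12.0),
                "metastasis": (183.0, 12.0),
                "plasma": (309.0, 12.0),
            },
            error_rate=1e-4,
            n_null_sites=200,
            normal_alt_rate=5e-4,
            frac_nonsynonymous=1.0,
            seed=0,
            primary_marker_gene="PIK3CA-like",
            met_marker_gene="ESR1-like",
        )
    raise ConfigError(f"unknown preset {name!r}; expected patient1 or patient2")


def simulate_treatment_response(
    table: VariantTable,
    truth: list[TruthRecord],
    cfg: ScenarioConfig,
    during_tumor_fraction: float,
    seed: int,
    sample_id: str = "plasma_during",
) -> tuple[VariantTable, list[TruthRecord]]:
    """Append a second plasma draw at a new tumor fraction to a cohort.

    The mutation truth is unchanged; only the plasma tumor fraction moves
    (treatment response lowers it, progression may raise it — the latter
    triggers a warning, not an error).
    """
    if not 0.0 <= during_tumor_fraction <= 1.0:
        raise ConfigError("during_tumor_fraction must be in [0, 1]")
    if during_tumor_fraction > cfg.tumor_fraction_plasma:
        warnings.warn(
            "during-treatment tumor fraction exceeds the pre-treatment one "
            "(progression)",
            stacklevel=2,
        )
    if sample_id in table.sample_ids:
        raise ConfigError(f"sample {sample_id!r} already exists in the cohort")
    rng = np.random.default_rng(seed)
    mean, disp = cfg.depth_model["plasma"]
    truth_by_key = {t.key: t for t in truth}
    new_variants: list[MultiSampleVariant] = []
    new_truth: list[TruthRecord] = []
    during_cfg = replace(cfg, tumor_fraction_plasma=during_tumor_fraction)
    for v in table:
        t = truth_by_key[v.key]
        tv = _true_vaf(t.clone, "plasma", during_cfg)
        alt_prob = tv + (1.0 - tv) * cfg.error_rate
        obs = dict(v.observations)
        obs[sample_id] = _draw_observation(rng, mean, disp, alt_prob)
        roles = dict(v.sample_roles)
        roles[sample_id] = "plasma"
        new_variants.append(
            MultiSampleVariant(
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                annotation=v.annotation,
                observations=obs,
                sample_roles=roles,
            )
        )
        new_truth.append(
            TruthRecord(
                key=t.key,
                clone=t.clone,
                gene=t.gene,
                true_vaf={**t.true_vaf, sample_id: tv},
            )
        )
    new_table = VariantTable(
        variants=new_variants,
        sample_ids=table.sample_ids + [sample_id],
        sample_roles={**table.sample_roles, sample_id: "plasma"},
    )
    return new_table, new_truth
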
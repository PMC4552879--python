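"""Somatic mutation filter cascade for tumor/metastasis/plasma samples.

Candidate variants (as produced upstream by a paired tumor/normal caller)
are accepted as somatic mutations in a case sample when, in order:

* ``germline_db`` — not a dbSNP variant, unless also catalogued in COSMIC
  (known oncogenic hotspots, e.g. KRAS/PIK3CA, are rescued);
* ``depth_case`` — sequencing depth in the case sample ≥ 30×;
* ``depth_normal`` — depth in the matched normal ≥ 10×;
* ``alt_support`` — at least 2 reads carry the variant allele;
* ``vaf`` — variant allele fraction ≥ 10% for tissue (tumor/metastasis)
  samples, ≥ 1.5% for plasma samples;

and, for plasma (cfDNA) samples only:

* ``normal_contamination`` — the matched normal has at most 1 alt read;
* ``strand`` — alt reads occur on both sequencing strands.

All comparisons are inclusive (≥ passes).  Every failing rule is recorded,
not only the first, so audit tables are informative; the call/no-call
outcome is the conjunction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .model import (
    ConfigError,
    MultiSampleVariant,
    ValidationError,
    VariantKey,
    VariantTable,
)

#: Rule identifiers in audit/evaluation order.
RULES = (
    "germline_db",
    "depth_case",
    "depth_normal",
    "alt_support",
    "vaf",
    "normal_contamination",
    "strand",
)

_PLASMA_ONLY_RULES = ("normal_contamination", "strand")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the somatic filter cascade (defaults as documented above)."""

    min_depth_case: int = 30
    min_depth_normal: int = 10
    min_vaf_tumor: float = 0.10
    min_vaf_plasma: float = 0.015
    min_alt_reads: int = 2
    max_normal_alt_reads: int = 1
    require_both_strands_plasma: bool = True
    dbsnp_excludes_unless_cosmic: bool = True

    def __post_init__(self) -> None:
        for name in (
            "min_depth_case",
            "min_depth_normal",
            "min_alt_reads",
            "max_normal_alt_reads",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("min_vaf_tumor", "min_vaf_plasma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown filter config fields {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the cascade for one variant in one sample.

    ``called`` is true iff ``failed_rules`` is empty.
    """

    sample_id: str
    called: bool
    failed_rules: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.called != (not self.failed_rules):
            raise ValidationError("called must equal failed_rules == empty set")


def classify_variant(
    v: MultiSampleVariant, sample_id: str, cfg: FilterConfig
) -> FilterDecision:
    """Apply the full cascade to one variant in one case sample."""
    role = v.role_of(sample_id)
    if role not in ("tumor", "metastasis", "plasma"):
        raise ValidationError(
            f"sample {sample_id!r} has role {role!r}; cascade applies to "
            "tumor, metastasis or plasma samples"
        )
    normal_id = next(
        (s for s, r in v.sample_roles.items() if r == "normal"), None
    )
    if normal_id is None:
        raise ValidationError("no normal-role sample in cohort")
    obs = v.observations.get(sample_id)
    if obs is None:
        raise ValidationError(
            f"no observation for case sample {sample_id!r} at "
            f"{v.chrom}:{v.pos}"
        )
    normal = v.observations.get(normal_id)
    if normal is None:
        raise ValidationError(
            f"no observation for normal sample {normal_id!r} at "
            f"{v.chrom}:{v.pos}"
        )

    failed: set[str] = set()
    ann = v.annotation
    if ann.in_dbsnp and not (
        cfg.dbsnp_excludes_unless_cosmic and ann.in_cosmic
    ):
        failed.add("germline_db")
    if obs.depth < cfg.min_depth_case:
        failed.add("depth_case")
    if normal.depth < cfg.min_depth_normal:
        failed.add("depth_normal")
    if obs.alt_count < cfg.min_alt_reads:
        failed.add("alt_support")
    min_vaf = cfg.min_vaf_plasma if role == "plasma" else cfg.min_vaf_tumor
    if obs.vaf < min_vaf:
        failed.add("vaf")
    if role == "plasma":
        if normal.alt_count > cfg.max_normal_alt_reads:
            failed.add("normal_contamination")
        if cfg.require_both_strands_plasma and (
            obs.alt_fwd < 1 or obs.alt_rev < 1
        ):
            failed.add("strand")
    return FilterDecision(
        sample_id=sample_id, called=not failed, failed_rules=frozenset(failed)
    )


def apply_filters(
    table: VariantTable, cfg: FilterConfig
) -> tuple[dict[str, set[VariantKey]], pd.DataFrame]:
    """Classify every variant in every non-normal sample.

    Returns ``(calls, audit)`` where ``calls`` maps sample-id to the set of
    called variant keys and ``audit`` has one row per (variant, case sample)
    with the full rule outcome.
    """
    table.validate()
    case_ids = table.case_ids
    calls: dict[str, set[VariantKey]] = {sid: set() for sid in case_ids}
    rows = []
    for v in table:
        for sid in case_ids:
            try:
                decision = classify_variant(v, sid, cfg)
            except ValidationError as exc:
                raise ValidationError(
                    f"{v.chrom}:{v.pos} {v.ref}>{v.alt}: {exc}"
                ) from exc
            if decision.called:
                calls[sid].add(v.key)
            rows.append(
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "sample_id": sid,
                    "role": table.sample_roles[sid],
                    "called": decision.called,
                    "failed_rules": ",".join(sorted(decision.failed_rules)),
                }
            )
    audit = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "sample_id",
            "role",
            "called",
            "failed_rules",
        ],
    )
    return calls, audit
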
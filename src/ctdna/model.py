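"""Domain types for multi-sample variant read-count data.

A cohort is one patient's set of sequenced samples: exactly one matched
normal (germline, e.g. buffy coat) plus any number of tumor, metastasis and
plasma (cfDNA) samples.  Every variant carries per-sample read evidence —
total depth, alt-supporting read count, and the strand split of the alt
reads — from which the variant allele fraction (VAF) is always derived as
``alt_count / depth``, never stored.

Coordinates are 1-based and fully closed, matching VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

VALID_ROLES = ("normal", "tumor", "metastasis", "plasma")

#: (chrom, pos, ref, alt) — the identity of a variant within a cohort.
VariantKey = tuple[str, int, str, str]


class CtdnaError(Exception):
    """Base class for errors raised by this package."""


class ParseError(CtdnaError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(CtdnaError):
    """A domain invariant was violated."""


class ConfigError(CtdnaError):
    """A configuration (role map, filter config, scenario) is inconsistent."""


@dataclass(frozen=True)
class SampleObservation:
    """Read evidence for one variant in one sample.

    Invariants: ``alt_fwd + alt_rev == alt_count`` and
    ``alt_count <= depth``; all counts non-negative.
    """

    depth: int
    alt_count: int
    alt_fwd: int
    alt_rev: int

    def __post_init__(self) -> None:
        for name in ("depth", "alt_count", "alt_fwd", "alt_rev"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")
        if self.alt_fwd + self.alt_rev != self.alt_count:
            raise ValidationError(
                f"alt_fwd + alt_rev = {self.alt_fwd + self.alt_rev} "
                f"!= alt_count = {self.alt_count}"
            )
        if self.alt_count > self.depth:
            raise ValidationError(
                f"alt_count = {self.alt_count} exceeds depth = {self.depth}"
            )

    @property
    def vaf(self) -> float:
        """Variant allele fraction, alt_count / depth (0.0 at zero depth)."""
        return self.alt_count / self.depth if self.depth > 0 else 0.0


@dataclass(frozen=True)
class VariantAnnotation:
    """Database membership and functional annotation of a variant."""

    in_dbsnp: bool = False
    in_cosmic: bool = False
    nonsynonymous: bool = True
    gene: str = ""


@dataclass
class MultiSampleVariant:
    """One genomic variant with per-sample read evidence.

    ``observations`` maps sample-id to :class:`SampleObservation`;
    ``sample_roles`` maps sample-id to one of ``normal``, ``tumor``,
    ``metastasis``, ``plasma``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    annotation: VariantAnnotation = field(default_factory=VariantAnnotation)
    observations: dict[str, SampleObservation] = field(default_factory=dict)
    sample_roles: dict[str, str] = field(default_factory=dict)

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    def role_of(self, sample_id: str) -> str:
        try:
            return self.sample_roles[sample_id]
        except KeyError:
            raise ValidationError(f"no role declared for sample {sample_id!r}")

    def vaf(self, sample_id: str) -> float:
        try:
            return self.observations[sample_id].vaf
        except KeyError:
            raise ValidationError(
                f"no observation for sample {sample_id!r} at "
                f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"
            )


@dataclass
class VariantTable:
    """An ordered cohort of :class:`MultiSampleVariant`.

    Invariants (checked by :meth:`validate`): exactly one sample with role
    ``normal``; (chrom, pos, ref, alt) unique; every variant's observation
    keys and role keys are a subset of ``sample_ids``.
    """

    variants: list[MultiSampleVariant] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    sample_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for sid, role in self.sample_roles.items():
            if role not in VALID_ROLES:
                raise ValidationError(
                    f"sample {sid!r} has unknown role {role!r}; "
                    f"expected one of {VALID_ROLES}"
                )
        missing = [s for s in self.sample_roles if s not in self.sample_ids]
        if missing:
            raise ValidationError(f"roles declared for unknown samples {missing}")
        unroled = [s for s in self.sample_ids if s not in self.sample_roles]
        if unroled:
            raise ValidationError(f"no role declared for samples {unroled}")
        normals = [s for s, r in self.sample_roles.items() if r == "normal"]
        if self.sample_ids and len(normals) != 1:
            raise ValidationError(
                f"cohort must have exactly one normal sample, found {normals}"
            )
        seen: set[VariantKey] = set()
        for v in self.variants:
            if v.key in seen:
                raise ValidationError(f"duplicate variant {v.key}")
            seen.add(v.key)
            extra = set(v.observations) - set(self.sample_ids)
            if extra:
                raise ValidationError(
                    f"variant {v.key} has observations for unknown samples {extra}"
                )
            for sid, role in v.sample_roles.items():
                if self.sample_roles.get(sid) != role:
                    raise ValidationError(
                        f"variant {v.key} declares role {role!r} for {sid!r}, "
                        f"cohort says {self.sample_roles.get(sid)!r}"
                    )

    @property
    def normal_id(self) -> str:
        for sid, role in self.sample_roles.items():
            if role == "normal":
                return sid
        raise ValidationError("cohort has no normal sample")

    @property
    def case_ids(self) -> list[str]:
        """Non-normal sample ids in cohort order."""
        return [s for s in self.sample_ids if self.sample_roles[s] != "normal"]

    def __iter__(self) -> Iterator[MultiSampleVariant]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def get(self, key: VariantKey) -> MultiSampleVariant:
        for v in self.variants:
            if v.key == key:
                return v
        raise KeyError(key)

    def by_key(self) -> dict[VariantKey, MultiSampleVariant]:
        return {v.key: v for v in self.variants}
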
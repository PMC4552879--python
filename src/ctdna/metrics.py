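"""ctDNA summary metrics: tumor fraction, concordance, correlation, tracking.

The tumor-fraction estimator uses the heterozygous-diploid convention: a
clonal somatic mutation sits on one of two alleles of every tumor-derived
genome, so the tumor-derived fraction of cfDNA is twice the mean variant
allele fraction of clonal mutations, clipped at 1.  Copy number and LOH are
deliberately ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats

from .filters import FilterConfig, classify_variant
from .model import CtdnaError, ValidationError, VariantKey, VariantTable


class UndefinedInputError(CtdnaError):
    """The requested statistic is undefined for the given input."""


def mean_vaf(
    calls: set[VariantKey], sample_id: str, table: VariantTable
) -> float:
    """Arithmetic mean VAF of ``calls`` in ``sample_id``."""
    if not calls:
        raise UndefinedInputError("mean VAF of an empty call set is undefined")
    by_key = table.by_key()
    vafs = []
    for key in sorted(calls):
        if key not in by_key:
            raise ValidationError(f"call {key} not present in table")
        vafs.append(by_key[key].vaf(sample_id))
    return sum(vafs) / len(vafs)


def estimate_tumor_fraction(mean_vaf: float) -> float:
    """Tumor-derived fraction of cfDNA from the mean clonal VAF.

    Returns ``min(2 * mean_vaf, 1.0)`` under the heterozygous-diploid
    assumption (one mutant of two alleles per tumor genome).
    """
    if not 0.0 <= mean_vaf <= 1.0:
        raise ValueError(f"mean_vaf must be in [0, 1], got {mean_vaf}")
    return min(2.0 * mean_vaf, 1.0)


def as_percent(fraction: float, decimals: int = 1) -> float:
    """Render a fraction as a percentage, rounding half away from zero."""
    q = Decimal(10) ** -decimals
    return float(
        (Decimal(str(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class ConcordanceSummary:
    """Partition of two samples' calls into shared and private sets.

    ``query_only_subthreshold_in_reference`` collects query-private variants
    that do have ≥1 supporting read in the reference sample but sit below
    the reference's VAF calling cutoff — the "present but below our calling
    cutoff" category.
    """

    shared: frozenset[VariantKey]
    reference_only: frozenset[VariantKey]
    query_only: frozenset[VariantKey]
    query_only_subthreshold_in_reference: frozenset[VariantKey]

    def __post_init__(self) -> None:
        if self.shared & self.reference_only or self.shared & self.query_only:
            raise ValidationError("concordance sets must be disjoint")
        if not self.query_only_subthreshold_in_reference <= self.query_only:
            raise ValidationError(
                "subthreshold set must be a subset of query_only"
            )


def concordance(
    reference_calls: set[VariantKey],
    reference_sample_id: str,
    query_sample_id: str,
    table: VariantTable,
    cfg: FilterConfig,
) -> ConcordanceSummary:
    """Compare reference calls against calls made in the query sample.

    The query sample is classified with its own role's rules; the
    subthreshold category uses the reference sample's role-specific VAF
    cutoff.
    """
    for sid in (reference_sample_id, query_sample_id):
        if sid not in table.sample_ids:
            raise ValidationError(f"unknown sample {sid!r}")
    by_key = table.by_key()
    query_calls = {
        v.key
        for v in table
        if query_sample_id in v.observations
        and classify_variant(v, query_sample_id, cfg).called
    }
    shared = frozenset(reference_calls & query_calls)
    reference_only = frozenset(reference_calls - query_calls)
    query_only = frozenset(query_calls - reference_calls)
    ref_role = table.sample_roles[reference_sample_id]
    ref_cutoff = (
        cfg.min_vaf_plasma if ref_role == "plasma" else cfg.min_vaf_tumor
    )
    subthreshold = frozenset(
        key
        for key in query_only
        if (obs := by_key[key].observations.get(reference_sample_id))
        is not None
        and obs.alt_count >= 1
        and obs.vaf < ref_cutoff
    )
    return ConcordanceSummary(shared, reference_only, query_only, subthreshold)


def vaf_correlation(
    sample_a: str,
    sample_b: str,
    variants: set[VariantKey],
    table: VariantTable,
) -> float:
    """Pearson correlation of paired VAFs over ``variants``."""
    by_key = table.by_key()
    xs, ys = [], []
    for key in sorted(variants):
        v = by_key.get(key)
        if v is None:
            raise ValidationError(f"variant {key} not present in table")
        xs.append(v.vaf(sample_a))
        ys.append(v.vaf(sample_b))
    if len(xs) < 3:
        raise UndefinedInputError(
            f"need >= 3 paired observations, got {len(xs)}"
        )
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise UndefinedInputError("correlation undefined at zero variance")
    return float(stats.pearsonr(xs, ys).statistic)


@dataclass(frozen=True)
class ValidationOutcome:
    """Orthogonal-platform validation tallies for a set of tested mutations."""

    confirmed: int
    failed: int
    not_sequenced: int = 0

    def __post_init__(self) -> None:
        if min(self.confirmed, self.failed, self.not_sequenced) < 0:
            raise ValueError("validation counts must be non-negative")


def validation_rate(v: ValidationOutcome) -> float:
    """confirmed / (confirmed + failed); sites that did not sequence are excluded."""
    denom = v.confirmed + v.failed
    if denom < 1:
        raise UndefinedInputError(
            "validation rate undefined with no sequenced sites"
        )
    return v.confirmed / denom


def plasma_yield(
    volume_extracted_ml: float, concentration_ng_per_ml: float
) -> float:
    """Total cfDNA recovered (ng) from extracted plasma volume × concentration."""
    if volume_extracted_ml < 0 or concentration_ng_per_ml < 0:
        raise ValueError("volume and concentration must be non-negative")
    return volume_extracted_ml * concentration_ng_per_ml


@dataclass(frozen=True)
class LongitudinalComparison:
    """Paired pre/during-treatment VAFs for a tracked mutation set.

    Means are taken over sites with at least one alt read at that timepoint
    (``None`` when no site is detected); undetected sites are counted
    separately rather than averaged in as zeros.
    """

    per_variant: pd.DataFrame
    mean_vaf_pre: float | None
    mean_vaf_during: float | None
    n_zero_pre: int
    n_zero_during: int


def longitudinal_compare(
    pre_sample_id: str,
    during_sample_id: str,
    tracked: set[VariantKey],
    table: VariantTable,
) -> LongitudinalComparison:
    """Quantify a tracked mutation set at two plasma timepoints."""
    by_key = table.by_key()
    missing = [
        key
        for key in sorted(tracked)
        if key not in by_key
        or pre_sample_id not in by_key[key].observations
        or during_sample_id not in by_key[key].observations
    ]
    if missing:
        raise ValidationError(
            f"tracked variants missing an observation at a timepoint: {missing}"
        )
    rows = []
    for key in sorted(tracked):
        v = by_key[key]
        pre, dur = v.observations[pre_sample_id], v.observations[during_sample_id]
        rows.append(
            {
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "vaf_pre": pre.vaf,
                "vaf_during": dur.vaf,
                "alt_pre": pre.alt_count,
                "alt_during": dur.alt_count,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "vaf_pre",
            "vaf_during",
            "alt_pre",
            "alt_during",
        ],
    )

    def _mean_detected(col_vaf: str, col_alt: str) -> float | None:
        detected = frame[frame[col_alt] >= 1]
        return float(detected[col_vaf].mean()) if len(detected) else None

    return LongitudinalComparison(
        per_variant=frame,
        mean_vaf_pre=_mean_detected("vaf_pre", "alt_pre"),
        mean_vaf_during=_mean_detected("vaf_during", "alt_during"),
        n_zero_pre=int((frame["alt_pre"] == 0).sum()),
        n_zero_during=int((frame["alt_during"] == 0).sum()),
    )
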
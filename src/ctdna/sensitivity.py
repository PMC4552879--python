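"""Detection power for a variant at true plasma VAF f sequenced to depth D.

A site with true tumor-derived allele fraction ``f`` read to depth ``D``
with per-read error rate ``e`` toward the alt allele yields alt reads
``K ~ Binomial(D, p)`` with ``p = f + (1 - f) e`` (error reads are
indistinguishable from true alt reads).  The plasma filter calls the site
when ``K >= k_min`` with ``k_min = max(min_alt_reads,
ceil(min_vaf_plasma * D))`` (inclusive at exact integer boundaries) and,
when the both-strands rule is on, when the K alt reads do not all fall on
one strand.  Modeling strand assignment as an independent fair coin per
read, the both-strands probability given K = k >= 1 alt reads is
``1 - 2 (1/2)^k``.

The analytic form is cross-validated by a Monte Carlo implementation that
runs the actual filter cascade on simulated observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .filters import FilterConfig, classify_variant
from .model import (
    CtdnaError,
    MultiSampleVariant,
    SampleObservation,
    ValidationError,
)

_CEIL_EPS = 1e-9  # absorb float noise at exact min_vaf * depth boundaries


class PowerSearchError(CtdnaError):
    """The requested power is unreachable within the depth cap."""


@dataclass(frozen=True)
class PowerQuery:
    """One point of the power surface: depth, true VAF, error rate, thresholds."""

    depth: int
    true_vaf: float
    error_rate: float = 0.0
    cfg: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValidationError("depth must be >= 0")
        if not 0.0 <= self.true_vaf <= 1.0:
            raise ValidationError("true_vaf must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValidationError("error_rate must be in [0, 1]")

    @property
    def alt_read_probability(self) -> float:
        return self.true_vaf + (1.0 - self.true_vaf) * self.error_rate


def _k_min(cfg: FilterConfig, depth: int) -> int:
    from_vaf = math.ceil(cfg.min_vaf_plasma * depth - _CEIL_EPS)
    return max(cfg.min_alt_reads, from_vaf, 0)


def detection_probability_analytic(q: PowerQuery) -> float:
    """Probability the plasma filter calls the site (clean matched normal).

    Sums ``P(K = k) * S(k)`` for ``k`` from ``k_min`` to depth, where
    ``S(k) = 1 - 2 (1/2)^k`` under the both-strands rule and 1 otherwise.
    The depth rule of the cascade applies: power is 0 below
    ``cfg.min_depth_case``.
    """
    cfg = q.cfg
    if q.depth < cfg.min_depth_case:
        return 0.0
    p = q.alt_read_probability
    if p <= 0.0:
        return 0.0
    k_min = _k_min(cfg, q.depth)
    if cfg.require_both_strands_plasma:
        k_min = max(k_min, 1)
    if k_min > q.depth:
        return 0.0
    tail = float(stats.binom.sf(k_min - 1, q.depth, p))
    if not cfg.require_both_strands_plasma:
        return min(max(tail, 0.0), 1.0)
    # sum pmf(k) * 2 (1/2)^k over k >= k_min in closed form:
    # (1 - p/2)^D * P(K' >= k_min) with K' ~ Binom(D, (p/2) / (1 - p/2))
    log_scale = q.depth * math.log1p(-p / 2.0)
    p_half = (p / 2.0) / (1.0 - p / 2.0)
    one_strand = 2.0 * math.exp(log_scale) * float(
        stats.binom.sf(k_min - 1, q.depth, p_half)
    )
    return min(max(tail - one_strand, 0.0), 1.0)


@dataclass(frozen=True)
class McEstimate:
    """Monte Carlo power estimate with its binomial standard error."""

    value: float
    stderr: float
    n_reps: int


def detection_probability_mc(
    q: PowerQuery, n_reps: int, seed: int
) -> McEstimate:
    """Monte Carlo power: simulate alt counts and strand splits, then run the
    actual plasma filter path (with a clean, deep matched normal).

    Replicate outcomes with identical (alt, forward) counts are classified
    once and reused; the decision always comes from
    :func:`ctdna.filters.classify_variant`.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    p = q.alt_read_probability
    alts = rng.binomial(q.depth, p, size=n_reps)
    fwds = rng.binomial(alts, 0.5)
    normal_depth = max(q.cfg.min_depth_normal, 100)
    decisions: dict[tuple[int, int], bool] = {}
    n_pass = 0
    for alt, fwd in zip(alts.tolist(), fwds.tolist()):
        key = (alt, fwd)
        if key not in decisions:
            v = MultiSampleVariant(
                chrom="sim",
                pos=1,
                ref="A",
                alt="T",
                observations={
                    "plasma": SampleObservation(q.depth, alt, fwd, alt - fwd),
                    "normal": SampleObservation(normal_depth, 0, 0, 0),
                },
                sample_roles={"plasma": "plasma", "normal": "normal"},
            )
            decisions[key] = classify_variant(v, "plasma", q.cfg).called
        n_pass += decisions[key]
    phat = n_pass / n_reps
    stderr = math.sqrt(phat * (1.0 - phat) / n_reps)
    return McEstimate(value=phat, stderr=stderr, n_reps=n_reps)


def min_depth_for_power(
    true_vaf: float,
    target_power: float,
    cfg: FilterConfig | None = None,
    error_rate: float = 0.0,
    depth_cap: int = 10_000_000,
) -> int:
    """Smallest depth whose analytic detection power reaches ``target_power``.

    Doubling search followed by bisection.  Power as a function of depth has
    small sawtooth steps where ``ceil(min_vaf_plasma * D)`` jumps, so
    non-decrease is asserted along the (coarse) doubling path only and the
    bisection result is the boundary of the monotone envelope.
    """
    cfg = cfg or FilterConfig()
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0, 1)")
    if true_vaf <= error_rate:
        raise ValueError("true_vaf must exceed error_rate for a reachable target")

    def power(d: int) -> float:
        return detection_probability_analytic(
            PowerQuery(depth=d, true_vaf=true_vaf, error_rate=error_rate, cfg=cfg)
        )

    lo = max(cfg.min_depth_case, 1)
    hi = lo
    last = power(hi)
    while last < target_power:
        if hi >= depth_cap:
            raise PowerSearchError(
                f"power {target_power} unreachable at depth cap {depth_cap} "
                f"(reached {last:.3g}); the VAF threshold dominates"
            )
        hi = min(hi * 2, depth_cap)
        cur = power(hi)
        if cur < last - 1e-9:
            raise PowerSearchError(
                "power decreased along the doubling path; the target is "
                "unreachable under these thresholds"
            )
        last = cur
    while lo < hi:
        mid = (lo + hi) // 2
        if power(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def power_grid(
    depths,
    vafs,
    cfg: FilterConfig | None = None,
    error_rate: float = 0.0,
):
    """Analytic power over a (depth, vaf) grid as a list of dict rows."""
    cfg = cfg or FilterConfig()
    rows = []
    for d in depths:
        for f in vafs:
            rows.append(
                {
                    "depth": int(d),
                    "vaf": float(f),
                    "power": detection_probability_analytic(
                        PowerQuery(
                            depth=int(d),
                            true_vaf=float(f),
                            error_rate=error_rate,
                            cfg=cfg,
                        )
                    ),
                }
            )
    return rows
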
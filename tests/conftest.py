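import numpy as np
import pytest

from ctdna.model import (
    MultiSampleVariant,
    SampleObservation,
    VariantAnnotation,
    VariantTable,
)
from ctdna.simulate import preset_scenario, simulate_cohort

DEFAULT_ROLES = {
    "normal": "normal",
    "primary": "tumor",
    "metastasis": "metastasis",
    "plasma": "plasma",
}


def mk_variant(
    pos,
    obs,
    roles=None,
    chrom="1",
    ref="A",
    alt="T",
    in_dbsnp=False,
    in_cosmic=False,
    nonsynonymous=True,
    gene="",
):
    """Build a MultiSampleVariant from {sample: (depth, alt, fwd, rev)}."""
    roles = roles or {s: DEFAULT_ROLES[s] for s in obs}
    return MultiSampleVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        annotation=VariantAnnotation(
            in_dbsnp=in_dbsnp,
            in_cosmic=in_cosmic,
            nonsynonymous=nonsynonymous,
            gene=gene,
        ),
        observations={s: SampleObservation(*counts) for s, counts in obs.items()},
        sample_roles=roles,
    )


def mk_table(variants):
    sample_ids = list(variants[0].sample_roles) if variants else []
    roles = dict(variants[0].sample_roles) if variants else {}
    return VariantTable(
        variants=list(variants), sample_ids=sample_ids, sample_roles=roles
    )


def random_table(rng, n_variants=50, include_dbsnp=True):
    """Random 4-sample cohort exercising every rule boundary."""
    variants = []
    for i in range(n_variants):
        obs = {}
        for sid in DEFAULT_ROLES:
            depth = int(rng.integers(0, 600))
            alt = int(rng.integers(0, depth + 1)) if depth else 0
            if rng.random() < 0.5:  # half the sites at low/no support
                alt = min(alt, int(rng.integers(0, 4)))
            fwd = int(rng.integers(0, alt + 1)) if alt else 0
            obs[sid] = (depth, alt, fwd, alt - fwd)
        variants.append(
            mk_variant(
                pos=1000 + i,
                obs=obs,
                roles=dict(DEFAULT_ROLES),
                in_dbsnp=include_dbsnp and rng.random() < 0.2,
                in_cosmic=rng.random() < 0.2,
                nonsynonymous=rng.random() < 0.8,
            )
        )
    return mk_table(variants)


@pytest.fixture(scope="session")
def patient1_cohort():
    from dataclasses import replace

    cfg = replace(preset_scenario("patient1"), seed=11)
    table, truth = simulate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def patient2_cohort():
    from dataclasses import replace

    cfg = replace(preset_scenario("patient2"), seed=11)
    table, truth = simulate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
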
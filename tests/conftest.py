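import numpy as np
import pytest

from adaptabench import (
    BucketSpec,
    Roster,
    SyntheticConfig,
    fast_config,
    generate_roster,
    make_split_plan,
    uniform_year_counts,
)
from adaptabench.ensemble import MetaConfig


def toy_roster(n=12, n_desc=3, seed=0, years=None, labels=None):
    """Small hand-sized roster for unit tests."""
    rng = np.random.default_rng(seed)
    if years is None:
        years = rng.integers(1980, 2010, n)
    if labels is None:
        labels = np.arange(n) % 2
    return Roster(
        drug_ids=[f"T{i}" for i in range(n)],
        approval_years=np.asarray(years),
        labels=np.asarray(labels),
        descriptors=rng.standard_normal((n, n_desc)),
        descriptor_names=[f"d{j}" for j in range(n_desc)],
    )


#: 5 buckets of 40 over 1997-2016, dev pool 300 over 1982-1996
SMALL_BUCKET_SPEC = BucketSpec(
    ((1997, 2000), (2001, 2004), (2005, 2008), (2009, 2012), (2013, 2016))
)


def small_audit_roster(seed=0, drift_rate=0.0, effect_size=1.0):
    """Reduced-scale audit roster: dev pool 300, five buckets of 40."""
    year_counts = uniform_year_counts(range(1982, 1997), 20)
    year_counts.update(uniform_year_counts(range(1997, 2017), 10))
    cfg = SyntheticConfig(
        n_features=20,
        n_informative=6,
        effect_size=effect_size,
        drift_rate=drift_rate,
        year_counts=year_counts,
        seed=seed,
    )
    return generate_roster(cfg)


def small_split(seed=0, drift_rate=0.0, effect_size=1.0):
    return make_split_plan(
        small_audit_roster(seed, drift_rate, effect_size), spec=SMALL_BUCKET_SPEC
    )


def tiny_ensemble_config(seed=0):
    """Cheapest sensible full-stack configuration for protocol-shape tests."""
    return fast_config(
        seed=seed,
        meta=MetaConfig(hidden_layer_sizes=(6,), max_epochs=25, patience=8),
    )


@pytest.fixture
def separable_roster():
    """Well-separated classes, no drift: any sane learner scores highly."""
    cfg = SyntheticConfig(
        n_features=10,
        n_informative=5,
        effect_size=4.0,
        year_counts=uniform_year_counts(range(1985, 1995), 40),
        seed=7,
    )
    return generate_roster(cfg)
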
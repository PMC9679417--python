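"""Synthetic rosters with class signal and controllable temporal drift.

The generator emulates the statistical structure the adaptability framework
assumes of a hepatotoxicity roster: binary labels, approval years, and
real-valued descriptors whose class-conditional distributions may drift
with approval year.  It makes no claim of chemical realism — descriptors
are Gaussian, not Mold2 marginals.

Model.  For a drug approved in year t with label y in {0, 1}, each of the
``n_informative`` informative descriptors is drawn

    x ~ Normal( (y - 1/2) * effect_size + drift_rate * (t - base_year), 1 )

so the two class means are ``effect_size`` standard deviations apart, and
both class means translate together at ``drift_rate`` sd per year — a
covariate-shift mechanism under which a boundary learned on old drugs
misfires on new ones.  The remaining descriptors are Normal(0, 1) noise.

A roster-shaped fixture mirroring the DILIst audit composition is also
provided: 1,002 drugs, 753 approved before 1997, and five post-1997 test
buckets of 53 (36+/17-), 44 (29+/15-), 46 (24+/22-), 45 (23+/22-) and
61 (38+/23-) drugs with years inside the printed ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .roster import Roster
from .timesplit import DEFAULT_BUCKET_SPEC, DEFAULT_CUTOFF_YEAR, BucketSpec

__all__ = [
    "SyntheticConfig",
    "generate_roster",
    "make_dilist_fixture",
    "uniform_year_counts",
    "DILIST_BUCKET_COMPOSITION",
    "DILIST_DEV_SIZE",
    "DILIST_TEST_PREVALENCE",
    "DEFAULT_EFFECT_SIZE",
    "STRONG_DRIFT_RATE",
]

#: (positives, negatives) per test bucket of the audited dataset
DILIST_BUCKET_COMPOSITION = ((36, 17), (29, 15), (24, 22), (23, 22), (38, 23))

#: study conditions: per-feature class separation, and the drift rate of the
#: strong-drift condition.  0.02 sd/year accumulates, across the 23-year test
#: horizon, a shift on the discriminant axis comparable to the full class
#: separation — strong enough to dominate, while keeping the classifier out of
#: the degenerate regime where it calls a single class and MCC is undefined.
DEFAULT_EFFECT_SIZE = 1.0
STRONG_DRIFT_RATE = 0.02
DILIST_DEV_SIZE = 753
#: positive fraction of the 249-drug test pool: 150/249
DILIST_TEST_PREVALENCE = sum(p for p, _ in DILIST_BUCKET_COMPOSITION) / sum(
    p + n for p, n in DILIST_BUCKET_COMPOSITION
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative settings for a synthetic roster.

    Parameters
    ----------
    n_features : int
        Total descriptor columns.
    n_informative : int
        Leading columns carrying class signal (<= n_features).
    effect_size : float
        Class-mean separation on each informative descriptor, in sd units.
    drift_rate : float
        Common per-year shift of both class-conditional means, sd/year.
    year_counts : mapping year -> (n_positive, n_negative)
        Exact composition of the roster, one cell per (year, class).
    base_year : int
        Year at which the drift term vanishes.
    seed : int
        Seed for all randomness; identical configs generate identical rosters.
    """

    n_features: int = 30
    n_informative: int = 10
    effect_size: float = 1.0
    drift_rate: float = 0.0
    year_counts: dict[int, tuple[int, int]] = field(default_factory=dict)
    base_year: int = DEFAULT_CUTOFF_YEAR
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_informative <= self.n_features:
            raise ValueError("need 0 < n_informative <= n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not self.year_counts:
            raise ValueError("year_counts must be non-empty")
        for year, (npos, nneg) in self.year_counts.items():
            if npos < 0 or nneg < 0:
                raise ValueError(f"negative count for year {year}")


def uniform_year_counts(
    years, n_per_year: int, prevalence: float = DILIST_TEST_PREVALENCE
) -> dict[int, tuple[int, int]]:
    """Spread ``n_per_year`` drugs over each year at a fixed positive fraction."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    counts = {}
    for year in years:
        npos = int(round(n_per_year * prevalence))
        counts[int(year)] = (npos, n_per_year - npos)
    return counts


def generate_roster(cfg: SyntheticConfig, id_prefix: str = "D") -> Roster:
    """Draw a roster from the Gaussian drift model, reproducibly from the seed.

    Rows are ordered by year, positives before negatives within a year;
    ids are ``D0001, D0002, ...`` in row order.
    """
    rng = np.random.default_rng(cfg.seed)
    years_out, labels_out, blocks = [], [], []
    for year in sorted(cfg.year_counts):
        npos, nneg = cfg.year_counts[year]
        for label, count in ((1, npos), (0, nneg)):
            if count == 0:
                continue
            X = rng.standard_normal((count, cfg.n_features))
            shift = (label - 0.5) * cfg.effect_size + cfg.drift_rate * (year - cfg.base_year)
            X[:, : cfg.n_informative] += shift
            years_out.extend([year] * count)
            labels_out.extend([label] * count)
            blocks.append(X)
    n = len(years_out)
    width = len(str(n))
    return Roster(
        drug_ids=[f"{id_prefix}{i + 1:0{width}d}" for i in range(n)],
        approval_years=np.array(years_out, dtype=int),
        labels=np.array(labels_out, dtype=int),
        descriptors=np.vstack(blocks),
        descriptor_names=[f"desc_{j + 1}" for j in range(cfg.n_features)],
    )


def make_dilist_fixture(
    seed: int = 0,
    n_features: int = 30,
    n_informative: int = 10,
    effect_size: float = 1.0,
    drift_rate: float = 0.0,
    dev_prevalence: float = DILIST_TEST_PREVALENCE,
    dev_year_range: tuple[int, int] = (1960, 1996),
    bucket_spec: BucketSpec = DEFAULT_BUCKET_SPEC,
) -> Roster:
    """A 1,002-drug synthetic roster with the audited dataset's composition.

    753 development drugs carry approval years uniformly placed in
    ``dev_year_range`` (all before the 1997 cutoff) with the label split set
    by ``dev_prevalence`` (default: the test pool's printed prevalence,
    150/249).  The 249 test drugs reproduce the printed per-bucket
    (positive, negative) counts exactly, with years uniformly placed inside
    each printed range.  Counts are fixed by construction; only descriptor
    values and year placements vary with the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x_D111]))
    year_counts: dict[int, tuple[int, int]] = {}

    n_dev_pos = int(round(DILIST_DEV_SIZE * dev_prevalence))
    dev_years = rng.integers(dev_year_range[0], dev_year_range[1] + 1, DILIST_DEV_SIZE)
    dev_labels = np.zeros(DILIST_DEV_SIZE, dtype=int)
    dev_labels[:n_dev_pos] = 1
    rng.shuffle(dev_labels)  # labels independent of year within the dev pool
    for year, lab in zip(dev_years.tolist(), dev_labels.tolist()):
        pos, neg = year_counts.get(year, (0, 0))
        year_counts[year] = (pos + lab, neg + 1 - lab)

    for (start, end), (npos, nneg) in zip(bucket_spec.ranges, DILIST_BUCKET_COMPOSITION):
        pos_years = rng.integers(start, end + 1, npos)
        neg_years = rng.integers(start, end + 1, nneg)
        for year in pos_years.tolist():
            pos, neg = year_counts.get(year, (0, 0))
            year_counts[year] = (pos + 1, neg)
        for year in neg_years.tolist():
            pos, neg = year_counts.get(year, (0, 0))
            year_counts[year] = (pos, neg + 1)

    cfg = SyntheticConfig(
        n_features=n_features,
        n_informative=n_informative,
        effect_size=effect_size,
        drift_rate=drift_rate,
        year_counts=year_counts,
        base_year=DEFAULT_CUTOFF_YEAR,
        seed=int(np.random.SeedSequence([seed, 0x_F17]).generate_state(1)[0] % 2**31),
    )
    return generate_roster(cfg)
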
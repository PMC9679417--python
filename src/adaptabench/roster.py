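"""Compound rosters: labeled, year-stamped molecular-descriptor tables.

A roster is the universal input of the package: one row per drug, with a
unique identifier, an integer approval year, a binary hepatotoxicity (DILI)
label and a fixed-width block of real-valued descriptor columns (generic
stand-ins for 2D structural descriptors such as Mold2).  Rosters are read
from and written to delimited text with a mandatory header::

    drug_id, approval_year, dili_label, <descriptor columns...>

Labels are accepted as ``{0, 1}`` or as the ``-``/``+`` notation common in
DILI datasets (mapped to 0/1).  Validation is strict: duplicate identifiers,
implausible years, and missing or non-finite descriptor values are hard
errors with coordinates — never silently imputed or dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Roster",
    "RosterFormatError",
    "RosterValidationError",
    "read_roster",
    "write_roster",
    "write_metric_table",
    "read_metric_table",
    "METRIC_TABLE_COLUMNS",
]

MANDATORY_COLUMNS = ("drug_id", "approval_year", "dili_label")

#: plausible approval-year window; records outside it are rejected at I/O
YEAR_RANGE = (1900, 2030)

LABEL_MAP = {"0": 0, "1": 1, "-": 0, "+": 1, "–": 0, "−": 0}


class RosterFormatError(ValueError):
    """Structural problem with a roster file (missing column, bad header)."""


class RosterValidationError(ValueError):
    """A roster violates a typed invariant (duplicate id, bad year/label/value)."""


@dataclass(frozen=True)
class Roster:
    """An ordered collection of labeled, year-stamped descriptor vectors.

    Attributes
    ----------
    drug_ids : list of str
        Unique opaque identifiers, in file/row order.
    approval_years : ndarray of int
        Calendar year each drug entered the market.
    labels : ndarray of int
        1 = DILI positive ("+"), 0 = DILI negative ("-").
    descriptors : ndarray, shape (n_drugs, n_descriptors)
        Real-valued descriptor matrix; all entries finite.
    descriptor_names : list of str
        Column identifiers, one per descriptor column.
    """

    drug_ids: list[str]
    approval_years: np.ndarray
    labels: np.ndarray
    descriptors: np.ndarray
    descriptor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        object.__setattr__(self, "approval_years", np.asarray(self.approval_years, dtype=int))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        desc = np.asarray(self.descriptors, dtype=float)
        if desc.ndim != 2:
            desc = desc.reshape(len(self.drug_ids), -1)
        object.__setattr__(self, "descriptors", desc)
        _validate(self)

    def __len__(self) -> int:
        return len(self.drug_ids)

    @property
    def n_descriptors(self) -> int:
        return self.descriptors.shape[1]

    def subset(self, index: np.ndarray) -> "Roster":
        """Row-subset by boolean mask or integer index array, order preserved."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return Roster(
            drug_ids=[self.drug_ids[i] for i in index],
            approval_years=self.approval_years[index],
            labels=self.labels[index],
            descriptors=self.descriptors[index],
            descriptor_names=list(self.descriptor_names),
        )

    def concat(self, *others: "Roster") -> "Roster":
        """Row-concatenate rosters sharing a descriptor namespace."""
        rosters = (self, *others)
        for r in others:
            if r.descriptor_names != self.descriptor_names:
                raise RosterValidationError("descriptor namespaces differ across rosters")
        return Roster(
            drug_ids=[d for r in rosters for d in r.drug_ids],
            approval_years=np.concatenate([r.approval_years for r in rosters]),
            labels=np.concatenate([r.labels for r in rosters]),
            descriptors=np.vstack([r.descriptors for r in rosters]),
            descriptor_names=list(self.descriptor_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.descriptors, columns=self.descriptor_names)
        df.insert(0, "dili_label", self.labels)
        df.insert(0, "approval_year", self.approval_years)
        df.insert(0, "drug_id", self.drug_ids)
        return df


def _validate(roster: Roster) -> None:
    n = len(roster.drug_ids)
    if roster.approval_years.shape != (n,) or roster.labels.shape != (n,):
        raise RosterValidationError("column lengths disagree with number of drug ids")
    if roster.descriptors.shape[0] != n:
        raise RosterValidationError("descriptor row count disagrees with number of drug ids")
    if roster.descriptor_names and len(roster.descriptor_names) != roster.descriptors.shape[1]:
        raise RosterValidationError(
            f"{len(roster.descriptor_names)} descriptor names for "
            f"{roster.descriptors.shape[1]} descriptor columns"
        )
    seen: dict[str, int] = {}
    dupes = []
    for d in roster.drug_ids:
        seen[d] = seen.get(d, 0) + 1
        if seen[d] == 2:
            dupes.append(d)
    if dupes:
        raise RosterValidationError(f"duplicate drug_id values: {dupes}")
    lo, hi = YEAR_RANGE
    bad_year = (roster.approval_years < lo) | (roster.approval_years > hi)
    if n and bad_year.any():
        ids = [roster.drug_ids[i] for i in np.flatnonzero(bad_year)[:5]]
        raise RosterValidationError(f"approval_year outside {lo}-{hi} for drugs {ids}")
    if n and not np.isin(roster.labels, (0, 1)).all():
        bad = np.flatnonzero(~np.isin(roster.labels, (0, 1)))[:5]
        raise RosterValidationError(
            f"dili_label not in {{0,1}} at rows {bad.tolist()}"
        )
    if n and not np.isfinite(roster.descriptors).all():
        r, c = [x[0] for x in np.nonzero(~np.isfinite(roster.descriptors))]
        name = roster.descriptor_names[c] if roster.descriptor_names else f"col {c}"
        raise RosterValidationError(
            f"non-finite descriptor value at row {r} (drug {roster.drug_ids[r]}), column {name}"
        )


def _sniff_delimiter(path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample.splitlines()[0] else ","


def read_roster(path, delimiter: str | None = None) -> Roster:
    """Read and validate a roster table (CSV/TSV, delimiter sniffed).

    Parameters
    ----------
    path : path-like
        Table with header ``drug_id, approval_year, dili_label`` followed by
        at least one descriptor column.
    delimiter : str, optional
        Explicit field delimiter; sniffed from the file when omitted.

    Raises
    ------
    RosterFormatError
        If a mandatory column is missing or there are no descriptor columns.
    RosterValidationError
        On duplicate ids, out-of-range years, bad labels, or non-finite /
        missing descriptor values (with row/column coordinates).
    """
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={"drug_id": str}, float_precision="round_trip")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise RosterFormatError(f"mandatory column {col!r} missing from {path}")
    desc_names = [c for c in df.columns if c not in MANDATORY_COLUMNS]
    if not desc_names:
        raise RosterFormatError(f"no descriptor columns found in {path}")

    years = pd.to_numeric(df["approval_year"], errors="coerce")
    if years.isna().any() or (years != years.round()).any():
        rows = years.index[years.isna() | (years != years.round())].tolist()[:5]
        raise RosterValidationError(f"non-integer approval_year at rows {rows}")

    raw_labels = df["dili_label"].astype(str).str.strip()
    unknown = ~raw_labels.isin(LABEL_MAP)
    if unknown.any():
        rows = df.index[unknown].tolist()[:5]
        raise RosterValidationError(
            f"dili_label must be 0/1 or -/+; bad values at rows {rows}"
        )
    labels = raw_labels.map(LABEL_MAP).to_numpy(dtype=int)

    desc = df[desc_names].apply(pd.to_numeric, errors="coerce")
    if desc.isna().to_numpy().any():
        r, c = np.argwhere(desc.isna().to_numpy())[0]
        raise RosterValidationError(
            f"missing or non-numeric descriptor at row {r} "
            f"(drug {df['drug_id'].iloc[r]}), column {desc_names[c]}"
        )

    return Roster(
        drug_ids=df["drug_id"].tolist(),
        approval_years=years.to_numpy(dtype=int),
        labels=labels,
        descriptors=desc.to_numpy(dtype=float),
        descriptor_names=desc_names,
    )


def write_roster(roster: Roster, path, delimiter: str = "\t") -> None:
    """Write a roster back to delimited text (header included, row order kept)."""
    roster.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# metric tables

METRIC_TABLE_COLUMNS = (
    "test_bucket", "stage", "TP", "TN", "FP", "FN",
    "auc", "accuracy", "sensitivity", "specificity", "f1", "mcc", "ba",
)


def write_metric_table(reports, path) -> None:
    """Write labeled metric reports as a TSV with bit-stable ordering.

    ``reports`` is an iterable of ``(test_bucket, stage, MetricReport)``
    triples; ``stage`` is an integer, 0 for the locked baseline and k >= 1
    for the k-th adaptive retraining stage.  Rows are sorted by
    (test_bucket, stage).  Undefined metrics are written as ``NA``.
    """
    rows = sorted(reports, key=lambda t: (t[0], t[1]))
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(METRIC_TABLE_COLUMNS) + "\n")
        for bucket, stage, rep in rows:
            c = rep.counts
            vals = [bucket, stage, c.tp, c.tn, c.fp, c.fn]
            for m in (rep.auc, rep.accuracy, rep.sensitivity,
                      rep.specificity, rep.f1, rep.mcc, rep.ba):
                vals.append("NA" if m is None or np.isnan(m) else repr(float(m)))
            fh.write("\t".join(str(v) for v in vals) + "\n")


def read_metric_table(path) -> pd.DataFrame:
    """Read a metric table written by :func:`write_metric_table`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
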
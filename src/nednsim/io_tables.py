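"""Genus-level abundance tables with sampling dates, and day-pair building.

Input is the field's usual wide TSV — first column the genus label, one
column per sample — plus a companion metadata TSV mapping sample ids to
ISO-8601 collection dates. Two operations prepare such a table for
modelling: keeping the genera whose dataset-wide mean abundance clears a
threshold (default 1%) while lumping the rest into a trailing "other"
genus, and pairing samples whose collection dates are exactly a fixed
number of days apart into a training/evaluation dataset.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FLOOR, Composition
from .fitting import DayPairDataset

__all__ = [
    "SampleTable",
    "read_sample_table",
    "select_model_genera",
    "build_day_pairs",
]

logger = logging.getLogger(__name__)

OTHER_LABEL = "other"
COLUMN_SUM_TOL = 1e-6


@dataclass
class SampleTable:
    """Relative-abundance matrix (genera x samples) with per-sample dates."""

    genera: tuple[str, ...]
    sample_ids: tuple[str, ...]
    dates: tuple[dt.date, ...]
    values: np.ndarray  # (k, n_samples)

    def __post_init__(self) -> None:
        self.genera = tuple(self.genera)
        self.sample_ids = tuple(self.sample_ids)
        self.dates = tuple(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        k, n = len(self.genera), len(self.sample_ids)
        if self.values.shape != (k, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{k} genera x {n} samples"
            )
        if len(self.dates) != n:
            raise ValueError("need exactly one collection date per sample")
        if len(set(self.genera)) != k:
            raise ValueError("genus labels must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        sums = self.values.sum(axis=0)
        off = np.abs(sums - 1.0) > COLUMN_SUM_TOL
        if np.any(off):
            logger.warning(
                "renormalizing %d sample column(s) whose total deviates "
                "from 1 by more than %g",
                int(off.sum()),
                COLUMN_SUM_TOL,
            )
            self.values = self.values / sums

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def k(self) -> int:
        return len(self.genera)

    def composition(self, sample: str | int) -> Composition:
        """Model state of one sample; sub-floor entries are raised to the
        1e-6 floor and the column rescaled to its original total."""
        j = sample if isinstance(sample, int) else self.sample_ids.index(sample)
        col = self.values[:, j]
        floored = np.maximum(col, FLOOR)
        floored = floored * (col.sum() / floored.sum())
        return Composition(self.genera, floored)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genera),
                            columns=list(self.sample_ids))

    def to_tsv(self, abundance_path: str | Path, metadata_path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "genus"
        frame.to_csv(abundance_path, sep="\t")
        meta = pd.DataFrame(
            {"sample_id": list(self.sample_ids),
             "collection_date": [d.isoformat() for d in self.dates]}
        )
        meta.to_csv(metadata_path, sep="\t", index=False)


def read_sample_table(
    abundance_path: str | Path, metadata_path: str | Path
) -> SampleTable:
    """Read the wide abundance TSV and its sample-date metadata TSV."""
    frame = pd.read_csv(abundance_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if not {"sample_id", "collection_date"} <= set(meta.columns):
        raise ValueError(
            "metadata must have 'sample_id' and 'collection_date' columns"
        )
    dates_by_id = dict(zip(meta["sample_id"], meta["collection_date"]))
    sample_ids = [str(c) for c in frame.columns]
    missing = [s for s in sample_ids if s not in dates_by_id]
    if missing:
        raise ValueError(f"metadata lacks dates for samples {missing}")
    dates = tuple(dt.date.fromisoformat(dates_by_id[s]) for s in sample_ids)
    return SampleTable(
        genera=tuple(str(g) for g in frame.index),
        sample_ids=tuple(sample_ids),
        dates=dates,
        values=frame.to_numpy(dtype=float),
    )


def select_model_genera(
    table: SampleTable, mean_threshold: float = 0.01
) -> SampleTable:
    """Keep genera whose dataset-wide mean abundance exceeds the threshold;
    sum everything else into a trailing "other" genus.

    Per-sample column totals are conserved exactly: the "other" row absorbs
    whatever the dropped genera carried (it is present, possibly all-zero,
    even when every genus passes).
    """
    if table.n_samples == 0:
        raise ValueError("cannot select genera from an empty table")
    means = table.values.mean(axis=1)
    keep = means > mean_threshold
    if not np.any(keep):
        raise ValueError(
            f"no genus has mean abundance above {mean_threshold}; "
            "nothing to model"
        )
    kept = [g for g, k_ in zip(table.genera, keep) if k_]
    if OTHER_LABEL in kept:
        kept.remove(OTHER_LABEL)
        other_rows = ~keep | np.array([g == OTHER_LABEL for g in table.genera])
    else:
        other_rows = ~keep
    kept_idx = [table.genera.index(g) for g in kept]
    other = table.values[other_rows].sum(axis=0)
    values = np.vstack([table.values[kept_idx], other])
    return SampleTable(
        genera=tuple(kept) + (OTHER_LABEL,),
        sample_ids=table.sample_ids,
        dates=table.dates,
        values=values,
    )


def build_day_pairs(
    table: SampleTable, horizon: int = 1, genera: Sequence[str] | None = None
) -> DayPairDataset:
    """Pair samples whose collection dates are exactly ``horizon`` days apart.

    One pair per sample whose date plus the horizon matches another
    sample's date, ordered by start date. When several samples share a
    date the first in file order is used and the duplicate count is
    logged. Pairing is exact calendar-day arithmetic.
    """
    if horizon not in (1, 2, 3):
        raise ValueError(f"horizon must be 1, 2 or 3, got {horizon}")
    first_on_date: dict[dt.date, int] = {}
    n_dups = 0
    for j, d in enumerate(table.dates):
        if d in first_on_date:
            n_dups += 1
        else:
            first_on_date[d] = j
    if n_dups:
        logger.warning(
            "%d sample(s) share a collection date with an earlier sample; "
            "keeping the first in file order",
            n_dups,
        )
    delta = dt.timedelta(days=horizon)
    pairs = []
    for d in sorted(first_on_date):
        if d + delta in first_on_date:
            start = table.composition(first_on_date[d])
            end = table.composition(first_on_date[d + delta])
            if genera is not None:
                start = start.reorder(genera)
                end = end.reorder(genera)
            pairs.append((start, end))
    if not pairs:
        raise ValueError(
            f"no two samples are exactly {horizon} day(s) apart"
        )
    return DayPairDataset.from_pairs(pairs, horizon=horizon)
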
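"""Tabular input/output and stimulus-pool curation.

The three tables of the study design — a stimulus table (one row per
music excerpt with its expert complexity score), a liking matrix
(participants x excerpts, 0-100 visual-analogue ratings) and a trait
table (per-participant questionnaire scores) — are carried as thin
validated wrappers around pandas DataFrames.  All files are plain CSV,
UTF-8, header row required, decimal point.

Curation helpers reproduce the construction of the stimulus set from a
larger pool: deduplication of recurring complexity scores (keeping the
excerpt whose expert ratings had the lowest variance) and allocation of
excerpts to presentation blocks with balanced complexity means and
variances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StimulusTable",
    "LikingMatrix",
    "TraitTable",
    "load_table1",
    "read_stimulus_table",
    "read_liking_matrix",
    "read_trait_table",
    "write_stimulus_table",
    "write_liking_matrix",
    "write_trait_table",
    "write_report",
    "dedupe_pool",
    "allocate_blocks",
]

TRAIT_COLUMNS = (
    "capep",
    "aq",
    "ace",
    "baisv",
    "mood",
    "training_years",
    "daily_listening_h",
)


class TableValidationError(ValueError):
    """A table violates one of its declared invariants."""


@dataclass(frozen=True)
class StimulusTable:
    """Ordered collection of music excerpts with complexity scores.

    Parameters
    ----------
    df : DataFrame
        Must contain ``excerpt_id`` (unique labels) and ``complexity``
        (expert-mean score on a 1-10 scale).  Optional columns:
        ``rating_variance``, ``block``, ``duration_s``, ``entropy``
        (Wiener entropy in [0, 1]), ``is_warmup``, and any extras such
        as ``avg_liking``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.empty:
            raise TableValidationError("stimulus table is empty")
        for col in ("excerpt_id", "complexity"):
            if col not in df.columns:
                raise TableValidationError(f"stimulus table lacks column {col!r}")
        if df["excerpt_id"].duplicated().any():
            dup = df.loc[df["excerpt_id"].duplicated(), "excerpt_id"].iloc[0]
            raise TableValidationError(f"duplicate excerpt id {dup!r}")
        comp = pd.to_numeric(df["complexity"], errors="coerce")
        if comp.isna().any():
            row = int(np.flatnonzero(comp.isna())[0])
            raise TableValidationError(f"non-numeric complexity in row {row}")
        if ((comp < 1) | (comp > 10)).any():
            bad = comp[(comp < 1) | (comp > 10)].iloc[0]
            raise TableValidationError(f"complexity {bad} outside [1, 10]")
        if "duration_s" in df.columns:
            dur = df["duration_s"].dropna()
            if (dur <= 0).any():
                raise TableValidationError("duration_s must be positive")
        if "entropy" in df.columns:
            ent = df["entropy"].dropna()
            if ((ent < 0) | (ent > 1)).any():
                raise TableValidationError("entropy outside [0, 1]")
        if "is_warmup" not in df.columns:
            object.__setattr__(
                self, "df", df.assign(is_warmup=False).reset_index(drop=True)
            )
        else:
            object.__setattr__(self, "df", df.reset_index(drop=True))

    @property
    def non_warmup(self) -> pd.DataFrame:
        return self.df.loc[~self.df["is_warmup"].astype(bool)]

    @property
    def excerpt_ids(self) -> list[str]:
        return list(self.non_warmup["excerpt_id"])

    @property
    def complexity(self) -> pd.Series:
        """Complexity scores of the non-warm-up excerpts, indexed by id."""
        nw = self.non_warmup
        return pd.Series(
            nw["complexity"].to_numpy(float), index=nw["excerpt_id"], name="complexity"
        )

    @property
    def complexity_range(self) -> tuple[float, float]:
        c = self.non_warmup["complexity"].astype(float)
        return float(c.min()), float(c.max())

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class LikingMatrix:
    """Participants x excerpts matrix of 0-100 liking ratings.

    ``df`` is wide: index = participant ids, one column per excerpt id.
    Missing cells are NaN.  When a :class:`StimulusTable` is supplied the
    column set must be a subset of its non-warm-up excerpt ids.
    """

    df: pd.DataFrame
    stimuli: StimulusTable | None = None

    def __post_init__(self) -> None:
        df = self.df
        if df.empty:
            raise TableValidationError("liking matrix is empty")
        vals = df.to_numpy(float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 100)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise TableValidationError(
                f"rating {vals[i, j]} outside [0, 100] at participant "
                f"{df.index[i]!r}, excerpt {df.columns[j]!r}"
            )
        if self.stimuli is not None:
            known = set(self.stimuli.excerpt_ids)
            unknown = [c for c in df.columns if c not in known]
            if unknown:
                raise TableValidationError(
                    f"excerpt id {unknown[0]!r} not present in the stimulus table"
                )

    @property
    def participant_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(float)

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class TraitTable:
    """Per-participant questionnaire scores and covariates."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.empty:
            raise TableValidationError("trait table is empty")
        for col in ("capep", "aq"):
            if col in df.columns:
                v = df[col].dropna()
                if ((v < 1) | (v > 4)).any():
                    raise TableValidationError(f"{col} outside [1, 4]")
        for col in ("ace", "training_years", "daily_listening_h", "baisv"):
            if col in df.columns and (df[col].dropna() < 0).any():
                raise TableValidationError(f"{col} must be non-negative")

    @property
    def participant_ids(self) -> list[str]:
        return list(self.df.index)

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# readers / writers


def load_table1() -> StimulusTable:
    """The packaged 29-excerpt stimulus set used throughout as default."""
    with resources.files("sweetspot.data").joinpath("table1.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return StimulusTable(df)


def read_stimulus_table(path: str | Path, *, sep: str = ",") -> StimulusTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise TableValidationError(f"{path} contains no rows")
    return StimulusTable(df)


def read_liking_matrix(
    path: str | Path, stimuli: StimulusTable | None = None, *, sep: str = ","
) -> LikingMatrix:
    df = pd.read_csv(path, sep=sep)
    if "participant_id" not in df.columns:
        raise TableValidationError(f"{path} lacks a participant_id column")
    df = df.set_index("participant_id")
    return LikingMatrix(df, stimuli)


def read_trait_table(path: str | Path, *, sep: str = ",") -> TraitTable:
    df = pd.read_csv(path, sep=sep)
    if "participant_id" not in df.columns:
        raise TableValidationError(f"{path} lacks a participant_id column")
    return TraitTable(df.set_index("participant_id"))


def write_stimulus_table(table: StimulusTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def write_liking_matrix(matrix: LikingMatrix, path: str | Path) -> None:
    matrix.df.to_csv(path, index_label="participant_id")


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    table.df.to_csv(path, index_label="participant_id")


def write_report(results: dict, path: str | Path) -> None:
    """Serialise a (possibly nested) results mapping as sorted JSON."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(
        json.dumps(results, indent=2, sort_keys=True, default=_default) + "\n"
    )


# ---------------------------------------------------------------------------
# curation


def dedupe_pool(pool: StimulusTable) -> StimulusTable:
    """Collapse recurring complexity scores, keeping the lowest-variance excerpt.

    Among excerpts sharing a complexity score the one whose expert ratings
    had the smallest variance survives; ties on both complexity and
    variance keep the first occurrence (logged).  Input order is preserved.
    """
    df = pool.df
    if "rating_variance" not in df.columns or df["rating_variance"].isna().any():
        raise TableValidationError("dedupe_pool requires rating_variance on every row")
    keep: list[int] = []
    for _, grp in df.groupby("complexity", sort=False):
        v = grp["rating_variance"].to_numpy(float)
        best = int(np.argmin(v))  # argmin keeps the first on ties
        if (v == v[best]).sum() > 1:
            logger.warning(
                "tie on complexity %s and variance %s: keeping first occurrence %r",
                grp["complexity"].iloc[0],
                v[best],
                grp["excerpt_id"].iloc[best],
            )
        keep.append(grp.index[best])
    return StimulusTable(df.loc[sorted(keep)].reset_index(drop=True))


def _block_spread(complexities: np.ndarray, assignment: np.ndarray, k: int) -> float:
    means = np.array([complexities[assignment == b].mean() for b in range(k)])
    vars_ = np.array([complexities[assignment == b].var() for b in range(k)])
    return float(np.ptp(means) + np.ptp(vars_))


def allocate_blocks(table: StimulusTable, k: int = 4) -> StimulusTable:
    """Assign excerpts to ``k`` blocks balancing complexity means and variances.

    Excerpts are sorted by complexity and dealt in serpentine (snake)
    order, so each block receives one excerpt per pass of ``k`` with the
    direction alternating; a single greedy pass of within-pair swaps then
    reduces the residual spread of block means and variances.  Block
    sizes differ by at most one.  Warm-up rows are left unassigned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nw = table.non_warmup
    n = len(nw)
    if k > n:
        raise ValueError(f"cannot allocate {n} excerpts into {k} blocks")
    order = np.argsort(nw["complexity"].to_numpy(float), kind="stable")
    assignment = np.empty(n, dtype=int)
    for rank, pos in enumerate(order):
        cycle, offset = divmod(rank, k)
        assignment[pos] = offset if cycle % 2 == 0 else k - 1 - offset
    comp = nw["complexity"].to_numpy(float)
    # one greedy improvement pass: swap pairs across blocks if the spread
    # of block means+variances drops (sizes are untouched by swaps)
    best = _block_spread(comp, assignment, k)
    for i in range(n):
        for j in range(i + 1, n):
            if assignment[i] == assignment[j]:
                continue
            assignment[i], assignment[j] = assignment[j], assignment[i]
            s = _block_spread(comp, assignment, k)
            if s < best - 1e-12:
                best = s
            else:
                assignment[i], assignment[j] = assignment[j], assignment[i]
    df = table.df.copy()
    df["block"] = pd.array([pd.NA] * len(df), dtype="Int64")
    df.loc[nw.index, "block"] = assignment + 1
    return StimulusTable(df)
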
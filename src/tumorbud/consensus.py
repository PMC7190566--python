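"""Multi-observer rating panels and the >=70% majority consensus rule.

Each candidate object is scored by a fixed number of raters as tumor bud
(``TB``), poorly differentiated cluster (``PDC``), or ``NEITHER``.  A fused
"gold standard" label is assigned when at least 70% of the raters agree —
5 of 7 raters, or 8 of 11.  Objects split into three agreement tiers:
``uniform`` (all raters agree), ``majority`` (the 70% rule is met but not
unanimously), and ``no_agreement`` (fused label ``NONE``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 3-class rating alphabet, in canonical column order.
CATEGORIES: tuple[str, str, str] = ("TB", "PDC", "NEITHER")
#: Fused label of objects on which no consensus is reached.
NO_CONSENSUS = "NONE"
TIERS = ("uniform", "majority", "no_agreement")

DEFAULT_VOTE_FRACTION = 0.7
_FLOAT_GUARD = 1e-9  # shields t/n >= fraction from binary-float artifacts


class PanelError(ValueError):
    """Rating panel violates its contract (alphabet, completeness, ids)."""


@dataclass
class RatingPanel:
    """Objects x raters categorical rating matrix.

    ``ratings``: DataFrame indexed by object id with one column per rater;
    cells hold a category token or NaN (rater did not score that object).
    Every object must carry the same number of non-missing ratings — the study
    design guarantees a constant panel size per set — so incomplete panels are
    rejected rather than imputed.

    ``rater_groups`` optionally records which object set each rater scored.
    """

    ratings: pd.DataFrame
    rater_groups: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        df = self.ratings
        if df.index.has_duplicates:
            raise PanelError("duplicate object ids in panel")
        if df.columns.has_duplicates:
            raise PanelError("duplicate rater ids in panel")
        values = df.to_numpy(dtype=object)
        ok = np.isin(values, CATEGORIES) | pd.isna(values.astype(object))
        if not ok.all():
            bad = sorted({str(v) for v in values[~ok]})
            raise PanelError(f"unknown rating tokens: {bad!r}")
        if len(df) > 0:
            counts = df.notna().to_numpy().sum(axis=1)
            if counts.min() != counts.max():
                raise PanelError(
                    "panel incomplete: per-object rating counts vary "
                    f"({counts.min()}..{counts.max()})")
            if counts[0] == 0:
                raise PanelError("panel has objects with zero ratings")
        if self.rater_groups is not None:
            unknown = set(self.rater_groups) - set(df.columns)
            if unknown:
                raise PanelError(f"rater_groups references unknown raters: {unknown}")

    @property
    def n_objects(self) -> int:
        return len(self.ratings)

    @property
    def n_raters(self) -> int:
        """Ratings per object (constant by the completeness invariant)."""
        if len(self.ratings) == 0:
            return len(self.ratings.columns)
        return int(self.ratings.notna().to_numpy().sum(axis=1)[0])

    @property
    def object_ids(self) -> list:
        return list(self.ratings.index)

    @property
    def rater_ids(self) -> list[str]:
        return list(self.ratings.columns)

    def vote_counts(self) -> np.ndarray:
        """(n_objects, 3) integer matrix of votes per category."""
        vals = self.ratings.to_numpy(dtype=object)
        return np.stack([(vals == c).sum(axis=1) for c in CATEGORIES], axis=1)

    def subset_objects(self, object_ids) -> "RatingPanel":
        """Panel restricted to the given objects, dropping unused raters."""
        sub = self.ratings.loc[list(object_ids)]
        sub = sub.dropna(axis=1, how="all")
        groups = None
        if self.rater_groups is not None:
            groups = {r: g for r, g in self.rater_groups.items() if r in sub.columns}
        return RatingPanel(sub, groups)


def vote_threshold(n_raters: int, fraction: float = DEFAULT_VOTE_FRACTION) -> int:
    """Smallest integer t with t / n_raters >= fraction.

    Reproduces the published instances: 5 of 7 and 8 of 11 at 70%.  Fractions
    at or below 1/2 are rejected — the winning class is only guaranteed unique
    under a strict majority.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be a positive integer")
    if not 0.5 < fraction <= 1.0:
        raise ValueError("vote fraction must lie in (0.5, 1]")
    t = math.ceil(fraction * n_raters - _FLOAT_GUARD)
    return max(1, t)


@dataclass(frozen=True)
class ConsensusEntry:
    """Fused label for one object: vote counts, agreement tier, label."""

    counts: tuple[int, int, int]
    tier: str
    label: str


def consensus_label(votes, n_raters: int,
                    fraction: float = DEFAULT_VOTE_FRACTION) -> ConsensusEntry:
    """Fuse one object's vote counts under the >=70% rule."""
    counts = tuple(int(v) for v in votes)
    if len(counts) != len(CATEGORIES) or any(v < 0 for v in counts):
        raise ValueError("votes must be 3 nonnegative counts")
    if sum(counts) != n_raters:
        raise ValueError(f"votes sum to {sum(counts)}, expected n_raters={n_raters}")
    t = vote_threshold(n_raters, fraction)
    top = max(counts)
    if top < t:
        return ConsensusEntry(counts, "no_agreement", NO_CONSENSUS)
    label = CATEGORIES[counts.index(top)]  # unique: top > n/2
    tier = "uniform" if top == n_raters else "majority"
    return ConsensusEntry(counts, tier, label)


def consensus_table(panel: RatingPanel,
                    fraction: float = DEFAULT_VOTE_FRACTION) -> pd.DataFrame:
    """Per-object vote counts, tier and fused label."""
    counts = panel.vote_counts()
    n = panel.n_raters
    df = pd.DataFrame(counts, index=panel.ratings.index,
                      columns=[f"n_{c}" for c in CATEGORIES])
    if len(df) == 0:
        df["tier"] = pd.Series(dtype=object)
        df["label"] = pd.Series(dtype=object)
        return df
    t = vote_threshold(n, fraction)
    top = counts.max(axis=1)
    arg = counts.argmax(axis=1)
    tier = np.where(top == n, "uniform",
                    np.where(top >= t, "majority", "no_agreement"))
    label = np.where(top >= t, np.array(CATEGORIES, dtype=object)[arg], NO_CONSENSUS)
    df["tier"] = tier
    df["label"] = label
    return df


@dataclass(frozen=True)
class ConsensusSummary:
    """Counts of objects per (agreement tier x class), plus no-agreement.

    Mirrors the study's summary-table layout: uniform and 70%-majority counts
    per class, and a single no-agreement column.
    """

    counts: pd.DataFrame  # index: uniform/majority; columns: CATEGORIES
    no_agreement: int
    n_objects: int

    @property
    def uniform_count(self) -> int:
        return int(self.counts.loc["uniform"].sum())

    @property
    def majority_count(self) -> int:
        return int(self.counts.loc["majority"].sum())

    @property
    def definite_count(self) -> int:
        """Objects with a fused label (uniform + majority)."""
        return self.uniform_count + self.majority_count

    def fraction(self, count: int) -> float:
        return count / self.n_objects if self.n_objects else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Tidy (tier, class, count, pct) table including no-agreement."""
        rows = []
        for tier in ("uniform", "majority"):
            for c in CATEGORIES:
                n = int(self.counts.loc[tier, c])
                rows.append((tier, c, n, 100.0 * self.fraction(n)))
        rows.append(("no_agreement", NO_CONSENSUS, self.no_agreement,
                     100.0 * self.fraction(self.no_agreement)))
        return pd.DataFrame(rows, columns=["tier", "class", "count", "pct"])

    def __str__(self) -> str:
        lines = [f"{'':14s}" + "".join(f"{c:>10s}" for c in CATEGORIES)]
        for tier, title in (("uniform", "Uniform"), ("majority", "70% majority")):
            row = self.counts.loc[tier]
            lines.append(f"{title:14s}" + "".join(f"{int(row[c]):>10d}" for c in CATEGORIES))
        lines.append(f"{'No agreement':14s}{self.no_agreement:>10d}")
        return "\n".join(lines)


def summarize_consensus(panel: RatingPanel,
                        fraction: float = DEFAULT_VOTE_FRACTION) -> ConsensusSummary:
    """Aggregate a panel into tier x class counts (the study's Table-1 shape)."""
    table = consensus_table(panel, fraction)
    counts = pd.DataFrame(0, index=["uniform", "majority"], columns=list(CATEGORIES))
    for tier in ("uniform", "majority"):
        sub = table[table["tier"] == tier]
        for c in CATEGORIES:
            counts.loc[tier, c] = int((sub["label"] == c).sum())
    no_agreement = int((table["tier"] == "no_agreement").sum())
    return ConsensusSummary(counts, no_agreement, len(table))


def per_rater_counts(panel: RatingPanel) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-rater class counts, plus per-group mean/sd when groups are set.

    Returns ``(per_rater, group_stats)``.  ``per_rater`` is indexed by rater
    with one integer column per category.  ``group_stats`` (None without
    group metadata) holds sample (n-1) standard deviations; a single-rater
    group has sd reported as 0.0 with ``sd_degenerate=True``.
    """
    per_rater = pd.DataFrame(
        {c: [(panel.ratings[r] == c).sum() for r in panel.rater_ids]
         for c in CATEGORIES},
        index=pd.Index(panel.rater_ids, name="rater"), dtype=int)
    if panel.rater_groups is None:
        return per_rater, None
    rows = []
    groups = sorted(set(panel.rater_groups.values()))
    for g in groups:
        raters = [r for r in panel.rater_ids if panel.rater_groups.get(r) == g]
        block = per_rater.loc[raters]
        for c in CATEGORIES:
            vals = block[c].to_numpy(dtype=float)
            degenerate = len(vals) < 2
            sd = 0.0 if degenerate else float(np.std(vals, ddof=1))
            rows.append((g, c, float(vals.mean()) if len(vals) else float("nan"),
                         sd, len(vals), degenerate))
    stats = pd.DataFrame(rows, columns=["group", "class", "mean", "sd",
                                        "n_raters", "sd_degenerate"])
    return per_rater, stats
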
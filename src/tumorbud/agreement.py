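"""Chance-corrected interobserver agreement: Fleiss and Cohen kappa.

Fleiss kappa measures agreement among a fixed number of raters assigning
categorical labels to many subjects; Cohen kappa measures agreement between
two raters over a shared subject set.  Both are reported with the Landis-Koch
verbal bands (poor / fair / moderate / good / very good).

Degenerate panels in which every rating across all objects falls in a single
class saturate both observed and expected agreement; kappa is defined as 1
there (and is uninformative — chance correction has no variation to correct).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import CATEGORIES, RatingPanel


def _count_matrix(panel_or_counts) -> np.ndarray:
    if isinstance(panel_or_counts, RatingPanel):
        return panel_or_counts.vote_counts().astype(float)
    counts = np.asarray(panel_or_counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("expected an (objects x categories) count matrix")
    return counts


def fleiss_kappa(panel_or_counts) -> float:
    """Fleiss kappa for a complete multi-rater categorical panel.

    With ``n_ij`` raters assigning object i to class j and n raters per
    object:  P_i = (sum_j n_ij^2 - n) / (n (n-1)),  Pbar = mean_i P_i,
    p_j = sum_i n_ij / (N n),  Pbar_e = sum_j p_j^2,
    kappa = (Pbar - Pbar_e) / (1 - Pbar_e).

    Perfect agreement returns exactly 1.0 (guarding the Pbar_e -> 1
    degenerate denominator).
    """
    counts = _count_matrix(panel_or_counts)
    if counts.shape[0] < 1:
        raise ValueError("need at least one object")
    n_per = counts.sum(axis=1)
    n = n_per[0]
    if not np.all(n_per == n):
        raise ValueError("rater count must be constant across objects")
    if n < 2:
        raise ValueError("Fleiss kappa needs at least 2 raters per object")
    if np.all(counts.max(axis=1) == n):
        return 1.0  # every object unanimous, incl. single-class panels
    p_i = ((counts ** 2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / (counts.shape[0] * n)
    p_e = float((p_j ** 2).sum())
    return float((p_bar - p_e) / (1.0 - p_e))


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Unweighted Cohen kappa between two raters over the same objects.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement fraction
    and p_e the chance agreement from the two raters' marginal class
    fractions.  Identical vectors give exactly 1.0.
    """
    a = np.asarray(ratings_a, dtype=object)
    b = np.asarray(ratings_b, dtype=object)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rating vectors must be 1-D and of equal length")
    if a.size < 1:
        raise ValueError("need at least one shared object")
    p_o = float(np.mean(a == b))
    if p_o == 1.0:
        return 1.0
    cats = sorted(set(a.tolist()) | set(b.tolist()), key=str)
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    return float((p_o - p_e) / (1.0 - p_e))


def pairwise_kappa_matrix(panel: RatingPanel) -> pd.DataFrame:
    """Symmetric rater x rater Cohen-kappa matrix.

    Each entry uses only the objects both raters scored; pairs with no shared
    objects — raters from disjoint study sets — are left NaN (absence of data
    is not agreement).  The diagonal is NaN by convention.
    """
    raters = panel.rater_ids
    mat = pd.DataFrame(np.nan, index=raters, columns=raters, dtype=float)
    vals = panel.ratings
    for i, ra in enumerate(raters):
        for rb in raters[i + 1:]:
            shared = vals[ra].notna() & vals[rb].notna()
            if not shared.any():
                continue
            k = cohen_kappa(vals.loc[shared, ra].to_numpy(),
                            vals.loc[shared, rb].to_numpy())
            mat.loc[ra, rb] = k
            mat.loc[rb, ra] = k
    return mat


#: Landis-Koch verbal bands, upper-inclusive: poor (-inf, 0.20], fair
#: (0.20, 0.40], moderate (0.40, 0.60], good (0.60, 0.80], very good (0.80, 1].
_BANDS = ((0.20, "poor"), (0.40, "fair"), (0.60, "moderate"), (0.80, "good"))


def interpret_kappa(k: float) -> str:
    """Landis-Koch band label for a kappa value in [-1, 1]."""
    if not np.isfinite(k) or not -1.0 - 1e-12 <= k <= 1.0 + 1e-12:
        raise ValueError(f"kappa must lie in [-1, 1], got {k!r}")
    for hi, name in _BANDS:
        if k <= hi:
            return name
    return "very good"


@dataclass(frozen=True)
class AgreementReport:
    """Fleiss kappa per object group plus the pairwise Cohen-kappa matrix."""

    fleiss: dict[str, float]          # group name -> kappa ("all" if ungrouped)
    fleiss_bands: dict[str, str]
    cohen_matrix: pd.DataFrame
    cohen_bands: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = [("fleiss", g, k, self.fleiss_bands[g])
                for g, k in self.fleiss.items()]
        raters = list(self.cohen_matrix.index)
        for i, ra in enumerate(raters):
            for rb in raters[i + 1:]:
                v = self.cohen_matrix.loc[ra, rb]
                if np.isfinite(v):
                    rows.append(("cohen", f"{ra}|{rb}", float(v),
                                 self.cohen_bands.loc[ra, rb]))
        return pd.DataFrame(rows, columns=["statistic", "group_or_pair",
                                           "value", "band"])


def compute_agreement(panel: RatingPanel,
                      object_groups: pd.Series | None = None) -> AgreementReport:
    """Fleiss kappa per object group and all pairwise Cohen kappas.

    ``object_groups`` maps object id -> group label (e.g. the study's two
    1500-candidate sets); without it a single "all" group is used.  Within
    each group, raters who scored none of its objects are dropped before the
    Fleiss computation.
    """
    fleiss: dict[str, float] = {}
    if object_groups is None:
        fleiss["all"] = fleiss_kappa(panel)
    else:
        groups = object_groups.reindex(panel.ratings.index)
        if groups.isna().any():
            raise ValueError("object_groups must cover every panel object")
        for g in sorted(groups.unique(), key=str):
            sub = panel.subset_objects(groups.index[groups == g])
            fleiss[str(g)] = fleiss_kappa(sub)
    bands = {g: interpret_kappa(k) for g, k in fleiss.items()}
    cohen = pairwise_kappa_matrix(panel)
    cohen_bands = cohen.map(
        lambda v: interpret_kappa(v) if np.isfinite(v) else "")
    return AgreementReport(fleiss, bands, cohen, cohen_bands)
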
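"""Hit calling and rank statistics for the nemadipine-A growth-arrest suppressor screen.

Wells of ~20 synchronized L1 *unc-68* worms are exposed to nemadipine-A plus a
candidate chemical; after six days the L4 and adult worms in each well are
counted.  A chemical is a primary hit when every replicate well contains at
least one developed (L4/adult) worm.  Because some worms develop by chance
("random escapees"), developmental-stage distributions are also compared to an
escapee baseline with a Kruskal–Wallis test and Dunn's post-test on stage
rank scores (L1-L3 → 1, L4 → 2, adult → 3).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WELL_COLUMNS",
    "ImputedWell",
    "HitCall",
    "RankTestResult",
    "validate_wells",
    "impute_stage_counts",
    "escapee_rate",
    "call_hits",
    "stage_rank_test",
    "retest_confirm",
    "wells_to_ranks",
]

logger = logging.getLogger(__name__)

#: canonical column order of a well table
WELL_COLUMNS = [
    "condition_id",
    "replicate",
    "count_L1L3",
    "count_L4",
    "count_adult",
    "is_control",
]

STAGE_RANKS = {"count_L1L3": 1, "count_L4": 2, "count_adult": 3}


@dataclass(frozen=True)
class ImputedWell:
    condition_id: str
    replicate: int
    count_L4: int
    count_adult: int
    assumed_n: int
    imputed_L1L3: int
    clamped: bool


@dataclass(frozen=True)
class HitCall:
    condition_id: str
    escaped_per_replicate: tuple[int, ...]
    is_primary_hit: bool
    p_vs_baseline: float = float("nan")
    adjusted_p: float = float("nan")


@dataclass(frozen=True)
class RankTestResult:
    H: float
    df: int
    omnibus_p: float
    per_group: pd.DataFrame  # group_id, n, mean_rank, dunn_z, p_unadjusted, p_adjusted


def validate_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Validate a well table and return it with canonical dtypes.

    Raises ``ValueError`` on missing columns, negative counts or an empty table.
    """
    if wells is None or len(wells) == 0:
        raise ValueError("well table is empty: no records")
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise ValueError(f"well table missing columns: {missing}")
    out = wells.copy()
    for col in ("count_L1L3", "count_L4", "count_adult"):
        vals = pd.to_numeric(out[col], errors="raise")
        if (vals < 0).any():
            bad = out.loc[vals < 0, "condition_id"].head(20).tolist()
            raise ValueError(f"negative counts in {col} for conditions {bad}")
        out[col] = vals.astype(int)
    out["is_control"] = out["is_control"].astype(bool)
    return out


def impute_stage_counts(well: Mapping | pd.Series, assumed_n: int = 20) -> ImputedWell:
    """Impute the uncounted L1-L3 larvae from the developed-worm counts.

    The screen only counted developed (L4/adult) worms per well; the arrested
    larvae are recovered post hoc by assuming ``assumed_n`` worms were plated,
    so ``imputed_L1L3 = max(0, assumed_n - L4 - adult)``.  When the observed
    developed count exceeds ``assumed_n`` the imputation clamps at zero and the
    well is flagged, since the true plated number varied (~15-25).
    """
    if assumed_n < 1:
        raise ValueError(f"assumed_n must be >= 1, got {assumed_n}")
    l4 = int(well["count_L4"])
    adult = int(well["count_adult"])
    if l4 < 0 or adult < 0:
        raise ValueError("stage counts must be non-negative")
    escaped = l4 + adult
    clamped = escaped > assumed_n
    if clamped:
        logger.warning(
            "well %s/%s: observed %d developed worms exceed assumed n=%d; clamping L1-L3 at 0",
            well.get("condition_id", "?"), well.get("replicate", "?"), escaped, assumed_n,
        )
    return ImputedWell(
        condition_id=str(well.get("condition_id", "")),
        replicate=int(well.get("replicate", 0)),
        count_L4=l4,
        count_adult=adult,
        assumed_n=assumed_n,
        imputed_L1L3=max(0, assumed_n - escaped),
        clamped=clamped,
    )


def impute_table(wells: pd.DataFrame, assumed_n: int = 20) -> pd.DataFrame:
    """Vectorised :func:`impute_stage_counts` over a well table."""
    wells = validate_wells(wells)
    escaped = wells["count_L4"] + wells["count_adult"]
    out = wells.copy()
    out["assumed_n"] = assumed_n
    out["imputed_L1L3"] = np.maximum(0, assumed_n - escaped)
    out["clamped"] = escaped > assumed_n
    n_clamped = int(out["clamped"].sum())
    if n_clamped:
        logger.warning("%d wells exceeded assumed n=%d and were clamped", n_clamped, assumed_n)
    return out


def escapee_rate(wells: pd.DataFrame) -> tuple[float, int, int]:
    """Fraction of wells containing >= 1 developed (L4/adult) worm.

    Returns ``(fraction, wells_with_escapee, wells_total)``.  The reporting
    convention rounds the percentage to one decimal (e.g. 62/760 -> 8.2%).
    """
    wells = validate_wells(wells)
    escaped = (wells["count_L4"] + wells["count_adult"]) >= 1
    n_esc = int(escaped.sum())
    n_tot = len(wells)
    return n_esc / n_tot, n_esc, n_tot


def escapee_rate_pct(wells: pd.DataFrame) -> float:
    frac, _, _ = escapee_rate(wells)
    return round(100.0 * frac, 1)


def call_hits(
    wells: pd.DataFrame,
    min_escaped: int = 1,
    require_all_replicates: bool = True,
) -> tuple[list[HitCall], float]:
    """Primary hit calling: a condition is a hit when its replicate wells
    contain developed worms.

    With the defaults, a hit needs >= 1 L4/adult worm in *every* replicate
    (the duplicate-well criterion).  Control wells are excluded from the
    condition tally.  Returns the hit calls and the hit rate as a percentage
    rounded to one decimal.
    """
    wells = validate_wells(wells)
    exp = wells.loc[~wells["is_control"]]
    if len(exp) == 0:
        raise ValueError("no experimental (non-control) wells present")
    calls: list[HitCall] = []
    escaped = exp["count_L4"] + exp["count_adult"]
    for cond, grp_escaped in escaped.groupby(exp["condition_id"], sort=True):
        per_rep = tuple(int(x) for x in grp_escaped)
        ok = per_rep and (
            all(x >= min_escaped for x in per_rep)
            if require_all_replicates
            else any(x >= min_escaped for x in per_rep)
        )
        calls.append(HitCall(condition_id=str(cond), escaped_per_replicate=per_rep, is_primary_hit=bool(ok)))
    n_hit = sum(c.is_primary_hit for c in calls)
    rate_pct = round(100.0 * n_hit / len(calls), 1)
    return calls, rate_pct


def wells_to_ranks(wells: pd.DataFrame, assumed_n: int | None = 20) -> dict[str, np.ndarray]:
    """Expand a well table into per-worm stage rank scores per condition.

    Each worm contributes a rank of 1 (L1-L3), 2 (L4) or 3 (adult).  When
    ``assumed_n`` is given the L1-L3 count is replaced by the post-hoc
    imputation; pass ``None`` to use observed L1-L3 counts.
    """
    if assumed_n is not None:
        wells = impute_table(wells, assumed_n)
        l13_col = "imputed_L1L3"
    else:
        wells = validate_wells(wells)
        l13_col = "count_L1L3"
    groups: dict[str, list[int]] = {}
    for _, row in wells.iterrows():
        ranks = groups.setdefault(str(row["condition_id"]), [])
        ranks.extend([1] * int(row[l13_col]))
        ranks.extend([2] * int(row["count_L4"]))
        ranks.extend([3] * int(row["count_adult"]))
    return {k: np.asarray(v, dtype=float) for k, v in groups.items()}


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _kw_H(groups: Sequence[np.ndarray]) -> tuple[float, int]:
    """Tie-corrected Kruskal-Wallis H; returns (H, df). H=0 when all tied."""
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    idx = 0
    ssq = 0.0
    for g in groups:
        r = ranks[idx: idx + g.size]
        idx += g.size
        ssq += r.sum() ** 2 / g.size
    H = 12.0 / (N * (N + 1)) * ssq - 3.0 * (N + 1)
    tie = _tie_term(pooled)
    denom = 1.0 - tie / (N**3 - N) if N > 1 else 0.0
    if denom <= 0:
        return 0.0, len(groups) - 1  # every observation tied
    return H / denom, len(groups) - 1


def _exact_permutation_p(groups: Sequence[np.ndarray], H_obs: float) -> float:
    """Exact permutation p for the KW statistic by full enumeration of group
    assignments (feasible for pooled N up to ~12)."""
    pooled = np.concatenate(groups)
    sizes = [g.size for g in groups]
    N = pooled.size
    count = 0
    total = 0
    indices = list(range(N))

    def rec(remaining: list[int], size_idx: int, chosen: list[np.ndarray]):
        nonlocal count, total
        if size_idx == len(sizes) - 1:
            chosen_final = chosen + [pooled[np.asarray(remaining)]]
            H, _ = _kw_H(chosen_final)
            total += 1
            if H >= H_obs - 1e-12:
                count += 1
            return
        for combo in itertools.combinations(remaining, sizes[size_idx]):
            rest = [i for i in remaining if i not in set(combo)]
            rec(rest, size_idx + 1, chosen + [pooled[np.asarray(combo)]])

    rec(indices, 0, [])
    return count / total


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    if method in ("bonferroni", "holm", "fdr_bh", "sidak"):
        from statsmodels.stats.multitest import multipletests

        return multipletests(np.clip(pvals, 0, 1), method=method)[1]
    if method == "none":
        return pvals
    raise ValueError(f"unknown adjustment method: {method}")


def stage_rank_test(
    groups: Mapping[str, Sequence[float]],
    reference: str,
    adjust: str = "bonferroni",
    method: str = "asymptotic",
) -> RankTestResult:
    """Kruskal-Wallis omnibus test plus Dunn's post-test of each group against
    a reference group.

    ``groups`` maps group ids to observations (here, per-worm stage ranks in
    {1,2,3}; any ordinal values work).  The Dunn z for group *i* versus the
    reference compares mean pooled ranks with the tie-corrected standard
    error; p-values over the vs-reference family are adjusted with the
    Bonferroni rule by default, matching the common implementation of "Dunn's
    multiple comparisons post-test".  ``method='exact'`` replaces the
    chi-square omnibus p with full permutation enumeration (small N only).

    Degenerate all-tied data yields H=0, p=1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not among groups")
    ids = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in ids]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")

    H, df = _kw_H(arrays)
    pooled = np.concatenate(arrays)
    N = pooled.size
    all_tied = np.unique(pooled).size == 1
    if all_tied:
        omnibus_p = 1.0
    elif method == "exact":
        omnibus_p = _exact_permutation_p(arrays, H)
    else:
        omnibus_p = float(stats.chi2.sf(H, df))

    # Dunn z vs reference on pooled mid-ranks
    ranks = stats.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    idx = 0
    for gid, a in zip(ids, arrays):
        mean_ranks[gid] = float(ranks[idx: idx + a.size].mean())
        sizes[gid] = a.size
        idx += a.size
    tie = _tie_term(pooled)
    var_core = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1)) if N > 1 else 0.0

    rows = []
    others = [g for g in ids if g != reference]
    for gid in others:
        if all_tied or var_core <= 0:
            z, p_un = 0.0, 1.0
        else:
            se = np.sqrt(var_core * (1.0 / sizes[gid] + 1.0 / sizes[reference]))
            z = (mean_ranks[gid] - mean_ranks[reference]) / se
            p_un = float(2.0 * stats.norm.sf(abs(z)))
        rows.append((gid, sizes[gid], mean_ranks[gid], z, p_un))
    per = pd.DataFrame(rows, columns=["group_id", "n", "mean_rank", "dunn_z", "p_unadjusted"])
    per["p_adjusted"] = _adjust(per["p_unadjusted"].to_numpy(), adjust)
    return RankTestResult(H=H, df=df, omnibus_p=omnibus_p, per_group=per)


def retest_confirm(
    primary: Sequence[HitCall],
    retest_wells: pd.DataFrame,
    min_escaped: int = 1,
    require_all_replicates: bool = True,
) -> set[str]:
    """Conditions from the primary hit list that satisfy the hit criterion
    again in an independent retest dataset."""
    primary_ids = {c.condition_id for c in primary if c.is_primary_hit}
    retest_calls, _ = call_hits(
        retest_wells, min_escaped=min_escaped, require_all_replicates=require_all_replicates
    )
    confirmed = set()
    for call in retest_calls:
        if call.condition_id not in primary_ids:
            warnings.warn(
                f"retested condition {call.condition_id!r} was not a primary hit",
                stacklevel=2,
            )
        if call.is_primary_hit:
            confirmed.add(call.condition_id)
    return confirmed
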
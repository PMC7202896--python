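"""Chemical-genetic interaction scoring on larval movement speed.

Movement speeds are normalized per assay to the mean of vehicle-treated
wild-type siblings, so the four group means live on a scale where the
wild-type/vehicle mean W is 1.  With G the mutant/vehicle mean and C the
wild-type/chemical mean, the expected double-perturbation mean is

    additive:        E = G + C - 1        (unnormalized: Wg + Wc - W)
    multiplicative:  E = G * C            (unnormalized: Wg * Wc / W)

and the interaction score is eps = observed mutant/chemical mean - E.  A
nonzero eps means the chemical's effect on the mutant is not predicted by
combining the single-perturbation effects.  Significance comes from the
genotype x treatment interaction term of a two-way ANOVA, with Tukey's HSD
for pairwise group contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SPEED_COLUMNS",
    "InteractionResult",
    "normalize_speeds",
    "expected_phenotype",
    "interaction_score",
    "group_means",
    "two_way_anova_tukey",
    "interaction_test",
    "power_two_groups",
]

SPEED_COLUMNS = ["larva_id", "assay_id", "genotype", "treatment", "speed_mm_s"]

WT = "WT"
VEHICLE = "vehicle"


@dataclass
class InteractionResult:
    W: float
    G: float
    C: float
    GC_obs: float
    E_add: float
    E_mult: float
    eps_add: float
    eps_mult: float
    p_interaction: float
    anova: pd.DataFrame
    tukey: pd.DataFrame
    classification: str  # positive | negative | none
    add_floor_flag: bool = False  # additive expectation fell below 0 speed


def _check_speed_frame(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SPEED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"speed table missing columns: {missing}")
    if (records["speed_mm_s"] < 0).any():
        raise ValueError("raw speeds must be non-negative")
    return records


def normalize_speeds(records: pd.DataFrame) -> pd.DataFrame:
    """Fill ``speed_norm`` = raw speed / mean WT-vehicle speed of the same assay.

    Each assay must contain a WT-vehicle reference group with nonzero mean;
    otherwise the offending assay is named in the error.
    """
    records = _check_speed_frame(records).copy()
    norm = np.empty(len(records), dtype=float)
    for assay, grp in records.groupby("assay_id", sort=False):
        ref = grp.loc[(grp["genotype"] == WT) & (grp["treatment"] == VEHICLE), "speed_mm_s"]
        if len(ref) == 0:
            raise ValueError(f"assay {assay!r} has no WT-vehicle reference group")
        ref_mean = float(ref.mean())
        if ref_mean <= 0:
            raise ValueError(f"assay {assay!r}: WT-vehicle reference mean is 0")
        norm[records.index.get_indexer(grp.index)] = grp["speed_mm_s"].to_numpy() / ref_mean
    records["speed_norm"] = norm
    return records


def expected_phenotype(G: float, C: float, model: str) -> float:
    """Expected normalized double-perturbation mean under a combination model
    (W = 1 on the normalized scale)."""
    if G < 0 or C < 0:
        raise ValueError("normalized means must be non-negative")
    if model == "additive":
        return G + C - 1.0
    if model == "multiplicative":
        return G * C
    raise ValueError(f"unknown interaction model: {model!r}")


def interaction_score(G: float, C: float, GC_obs: float) -> tuple[float, float]:
    """(eps_add, eps_mult): deviation of the observed double-perturbation mean
    from the additive and multiplicative expectations."""
    return (
        GC_obs - expected_phenotype(G, C, "additive"),
        GC_obs - expected_phenotype(G, C, "multiplicative"),
    )


def group_means(records: pd.DataFrame, chemical: str | None = None) -> dict[str, float]:
    """Normalized group means W, G, C, GC for one chemical's 2x2 design."""
    if "speed_norm" not in records.columns:
        records = normalize_speeds(records)
    if chemical is None:
        chems = sorted(set(records["treatment"]) - {VEHICLE})
        if len(chems) != 1:
            raise ValueError(f"specify chemical: found treatments {chems}")
        chemical = chems[0]
    out = {}
    for key, (geno, treat) in {
        "W": (WT, VEHICLE),
        "G": ("mutant", VEHICLE),
        "C": (WT, chemical),
        "GC": ("mutant", chemical),
    }.items():
        sel = records.loc[
            (records["genotype"] == geno) & (records["treatment"] == treat), "speed_norm"
        ]
        if len(sel) == 0:
            raise ValueError(f"missing group: genotype={geno}, treatment={treat}")
        out[key] = float(sel.mean())
    return out


def two_way_anova_tukey(
    df: pd.DataFrame, value: str, factor_a: str, factor_b: str
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Two-way fixed-effects ANOVA (type-II sums of squares, so unbalanced
    designs are handled) plus Tukey HSD over all factor-combination groups.

    Returns (anova table, interaction-term p, tukey table).  When the
    interaction and residual sums of squares both vanish (noise-free data),
    the F ratio is 0/0 and the interaction p is reported as 1: there is no
    evidence of interaction.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    counts = df.groupby([factor_a, factor_b])[value].count()
    if (counts < 2).any() or len(counts) < 4:
        raise ValueError("need >= 2 observations in every cell of the 2x2 design")

    work = df[[factor_a, factor_b, value]].rename(
        columns={factor_a: "A", factor_b: "B", value: "y"}
    )
    model = ols("y ~ C(A) * C(B)", data=work).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on zero residual SS
        anova = sm.stats.anova_lm(model, typ=2)
    inter_row = anova.loc["C(A):C(B)"]
    ss_inter = float(inter_row["sum_sq"])
    ss_resid = float(anova.loc["Residual", "sum_sq"])
    scale = max(float(np.sum(work["y"] ** 2)), 1.0)
    if ss_inter / scale < 1e-14 and ss_resid / scale < 1e-14:
        p_inter = 1.0
    else:
        p_inter = float(inter_row["PR(>F)"])
        if np.isnan(p_inter) and ss_inter / scale < 1e-14:
            p_inter = 1.0
    labels = work["A"].astype(str) + ":" + work["B"].astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance toy data
        tk = pairwise_tukeyhsd(work["y"].to_numpy(), labels.to_numpy())
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return anova, p_inter, tukey


def interaction_test(
    records: pd.DataFrame,
    chemical: str | None = None,
    alpha: float = 0.05,
    model: str = "multiplicative",
) -> InteractionResult:
    """Full interaction analysis of a genotype x treatment speed dataset.

    Normalizes speeds (if not already normalized), computes the four group
    means and both eps scores, runs the two-way ANOVA with Tukey post-test on
    normalized speed, and classifies the interaction as positive/negative/none
    from the sign of the chosen model's eps when the interaction term is
    significant at ``alpha``.
    """
    if "speed_norm" not in records.columns:
        records = normalize_speeds(records)
    means = group_means(records, chemical=chemical)
    G, C, GC = means["G"], means["C"], means["GC"]
    E_add = expected_phenotype(G, C, "additive")
    E_mult = expected_phenotype(G, C, "multiplicative")
    eps_add, eps_mult = interaction_score(G, C, GC)

    anova, p_inter, tukey = two_way_anova_tukey(
        records, value="speed_norm", factor_a="genotype", factor_b="treatment"
    )
    eps = eps_mult if model == "multiplicative" else eps_add
    if p_inter < alpha and eps > 0:
        classification = "positive"
    elif p_inter < alpha and eps < 0:
        classification = "negative"
    else:
        classification = "none"
    return InteractionResult(
        W=means["W"],
        G=G,
        C=C,
        GC_obs=GC,
        E_add=E_add,
        E_mult=E_mult,
        eps_add=eps_add,
        eps_mult=eps_mult,
        p_interaction=p_inter,
        anova=anova,
        tukey=tukey,
        classification=classification,
        add_floor_flag=E_add < 0,
    )


def power_two_groups(
    mean1: float,
    sd1: float,
    mean2: float,
    sd2: float,
    n_per_group: int,
    alpha: float = 0.05,
    welch: bool = False,
) -> float:
    """Power of a two-sided two-sample t test at the given group means/SDs.

    Uses the noncentral t distribution.  Pooled variance by default; Welch
    uses the Welch-Satterthwaite degrees of freedom.  Used to plan assay
    sample sizes (e.g. n = 9 larvae per group for near-certain detection of
    the wild-type vs mutant speed difference).
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    n = n_per_group
    se = np.sqrt(sd1**2 / n + sd2**2 / n)
    if se == 0:
        if mean1 == mean2:
            warnings.warn("degenerate case: zero variance and equal means; power = alpha")
            return alpha
        return 1.0
    if welch:
        df = se**4 / ((sd1**2 / n) ** 2 / (n - 1) + (sd2**2 / n) ** 2 / (n - 1))
    else:
        df = 2 * n - 2
        sp2 = (sd1**2 + sd2**2) / 2.0
        se = np.sqrt(2.0 * sp2 / n)
    nc = (mean1 - mean2) / se
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
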
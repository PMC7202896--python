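"""Calcium-transient and qPCR readouts for the myotube experiments.

Fura-2 ratiometric (340/380 nm) traces of myotubes challenged with 10 mM
caffeine are reduced to a peak response: the baseline is the mean ratio over
the 10 s before caffeine addition and the peak change is the maximum ratio
within 30 s after addition minus that baseline, optionally re-expressed
after normalizing the whole trace to its own baseline.  Paired resting-Ca2+
measurements of the same cells at 25 °C and 37 °C quantify temperature-
dependent Ca2+ leak, and comparative ddCt converts qPCR Ct values into
knockdown fold changes relative to a reference gene and negative-control
condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .interaction import two_way_anova_tukey

__all__ = [
    "CalciumTrace",
    "PeakResponse",
    "caffeine_response",
    "group_summary",
    "compare_groups_2way",
    "paired_temperature_test",
    "ddct_fold_change",
]


@dataclass
class CalciumTrace:
    cell_id: str
    group_id: str
    time: np.ndarray  # s, strictly increasing, uniform sampling
    ratio: np.ndarray  # 340/380 fluorescence ratio, > 0
    caffeine_time: float  # s

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.ratio.shape:
            raise ValueError("time and ratio must be matching 1-D arrays")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.ratio <= 0):
            raise ValueError("ratios must be positive")


@dataclass(frozen=True)
class PeakResponse:
    cell_id: str
    group_id: str
    baseline: float
    delta_peak: float
    normalized_delta: float
    peak_time: float


def caffeine_response(
    trace: CalciumTrace, baseline_window: float = 10.0, peak_window: float = 30.0
) -> PeakResponse:
    """Peak caffeine-evoked change of a ratiometric trace.

    Baseline = mean ratio over ``baseline_window`` seconds immediately before
    caffeine addition; peak change = max ratio within ``peak_window`` seconds
    after addition minus baseline.  ``normalized_delta`` divides the trace by
    its own baseline first, so responses are comparable across cells with
    different resting ratios.  Traces that do not cover both windows are
    rejected (the baseline average is part of the definition; partial windows
    are not shortened silently).
    """
    t0 = trace.caffeine_time
    t = trace.time
    if t[0] > t0 - baseline_window + 1e-9:
        raise ValueError(
            f"trace starts at {t[0]:.3f}s; needs >= {baseline_window}s of pre-addition data"
        )
    if t[-1] < t0 + peak_window - 1e-9:
        raise ValueError(
            f"trace ends at {t[-1]:.3f}s; needs >= {peak_window}s of post-addition data"
        )
    pre = (t >= t0 - baseline_window) & (t < t0)
    post = (t >= t0) & (t <= t0 + peak_window)
    baseline = float(trace.ratio[pre].mean())
    post_ratio = trace.ratio[post]
    i_peak = int(np.argmax(post_ratio))
    delta = float(post_ratio[i_peak] - baseline)
    return PeakResponse(
        cell_id=trace.cell_id,
        group_id=trace.group_id,
        baseline=baseline,
        delta_peak=delta,
        normalized_delta=delta / baseline,
        peak_time=float(t[post][i_peak]),
    )


def group_summary(responses: list[PeakResponse]) -> pd.DataFrame:
    """Per-group n, mean and SEM of the peak responses (both normalized and
    raw delta).  Groups with a single cell get SEM = NaN."""
    if not responses:
        raise ValueError("no responses to summarize")
    df = pd.DataFrame(
        {
            "group_id": [r.group_id for r in responses],
            "delta_peak": [r.delta_peak for r in responses],
            "normalized_delta": [r.normalized_delta for r in responses],
        }
    )
    rows = []
    for gid, grp in df.groupby("group_id", sort=True):
        n = len(grp)
        sem_norm = float(grp["normalized_delta"].sem()) if n > 1 else float("nan")
        sem_raw = float(grp["delta_peak"].sem()) if n > 1 else float("nan")
        rows.append(
            (gid, n, grp["normalized_delta"].mean(), sem_norm, grp["delta_peak"].mean(), sem_raw)
        )
    return pd.DataFrame(
        rows,
        columns=["group_id", "n", "mean_normalized_delta", "sem_normalized_delta",
                 "mean_delta_peak", "sem_delta_peak"],
    )


def compare_groups_2way(
    responses: list[PeakResponse],
    genotype_of: dict[str, str],
    treatment_of: dict[str, str],
    value: str = "normalized_delta",
):
    """Two-way ANOVA (genotype x treatment) with Tukey post-test on peak
    responses; the ANOVA machinery is shared with the interaction module."""
    df = pd.DataFrame(
        {
            "genotype": [genotype_of[r.group_id] for r in responses],
            "treatment": [treatment_of[r.group_id] for r in responses],
            "normalized_delta": [r.normalized_delta for r in responses],
            "delta_peak": [r.delta_peak for r in responses],
        }
    )
    return two_way_anova_tukey(df, value=value, factor_a="genotype", factor_b="treatment")


def paired_temperature_test(
    pairs: pd.DataFrame, method: str = "t"
) -> tuple[float, tuple[float, float], float]:
    """Paired comparison of resting Ca2+ measured in the same cells at 25 °C
    and then 37 °C.

    ``pairs`` needs columns ``ca_25`` and ``ca_37``.  Returns the mean
    per-cell delta (37 - 25), its 95% t confidence interval, and the paired
    test p (paired t by default, Wilcoxon signed-rank with ``method='wilcoxon'``).
    Zero-variance all-zero deltas give p = 1 with a warning.
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 paired cells")
    delta = (pairs["ca_37"] - pairs["ca_25"]).to_numpy(dtype=float)
    n = delta.size
    mean_d = float(delta.mean())
    sd = float(delta.std(ddof=1))
    if sd == 0:
        warnings.warn("all paired deltas identical; degenerate variance, p reported as 1")
        return mean_d, (mean_d, mean_d), 1.0
    sem = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    ci = (mean_d - tcrit * sem, mean_d + tcrit * sem)
    if method == "t":
        p = float(stats.ttest_rel(pairs["ca_37"], pairs["ca_25"]).pvalue)
    elif method == "wilcoxon":
        p = float(stats.wilcoxon(delta).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return mean_d, ci, p


def ddct_fold_change(
    table: pd.DataFrame,
    target: str,
    reference: str = "Tbp",
    control_condition: str = "neg-siRNA",
) -> pd.DataFrame:
    """Comparative ddCt relative expression of a target gene after knockdown.

    ``table`` has columns sample_id, condition, gene, ct (one row per
    technical replicate).  Per sample, dCt = mean Ct(target) - mean Ct(ref);
    ddCt subtracts the mean dCt of the control condition; fold = 2^(-ddCt),
    so the control-condition mean fold is 1 by construction.
    """
    for col in ("sample_id", "condition", "gene", "ct"):
        if col not in table.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    if not np.isfinite(table["ct"]).all():
        raise ValueError("Ct values must be finite")
    rows = []
    for (sample, cond), grp in table.groupby(["sample_id", "condition"], sort=True):
        tgt = grp.loc[grp["gene"] == target, "ct"]
        ref = grp.loc[grp["gene"] == reference, "ct"]
        if len(tgt) == 0 or len(ref) == 0:
            raise ValueError(f"sample {sample!r} lacks Ct replicates for target or reference")
        rows.append((sample, cond, float(tgt.mean()) - float(ref.mean())))
    dct = pd.DataFrame(rows, columns=["sample_id", "condition", "dct"])
    ctrl = dct.loc[dct["condition"] == control_condition, "dct"]
    if len(ctrl) == 0:
        raise ValueError(f"control condition {control_condition!r} absent from Ct table")
    dct["ddct"] = dct["dct"] - float(ctrl.mean())
    dct["fold_change"] = 2.0 ** (-dct["ddct"])
    return dct
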
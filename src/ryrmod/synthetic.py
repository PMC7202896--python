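"""Seeded synthetic-data generators for every analysis stage.

Each generator emulates the statistical structure its consuming stage
assumes — multinomial developmental-stage counts with a per-worm random-
escapee process, fingerprint libraries with planted similarity clusters and
planted hit enrichment, 2x2 movement-speed designs with a configurable
interaction, caffeine-evoked calcium transients, paired resting-Ca2+
measurements — so the whole pipeline is testable without any external data.
All randomness flows from one explicit integer seed per call; identical
seed + spec gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calcium import CalciumTrace
from .chem import ChemicalRecord
from .worm import WELL_COLUMNS

__all__ = [
    "LibrarySpec",
    "WormScreenSpec",
    "SpeedSpec",
    "TraceSpec",
    "gen_chemical_library",
    "gen_worm_screen",
    "gen_speed_dataset",
    "gen_calcium_traces",
    "gen_paired_resting",
    "per_worm_escape_prob_for_well_rate",
    "transient_shape",
]


def _check_fraction(name: str, x: float):
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {x}")


# ---------------------------------------------------------------- chemical


@dataclass(frozen=True)
class LibrarySpec:
    """Synthetic fingerprint library with planted structural clusters.

    Cluster members share a common bit core (each core bit present with
    probability ``within_cluster_bit_overlap``) on top of sparse background
    bits, so within-cluster Tanimoto exceeds between-cluster Tanimoto in
    expectation.  Hits are drawn per cluster at ``hit_rate_per_cluster`` and
    at ``hit_rate_background`` elsewhere.
    """

    n_compounds: int = 1000
    fp_bits: int = 256
    n_clusters: int = 2
    cluster_sizes: tuple[int, ...] = (10, 10)
    within_cluster_bit_overlap: float = 0.9
    background_bit_density: float = 0.02
    hit_rate_background: float = 0.01
    hit_rate_per_cluster: dict[int, float] = field(default_factory=dict)
    core_bits: int = 48
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 0 or self.fp_bits < 1:
            raise ValueError("n_compounds must be >= 0 and fp_bits >= 1")
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValueError("cluster_sizes length must equal n_clusters")
        if sum(self.cluster_sizes) > self.n_compounds:
            raise ValueError("sum of cluster sizes exceeds n_compounds")
        _check_fraction("within_cluster_bit_overlap", self.within_cluster_bit_overlap)
        _check_fraction("background_bit_density", self.background_bit_density)
        _check_fraction("hit_rate_background", self.hit_rate_background)
        for c, r in self.hit_rate_per_cluster.items():
            _check_fraction(f"hit_rate_per_cluster[{c}]", r)


def gen_chemical_library(spec: LibrarySpec) -> list[ChemicalRecord]:
    """Generate a compound library per :class:`LibrarySpec`.

    Compound ids are ``c0000``...; planted cluster members carry a class
    label ``cluster<j>`` so recovery can be scored against the truth.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ChemicalRecord] = []
    noise_free = spec.within_cluster_bit_overlap == 1.0 and spec.background_bit_density == 0.0
    idx = 0
    for j, size in enumerate(spec.cluster_sizes):
        core = rng.choice(spec.fp_bits, size=min(spec.core_bits, spec.fp_bits), replace=False)
        hit_rate = spec.hit_rate_per_cluster.get(j, spec.hit_rate_background)
        for _ in range(size):
            fp = np.zeros(spec.fp_bits, dtype=np.uint8)
            keep = rng.random(core.size) < spec.within_cluster_bit_overlap
            fp[core[keep]] = 1
            if not noise_free:
                fp |= (rng.random(spec.fp_bits) < spec.background_bit_density).astype(np.uint8)
            records.append(
                ChemicalRecord(
                    compound_id=f"c{idx:04d}",
                    fingerprint=fp,
                    class_labels=frozenset({f"cluster{j}"}),
                    is_hit=bool(rng.random() < hit_rate),
                )
            )
            idx += 1
    n_bg = spec.n_compounds - sum(spec.cluster_sizes)
    for _ in range(n_bg):
        fp = (rng.random(spec.fp_bits) < spec.background_bit_density).astype(np.uint8)
        records.append(
            ChemicalRecord(
                compound_id=f"c{idx:04d}",
                fingerprint=fp,
                class_labels=frozenset({"background"}),
                is_hit=bool(rng.random() < spec.hit_rate_background),
            )
        )
        idx += 1
    return records


# ---------------------------------------------------------------- worm screen


@dataclass(frozen=True)
class WormScreenSpec:
    """Synthetic developmental-arrest screen.

    Per well, the worm count is uniform over ``worms_per_well_range``
    (the real screen plated ~20, realistically 15-25).  Each worm escapes
    arrest (reaches L4/adult) independently with ``per_worm_escape_prob``
    unless its condition's ``rescue_effect`` overrides the stage distribution
    with explicit (L1-L3, L4, adult) probabilities.  Control wells use the
    escapee process only.
    """

    n_conditions: int = 100
    wells_per_condition: int = 2  # the screen ran duplicate wells
    worms_per_well_range: tuple[int, int] = (15, 25)
    per_worm_escape_prob: float = 0.0042
    rescue_effect: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    n_control_wells: int = 100
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.worms_per_well_range
        if lo < 1 or hi < lo:
            raise ValueError("worms_per_well_range must be a nonempty range with lower >= 1")
        _check_fraction("per_worm_escape_prob", self.per_worm_escape_prob)
        for cond, dist in self.rescue_effect.items():
            if len(dist) != 3 or abs(sum(dist) - 1.0) > 1e-9 or min(dist) < 0:
                raise ValueError(f"rescue_effect[{cond!r}] must be a 3-way distribution summing to 1")


def per_worm_escape_prob_for_well_rate(well_rate: float, n_worms: int = 20) -> float:
    """Per-worm escape probability p such that P(>=1 escapee in an n-worm
    well) equals ``well_rate``: p = 1 - (1 - rate)^(1/n)."""
    _check_fraction("well_rate", well_rate)
    return 1.0 - (1.0 - well_rate) ** (1.0 / n_worms)


def gen_worm_screen(spec: WormScreenSpec) -> pd.DataFrame:
    """Generate a well table (see ``worm.WELL_COLUMNS``) per :class:`WormScreenSpec`."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.worms_per_well_range
    rows = []

    def draw_well(cond: str, rep: int, is_control: bool):
        n = int(rng.integers(lo, hi + 1))
        dist = spec.rescue_effect.get(cond)
        if dist is not None and not is_control:
            counts = rng.multinomial(n, dist)
            l13, l4, adult = (int(x) for x in counts)
        else:
            esc = int(rng.binomial(n, spec.per_worm_escape_prob))
            # random escapees reach L4 or adult; the analysis only uses their sum
            adult = int(rng.binomial(esc, 0.5))
            l4 = esc - adult
            l13 = n - esc
        rows.append((cond, rep, l13, l4, adult, is_control))

    for i in range(spec.n_conditions):
        cond = f"chem{i:04d}"
        for rep in range(spec.wells_per_condition):
            draw_well(cond, rep, False)
    for w in range(spec.n_control_wells):
        draw_well("DMSO-control", w, True)
    return pd.DataFrame(rows, columns=WELL_COLUMNS)


# ---------------------------------------------------------------- speed


@dataclass(frozen=True)
class SpeedSpec:
    """2x2 movement-speed design with a configurable interaction.

    Group means on the normalized scale are 1 (WT/vehicle), ``genotype_effect``
    g (mutant/vehicle), ``chemical_effect`` c (WT/chemical), and
    g+c-1 / g*c / g*c+epsilon for the double group under the additive /
    multiplicative / custom model, before Gaussian noise on the raw scale
    (speeds floored at 0).
    """

    n_per_group: int = 10
    wt_mean: float = 1.0  # mm/s
    noise_sd: float = 0.1  # mm/s
    genotype_effect: float = 0.5
    chemical_effect: float = 0.8
    interaction_model: str = "multiplicative"
    epsilon: float = 0.0  # used by the custom model: double mean = g*c + epsilon
    n_assays: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.wt_mean <= 0:
            raise ValueError("wt_mean must be > 0")
        if self.noise_sd < 0 or self.genotype_effect < 0 or self.chemical_effect < 0:
            raise ValueError("noise_sd and effect multipliers must be >= 0")
        if self.interaction_model not in ("additive", "multiplicative", "custom"):
            raise ValueError(f"unknown interaction_model {self.interaction_model!r}")


def gen_speed_dataset(spec: SpeedSpec, chemical: str = "chem") -> pd.DataFrame:
    """Generate a speed table (larva_id, assay_id, genotype, treatment,
    speed_mm_s) per :class:`SpeedSpec`."""
    rng = np.random.default_rng(spec.seed)
    g, c = spec.genotype_effect, spec.chemical_effect
    if spec.interaction_model == "additive":
        double = g + c - 1.0
    elif spec.interaction_model == "multiplicative":
        double = g * c
    else:
        double = g * c + spec.epsilon
    group_means = {
        ("WT", "vehicle"): 1.0,
        ("mutant", "vehicle"): g,
        ("WT", chemical): c,
        ("mutant", chemical): double,
    }
    rows = []
    i = 0
    for assay in range(spec.n_assays):
        for (geno, treat), m in group_means.items():
            raw = m * spec.wt_mean + rng.normal(0.0, spec.noise_sd, spec.n_per_group)
            raw = np.maximum(raw, 0.0)
            for s in raw:
                rows.append((f"larva{i:05d}", f"assay{assay}", geno, treat, float(s)))
                i += 1
    return pd.DataFrame(
        rows, columns=["larva_id", "assay_id", "genotype", "treatment", "speed_mm_s"]
    )


# ---------------------------------------------------------------- calcium


@dataclass(frozen=True)
class TraceSpec:
    """Caffeine-evoked calcium transient: flat baseline plus a double-
    exponential transient of amplitude ``peak_delta`` starting at
    ``caffeine_time``, with Gaussian noise."""

    duration: float = 60.0  # s
    sample_rate: float = 10.0  # Hz
    caffeine_time: float = 15.0  # s
    baseline_ratio: float = 1.0
    peak_delta: float = 1.0
    rise_tau: float = 1.0  # s
    decay_tau: float = 8.0  # s
    noise_sd: float = 0.0
    n_cells_per_group: int = 10
    group_id: str = "group"
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if not 0 < self.caffeine_time < self.duration:
            raise ValueError("caffeine_time must fall inside the recording")
        if self.rise_tau <= 0 or self.decay_tau <= 0 or self.rise_tau == self.decay_tau:
            raise ValueError("taus must be positive and distinct")
        if self.baseline_ratio <= 0:
            raise ValueError("baseline_ratio must be > 0")


def transient_shape(t: np.ndarray, t0: float, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak double-exponential transient starting at t0.

    f(t) = exp(-(t-t0)/decay) - exp(-(t-t0)/rise) for t >= t0, scaled so the
    continuous-time maximum is exactly 1 (peak at
    t0 + rise*decay/(decay-rise) * ln(decay/rise)).
    """
    dt = np.maximum(t - t0, 0.0)
    f = np.where(t >= t0, np.exp(-dt / decay_tau) - np.exp(-dt / rise_tau), 0.0)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return f / peak


def gen_calcium_traces(spec: TraceSpec) -> list[CalciumTrace]:
    """Generate ``n_cells_per_group`` traces per :class:`TraceSpec`."""
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration * spec.sample_rate)) + 1
    t = np.arange(n_samples) / spec.sample_rate
    shape = transient_shape(t, spec.caffeine_time, spec.rise_tau, spec.decay_tau)
    traces = []
    for i in range(spec.n_cells_per_group):
        ratio = spec.baseline_ratio + spec.peak_delta * shape
        if spec.noise_sd > 0:
            ratio = ratio + rng.normal(0.0, spec.noise_sd, n_samples)
        ratio = np.maximum(ratio, 1e-6)  # ratios are physically positive
        traces.append(
            CalciumTrace(
                cell_id=f"{spec.group_id}-cell{i:03d}",
                group_id=spec.group_id,
                time=t,
                ratio=ratio,
                caffeine_time=spec.caffeine_time,
            )
        )
    return traces


def gen_paired_resting(
    n_cells: int, mean_25: float, delta_37: float, sd: float, seed: int = 0,
    group_id: str = "group",
) -> pd.DataFrame:
    """Paired resting-Ca2+ table: per cell, a 25 °C value and a correlated
    37 °C value shifted by ``delta_37`` plus noise."""
    if n_cells < 2:
        raise ValueError("need n_cells >= 2")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    ca25 = mean_25 + rng.normal(0.0, sd, n_cells)
    ca37 = ca25 + delta_37 + rng.normal(0.0, sd, n_cells)
    return pd.DataFrame(
        {
            "cell_id": [f"{group_id}-cell{i:03d}" for i in range(n_cells)],
            "group_id": group_id,
            "ca_25": ca25,
            "ca_37": ca37,
        }
    )
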
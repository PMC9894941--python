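"""Seeded generators for every input the analysis pipeline consumes.

The LH generator emulates serial tail-tip sampling — 5-min cadence over a
2-h session — with a minimal secretion model: pulse times follow a
stationary gamma renewal process (episodic, tunable regularity), each
pulse delivers an instantaneous log-normal bolus on top of a basal level,
and concentrations decay by first-order clearance with a fixed half-life.
Measurement noise is multiplicative Gaussian, scaled by a coefficient of
variation, and reported values are floored (optionally at the assay
sensitivity, 0.320 ng/mL).

None of the distributional choices or preset numbers are taken from data;
only the qualitative group ordering is fixed: letrozole (LET) presets
pulse faster, higher and on a higher basal than control (CON), and
time-restricted-feeding (LET_TRF) presets equal CON.

Estrous logs come from a first-order Markov chain over the four stages
with an optional "arrest bias" that inflates diestrus self-transition;
Ct tables come from an additive model on the cycle scale with a stable
reference gene.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .detect import LHProfile
from .estrous import STAGES, EstrousLog
from .qpcr import REFERENCE_GENES, CtRecord

__all__ = [
    "SimParams",
    "GroupPreset",
    "SimulatedProfile",
    "EstrousSimParams",
    "CtSimParams",
    "animal_seed",
    "simulate_pulse_times",
    "render_concentration",
    "noiseless_concentration",
    "simulate_profile",
    "simulate_cohort",
    "default_presets",
    "simulate_estrous_log",
    "simulate_ct_table",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one pulsatile LH profile.

    mean_ipi is the mean interpulse interval (min); ipi_shape the gamma
    shape of the interval distribution (higher = more regular); bolus_mu /
    bolus_sigma the log-scale parameters of the log-normal bolus height
    (median exp(bolus_mu) ng/mL); half_life the first-order clearance
    half-life (min); noise_cv the multiplicative measurement CV; floor the
    smallest reportable concentration. burn_in extends simulation before
    t=0 so the session starts in secretory steady state.
    """

    basal: float = 0.3
    mean_ipi: float = 60.0
    ipi_shape: float = 8.0
    bolus_mu: float = 0.0
    bolus_sigma: float = 0.25
    half_life: float = 15.0
    noise_cv: float = 0.05
    sample_interval: float = 5.0
    duration: float = 120.0
    burn_in: float = 60.0
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.basal < 0 or self.floor < 0:
            raise ValueError("basal and floor must be >= 0")
        if self.mean_ipi <= 0 or self.ipi_shape <= 0:
            raise ValueError("mean_ipi and ipi_shape must be > 0")
        if self.half_life <= 0:
            raise ValueError("half_life must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.sample_interval <= 0 or self.duration <= 0:
            raise ValueError("sample_interval and duration must be > 0")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")

    @property
    def sample_times(self) -> np.ndarray:
        """Sampling grid: floor(duration/interval)+1 points from t=0."""
        n = int(np.floor(self.duration / self.sample_interval)) + 1
        return np.arange(n) * self.sample_interval


@dataclass(frozen=True)
class GroupPreset:
    """A named study arm (group x diet) with its generative parameters."""

    name: str
    diet: str
    sim_params: SimParams

    @property
    def label(self) -> str:
        return f"{self.name}:{self.diet}"


@dataclass(frozen=True)
class SimulatedProfile:
    """A sampled profile plus its generative ground truth."""

    profile: LHProfile
    true_pulse_times: np.ndarray
    true_boluses: np.ndarray


def animal_seed(master_seed: int, label: str, index: int) -> np.random.SeedSequence:
    """Deterministic per-animal seed stream.

    Spawned as SeedSequence([master_seed, crc32(label), index]) so cohorts
    are reproducible and streams are independent across animals and
    platforms.
    """
    return np.random.SeedSequence([master_seed, zlib.crc32(label.encode()), index])


def _rng(seed: int | np.random.SeedSequence | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_pulse_times(
    params: SimParams, seed: int | np.random.SeedSequence | np.random.Generator
) -> np.ndarray:
    """Pulse times of a stationary gamma renewal process on [-burn_in, duration].

    Interpulse intervals are gamma(shape=ipi_shape, mean=mean_ipi). The
    process is started in equilibrium: the wait from -burn_in to the first
    pulse is a forward recurrence time, drawn as U * L with L length-biased
    (gamma with shape+1) and U uniform. In equilibrium the expected number
    of pulses in any window of length T is exactly T / mean_ipi.
    """
    rng = _rng(seed)
    scale = params.mean_ipi / params.ipi_shape
    t = -params.burn_in + rng.uniform() * rng.gamma(params.ipi_shape + 1.0, scale)
    times = []
    while t <= params.duration:
        times.append(t)
        t += rng.gamma(params.ipi_shape, scale)
    return np.asarray(times, dtype=float)


def noiseless_concentration(
    t: np.ndarray | float,
    pulse_times: np.ndarray,
    boluses: np.ndarray,
    params: SimParams,
) -> np.ndarray:
    """Dense noise-free signal C(t) = basal + sum_i b_i 2^-(t - t_i)/half_life.

    Each bolus is instantaneous and decays by first-order clearance from
    its pulse time onward.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    pulse_times = np.asarray(pulse_times, dtype=float)
    boluses = np.asarray(boluses, dtype=float)
    dt = t[:, None] - pulse_times[None, :]
    decay = np.where(dt >= 0, np.exp(-LN2 * np.maximum(dt, 0.0) / params.half_life), 0.0)
    return params.basal + decay @ boluses


def render_concentration(
    pulse_times: np.ndarray,
    boluses: np.ndarray,
    params: SimParams,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    *,
    animal_id: str = "sim",
    group: str = "",
    diet: str = "",
) -> LHProfile:
    """Sample the secretion signal on the 5-min grid with assay noise.

    Multiplicative noise (1 + noise_cv * z), z standard normal, is applied
    per sample; results are clipped from below at the reporting floor.
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    boluses = np.asarray(boluses, dtype=float)
    if len(pulse_times) != len(boluses):
        raise ValueError("pulse_times and boluses must have the same length")
    if np.any(np.diff(pulse_times) < 0):
        raise ValueError("pulse_times must be ascending")
    if np.any(boluses < 0):
        raise ValueError("boluses must be >= 0")
    t = params.sample_times
    values = noiseless_concentration(t, pulse_times, boluses, params)
    if params.noise_cv > 0:
        z = _rng(params.seed if seed is None else seed).standard_normal(len(t))
        values = values * (1.0 + params.noise_cv * z)
    values = np.maximum(values, params.floor)
    return LHProfile(animal_id=animal_id, times=t, values=values, group=group, diet=diet)


def simulate_profile(
    params: SimParams,
    seed: int | np.random.SeedSequence | None = None,
    *,
    animal_id: str = "sim",
    group: str = "",
    diet: str = "",
) -> SimulatedProfile:
    """One animal: draw pulse times and boluses, render the sampled profile."""
    rng = _rng(params.seed if seed is None else seed)
    pulse_times = simulate_pulse_times(params, rng)
    boluses = rng.lognormal(params.bolus_mu, params.bolus_sigma, size=len(pulse_times))
    profile = render_concentration(
        pulse_times, boluses, params, rng, animal_id=animal_id, group=group, diet=diet
    )
    return SimulatedProfile(
        profile=profile, true_pulse_times=pulse_times, true_boluses=boluses
    )


def default_presets(diet: str = "CHOW") -> list[GroupPreset]:
    """Study-arm presets encoding the qualitative group ordering.

    LET pulses three times as often (mean_ipi 20 vs 60 min), with twice
    the bolus median (2.0 vs 1.0 ng/mL) and a higher basal (0.8 vs 0.3
    ng/mL) than CON; LET_TRF equals CON. The numbers are implementer
    choices — the study reports no concentrations in text — only the
    ordering is constrained.
    """
    con = SimParams(basal=0.3, mean_ipi=60.0, bolus_mu=0.0)
    let = SimParams(basal=0.8, mean_ipi=20.0, bolus_mu=float(np.log(2.0)))
    presets = [
        GroupPreset("CON", diet, con),
        GroupPreset("LET", diet, let),
        GroupPreset("LET_TRF", diet, con),
    ]
    _validate_preset_ordering(presets)
    return presets


def _validate_preset_ordering(presets: Sequence[GroupPreset]) -> None:
    by_label = {p.label: p for p in presets}
    for p in presets:
        if p.name != "LET":
            continue
        con = by_label.get(f"CON:{p.diet}")
        if con is None:
            continue
        c, l = con.sim_params, p.sim_params
        ok = (
            l.mean_ipi < c.mean_ipi
            and np.exp(l.bolus_mu) > np.exp(c.bolus_mu)
            and l.basal > c.basal
        )
        if not ok:
            raise ValueError(
                f"LET preset ({p.diet}) must have smaller mean_ipi and larger "
                "bolus median and basal than CON"
            )


def simulate_cohort(
    presets: Sequence[GroupPreset],
    n_per_group: int,
    seed: int,
) -> list[SimulatedProfile]:
    """n_per_group animals per preset, each on an independent sub-stream.

    Per-animal streams are derived from the master seed, the preset label
    and the animal index (see animal_seed), so the cohort is reproducible
    and insensitive to preset order.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    labels = [p.label for p in presets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate preset names")
    out = []
    for preset in presets:
        for i in range(n_per_group):
            out.append(
                simulate_profile(
                    preset.sim_params,
                    animal_seed(seed, preset.label, i),
                    animal_id=f"{preset.name}-{preset.diet}-{i:03d}",
                    group=preset.name,
                    diet=preset.diet,
                )
            )
    return out


# ---------------------------------------------------------------------------
# estrous-stage logs


def _default_transition() -> np.ndarray:
    # rows/cols ordered P, E, M, D: mostly advance through the cycle
    return np.array(
        [
            [0.15, 0.75, 0.05, 0.05],
            [0.05, 0.15, 0.75, 0.05],
            [0.05, 0.05, 0.15, 0.75],
            [0.70, 0.05, 0.05, 0.20],
        ]
    )


@dataclass(frozen=True)
class EstrousSimParams:
    """Markov-chain generator for daily stage logs.

    arrest_bias moves probability mass onto the diestrus self-transition
    (the remaining row entries are rescaled), emulating cycle arrest.
    """

    days: int = 10
    stage_transition: np.ndarray = field(default_factory=_default_transition)
    arrest_bias: float = 0.0
    start_stage: str = "D"
    seed: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.stage_transition, dtype=float)
        object.__setattr__(self, "stage_transition", m)
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if m.shape != (4, 4) or np.any(m < 0):
            raise ValueError("stage_transition must be a nonnegative 4x4 matrix")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("stage_transition rows must sum to 1")
        if not 0 <= self.arrest_bias <= 1:
            raise ValueError("arrest_bias must be in [0, 1]")
        if self.start_stage not in STAGES:
            raise ValueError(f"start_stage must be one of {STAGES}")

    def effective_transition(self) -> np.ndarray:
        """Transition matrix after applying arrest_bias to the D row."""
        m = self.stage_transition.copy()
        d = STAGES.index("D")
        target = min(1.0, m[d, d] + self.arrest_bias)
        rest = 1.0 - m[d, d]
        if rest > 0:
            m[d] *= (1.0 - target) / rest
        else:
            m[d] = 0.0
        m[d, d] = target
        return m


def simulate_estrous_log(
    params: EstrousSimParams,
    *,
    animal_id: str = "sim",
    group: str = "",
    diet: str = "",
    seed: int | np.random.SeedSequence | None = None,
) -> EstrousLog:
    """A daily stage sequence of length params.days from the Markov chain."""
    rng = _rng(params.seed if seed is None else seed)
    m = params.effective_transition()
    state = STAGES.index(params.start_stage)
    stages = []
    for _ in range(params.days):
        stages.append(STAGES[state])
        state = rng.choice(4, p=m[state])
    return EstrousLog(animal_id=animal_id, stages=tuple(stages), group=group, diet=diet)


# ---------------------------------------------------------------------------
# qPCR Ct tables


@dataclass(frozen=True)
class CtSimParams:
    """Additive Ct model with group-level log2 expression shifts.

    effects maps gene -> {group: log2 fold effect}; a +1 effect lowers the
    gene's Ct by one cycle in that group (doubling expression). The
    tissue's reference gene must be listed and must have zero effect in
    every group (stable-reference assumption). Optional per-gene baselines
    shift Ct regardless of group.
    """

    tissue: str = "ovary"
    effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"L19": {}, "Cyp17": {"LET": 1.0}}
    )
    gene_baseline: Mapping[str, float] = field(default_factory=dict)
    groups: tuple[str, ...] = ("CON", "LET", "LET_TRF")
    diet: str = "CHOW"
    ct_base: float = 22.0
    ct_noise_sd: float = 0.15
    n_per_group: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue not in REFERENCE_GENES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        ref = REFERENCE_GENES[self.tissue]
        if ref not in self.effects:
            raise ValueError(f"reference gene {ref!r} missing from effects")
        if any(v != 0 for v in self.effects[ref].values()):
            raise ValueError(f"reference gene {ref!r} must have zero effects")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.ct_base <= 0:
            raise ValueError("ct_base must be > 0")


def simulate_ct_table(params: CtSimParams) -> list[CtRecord]:
    """Ct = ct_base - (gene baseline + group log2 effect) + noise, seeded."""
    rng = _rng(params.seed)
    records = []
    for group in params.groups:
        for i in range(params.n_per_group):
            sample_id = f"{group}-{params.diet}-{i:03d}"
            for gene in params.effects:
                effect = params.effects[gene].get(group, 0.0)
                base = params.gene_baseline.get(gene, 0.0)
                ct = params.ct_base - (base + effect)
                if params.ct_noise_sd > 0:
                    ct += params.ct_noise_sd * rng.standard_normal()
                records.append(
                    CtRecord(
                        sample_id=sample_id,
                        group=group,
                        diet=params.diet,
                        tissue=params.tissue,
                        gene=gene,
                        ct=float(ct),
                    )
                )
    return records
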
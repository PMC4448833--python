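"""Synthetic sighting-table generator with planted social structure.

The generator emulates a boat-survey study of a resident dolphin
population: ~150 individuals observed over ~124 sampling days yielding
~300 group sightings, with activity-dependent group sizes (socializing
groups largest, foraging smallest) and a latent community structure whose
strength depends on activity.  Groups are assembled generatively: a focal
individual seeds each sighting and companions are drawn by weighted
sampling, where belonging to the focal's planted community multiplies a
candidate's weight by ``within_community_preference[activity]`` (w_in = 1
means random association, the null of the permutation test).  Foraging
defaults to w_in = 1, encoding the absence of preferential foraging
associations.

Individuals are exchangeable by default (the focal is uniform and
companions are weighted only by community preference), so at w_in = 1 the
group-filling law is exactly the hypergeometric null of the data-stream
permutation test.  Optionally, gamma-distributed individual "sightability"
propensities produce overdispersed, right-tailed per-individual sighting
counts — note that such heterogeneity is a genuine departure from the
permutation null and inflates its rejection rate even without planted
preference.  Detection is imperfect: members are identified independently, failures
are counted in ``n_unidentified``, and a group with no identified member
is never recorded at all.  Because that truncation inflates the observed
identified proportion, ``detection_prob`` is defined on the observable
scale — the expected per-group proportion identified — and the internal
per-member identification rate is calibrated to hit it.  Dependent calves
accompany their mothers and are flagged in the registry so the calf
filter can remove them.

Timestamps are spaced > 60 minutes apart within a day, so the resight
filter retains all records unless a test constructs collisions on purpose.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .communities import Partition
from .sightings import (
    Activity,
    IndividualRegistry,
    SightingRecord,
    SightingTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_population",
    "simulate_sightings",
    "simulate_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic survey.

    Defaults mirror the Cedar Key study conditions: 150 adults, 124
    sampling days at ~2.44 sightings/day (~300 sightings), activity mix
    proportional to the observed 38/77/153 socialize/travel/forage split,
    per-activity mean group sizes 8.4/4.1/3.0, and a detection probability
    of 0.8.
    """

    n_individuals: int = 150
    n_calves: int = 10
    n_communities: int = 8
    n_days: int = 124
    mean_sightings_per_day: float = 2.44
    activity_mix: Mapping[str, float] = field(
        default_factory=lambda: {"socialize": 0.14, "travel": 0.29, "forage": 0.57}
    )
    group_size_mean: Mapping[str, float] = field(
        default_factory=lambda: {"socialize": 8.4, "travel": 4.1, "forage": 3.0}
    )
    # Odds multipliers for drawing a companion from the focal's community.
    # "High" values make socializing and travelling groups essentially
    # community-pure (at 1000, < 1% of companion draws are outsiders);
    # forage at 1 encodes no preferential foraging associations.
    within_community_preference: Mapping[str, float] = field(
        default_factory=lambda: {"socialize": 1000.0, "travel": 1000.0, "forage": 1.0}
    )
    group_size_dispersion: "float | None" = None  # None = zero-truncated Poisson
    detection_prob: float = 0.8
    unidentified_rate: float = 0.0  # extra unassociated unidentified animals
    # None = homogeneous sighting propensity (exchangeable individuals);
    # a float is the gamma shape of heterogeneous propensities (smaller =
    # more skewed counts, but a departure from the permutation null).
    sightability_shape: "float | None" = None
    start_date: dt.date = dt.date(2008, 7, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.activity_mix.values()) - 1.0) > 1e-9:
            raise ValueError("activity_mix must sum to 1")
        if any(m < 1 for m in self.group_size_mean.values()):
            raise ValueError("group-size means must be >= 1")
        if not (0 < self.detection_prob <= 1):
            raise ValueError("detection_prob must be in (0, 1]")
        if self.n_communities > self.n_individuals:
            raise ValueError("more communities than individuals")
        for act in self.activity_mix:
            if act not in self.group_size_mean:
                raise ValueError(f"no group_size_mean for activity {act!r}")
            Activity(act)  # must be a valid activity label


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: the community partition plus nuisance
    structure (calf mothers, sightability weights) needed to generate and
    to score recovery."""

    planted_partition: Partition
    config: SimulationConfig
    calf_mothers: Mapping[str, str]
    sightability: Mapping[str, float]

    def labels(self) -> dict[str, int]:
        return self.planted_partition.labels()

    def as_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["start_date"] = self.config.start_date.isoformat()
        cfg["activity_mix"] = dict(self.config.activity_mix)
        cfg["group_size_mean"] = dict(self.config.group_size_mean)
        cfg["within_community_preference"] = dict(self.config.within_community_preference)
        return {
            "planted_partition": {ind: lab for ind, lab in sorted(self.labels().items())},
            "calf_mothers": dict(self.calf_mothers),
            "config": cfg,
        }


def _truncated_count_sampler(mean: float, dispersion: "float | None"):
    """Return a draw(rng) -> int >= 1 with the requested mean.

    Zero-truncated Poisson by default; zero-truncated negative binomial
    (size = dispersion) when a dispersion is given.  The underlying
    parameter is calibrated so the *truncated* mean equals ``mean``.
    """
    if mean <= 1.0 + 1e-12:
        return lambda rng: 1
    if dispersion is None:
        lam = brentq(lambda l: l / (1.0 - np.exp(-l)) - mean, 1e-9, mean * 2 + 10)

        def draw(rng: np.random.Generator) -> int:
            while True:
                k = int(rng.poisson(lam))
                if k > 0:
                    return k

        return draw
    r = float(dispersion)

    def trunc_mean(mu: float) -> float:
        p0 = (r / (r + mu)) ** r
        return mu / (1.0 - p0)

    mu = brentq(lambda m: trunc_mean(m) - mean, 1e-9, mean * 2 + 10)
    p = r / (r + mu)

    def draw_nb(rng: np.random.Generator) -> int:
        while True:
            k = int(rng.negative_binomial(r, p))
            if k > 0:
                return k

    return draw_nb


def _size_pmf(mean: float, dispersion: "float | None", cap: int = 300) -> np.ndarray:
    """Zero-truncated pmf over sizes 1..cap for one activity."""
    from scipy import stats as sps

    s = np.arange(1, cap + 1)
    if mean <= 1.0 + 1e-12:
        pmf = np.zeros(cap)
        pmf[0] = 1.0
        return pmf
    if dispersion is None:
        lam = brentq(lambda l: l / (1.0 - np.exp(-l)) - mean, 1e-9, mean * 2 + 10)
        pmf = sps.poisson.pmf(s, lam)
    else:
        r = float(dispersion)
        mu = brentq(
            lambda m: m / (1.0 - (r / (r + m)) ** r) - mean, 1e-9, mean * 2 + 10
        )
        pmf = sps.nbinom.pmf(s, r, r / (r + mu))
    return pmf / pmf.sum()


def _member_identification_rate(config: SimulationConfig) -> float:
    """Per-member Bernoulli rate whose truncated per-group identified
    proportion equals ``detection_prob``.

    For a group of size s with i.i.d. detection at rate p, the recorded
    (>= 1 identified) groups have E[identified fraction] = p / (1-(1-p)^s);
    the rate solves the size-mixture average of that equal to the target.
    Calves are ignored in the calibration (second-order effect).
    """
    target = config.detection_prob
    if target >= 1.0:
        return 1.0
    sizes = np.arange(1, 301)
    weights = np.zeros_like(sizes, dtype=float)
    for act, w_act in config.activity_mix.items():
        weights += w_act * _size_pmf(
            config.group_size_mean[act], config.group_size_dispersion
        )

    def mean_prop(p: float) -> float:
        return float(np.sum(weights * p / (1.0 - (1.0 - p) ** sizes)))

    floor = mean_prop(1e-9)  # limit p->0 is E[1/s]
    if target <= floor:
        raise ValueError(
            f"detection_prob {target} unreachable: recorded groups always have "
            f"identified proportion >= {floor:.3f} under this size mixture"
        )
    return brentq(lambda p: mean_prop(p) - target, 1e-9, 1.0)


def simulate_population(
    config: SimulationConfig,
) -> tuple[IndividualRegistry, GroundTruth]:
    """Create the individual registry and the planted ground truth.

    Adults are assigned to communities uniformly at random; each calf is
    attached to a distinct adult "mother" and is co-sighted with her.
    Deterministic for a fixed config (seed stream [seed, 0]).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    adults = [f"D{i:03d}" for i in range(1, config.n_individuals + 1)]
    calves = [f"C{i:02d}" for i in range(1, config.n_calves + 1)]
    community = rng.integers(0, config.n_communities, size=len(adults))
    blocks: dict[int, set[str]] = {}
    for ind, c in zip(adults, community):
        blocks.setdefault(int(c), set()).add(ind)
    partition = Partition(
        blocks=tuple(frozenset(b) for _, b in sorted(blocks.items())),
        network_activity="all",
    )
    mothers = rng.choice(adults, size=len(calves), replace=False)
    if config.sightability_shape is None:
        sightability = np.ones(len(adults))
    else:
        sightability = rng.gamma(
            config.sightability_shape,
            1.0 / config.sightability_shape,
            size=len(adults),
        )
    registry = IndividualRegistry(
        {**{a: False for a in adults}, **{c: True for c in calves}}
    )
    truth = GroundTruth(
        planted_partition=partition,
        config=config,
        calf_mothers={c: str(m) for c, m in zip(calves, mothers)},
        sightability={a: float(s) for a, s in zip(adults, sightability)},
    )
    return registry, truth


def simulate_sightings(
    registry: IndividualRegistry, truth: GroundTruth
) -> SightingTable:
    """Generate the sighting table implied by the planted structure.

    Deterministic for a fixed config (seed stream [seed, 1]).
    """
    config = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    adults = sorted(a for a, c in registry.entries.items() if not c)
    labels = truth.labels()
    comm = np.array([labels[a] for a in adults])
    sightability = np.array([truth.sightability[a] for a in adults])
    mothers_of: dict[str, list[str]] = {}
    for calf, mother in truth.calf_mothers.items():
        mothers_of.setdefault(mother, []).append(calf)

    size_samplers = {
        act: _truncated_count_sampler(m, config.group_size_dispersion)
        for act, m in config.group_size_mean.items()
    }
    activities = sorted(config.activity_mix)
    mix = np.array([config.activity_mix[a] for a in activities])
    mix = mix / mix.sum()
    focal_p = sightability / sightability.sum()
    p_identify = _member_identification_rate(config)

    records: list[SightingRecord] = []
    sighting_no = 0
    for day in range(config.n_days):
        date = config.start_date + dt.timedelta(days=day)
        n_today = int(rng.poisson(config.mean_sightings_per_day))
        minutes = 480 + int(rng.integers(0, 30))
        for _ in range(n_today):
            if minutes > 1380:  # survey day over
                break
            activity = activities[int(rng.choice(len(activities), p=mix))]
            size = size_samplers[activity](rng)
            if size > len(adults):
                logger.warning(
                    "target group size %d exceeds population %d; truncating",
                    size, len(adults),
                )
                size = len(adults)
            focal_idx = int(rng.choice(len(adults), p=focal_p))
            group_idx = [focal_idx]
            if size > 1:
                w_in = config.within_community_preference.get(activity, 1.0)
                weights = sightability * np.where(comm == comm[focal_idx], w_in, 1.0)
                weights[focal_idx] = 0.0
                companions = rng.choice(
                    len(adults), size=size - 1, replace=False, p=weights / weights.sum()
                )
                group_idx.extend(int(i) for i in companions)
            group = [adults[i] for i in group_idx]
            calves_present = [c for m in group for c in mothers_of.get(m, [])]
            identified = []
            n_unid = 0
            for member in group + calves_present:
                if rng.random() < p_identify:
                    identified.append(member)
                else:
                    n_unid += 1
            if config.unidentified_rate > 0:
                n_unid += int(rng.poisson(config.unidentified_rate))
            minutes_this = minutes
            minutes += 61 + int(rng.integers(0, 30))
            if not identified:
                logger.debug("group with no identified member not recorded")
                continue
            sighting_no += 1
            records.append(
                SightingRecord(
                    sighting_id=f"S{sighting_no:05d}",
                    date=date,
                    time=dt.time(minutes_this // 60, minutes_this % 60),
                    activity=Activity(activity),
                    members=frozenset(identified),
                    n_unidentified=n_unid,
                )
            )
    return SightingTable(tuple(records))


def simulate_study(
    config: SimulationConfig,
) -> tuple[IndividualRegistry, GroundTruth, SightingTable]:
    """Population + sightings in one call."""
    registry, truth = simulate_population(config)
    table = simulate_sightings(registry, truth)
    return registry, truth, table
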
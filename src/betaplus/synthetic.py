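"""Synthetic inputs with the statistical structure each stage assumes.

No raw clonogenic measurements or event streams ship with this package;
these generators produce test and demonstration inputs that mirror the
study designs the pipeline targets: an X-ray reference arm on a
0-7.5 Gy grid in 2.5 Gy steps, a beta-plus arm on a 10-30 Gy grid, and
deposition-event streams over the linear DNA geometry.  All generators
are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .geometry import DNAGeometry, SourceVolume, default_source, sample_source_points
from .survival import ColonyRecord, LQFit, dose_at_sf
from .damage import ScoringRules, StrandBreak, score_dsbs

__all__ = [
    "SurvivalSimSpec",
    "EventSimSpec",
    "make_survival_dataset",
    "make_two_arm_study",
    "make_event_stream",
    "XRAY_DOSES_GY",
    "F18_DOSES_GY",
]

#: X-ray reference-arm dose grid: 0 to 7.5 Gy in 2.5 Gy increments
XRAY_DOSES_GY: Tuple[float, ...] = (0.0, 2.5, 5.0, 7.5)
#: beta-plus arm dose grid: 10 to 30 Gy
F18_DOSES_GY: Tuple[float, ...] = (0.0, 10.0, 20.0, 30.0)


@dataclass(frozen=True)
class SurvivalSimSpec:
    """Generating model for a synthetic clonogenic dataset.

    Colonies are Poisson with mean ``cells_seeded * PE * SF(dose)``
    (truncated at cells seeded); binomial noise is available via
    ``noise="binomial"``.  ``cells_seeded`` may be a single count, a
    per-dose sequence, or ``"auto"``, which seeds each dose aiming for
    ~100 expected colonies — the standard clonogenic design of seeding
    more cells at higher doses.
    """

    alpha: float = 0.2  # Gy^-1
    beta: float = 0.0546  # Gy^-2
    doses: Tuple[float, ...] = XRAY_DOSES_GY
    cells_seeded: Union[int, str, Tuple[int, ...]] = "auto"
    plating_efficiency: float = 0.5
    replicates: int = 3
    seed: int = 0
    arm: str = "synthetic"
    noise: str = "poisson"
    auto_target_colonies: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.plating_efficiency <= 1.0:
            raise ValueError("plating_efficiency must be in (0, 1]")
        if 0.0 not in self.doses:
            raise ValueError("dose grid must include the 0 Gy control")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise not in ("poisson", "binomial"):
            raise ValueError("noise must be 'poisson' or 'binomial'")

    def sf(self, dose: float) -> float:
        return math.exp(-(self.alpha * dose + self.beta * dose * dose))

    def seeded_at(self, dose: float) -> int:
        if isinstance(self.cells_seeded, str):
            if self.cells_seeded != "auto":
                raise ValueError("cells_seeded must be an int, a sequence or 'auto'")
            expect = self.plating_efficiency * self.sf(dose)
            return max(int(math.ceil(self.auto_target_colonies / expect)), 1)
        if isinstance(self.cells_seeded, (tuple, list)):
            return int(self.cells_seeded[self.doses.index(dose)])
        return int(self.cells_seeded)


def make_survival_dataset(spec: SurvivalSimSpec) -> List[ColonyRecord]:
    """Draw one synthetic clonogenic dataset; deterministic given seed."""
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0x5F)))
    records: List[ColonyRecord] = []
    for dose in spec.doses:
        seeded = spec.seeded_at(dose)
        mean = seeded * spec.plating_efficiency * spec.sf(dose)
        for rep in range(spec.replicates):
            if spec.noise == "poisson":
                colonies = int(min(rng.poisson(mean), seeded))
            else:
                colonies = int(rng.binomial(seeded, mean / seeded))
            records.append(
                ColonyRecord(
                    arm=spec.arm,
                    dose_gy=dose,
                    cells_seeded=seeded,
                    colonies=colonies,
                    replicate=rep,
                )
            )
    return records


def make_two_arm_study(
    rbe_truth: float,
    reference: Optional[SurvivalSimSpec] = None,
    test_doses: Tuple[float, ...] = F18_DOSES_GY,
    sf_level: float = 0.5,
    seed: int = 0,
) -> Tuple[List[ColonyRecord], List[ColonyRecord]]:
    """Construct a two-arm study with a known RBE at ``sf_level``.

    The test arm's survival curve is the reference curve with dose
    rescaled, SF_test(D) = SF_ref(rbe_truth * D), i.e. alpha_test =
    rbe * alpha_ref and beta_test = rbe^2 * beta_ref; then
    D_test(sf) = D_ref(sf) / rbe_truth exactly for every level, and
    rbe_truth = 1 gives statistically identical arms.
    """
    if not rbe_truth > 0:
        raise ValueError("rbe_truth must be positive")
    ref = reference if reference is not None else SurvivalSimSpec(arm="xray", seed=seed)
    test = replace(
        ref,
        alpha=ref.alpha * rbe_truth,
        beta=ref.beta * rbe_truth**2,
        doses=tuple(test_doses),
        arm="f18",
        seed=seed + 1,
    )
    return make_survival_dataset(ref), make_survival_dataset(test)


@dataclass(frozen=True)
class EventSimSpec:
    """Generating model for synthetic deposition-event streams.

    Events per primary are Poisson; per-event energies uniform in
    ``energy_range_ev``; positions either uniform in the source
    cylinder or clustered near the DNA (uniform within 1.2x the outer
    radius over the DNA length), which yields enough backbone hits for
    scoring tests at small n.
    """

    n_primaries: int = 100
    events_per_primary_mean: float = 8.0
    energy_range_ev: Tuple[float, float] = (5.0, 25.0)
    spatial_distribution: str = "clustered-near-DNA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_primaries < 0:
            raise ValueError("n_primaries must be >= 0")
        if self.events_per_primary_mean < 0:
            raise ValueError("events_per_primary_mean must be >= 0")
        if self.spatial_distribution not in ("uniform-in-source", "clustered-near-DNA"):
            raise ValueError("unknown spatial_distribution")


def make_event_stream(
    spec: EventSimSpec,
    geom: DNAGeometry,
    source: Optional[SourceVolume] = None,
    rules: ScoringRules = ScoringRules(),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Generate a synthetic event stream plus its scored ground truth.

    Returns ``(positions, energies_ev, primary_ids, truth)`` where
    ``truth`` holds the SSB/DSB counts computed by an independent naive
    pass (scalar per-volume accumulation and pairwise sweep), recorded
    alongside so consumers can verify the scoring pipeline.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xE7)))
    src = source if source is not None else default_source(geom)
    counts = rng.poisson(spec.events_per_primary_mean, spec.n_primaries)
    total = int(counts.sum())
    if spec.spatial_distribution == "uniform-in-source":
        pos = sample_source_points(src, rng, total)
    else:
        r = 1.2 * geom.outer_radius * np.sqrt(rng.random(total))
        phi = rng.random(total) * 2.0 * math.pi
        z = rng.random(total) * geom.total_length
        pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    lo, hi = spec.energy_range_ev
    energies = lo + (hi - lo) * rng.random(total)
    pids = np.repeat(np.arange(spec.n_primaries, dtype=np.int64), counts)
    truth = _naive_score(pos, energies, pids, geom, rules)
    return pos, energies, pids, truth


def _naive_score(
    positions: np.ndarray,
    energies: np.ndarray,
    primary_ids: np.ndarray,
    geom: DNAGeometry,
    rules: ScoringRules,
) -> dict:
    """Reference scorer: scalar classification, dict accumulation,
    greedy pairing on explicitly sorted break lists.  Deliberately
    simple and separate from the vectorised pipeline."""
    from .geometry import classify_point, Region

    acc: dict = {}
    for p, e, pid in zip(positions, energies, primary_ids):
        vid = classify_point(geom, p)
        if vid.region is not Region.BACKBONE:
            continue
        key = (int(pid), vid.strand, vid.base_index)
        if rules.accumulation == "per_volume_per_primary":
            acc[key] = acc.get(key, 0.0) + float(e)
        else:
            if float(e) >= rules.ssb_threshold_ev:
                acc[key] = max(acc.get(key, 0.0), float(e))
    breaks_by_pid: dict = {}
    for (pid, s, b), e in acc.items():
        if e >= rules.ssb_threshold_ev:
            breaks_by_pid.setdefault(pid, []).append(StrandBreak(s, b, e, pid))
    ssb = sum(len(v) for v in breaks_by_pid.values())
    dsb = sum(score_dsbs(v, rules) for v in breaks_by_pid.values())
    return {"ssb_count": int(ssb), "dsb_count": int(dsb)}
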
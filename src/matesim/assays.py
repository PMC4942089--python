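"""Batch mating assays: efficiency, direction plots, discrimination,
competition, and Fisher's exact comparisons.

Mating efficiency (ME) is the fraction of replicate simulations meeting the
success criterion.  Mating discrimination (MD) is, among successful matings
in a scenario with one pheromone-producing alpha-cell and one or more
non-producers, the fraction that mated with the producer.  Mating
competition tallies which of two a-cell genotypes wins a shared alpha-cell.

Projection direction conventions: for each cell the projection angle is
measured between the polarisome direction (from the cell's initial center)
and the axis toward the partner's initial center — counterclockwise-positive
for the alpha-cell and clockwise-positive for the a-cell, both in
[-pi/2, pi/2], so that a pair of cells pointing straight at each other gives
equal angles (a point on the diagonal of the direction plot).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from matesim.simulation import (
    ScenarioConfig,
    SimulationResult,
    run_simulation,
)


@dataclass
class DirectionPair:
    """Time-averaged projection angles of one two-cell simulation."""

    theta_alpha: float   # alpha-cell angle, counterclockwise, [-pi/2, pi/2]
    theta_a: float       # a-cell angle, clockwise, same range

    @property
    def diagonal_distance(self) -> float:
        """Perpendicular distance from the identity diagonal in the
        (theta_alpha, theta_a) plane."""
        return abs(self.theta_a - self.theta_alpha) / np.sqrt(2.0)


@dataclass
class BatchSummary:
    """Counts and summary statistics over a batch of replicates."""

    n_reps: int
    n_success: int
    mating_times: list[float]
    n_correct: Optional[int] = None        # discrimination batches only
    direction_pairs: list[DirectionPair] = dc_field(default_factory=list)

    @property
    def efficiency(self) -> float:
        return self.n_success / self.n_reps

    @property
    def discrimination(self) -> Optional[float]:
        if self.n_correct is None or self.n_success == 0:
            return None
        return self.n_correct / self.n_success

    @property
    def mean_mating_time(self) -> Optional[float]:
        return float(np.mean(self.mating_times)) if self.mating_times else None

    @property
    def sd_mating_time(self) -> Optional[float]:
        if len(self.mating_times) < 2:
            return None
        return float(np.std(self.mating_times, ddof=1))

    @property
    def mean_diagonal_deviation(self) -> Optional[float]:
        if not self.direction_pairs:
            return None
        return float(np.mean([p.diagonal_distance for p in self.direction_pairs]))


def batch_seeds(seed_base: int, n_reps: int) -> list[int]:
    """Deterministic per-replicate root seeds (kept below 2**31)."""
    ss = np.random.SeedSequence(seed_base)
    return [int(s) for s in ss.generate_state(n_reps) % (2**31 - 1)]


def run_batch(config: ScenarioConfig, n_reps: int = 20,
              seed_base: int = 0) -> list[SimulationResult]:
    """Run ``n_reps`` replicates differing only in their noise seeds."""
    return [run_simulation(config, seed=s)
            for s in batch_seeds(seed_base, n_reps)]


def _signed_angle(u: np.ndarray, d: np.ndarray) -> float:
    """Counterclockwise angle from axis u to direction d."""
    return float(np.arctan2(u[0] * d[1] - u[1] * d[0], u @ d))


def _cell_angles(result: SimulationResult, cell_id: str,
                 partner_id: str) -> np.ndarray:
    """Per-sample projection angle of one cell in its partner-axis frame."""
    c0 = np.asarray(result.centers0[cell_id])
    p0 = np.asarray(result.centers0[partner_id])
    u = p0 - c0
    u = u / np.hypot(*u)
    pts = result.polarisome_points[cell_id]
    ok = np.isfinite(pts[:, 0])
    angles = np.full(len(pts), np.nan)
    for i in np.nonzero(ok)[0]:
        d = pts[i] - c0
        nd = np.hypot(*d)
        if nd == 0:
            continue
        theta = _signed_angle(u, d / nd)
        if result.mating_types[cell_id] == "a":
            theta = -theta  # a-cell angles are clockwise-positive
        angles[i] = theta
    return np.clip(angles, -np.pi / 2, np.pi / 2)


def direction_pair(result: SimulationResult,
                   a_id: Optional[str] = None,
                   alpha_id: Optional[str] = None) -> Optional[DirectionPair]:
    """Time-averaged (theta_alpha, theta_a) for one simulation.

    Samples taken before a cell polarized are skipped.  Returns None when
    either cell never polarized.
    """
    if a_id is None:
        a_id = next(i for i in result.cell_ids if result.mating_types[i] == "a")
    if alpha_id is None:
        alpha_id = next(i for i in result.cell_ids
                        if result.mating_types[i] == "alpha")
    th_a = _cell_angles(result, a_id, alpha_id)
    th_alpha = _cell_angles(result, alpha_id, a_id)
    if not (np.isfinite(th_a).any() and np.isfinite(th_alpha).any()):
        return None
    return DirectionPair(
        theta_alpha=float(np.nanmean(th_alpha)),
        theta_a=float(np.nanmean(th_a)),
    )


def diagonal_deviation(pairs: Sequence[DirectionPair]) -> float:
    """Batch-mean perpendicular distance of direction points from the
    identity diagonal of the direction plot, in radians."""
    if not pairs:
        raise ValueError("no direction pairs")
    return float(np.mean([p.diagonal_distance for p in pairs]))


def mating_efficiency(batch: Sequence[SimulationResult]) -> BatchSummary:
    """Successes / total over a batch, with mating-time statistics and the
    direction pairs of the successful two-cell matings."""
    if not batch:
        raise ValueError("empty batch")
    times = [r.mating_time for r in batch if r.success]
    dps = []
    for r in batch:
        dp = direction_pair(r)
        if dp is not None:
            dps.append(dp)
    return BatchSummary(
        n_reps=len(batch),
        n_success=sum(r.success for r in batch),
        mating_times=[t for t in times if t is not None],
        direction_pairs=dps,
    )


def mating_discrimination(batch: Sequence[SimulationResult],
                          producer_id: Optional[str] = None) -> BatchSummary:
    """Fraction of successful matings whose partner is the alpha-factor
    producer.  MD is undefined (None) when there are no successes."""
    if not batch:
        raise ValueError("empty batch")
    if producer_id is None:
        cfg = batch[0].config
        ids = batch[0].cell_ids
        producers = [
            ids[i] for i, c in enumerate(cfg.cells)
            if c.mating_type == "alpha" and c.producer
        ]
        if len(producers) != 1:
            raise ValueError(
                "scenario must have exactly one producing alpha-cell; "
                f"found {len(producers)}"
            )
        producer_id = producers[0]
    summary = mating_efficiency(batch)
    summary.n_correct = sum(
        1 for r in batch
        if r.success and r.partner is not None and r.partner[1] == producer_id
    )
    return summary


def competition_outcome(batch: Sequence[SimulationResult]) -> dict[str, int]:
    """Per-a-cell win counts in a two-a-cells / one-alpha-cell scenario.

    The winner of a replicate is the a-cell that meets the success criterion
    with the alpha-cell; replicates with no success are tallied under
    'none'.  (Simultaneous contact cannot occur: detection scans pairs in a
    fixed order at each sample, and a double contact within one sample
    interval would be recorded for the first pair — counted as a tie.)
    """
    if not batch:
        raise ValueError("empty batch")
    a_ids = [i for i in batch[0].cell_ids if batch[0].mating_types[i] == "a"]
    wins = {i: 0 for i in a_ids}
    wins["none"] = 0
    wins["tie"] = 0
    for r in batch:
        if not r.success or r.partner is None:
            wins["none"] += 1
            continue
        winner, alpha_id = r.partner
        # check for a tie: another a-cell pair below threshold at same sample
        k = int(np.argmin(np.abs(r.times - r.mating_time)))
        thr = r.config.threshold()
        tied = [
            a for a in a_ids
            if a != winner
            and np.isfinite(r.distances[(a, alpha_id)][k])
            and r.distances[(a, alpha_id)][k] < thr
        ]
        if tied:
            wins["tie"] += 1
        else:
            wins[winner] += 1
    return wins


def fisher_exact(table: Sequence[Sequence[int]],
                 alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value on a 2x2 count table.

    ``alternative`` is 'two-sided', 'greater' or 'less' (the directional
    forms test whether the first row's success odds exceed / fall below the
    second row's).  Counts must be nonnegative integers.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = t.astype(int)
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    return float(stats.fisher_exact(t, alternative=alternative).pvalue)


def efficiency_comparison(n1: int, N1: int, n2: int, N2: int,
                          alternative: str = "two-sided") -> float:
    """Fisher p-value comparing two success proportions n1/N1 vs n2/N2."""
    return fisher_exact([[n1, N1 - n1], [n2, N2 - n2]], alternative)
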
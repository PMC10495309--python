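"""Stochastic rejoining of DSB free ends over a fixed repair window.

Each DSB contributes two co-located free ends.  Ends belonging to simple
breaks initiate joining events with the fast rate, ends of complex breaks
with the slow rate (each end carries half the break-level rate, so an
isolated break rejoins as a Poisson process with its class rate).  When an
end fires, its partner is drawn among all currently free, repair-competent
ends with Gaussian distance weight exp(-d^2 / (2 sigma^2)); the original
partner (the break's other end, at distance zero) is always a candidate.
Joining the original partner restores the break; joining any other end is
a misrepair.  The simulation is an exact event-driven (Gillespie) loop.

At the end of the repair window a break is classified as

* residual   -- at least one end still free (or the break was flagged
                unrepairable up front, which models irreversibly complex
                lesions);
* correct    -- both ends joined, to each other;
* misrepaired -- both ends joined, at least one to a wrong partner.

Post-repair damage is residual + misrepaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .damage import DamageRecord

__all__ = ["RepairParams", "RepairOutcome", "repair_run", "mean_post_repair"]


@dataclass(frozen=True)
class RepairParams:
    """Repair-kinetics parameters.

    Rates are per hour; ``misjoin_sigma_um`` is the distance scale of
    wrong-end pairing; ``complex_unrepaired_prob`` is the per-break
    probability that a complex lesion cannot be rejoined at all within the
    window.  The defaults for the latter two were calibrated once so the
    post-repair/initial slope ratios of the two emitters land near the
    reference fit tables (Lu-177 ~ 0.21 with upward curvature, Ac-225 ~
    0.92 and linear), then frozen.
    """

    lambda_fast: float = 2.07
    lambda_slow: float = 0.259
    repair_time_h: float = 24.0
    misjoin_sigma_um: float = 0.19
    complex_unrepaired_prob: float = 0.86
    repetitions: int = 10

    def __post_init__(self) -> None:
        if self.lambda_fast <= 0 or self.lambda_slow <= 0:
            raise ValueError("repair rates must be positive")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not 0.0 <= self.complex_unrepaired_prob <= 1.0:
            raise ValueError("complex_unrepaired_prob must be a probability")


@dataclass(frozen=True)
class RepairOutcome:
    """End-state partition of the initial breaks after the repair window."""

    n_correct: int
    n_misrepaired: int
    n_residual: int

    def __post_init__(self) -> None:
        if min(self.n_correct, self.n_misrepaired, self.n_residual) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_initial(self) -> int:
        return self.n_correct + self.n_misrepaired + self.n_residual

    @property
    def n_post(self) -> int:
        return self.n_misrepaired + self.n_residual


def repair_run(
    damage: DamageRecord,
    params: RepairParams = RepairParams(),
    rng: np.random.Generator | int | None = None,
) -> RepairOutcome:
    """One stochastic repair realisation of the given damage pattern."""
    rng = np.random.default_rng(rng)
    n = damage.n_dsb
    if n == 0:
        return RepairOutcome(0, 0, 0)

    is_complex = np.asarray(damage.dsb_complex, dtype=bool)
    blocked = is_complex & (rng.random(n) < params.complex_unrepaired_prob)

    active = np.nonzero(~blocked)[0]
    m = active.size
    if m == 0:
        return RepairOutcome(0, 0, int(n))

    # two ends per active break, co-located at the break position
    pos = np.repeat(damage.dsb_positions[active], 2, axis=0)
    break_of_end = np.repeat(np.arange(m), 2)
    rate = np.where(is_complex[active], params.lambda_slow, params.lambda_fast)[break_of_end] / 2.0
    free = np.ones(2 * m, dtype=bool)
    joined_to = np.full(2 * m, -1, dtype=np.int64)

    sigma = params.misjoin_sigma_um
    t = 0.0
    t_end = params.repair_time_h
    while True:
        free_idx = np.nonzero(free)[0]
        if free_idx.size < 2:
            break
        rates = rate[free_idx]
        total = rates.sum()
        t += rng.exponential(1.0 / total)
        if t > t_end:
            break
        i = free_idx[rng.choice(free_idx.size, p=rates / total)]
        cand = free_idx[free_idx != i]
        d2 = np.einsum("ij,ij->i", pos[cand] - pos[i], pos[cand] - pos[i])
        if sigma > 0:
            w = np.exp(-d2 / (2.0 * sigma * sigma))
        else:
            w = (d2 == 0.0).astype(float)
        wsum = w.sum()
        if wsum <= 0:
            # no reachable partner; the end stays free (no-op event)
            continue
        j = cand[rng.choice(cand.size, p=w / wsum)]
        free[i] = free[j] = False
        joined_to[i] = j
        joined_to[j] = i

    e1 = np.arange(0, 2 * m, 2)
    e2 = e1 + 1
    both_joined = ~free[e1] & ~free[e2]
    correct = both_joined & (joined_to[e1] == e2)
    mis = both_joined & ~correct
    n_correct = int(correct.sum())
    n_mis = int(mis.sum())
    n_residual = int(n - n_correct - n_mis)
    return RepairOutcome(n_correct, n_mis, n_residual)


def mean_post_repair(
    damage: DamageRecord,
    params: RepairParams = RepairParams(),
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Mean and sample SD of the post-repair damage count over repetitions.

    Each repetition re-runs the stochastic rejoining with a derived seed;
    the (mean, sd) pair is one dose-effect data point and its error bar.
    """
    rng = np.random.default_rng(rng)
    posts = np.array(
        [repair_run(damage, params, child).n_post for child in rng.spawn(params.repetitions)],
        dtype=float,
    )
    sd = float(posts.std(ddof=1)) if params.repetitions >= 2 else 0.0
    return float(posts.mean()), sd
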
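"""Construction of the two study designs.

Experiment 1 is a trial-based electric-shock task: on each choice trial the
participant picks one of two prospective shock episodes, each described by an
expected shock count per 5-s train (magnitude, 3-12 total shocks) and a delay
in trials (4-51).  Choices and outcomes are interleaved within a single run,
so the schedule must map every choice option to a unique future outcome trial
without running past the end of the run.

Experiment 2 is a hypothetical dental-appointment task: the sooner
appointment is always "today" (delay 0) and the later one occurs at one of
six delays up to 237 days, with pain magnitudes expressed as a percentage of
the worst imaginable dental pain.

Both generators counterbalance magnitude ordering: mirrored pairs share the
same delays with swapped magnitudes, so a decision-maker whose value function
is monotone in magnitude (and delay-independent) chooses the later option on
exactly half of the trials in expectation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ChoiceOption",
    "ChoicePair",
    "Schedule",
    "DesignConfig",
    "DesignInfeasibleError",
    "generate_exp1_choice_set",
    "generate_exp1_schedule",
    "generate_exp2_choice_set",
    "bin_delay_difference",
    "pairs_to_frame",
    "pairs_from_frame",
    "schedule_to_csv",
]

EXP2_MAGNITUDES = (60, 55, 51, 46, 37, 16)
EXP2_DELAYS = (1, 5, 13, 32, 89, 237)

#: Delay-difference tertile edges, per experiment: (short_hi, medium_hi).
#: Exp 1: short 1-10, medium 11-20, long >20 trials.
#: Exp 2: short 1-5, medium 13-32, long 89-237 days (the offered delays are
#: sparse; intermediate values fall into the nearest enclosing band).
_BIN_EDGES = {1: (10, 20), 2: (5, 32)}


class DesignInfeasibleError(RuntimeError):
    """Raised when a design configuration cannot be satisfied."""


@dataclass(frozen=True)
class ChoiceOption:
    """One prospective painful outcome: magnitude and delay.

    magnitude: expected pain per episode (Exp 1: expected shocks per 5-s
        train; Exp 2: % of worst imaginable dental pain).
    delay: non-negative integer delay (Exp 1: trials; Exp 2: days).
    """

    magnitude: float
    delay: int

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")


@dataclass(frozen=True)
class ChoicePair:
    """A binary choice between a sooner and a later painful option."""

    sooner: ChoiceOption
    later: ChoiceOption
    side_of_sooner: str = "left"  # which screen side the sooner option takes
    frame: str = "unframed"  # pain | relief | unframed

    def __post_init__(self):
        if self.sooner.delay > self.later.delay:
            raise ValueError("sooner option must not be more delayed than later")
        if self.frame not in ("pain", "relief", "unframed"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.side_of_sooner not in ("left", "right"):
            raise ValueError("side_of_sooner must be 'left' or 'right'")

    @property
    def delay_difference(self) -> int:
        return self.later.delay - self.sooner.delay


@dataclass
class Schedule:
    """An interleaved choice/outcome trial sequence for one Exp-1 run.

    ``trials`` holds one record per trial: ``("choice", pair_index)`` or
    ``("no_choice", None)``.  ``outcome_map`` maps each choice-trial index to
    the pair of absolute trial indices on which the sooner / later outcomes
    would be delivered; any trial not referenced by a chosen option delivers
    the baseline episode.
    """

    trials: list[tuple[str, int | None]]
    outcome_map: dict[int, tuple[int, int]]
    pairs: list[ChoicePair]
    config: "DesignConfig"
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def choice_trial_indices(self) -> list[int]:
        return [i for i, (kind, _) in enumerate(self.trials) if kind == "choice"]

    def validate(self) -> None:
        """Exhaustively re-check the scheduling constraints."""
        slots: list[int] = []
        for t, (s1, s2) in self.outcome_map.items():
            kind, pair_idx = self.trials[t]
            if kind != "choice":
                raise AssertionError(f"outcome_map keys must be choice trials, got {t}")
            pair = self.pairs[pair_idx]
            if s1 != t + pair.sooner.delay or s2 != t + pair.later.delay:
                raise AssertionError(f"outcome slots inconsistent with delays at trial {t}")
            # a zero-delay-difference pair's options share one outcome trial
            slots.extend({s1, s2})
        if len(slots) != len(set(slots)):
            raise AssertionError("outcome slots are not pairwise distinct")
        if slots and max(slots) >= self.n_trials:
            raise AssertionError("an outcome slot lies beyond the end of the run")


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the experimental designs.

    Defaults reproduce the published task structure: 95 choice trials per
    run, magnitudes 3-12 expected shocks, delays 4-51 trials, a 2-shocks/5-s
    baseline and a 14-shocks/5-s maximum used to derive the frame-specific
    display values.
    """

    n_choice_trials: int = 95
    magnitude_range: tuple[int, int] = (3, 12)
    delay_range: tuple[int, int] = (4, 51)
    #: sooner options are near-term: their delay is drawn from
    #: [delay lo, sooner_delay_max] (None = anywhere the difference permits).
    sooner_delay_max: int | None = 12
    n_zero_delay_pairs: int = 13  # zero delay-difference trials (incl. tie)
    counterbalance_sides: bool = True
    baseline_rate: float = 2.0
    maximum_rate: float = 14.0
    total_trials: int = 200
    schedule_retry_cap: int = 10_000
    exp2_magnitudes: tuple[int, ...] = EXP2_MAGNITUDES
    exp2_delays: tuple[int, ...] = EXP2_DELAYS

    def __post_init__(self):
        if self.n_choice_trials < 1:
            raise DesignInfeasibleError("need at least one choice trial")
        lo, hi = self.magnitude_range
        if not (0 <= lo < hi):
            raise DesignInfeasibleError("magnitude range must satisfy 0 <= lo < hi")
        dlo, dhi = self.delay_range
        if not (0 <= dlo <= dhi):
            raise DesignInfeasibleError("delay range must satisfy 0 <= lo <= hi")
        if self.n_zero_delay_pairs > self.n_choice_trials:
            raise DesignInfeasibleError("more zero-delay pairs than choice trials")


def bin_delay_difference(delay_difference: int, experiment: int) -> str:
    """Tertile label for a delay difference: zero / short / medium / long."""
    if delay_difference < 0:
        raise ValueError("delay difference must be non-negative")
    if experiment not in _BIN_EDGES:
        raise ValueError("experiment must be 1 or 2")
    short_hi, medium_hi = _BIN_EDGES[experiment]
    if delay_difference == 0:
        return "zero"
    if delay_difference <= short_hi:
        return "short"
    if delay_difference <= medium_hi:
        return "medium"
    return "long"


def _bin_dd_ranges(config: DesignConfig) -> dict[str, tuple[int, int]]:
    """Feasible delay-difference ranges for each non-zero Exp-1 bin."""
    dlo, dhi = config.delay_range
    max_dd = dhi - dlo
    short_hi, medium_hi = _BIN_EDGES[1]
    ranges = {
        "short": (1, min(short_hi, max_dd)),
        "medium": (short_hi + 1, min(medium_hi, max_dd)),
        "long": (medium_hi + 1, max_dd),
    }
    for name, (a, b) in ranges.items():
        if a > b:
            raise DesignInfeasibleError(
                f"delay range {config.delay_range} too narrow to populate the "
                f"'{name}' delay-difference bin"
            )
    return ranges


def generate_exp1_choice_set(config: DesignConfig, seed: int) -> list[ChoicePair]:
    """Generate a counterbalanced Experiment-1 choice set.

    Pairs come in mirrored twins: identical delays, swapped magnitudes.  With
    an odd trial count the one unmatched pair has equal magnitudes, so the
    ordering counterbalance (#larger-sooner vs #larger-later) always holds to
    within one and the expected later-choice rate of any magnitude-monotone,
    delay-indifferent decision-maker is exactly one half.
    """
    rng = np.random.default_rng(seed)
    n = config.n_choice_trials
    mlo, mhi = config.magnitude_range
    dlo, dhi = config.delay_range

    if mhi - mlo < 1:
        raise DesignInfeasibleError("magnitude range too narrow to counterbalance")

    n_mirror = n // 2
    n_tie = n % 2
    dd_ranges = _bin_dd_ranges(config)

    # allocate mirrored twins to bins: zero first, remainder split evenly
    z_twins = min(config.n_zero_delay_pairs // 2, n_mirror)
    rest = n_mirror - z_twins
    names = ["short", "medium", "long"]
    alloc = {"zero": z_twins}
    for i, name in enumerate(names):
        alloc[name] = rest // 3 + (1 if i < rest % 3 else 0)

    pairs: list[ChoicePair] = []
    for name, count in alloc.items():
        for _ in range(count):
            a, b = rng.choice(np.arange(mlo, mhi + 1), size=2, replace=False)
            if name == "zero":
                dd = 0
                d1_hi = dhi  # shared delay: anywhere in the range
            else:
                lo, hi = dd_ranges[name]
                dd = int(rng.integers(lo, hi + 1))
                d1_hi = dhi - dd
                if config.sooner_delay_max is not None:
                    d1_hi = min(d1_hi, config.sooner_delay_max)
            d1 = int(rng.integers(dlo, max(d1_hi, dlo) + 1))
            d2 = d1 + dd
            for xs, xl in ((int(a), int(b)), (int(b), int(a))):
                pairs.append(
                    ChoicePair(ChoiceOption(xs, d1), ChoiceOption(xl, d2))
                )
    if n_tie:
        x = int(rng.integers(mlo, mhi + 1))
        d = int(rng.integers(dlo, dhi + 1))
        pairs.append(ChoicePair(ChoiceOption(x, d), ChoiceOption(x, d)))

    # counterbalanced presentation side
    sides = np.array(["left", "right"]).repeat([(len(pairs) + 1) // 2, len(pairs) // 2])
    rng.shuffle(sides)
    order = rng.permutation(len(pairs))
    return [replace(pairs[i], side_of_sooner=str(sides[i])) for i in order]


def generate_exp2_choice_set(config: DesignConfig | None = None) -> list[ChoicePair]:
    """Generate the dental-appointment choice grid.

    The sooner appointment is always "today" (delay 0).  Each non-60%
    magnitude is paired against 60% pain at every later delay, in both
    orderings (larger pain sooner vs larger pain later); the 60-vs-60 tie is
    emitted once per delay.
    """
    config = config or DesignConfig()
    mags = config.exp2_magnitudes
    ref = max(mags)
    pairs: list[ChoicePair] = []
    side = 0
    for d in config.exp2_delays:
        for x in mags:
            orderings = [(x, ref)] if x == ref else [(x, ref), (ref, x)]
            for xs, xl in orderings:
                pairs.append(
                    ChoicePair(
                        ChoiceOption(xs, 0),
                        ChoiceOption(xl, int(d)),
                        side_of_sooner="left" if side % 2 == 0 else "right",
                    )
                )
                side += 1
    return pairs


def _try_schedule(
    pairs: list[ChoicePair], total: int, rng: np.random.Generator
) -> dict[int, int] | None:
    """One randomized greedy + min-conflicts attempt.

    Returns a map pair_index -> choice-trial position, or None on failure.
    Constraints: positions distinct; every position p with pair delays
    (d1, d2) claims outcome slots p+d1 and p+d2, all 2N slots distinct and
    < total.
    """
    n = len(pairs)
    d1 = np.array([p.sooner.delay for p in pairs])
    d2 = np.array([p.later.delay for p in pairs])

    assign = np.full(n, -1, dtype=int)
    slot_owner: dict[int, int] = {}
    pos_used: set[int] = set()

    def slots_of(i: int, pos: int) -> set[int]:
        # zero-delay-difference pairs claim a single shared outcome trial
        return {pos + d1[i], pos + d2[i]}

    def feasible_positions(i: int) -> np.ndarray:
        hi = total - 1 - d2[i]
        if hi < 0:
            return np.empty(0, dtype=int)
        cand = np.arange(0, hi + 1)
        ok = np.array(
            [
                c not in pos_used
                and all(s not in slot_owner for s in slots_of(i, c))
                for c in cand
            ]
        )
        return cand[ok]

    def place(i: int, pos: int) -> None:
        assign[i] = pos
        pos_used.add(pos)
        for s in slots_of(i, pos):
            slot_owner[s] = i

    def unplace(i: int) -> None:
        pos = assign[i]
        pos_used.discard(pos)
        for s in slots_of(i, pos):
            slot_owner.pop(s, None)
        assign[i] = -1

    order = rng.permutation(n)
    pending = []
    for i in order:
        cand = feasible_positions(i)
        if len(cand) == 0:
            pending.append(i)
        else:
            place(i, int(rng.choice(cand)))

    # min-conflicts repair: evict the owners of the slots a pending pair needs
    for _ in range(20 * n):
        if not pending:
            break
        i = pending.pop(0)
        cand = feasible_positions(i)
        if len(cand) > 0:
            place(i, int(rng.choice(cand)))
            continue
        hi = total - 1 - d2[i]
        if hi < 0:
            return None
        pos = int(rng.integers(0, hi + 1))
        evicted = set()
        for s in slots_of(i, pos):
            if s in slot_owner:
                evicted.add(slot_owner[s])
        if pos in pos_used:
            evicted.update(j for j in range(n) if assign[j] == pos)
        for j in evicted:
            unplace(j)
            pending.append(j)
        place(i, pos)
    if pending:
        return None
    return {int(i): int(assign[i]) for i in range(n)}


def generate_exp1_schedule(
    pairs: list[ChoicePair], config: DesignConfig, seed: int
) -> Schedule:
    """Interleave choice and no-choice trials for one Exp-1 run.

    Every choice option must resolve to a unique outcome trial within the
    run, mirroring the bounded random permutation used in the task.  Because
    late positions cannot host long delays, no-choice trials necessarily
    thicken toward the end of the run.
    """
    total = config.total_trials
    max_d2 = max((p.later.delay for p in pairs), default=0)
    n_slots = sum(1 if p.delay_difference == 0 else 2 for p in pairs)
    min_possible = n_slots + min((p.sooner.delay for p in pairs), default=0)
    if total < min_possible or total <= max_d2:
        raise DesignInfeasibleError(
            f"total_trials={total} cannot host {len(pairs)} choice trials with "
            f"delays up to {max_d2} (need at least {max(min_possible, max_d2 + 1)})"
        )
    rng = np.random.default_rng(seed)
    assign = None
    for _ in range(config.schedule_retry_cap):
        assign = _try_schedule(pairs, total, rng)
        if assign is not None:
            break
    if assign is None:
        raise DesignInfeasibleError(
            f"could not place {len(pairs)} choice trials in {total} trials after "
            f"{config.schedule_retry_cap} attempts; increase total_trials"
        )

    trials: list[tuple[str, int | None]] = [("no_choice", None)] * total
    outcome_map: dict[int, tuple[int, int]] = {}
    for pair_idx, pos in assign.items():
        trials[pos] = ("choice", pair_idx)
        p = pairs[pair_idx]
        outcome_map[pos] = (pos + p.sooner.delay, pos + p.later.delay)
    sched = Schedule(trials=trials, outcome_map=outcome_map, pairs=pairs,
                     config=config, seed=seed)
    sched.validate()
    return sched


# ---------------------------------------------------------------------------
# tabular serialization


def pairs_to_frame(pairs: list[ChoicePair]) -> pd.DataFrame:
    """Choice set as a DataFrame (one row per pair, in presentation order)."""
    return pd.DataFrame(
        {
            "trial_index": np.arange(len(pairs)),
            "s1_magnitude": [p.sooner.magnitude for p in pairs],
            "s2_magnitude": [p.later.magnitude for p in pairs],
            "d1": [p.sooner.delay for p in pairs],
            "d2": [p.later.delay for p in pairs],
            "frame": [p.frame for p in pairs],
            "side_of_sooner": [p.side_of_sooner for p in pairs],
        }
    )


def pairs_from_frame(df: pd.DataFrame) -> list[ChoicePair]:
    return [
        ChoicePair(
            ChoiceOption(float(r.s1_magnitude), int(r.d1)),
            ChoiceOption(float(r.s2_magnitude), int(r.d2)),
            side_of_sooner=str(getattr(r, "side_of_sooner", "left")),
            frame=str(getattr(r, "frame", "unframed")),
        )
        for r in df.itertuples(index=False)
    ]


def schedule_to_csv(schedule: Schedule) -> str:
    """Serialize a schedule to CSV text with a seed-bearing header comment."""
    rows = []
    for t, (kind, pair_idx) in enumerate(schedule.trials):
        if kind == "choice":
            p = schedule.pairs[pair_idx]
            s1, s2 = schedule.outcome_map[t]
            rows.append(
                (t, kind, p.sooner.magnitude, p.later.magnitude,
                 p.sooner.delay, p.later.delay, p.frame, p.side_of_sooner, s1, s2)
            )
        else:
            rows.append((t, kind, "", "", "", "", "", "", "", ""))
    df = pd.DataFrame(
        rows,
        columns=["trial_index", "kind", "s1_magnitude", "s2_magnitude", "d1",
                 "d2", "frame", "side_of_sooner", "outcome_slot_1", "outcome_slot_2"],
    )
    buf = io.StringIO()
    buf.write(f"# seed={schedule.seed} total_trials={schedule.n_trials}\n")
    df.to_csv(buf, index=False)
    return buf.getvalue()
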
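"""Trial-schedule construction for the probabilistic-context stop-signal task.

The task manipulates the probability of a stop signal across colored screen
contexts: green (0%), yellow (17%), orange (25%) and red (33%). Trials run in
blocks of 9, 18 or 27 same-context trials with no two consecutive blocks in
the same context. Each trial shows a neutral or a poker picture to be
categorized within a 1250 ms deadline; on stop trials an auditory signal
follows the picture at an adaptively tracked delay (SSD).

This module builds exact schedules: per-context go/stop counts per stimulus
type are conserved for every seed, every picture identity appears a fixed
number of times, and event onsets follow the stated trial timing (750 ms cue,
1250 ms picture, 2000 ms grey screen at each context change).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

CONTEXT_ORDER = ("green", "yellow", "orange", "red")
CONTEXT_PROBABILITY = {"green": 0.0, "yellow": 0.17, "orange": 0.25, "red": 0.33}
STIMULUS_TYPES = ("neutral", "poker")

SCHEDULE_COLUMNS = [
    "trial_index",
    "block_index",
    "context",
    "trial_kind",
    "stimulus_type",
    "picture_id",
    "onset_ms",
]


class InfeasibleDesignError(ValueError):
    """A schedule constraint cannot be satisfied; the message names it."""


@dataclass(frozen=True)
class ContextSpec:
    """One stop-signal probability context.

    Trial counts are per stimulus type: a context contributes
    ``2 * (n_go_per_stimulus + n_stop_per_stimulus)`` trials in total.
    """

    label: str
    nominal_stop_probability: float
    n_go_per_stimulus: int
    n_stop_per_stimulus: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.nominal_stop_probability <= 1.0:
            raise ValueError("nominal_stop_probability must lie in [0, 1]")
        if self.n_go_per_stimulus < 0 or self.n_stop_per_stimulus < 0:
            raise ValueError("trial counts must be non-negative")
        if self.nominal_stop_probability == 0.0 and self.n_stop_per_stimulus != 0:
            raise ValueError(
                f"context {self.label!r} has stop probability 0 but "
                f"{self.n_stop_per_stimulus} stop trials per stimulus"
            )

    @property
    def n_trials(self) -> int:
        return 2 * (self.n_go_per_stimulus + self.n_stop_per_stimulus)


@dataclass(frozen=True)
class DesignSpec:
    """Full parameterization of the task schedule.

    Timing constants are integer milliseconds. ``picture_duration_ms`` doubles
    as the categorization response deadline. The SSD staircase starts at
    ``ssd_initial_ms`` and moves in ``ssd_step_ms`` steps.
    """

    contexts: tuple[ContextSpec, ...]
    block_lengths: tuple[int, ...] = (9, 18, 27)
    n_pictures_per_stimulus: int = 18
    picture_repetitions: int = 12
    cue_duration_ms: int = 750
    picture_duration_ms: int = 1250
    context_change_gap_ms: int = 2000
    ssd_initial_ms: int = 800
    ssd_step_ms: int = 25
    training_trials_per_context: int = 9

    @property
    def n_trials(self) -> int:
        return sum(c.n_trials for c in self.contexts)

    @property
    def n_go_trials(self) -> int:
        return sum(2 * c.n_go_per_stimulus for c in self.contexts)

    @property
    def n_stop_trials(self) -> int:
        return sum(2 * c.n_stop_per_stimulus for c in self.contexts)

    def context(self, label: str) -> ContextSpec:
        for c in self.contexts:
            if c.label == label:
                return c
        raise KeyError(label)

    def stop_probability(self, label: str) -> float:
        return self.context(label).nominal_stop_probability

    def to_dict(self) -> dict:
        d = asdict(self)
        d["contexts"] = [asdict(c) for c in self.contexts]
        d["block_lengths"] = list(self.block_lengths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        d = dict(d)
        contexts = tuple(ContextSpec(**c) for c in d.pop("contexts"))
        if "block_lengths" in d:
            d["block_lengths"] = tuple(d["block_lengths"])
        return cls(contexts=contexts, **d)


def default_design() -> DesignSpec:
    """The study's task design with reconciled trial counts.

    Per-stimulus go counts are green 54, yellow 45, orange 40, red 36 and
    per-stimulus stop counts yellow 9, orange 14, red 18, which makes every
    context total 108 trials, 350 go and 82 stop trials overall, and
    432 = 36 pictures x 12 repetitions. (A green go count of 64 per stimulus
    would contradict all three totals and cannot be partitioned into blocks
    of 9/18/27; 54 satisfies every stated constraint simultaneously.)
    """
    return DesignSpec(
        contexts=(
            ContextSpec("green", 0.0, 54, 0),
            ContextSpec("yellow", 0.17, 45, 9),
            ContextSpec("orange", 0.25, 40, 14),
            ContextSpec("red", 0.33, 36, 18),
        )
    )


def scaled_design(factor: int) -> DesignSpec:
    """Default design with every per-context trial count multiplied.

    Used for long-run staircase and estimator-consistency experiments where
    many more stop trials are needed than one 432-trial run provides. Picture
    repetitions scale with the factor so picture balance stays exact.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    base = default_design()
    return DesignSpec(
        contexts=tuple(
            ContextSpec(
                c.label,
                c.nominal_stop_probability,
                c.n_go_per_stimulus * factor,
                c.n_stop_per_stimulus * factor,
            )
            for c in base.contexts
        ),
        picture_repetitions=base.picture_repetitions * factor,
    )


def _sample_block_composition(
    total: int, lengths: Sequence[int], rng: np.random.Generator, max_tries: int = 10_000
) -> list[int]:
    """Compose ``total`` as a sum of block lengths drawn uniformly.

    Lengths are drawn i.i.d. uniformly from ``lengths``; a sequence that
    overshoots the total is rejected wholesale and resampled, so the accepted
    sequence is an i.i.d. uniform draw conditioned on summing exactly to the
    total. Conditioning keeps the marginal 9/18/27 frequencies near-equal
    (per-draw redraws would instead skew heavily toward the shortest block).
    """
    lengths = sorted(lengths)
    if total == 0:
        return []
    arr = np.array(lengths)
    for _ in range(max_tries):
        remaining = total
        comp: list[int] = []
        while remaining > 0:
            draw = int(arr[rng.integers(len(arr))])
            if draw > remaining:
                comp = None
                break
            comp.append(draw)
            remaining -= draw
        if comp is not None:
            return comp
    raise InfeasibleDesignError(
        f"cannot compose {total} trials from block lengths {list(lengths)}"
    )


def build_block_sequence(
    design: DesignSpec, rng: np.random.Generator, max_tries: int = 10_000
) -> list[tuple[str, int]]:
    """Ordered (context, block_length) sequence for one run.

    Per-context block lengths sum exactly to that context's trial total and
    no two consecutive blocks share a context (rejection-sampled orderings).
    """
    blocks: list[tuple[str, int]] = []
    for c in design.contexts:
        if c.n_trials == 0:
            continue
        comp = _sample_block_composition(c.n_trials, design.block_lengths, rng, max_tries)
        blocks.extend((c.label, l) for l in comp)
    if not blocks:
        return []
    if len({ctx for ctx, _ in blocks}) == 1:
        # degenerate single-context design: the no-repetition constraint is
        # vacuous (there is nothing to alternate with)
        rng.shuffle(blocks)
        return blocks
    order = np.arange(len(blocks))
    for _ in range(min(max_tries, 1000)):
        rng.shuffle(order)
        seq = [blocks[i] for i in order]
        if all(seq[i][0] != seq[i + 1][0] for i in range(len(seq) - 1)):
            return seq
    # Many blocks: plain shuffling almost never avoids adjacent repeats, so
    # build the order constructively: draw the next context (never the
    # previous one) with probability proportional to its remaining blocks,
    # forcing any context whose remaining count exceeds half the remainder
    # (otherwise a dead end is unavoidable).
    lengths: dict[str, list[int]] = {}
    for ctx, l in blocks:
        lengths.setdefault(ctx, []).append(l)
    for ls in lengths.values():
        rng.shuffle(ls)
    remaining = {c: len(ls) for c, ls in lengths.items()}
    total = sum(remaining.values())
    seq = []
    prev = None
    while total > 0:
        forced = [c for c, r in remaining.items() if 2 * r > total]
        if forced:
            choice = forced[0]
            if choice == prev:
                raise InfeasibleDesignError(
                    f"context {choice!r} has too many blocks ({remaining[choice]} of "
                    f"{total} remaining) for a no-repeat ordering"
                )
        else:
            cands = [c for c, r in remaining.items() if r > 0 and c != prev]
            if not cands:
                raise InfeasibleDesignError(
                    "no context available without a consecutive repeat"
                )
            w = np.array([remaining[c] for c in cands], dtype=float)
            choice = cands[int(rng.choice(len(cands), p=w / w.sum()))]
        seq.append((choice, lengths[choice].pop()))
        remaining[choice] -= 1
        total -= 1
        prev = choice
    return seq


def _picture_pool(
    design: DesignSpec, stimulus: str, n_needed: int, rng: np.random.Generator
) -> list[str]:
    """Multiset of picture ids for one stimulus type, shuffled.

    Each of the ``n_pictures_per_stimulus`` identities appears exactly
    ``picture_repetitions`` times; their placement across contexts is random.
    """
    prefix = stimulus[0]
    ids = [f"{prefix}{i + 1:02d}" for i in range(design.n_pictures_per_stimulus)]
    pool = np.repeat(ids, design.picture_repetitions)
    if len(pool) != n_needed:
        raise InfeasibleDesignError(
            f"{stimulus} trial total {n_needed} != pictures x repetitions "
            f"({design.n_pictures_per_stimulus} x {design.picture_repetitions} = {len(pool)})"
        )
    rng.shuffle(pool)
    return list(pool)


def build_schedule(design: DesignSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Build one full-run trial schedule as a tidy DataFrame.

    Each context's pooled trial multiset (go/stop x neutral/poker at the exact
    DesignSpec counts) is distributed uniformly at random across that
    context's blocks. Onsets are cumulative cue + picture durations plus the
    grey-screen gap at every context change.
    """
    blocks = build_block_sequence(design, rng)

    # per-context trial multisets, shuffled
    pools: dict[str, list[tuple[str, str]]] = {}
    for c in design.contexts:
        pool = []
        for stim in STIMULUS_TYPES:
            pool += [("go", stim)] * c.n_go_per_stimulus
            pool += [("stop", stim)] * c.n_stop_per_stimulus
        rng.shuffle(pool)
        pools[c.label] = pool

    rows = []
    trial_index = 0
    onset = 0
    trial_len = design.cue_duration_ms + design.picture_duration_ms
    for block_index, (context, length) in enumerate(blocks):
        if block_index > 0:
            onset += design.context_change_gap_ms
        for _ in range(length):
            kind, stim = pools[context].pop()
            rows.append(
                {
                    "trial_index": trial_index,
                    "block_index": block_index,
                    "context": context,
                    "trial_kind": kind,
                    "stimulus_type": stim,
                    "picture_id": None,
                    "onset_ms": onset,
                }
            )
            trial_index += 1
            onset += trial_len
    leftovers = {k: len(v) for k, v in pools.items() if v}
    if leftovers:
        raise InfeasibleDesignError(f"block lengths did not exhaust trial pools: {leftovers}")

    df = pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)

    # deal balanced picture multisets onto each stimulus type's trial slots
    for stim in STIMULUS_TYPES:
        mask = df["stimulus_type"] == stim
        df.loc[mask, "picture_id"] = _picture_pool(design, stim, int(mask.sum()), rng)
    return df


def build_training_schedule(design: DesignSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Short familiarization run: one 9-trial block per context.

    Per-context composition mirrors the main run scaled down: the stop-trial
    count is the context total scaled to 9 trials (rounded), split as evenly
    as possible across stimulus types; green stays all-go. Picture identities
    are drawn at random (no balance constraint for training).
    """
    n = design.training_trials_per_context
    order = list(design.contexts)
    rng.shuffle(order)

    rows = []
    trial_index = 0
    onset = 0
    trial_len = design.cue_duration_ms + design.picture_duration_ms
    for block_index, c in enumerate(order):
        if block_index > 0:
            onset += design.context_change_gap_ms
        if c.n_trials > 0:
            n_stop = int(round(n * 2 * c.n_stop_per_stimulus / c.n_trials))
        else:
            n_stop = 0
        pool = []
        extra = int(rng.integers(2))  # random tie-break for odd splits
        for i, stim in enumerate(STIMULUS_TYPES):
            k_stop = n_stop // 2 + (1 if n_stop % 2 and i == extra else 0)
            pool += [("stop", stim)] * k_stop
        n_go = n - len(pool)
        for i, stim in enumerate(STIMULUS_TYPES):
            k_go = n_go // 2 + (1 if n_go % 2 and i == 1 - extra else 0)
            pool += [("go", stim)] * k_go
        rng.shuffle(pool)
        for kind, stim in pool:
            pic_num = int(rng.integers(design.n_pictures_per_stimulus)) + 1
            rows.append(
                {
                    "trial_index": trial_index,
                    "block_index": block_index,
                    "context": c.label,
                    "trial_kind": kind,
                    "stimulus_type": stim,
                    "picture_id": f"{stim[0]}{pic_num:02d}",
                    "onset_ms": onset,
                }
            )
            trial_index += 1
            onset += trial_len
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def schedule_to_csv(schedule: pd.DataFrame, path_or_buf=None):
    """Export a schedule deterministically (UTF-8, rows ordered by trial)."""
    out = schedule.sort_values("trial_index").loc[:, SCHEDULE_COLUMNS]
    return out.to_csv(path_or_buf, index=False)


def schedule_from_csv(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf)
    missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"schedule CSV missing columns: {missing}")
    return df[SCHEDULE_COLUMNS]
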
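"""Stimulus designs: travelling-wave tone progressions and REP/CTRL block runs.

The tonotopy paradigm presents 14 pure tones in half-octave steps (88 Hz to
8 kHz), 2 s per tone, followed by a 4 s silent pause: a 32-s cycle repeated
15 times per 8-min run, in an ascending run and a descending run.

The repetition paradigm alternates REP blocks (eight different exemplars of
the same sound source) and CTRL blocks (eight different sound sources):
16 s of stimulation (eight 500-ms sounds with a 1500-ms inter-stimulus
interval) followed by 14 s of silence, i.e. 30-s blocks, 8 blocks per
condition and run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TONOTOPY_FREQUENCIES",
    "FrequencyProgression",
    "Block",
    "BlockDesign",
    "make_block_design",
]

#: Pure-tone frequencies of the travelling-wave paradigm (Hz, half-octave steps).
TONOTOPY_FREQUENCIES: tuple[float, ...] = (
    88.0, 125.0, 177.0, 250.0, 354.0, 500.0, 707.0,
    1000.0, 1414.0, 2000.0, 2828.0, 4000.0, 5657.0, 8000.0,
)


@dataclass(frozen=True)
class FrequencyProgression:
    """Ordered tone progression of one travelling-wave run."""

    frequencies: tuple[float, ...] = TONOTOPY_FREQUENCIES
    step_duration: float = 2.0
    pause_duration: float = 4.0
    n_cycles: int = 15
    direction: str = "ascending"

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        if self.direction not in ("ascending", "descending"):
            raise ValueError("direction must be 'ascending' or 'descending'")
        diffs = np.diff(freqs)
        if self.direction == "ascending" and not np.all(diffs > 0):
            raise ValueError("ascending progression must be strictly increasing")
        if self.direction == "descending" and not np.all(diffs < 0):
            raise ValueError("descending progression must be strictly decreasing")
        if self.step_duration <= 0 or self.pause_duration < 0 or self.n_cycles < 1:
            raise ValueError("invalid progression timing")

    @property
    def n_steps(self) -> int:
        return len(self.frequencies)

    @property
    def cycle_duration(self) -> float:
        return self.n_steps * self.step_duration + self.pause_duration

    @property
    def run_duration(self) -> float:
        return self.n_cycles * self.cycle_duration

    @property
    def ascending_frequencies(self) -> tuple[float, ...]:
        return tuple(sorted(self.frequencies))

    def reversed(self) -> "FrequencyProgression":
        return FrequencyProgression(
            frequencies=tuple(reversed(self.frequencies)),
            step_duration=self.step_duration,
            pause_duration=self.pause_duration,
            n_cycles=self.n_cycles,
            direction="descending" if self.direction == "ascending" else "ascending",
        )

    def onset_of_step(self, step: int, cycle: int = 0) -> float:
        return cycle * self.cycle_duration + step * self.step_duration

    def to_dict(self) -> dict:
        return {
            "frequencies_hz": list(self.frequencies),
            "step_duration_s": self.step_duration,
            "pause_duration_s": self.pause_duration,
            "n_cycles": self.n_cycles,
            "direction": self.direction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrequencyProgression":
        return cls(
            frequencies=tuple(d["frequencies_hz"]),
            step_duration=d["step_duration_s"],
            pause_duration=d["pause_duration_s"],
            n_cycles=d["n_cycles"],
            direction=d["direction"],
        )


@dataclass(frozen=True)
class Block:
    """One 30-s REP or CTRL block."""

    condition: str
    onset: float
    stimulation_duration: float = 16.0
    silence_duration: float = 14.0
    stimulus_onsets: tuple[float, ...] = ()

    @property
    def duration(self) -> float:
        return self.stimulation_duration + self.silence_duration


@dataclass(frozen=True)
class BlockDesign:
    """Ordered non-overlapping blocks of one repetition-experiment run."""

    blocks: tuple[Block, ...]
    tr: float
    run_duration: float

    def __post_init__(self) -> None:
        onsets = [b.onset for b in self.blocks]
        if sorted(onsets) != onsets:
            raise ValueError("blocks must be ordered by onset")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.onset + a.duration > b.onset + 1e-9:
                raise ValueError("blocks overlap")
        n_rep = sum(b.condition == "REP" for b in self.blocks)
        n_ctrl = sum(b.condition == "CTRL" for b in self.blocks)
        if n_rep != n_ctrl:
            raise ValueError("REP and CTRL block counts must be equal")

    @property
    def n_frames(self) -> int:
        return int(round(self.run_duration / self.tr))

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(b.condition for b in self.blocks)

    def blocks_of(self, condition: str) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.condition == condition)

    def to_dict(self) -> dict:
        return {
            "tr_s": self.tr,
            "run_duration_s": self.run_duration,
            "blocks": [
                {
                    "condition": b.condition,
                    "onset_s": b.onset,
                    "stimulation_duration_s": b.stimulation_duration,
                    "silence_duration_s": b.silence_duration,
                    "stimulus_onsets_s": list(b.stimulus_onsets),
                }
                for b in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockDesign":
        blocks = tuple(
            Block(
                condition=b["condition"],
                onset=b["onset_s"],
                stimulation_duration=b["stimulation_duration_s"],
                silence_duration=b["silence_duration_s"],
                stimulus_onsets=tuple(b["stimulus_onsets_s"]),
            )
            for b in d["blocks"]
        )
        return cls(blocks=blocks, tr=d["tr_s"], run_duration=d["run_duration_s"])


def make_block_design(
    n_blocks_per_condition: int = 8,
    tr: float = 2.0,
    seed: int = 0,
    order: str = "alternate",
    stimulation_duration: float = 16.0,
    silence_duration: float = 14.0,
    stimulus_duration: float = 0.5,
    inter_stimulus_interval: float = 1.5,
) -> BlockDesign:
    """Build a REP/CTRL block design.

    ``order='alternate'`` alternates REP and CTRL blocks starting with REP;
    ``order='shuffle'`` pseudo-randomises the block order (seeded) under the
    constraint of equal condition counts.  Eight stimulus onsets are placed
    every ``stimulus_duration + inter_stimulus_interval`` seconds from block
    onset.
    """
    if n_blocks_per_condition < 1:
        raise ValueError("n_blocks_per_condition must be >= 1")
    block_duration = stimulation_duration + silence_duration
    if abs(block_duration / tr - round(block_duration / tr)) > 1e-9:
        raise ValueError(f"tr={tr} does not divide the block duration {block_duration}")
    soa = stimulus_duration + inter_stimulus_interval
    n_stimuli = int(round(stimulation_duration / soa))
    rel_onsets = tuple(i * soa for i in range(n_stimuli))

    conditions = ["REP", "CTRL"] * n_blocks_per_condition
    if order == "shuffle":
        rng = np.random.default_rng(seed)
        rng.shuffle(conditions)
    elif order != "alternate":
        raise ValueError("order must be 'alternate' or 'shuffle'")

    blocks = []
    for i, cond in enumerate(conditions):
        onset = i * block_duration
        blocks.append(
            Block(
                condition=cond,
                onset=onset,
                stimulation_duration=stimulation_duration,
                silence_duration=silence_duration,
                stimulus_onsets=tuple(onset + r for r in rel_onsets),
            )
        )
    run_duration = block_duration * len(conditions)
    return BlockDesign(blocks=tuple(blocks), tr=tr, run_duration=run_duration)
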
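"""Session design: block composition, pseudorandomized trial order.

A session is three blocks of 32 trials.  The first block has no directional
bias (24 experimental trials, 12 leftward / 12 rightward, plus 8 timing
distractors, 4/4); the two following blocks are biased 75/25 toward the
group's direction (24 experimental, 18 bias-direction / 6 opposite, plus 8
distractors, 6/2).  Ordering constraints: in the no-bias block no more than
two consecutive trials move in the same direction; in biased blocks no two
consecutive trials move opposite to the bias.  Constraints are enforced over
the full 32-trial stream (experimental and distractor trials jointly), since
that is the sequence a participant experiences.

On experimental trials the go tone sounds at 3.0 s, 0.5 s after motion onset;
on timing-distractor trials it coincides with motion onset at 2.5 s.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, GenerationError, ParseError

__all__ = [
    "Direction",
    "BlockKind",
    "TrialSpec",
    "SessionDesign",
    "generate_block",
    "generate_session",
    "MOTION_ONSET_T",
    "EXPERIMENTAL_TONE_T",
]

MOTION_ONSET_T = 2.5
EXPERIMENTAL_TONE_T = 3.0
MAX_ATTEMPTS = 10_000


class Direction(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"

    @property
    def sign(self) -> int:
        return 1 if self is Direction.RIGHT else -1

    @property
    def opposite(self) -> "Direction":
        return Direction.LEFT if self is Direction.RIGHT else Direction.RIGHT


class BlockKind(str, enum.Enum):
    NO_BIAS = "no_bias"
    BIASED_1 = "biased_1"
    BIASED_2 = "biased_2"


@dataclass(frozen=True)
class TrialSpec:
    """One trial's design-level description."""

    trial_index: int
    direction: Direction
    is_distractor: bool
    block_kind: BlockKind
    bias_direction: Direction | None
    tone_time: float

    def __post_init__(self) -> None:
        if (self.bias_direction is None) != (self.block_kind is BlockKind.NO_BIAS):
            raise ConfigurationError(
                "bias_direction must be None iff block_kind is no_bias"
            )
        expected_tone = MOTION_ONSET_T if self.is_distractor else EXPERIMENTAL_TONE_T
        if abs(self.tone_time - expected_tone) > 1e-9:
            raise ConfigurationError(
                f"tone_time {self.tone_time} inconsistent with distractor flag"
            )


@dataclass
class SessionDesign:
    """Three ordered blocks of 32 trials for one participant."""

    blocks: list[list[TrialSpec]]
    seed: int
    group: Direction

    def all_trials(self) -> list[TrialSpec]:
        return [t for block in self.blocks for t in block]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, block in enumerate(self.blocks):
            for t in block:
                rows.append(
                    {
                        "block": block_kind_of(b).value,
                        "trial": t.trial_index,
                        "direction": t.direction.value,
                        "is_distractor": t.is_distractor,
                        "tone_time_s": t.tone_time,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "group": self.group.value,
            "blocks": [
                {
                    "kind": block_kind_of(b).value,
                    "bias_direction": (
                        block[0].bias_direction.value if block[0].bias_direction else None
                    ),
                    "trials": [
                        {
                            "trial": t.trial_index,
                            "direction": t.direction.value,
                            "is_distractor": t.is_distractor,
                            "tone_time_s": t.tone_time,
                        }
                        for t in block
                    ],
                }
                for b, block in enumerate(self.blocks)
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SessionDesign":
        text = Path(source).read_text() if isinstance(source, Path) else source
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid session JSON: {exc}") from exc
        blocks = []
        for blk in payload["blocks"]:
            kind = BlockKind(blk["kind"])
            bias = Direction(blk["bias_direction"]) if blk["bias_direction"] else None
            blocks.append(
                [
                    TrialSpec(
                        trial_index=tr["trial"],
                        direction=Direction(tr["direction"]),
                        is_distractor=bool(tr["is_distractor"]),
                        block_kind=kind,
                        bias_direction=bias,
                        tone_time=float(tr["tone_time_s"]),
                    )
                    for tr in blk["trials"]
                ]
            )
        return cls(blocks=blocks, seed=int(payload["seed"]), group=Direction(payload["group"]))


def block_kind_of(position: int) -> BlockKind:
    return (BlockKind.NO_BIAS, BlockKind.BIASED_1, BlockKind.BIASED_2)[position]


def _composition(kind: BlockKind, bias: Direction | None) -> list[tuple[Direction, bool]]:
    """The unordered (direction, is_distractor) multiset of one block."""
    if kind is BlockKind.NO_BIAS:
        items = [(Direction.LEFT, False)] * 12 + [(Direction.RIGHT, False)] * 12
        items += [(Direction.LEFT, True)] * 4 + [(Direction.RIGHT, True)] * 4
    else:
        assert bias is not None
        items = [(bias, False)] * 18 + [(bias.opposite, False)] * 6
        items += [(bias, True)] * 6 + [(bias.opposite, True)] * 2
    return items


def _order_valid(directions: list[Direction], kind: BlockKind, bias: Direction | None) -> bool:
    if kind is BlockKind.NO_BIAS:
        # no more than two same-direction trials in a row
        run = 1
        for prev, cur in zip(directions, directions[1:]):
            run = run + 1 if cur is prev else 1
            if run > 2:
                return False
        return True
    # biased blocks: opposite-to-bias trials never adjacent
    assert bias is not None
    for prev, cur in zip(directions, directions[1:]):
        if prev is not bias and cur is not bias:
            return False
    return True


def generate_block(
    kind: BlockKind,
    bias_direction: Direction | None,
    seed: int,
    max_attempts: int = MAX_ATTEMPTS,
) -> list[TrialSpec]:
    """Pseudorandomize one 32-trial block by rejection sampling.

    Shuffles the block composition uniformly and rejects orders violating the
    adjacency constraints; deterministic given ``seed``.
    """
    if (bias_direction is None) != (kind is BlockKind.NO_BIAS):
        raise ConfigurationError(
            f"bias_direction={bias_direction!r} inconsistent with kind={kind.value}"
        )
    items = _composition(kind, bias_direction)
    rng = np.random.default_rng(seed)
    order = np.arange(len(items))
    for _ in range(max_attempts):
        rng.shuffle(order)
        shuffled = [items[i] for i in order]
        if _order_valid([d for d, _ in shuffled], kind, bias_direction):
            return [
                TrialSpec(
                    trial_index=i,
                    direction=d,
                    is_distractor=dis,
                    block_kind=kind,
                    bias_direction=bias_direction,
                    tone_time=MOTION_ONSET_T if dis else EXPERIMENTAL_TONE_T,
                )
                for i, (d, dis) in enumerate(shuffled)
            ]
    raise GenerationError(
        f"no valid {kind.value} order found in {max_attempts} attempts (seed={seed})"
    )


def generate_session(group: Direction, seed: int) -> SessionDesign:
    """One participant's session: a no-bias block, then two biased blocks."""
    if not isinstance(group, Direction):
        raise ConfigurationError(f"group must be a Direction, got {group!r}")
    child_seeds = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    blocks = [
        generate_block(BlockKind.NO_BIAS, None, int(child_seeds[0])),
        generate_block(BlockKind.BIASED_1, group, int(child_seeds[1])),
        generate_block(BlockKind.BIASED_2, group, int(child_seeds[2])),
    ]
    return SessionDesign(blocks=blocks, seed=seed, group=group)
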
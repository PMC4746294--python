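"""Adaptive n-back task engine and information-scaled accuracy scoring.

Each 20-trial block presents simultaneous position and image streams; raw
percent accuracy is scaled by the working-memory load of the current N level
(weights 0.33 / 0.66 / 1.0 for 1-/2-/3-back), and the level adapts between
blocks: above 80 % block accuracy raises N, below 20 % lowers it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

DEFAULT_WEIGHTS = {1: 0.33, 2: 0.66, 3: 1.0}


@dataclass(frozen=True)
class NBackConfig:
    """Scoring weights and adaptive-rule thresholds.

    ``normalization`` selects the accuracy scaling: "information" (the
    default printed weights), "bitwise" (log2 of the image×position state
    space held for N items, normalised to the 3-back value) or "log"
    (log(1+N)/log(4)). The alternatives exist for sensitivity checks and
    change little in practice.
    """

    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    up_threshold: float = 80.0
    down_threshold: float = 20.0
    n_min: int = 1
    n_max: int = 3
    normalization: str = "information"

    def __post_init__(self) -> None:
        if not (0 < self.down_threshold < self.up_threshold < 100):
            raise ConfigurationError("need 0 < down < up < 100")
        ws = [self.weights.get(n) for n in range(self.n_min, self.n_max + 1)]
        if any(w is None for w in ws) or any(b <= a for a, b in zip(ws, ws[1:])):
            raise ConfigurationError("weights must be defined and strictly increasing in N")
        if self.normalization not in ("information", "bitwise", "log"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")

    def weight(self, n_level: int) -> float:
        if self.normalization == "information":
            w = self.weights.get(n_level)
            if w is None:
                raise ConfigurationError(f"no weight for N={n_level}")
            return w
        if self.normalization == "bitwise":
            # bits held for N items of a 24-image × 9-position stimulus space
            return n_level / self.n_max
        return float(np.log1p(n_level) / np.log1p(self.n_max))


@dataclass
class NBackBlock:
    """One block: the (constant) N level and per-trial correctness of the
    position and image decision streams."""

    block_index: int
    day: int
    n_level: int
    position_correct: np.ndarray
    image_correct: np.ndarray

    def __post_init__(self) -> None:
        self.position_correct = np.asarray(self.position_correct, dtype=bool)
        self.image_correct = np.asarray(self.image_correct, dtype=bool)
        if len(self.position_correct) != len(self.image_correct):
            raise DataError("stream lengths differ")

    @property
    def n_trials(self) -> int:
        return len(self.position_correct)

    @property
    def raw_accuracy(self) -> float:
        """Combined % accuracy pooling both decision streams equally."""
        pooled = np.concatenate([self.position_correct, self.image_correct])
        return 100.0 * float(pooled.mean())


@dataclass
class NBackLog:
    """All blocks of one subject's sessions, in temporal order."""

    subject: str
    blocks: list  # of NBackBlock

    def levels(self) -> list[int]:
        return [b.n_level for b in self.blocks]


def scale_accuracy(raw: float, n_level: int, config: NBackConfig | None = None) -> float:
    """Scale raw percent accuracy by the information-content weight of N."""
    config = config or NBackConfig()
    if not 0.0 <= raw <= 100.0:
        raise DataError(f"raw accuracy {raw} outside [0, 100]")
    return raw * config.weight(n_level)


def adaptive_update(block_accuracy: float, n_level: int,
                    config: NBackConfig | None = None) -> int:
    """Next N level from one block's combined accuracy: +1 above the upper
    threshold, −1 below the lower, clipped to [n_min, n_max]."""
    config = config or NBackConfig()
    if not 0.0 <= block_accuracy <= 100.0:
        raise DataError(f"accuracy {block_accuracy} outside [0, 100]")
    if block_accuracy > config.up_threshold:
        n_level += 1
    elif block_accuracy < config.down_threshold:
        n_level -= 1
    return int(np.clip(n_level, config.n_min, config.n_max))


def score_log(log: NBackLog, config: NBackConfig | None = None,
              expected_trials: int = 20) -> pd.DataFrame:
    """Per-block accuracies: position / image / combined, raw and scaled.

    Raises DataError if any block does not hold ``expected_trials`` trials.
    """
    config = config or NBackConfig()
    rows = []
    for b in log.blocks:
        if b.n_trials != expected_trials:
            raise DataError(
                f"block {b.block_index} has {b.n_trials} trials, expected {expected_trials}")
        raw_pos = 100.0 * float(b.position_correct.mean())
        raw_img = 100.0 * float(b.image_correct.mean())
        raw_comb = b.raw_accuracy
        w = config.weight(b.n_level)
        rows.append({
            "subject": log.subject, "day": b.day, "block": b.block_index,
            "n_level": b.n_level,
            "raw_position": raw_pos, "raw_image": raw_img, "raw_combined": raw_comb,
            "scaled_position": raw_pos * w, "scaled_image": raw_img * w,
            "scaled_combined": raw_comb * w,
        })
    return pd.DataFrame(rows)


def replay_levels(log: NBackLog, config: NBackConfig | None = None) -> list[int]:
    """Recompute the N trajectory by applying the adaptive rule to the logged
    block accuracies; must reproduce the logged levels exactly."""
    config = config or NBackConfig()
    levels = [config.n_min]
    for b in log.blocks[:-1]:
        levels.append(adaptive_update(b.raw_accuracy, b.n_level, config))
    return levels


@dataclass(frozen=True)
class LevelStatistics:
    blocks_to_reach_2: Optional[int]
    blocks_to_reach_3: Optional[int]
    mean_streak_at_2: float
    mean_streak_at_3: float


def _streaks(levels: list[int], level: int) -> list[int]:
    runs, run = [], 0
    for lv in levels:
        if lv == level:
            run += 1
        elif run:
            runs.append(run)
            run = 0
    if run:
        runs.append(run)
    return runs


def level_statistics(log: NBackLog) -> LevelStatistics:
    """Blocks-to-reach 2/3 (1-based block count; the level only changes
    between blocks) and mean consecutive-block streak length at 2/3."""
    levels = log.levels()

    def first_at(level):
        for i, lv in enumerate(levels):
            if lv == level:
                return i + 1
        return None

    s2, s3 = _streaks(levels, 2), _streaks(levels, 3)
    return LevelStatistics(
        blocks_to_reach_2=first_at(2),
        blocks_to_reach_3=first_at(3),
        mean_streak_at_2=float(np.mean(s2)) if s2 else 0.0,
        mean_streak_at_3=float(np.mean(s3)) if s3 else 0.0,
    )
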
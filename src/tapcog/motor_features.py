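"""Block-level motor features: frequency, rhythm variability, dwell time, accuracy.

Four features summarize each tapping block:

* **frequency** — key presses per second: press count / block duration.
* **variability** — sample standard deviation (n-1 denominator) of the natural
  log of inter-press intervals, where an interval is the difference between
  successive key-*down* times.  Dimensionless and invariant to rescaling or
  shifting the timestamps; it quantifies tapping arrhythmia.
* **dwell time** — mean key-held duration (key-down to key-up), milliseconds.
* **accuracy** — a weighted per-press index: 1 point for the expected key,
  2 for a key adjacent to it, 3 for any other key, summed and divided by the
  number of presses.  1.0 means every press hit its target; 3.0 is the worst
  possible.

Inter-press intervals use key-down times only (a press "counts" when the key is
fully down); key-up times enter dwell time alone.  Missing preconditions (too
few presses) yield ``nan`` with a warning, never an exception, and never a
silent zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tapcog.keystroke_io import Cohort, Hand, TappingBlock, TestType

__all__ = [
    "FEATURE_COLUMNS",
    "DEFAULT_ADJACENCY",
    "TargetScheme",
    "tapping_frequency",
    "tapping_variability",
    "dwell_time",
    "accuracy_score",
    "block_features",
    "build_feature_table",
    "feature_column",
]

#: Default QWERTY adjacency: physical neighbours of each protocol target key.
DEFAULT_ADJACENCY: dict[str, frozenset[str]] = {
    "space": frozenset({"c", "v", "b", "n", "m"}),
    "s": frozenset({"a", "d", "w", "e", "z", "x"}),
    "semicolon": frozenset({"l", "p", "o", "apostrophe", "period", "slash"}),
}

#: Target keys of the alternate-key test, in canonical starting order.
ALTERNATE_TARGETS = ("s", "semicolon")


@dataclass(frozen=True)
class TargetScheme:
    """Expected key per press ordinal, plus adjacency sets for scoring.

    ``single``-mode schemes expect one fixed key on every press.  ``alternate``
    schemes expect strict alternation between two target keys, anchored to
    whichever of the two is pressed first (a participant may legitimately start
    on either key); if the first press hits neither target, alternation is
    anchored to the first target in ``targets``.  The expectation advances on
    every press, right or wrong: the protocol demands one alternation per
    press, so a repeated key is scored against the key that *should* have been
    next.
    """

    targets: tuple[str, ...]
    adjacency: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_ADJACENCY)
    )

    @classmethod
    def for_block(cls, block: TappingBlock) -> "TargetScheme":
        if block.test_type is TestType.SINGLE_KEY:
            return cls(targets=("space",))
        return cls(targets=ALTERNATE_TARGETS)

    def expected_sequence(self, pressed: list[str]) -> list[str]:
        """The expected key for each press, given what was actually pressed."""
        if len(self.targets) == 1:
            return [self.targets[0]] * len(pressed)
        first, second = self.targets
        if pressed and pressed[0] == second:
            first, second = second, first
        return [first if i % 2 == 0 else second for i in range(len(pressed))]

    def press_points(self, pressed: str, expected: str) -> int:
        if pressed == expected:
            return 1
        if pressed in self.adjacency.get(expected, frozenset()):
            return 2
        return 3


def _nan_with_warning(message: str) -> float:
    warnings.warn(message, stacklevel=3)
    return math.nan


def tapping_frequency(block: TappingBlock) -> float:
    """Key presses per second: press count divided by block duration."""
    return block.n_presses / block.duration_s


def tapping_variability(block: TappingBlock) -> float:
    """Sample SD of natural-log inter-press (key-down to key-down) intervals.

    Requires at least three presses (two intervals); fewer yields ``nan`` with
    a warning.  Non-positive intervals (simultaneous key-downs) are excluded,
    since their log is undefined.
    """
    downs = np.array([e.down_ms for e in block.events], dtype=float)
    intervals = np.diff(downs)
    intervals = intervals[intervals > 0]
    if intervals.size < 2:
        return _nan_with_warning(
            f"variability undefined with {block.n_presses} press(es); need >= 3"
        )
    logs = np.log(intervals)
    if np.all(logs == logs[0]):  # perfectly rhythmic: exactly zero, no fp residue
        return 0.0
    return float(np.std(logs, ddof=1))


def dwell_time(block: TappingBlock) -> float:
    """Mean key-held duration in milliseconds over all presses."""
    if block.n_presses == 0:
        return _nan_with_warning("dwell time undefined with zero presses")
    return float(np.mean([e.up_ms - e.down_ms for e in block.events]))


def accuracy_score(
    block: TappingBlock, target_scheme: TargetScheme | None = None
) -> float:
    """Weighted accuracy index in [1, 3]; 1.0 iff every press hit its expected key."""
    if block.n_presses == 0:
        return _nan_with_warning("accuracy undefined with zero presses")
    scheme = target_scheme or TargetScheme.for_block(block)
    pressed = [e.key_label for e in block.events]
    expected = scheme.expected_sequence(pressed)
    points = sum(scheme.press_points(p, x) for p, x in zip(pressed, expected))
    return points / len(pressed)


def block_features(
    block: TappingBlock, target_scheme: TargetScheme | None = None
) -> dict[str, float]:
    """All four features of one block."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            "freq": tapping_frequency(block),
            "var": tapping_variability(block),
            "dwell": dwell_time(block),
            "acc": accuracy_score(block, target_scheme),
        }


# ---------------------------------------------------------------------------
# per-participant feature table
# ---------------------------------------------------------------------------


def feature_column(
    test_type: TestType, feature: str, hand: Hand = Hand.DOMINANT, block_index: int = 1
) -> str:
    """Deterministic column name, e.g. ``sk_freq_b1`` or ``ak_var_nd``."""
    if TestType(test_type) is TestType.SINGLE_KEY:
        return f"sk_{feature}_b{block_index}"
    suffix = "d" if Hand(hand) is Hand.DOMINANT else "nd"
    return f"ak_{feature}_{suffix}"


def _columns() -> list[str]:
    cols = [
        feature_column(TestType.SINGLE_KEY, f, block_index=b)
        for f in ("freq", "var", "dwell", "acc")
        for b in (1, 2, 3, 4)
    ]
    cols += [
        feature_column(TestType.ALTERNATE_KEY, f, hand=h)
        for f in ("freq", "var", "dwell", "acc")
        for h in (Hand.DOMINANT, Hand.NON_DOMINANT)
    ]
    return cols


#: Stable column order of the per-participant feature table (24 features).
FEATURE_COLUMNS: list[str] = _columns()

#: The three candidate-feature sets used in model comparison.
SINGLE_KEY_FEATURES = [c for c in FEATURE_COLUMNS if c.startswith("sk_")]
ALTERNATE_KEY_FEATURES = [c for c in FEATURE_COLUMNS if c.startswith("ak_")]


def build_feature_table(
    cohort: Cohort,
    adjacency: dict[str, frozenset[str]] | None = None,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """One row per participant, 24 feature columns in :data:`FEATURE_COLUMNS` order.

    Missing blocks leave their four cells ``NaN`` — never silent zeros.
    Duplicate blocks for the same protocol slot also yield ``NaN`` (ambiguous).
    ``columns`` restricts computation (and output) to a subset of features.
    """
    out_cols = FEATURE_COLUMNS if columns is None else list(columns)
    wanted = set(out_cols)
    fns = {
        "freq": tapping_frequency,
        "var": tapping_variability,
        "dwell": dwell_time,
        "acc": accuracy_score,
    }
    rows = []
    for p in cohort.participants:
        row: dict[str, float] = {"participant_id": p.participant_id}
        counts: dict[tuple, int] = {}
        for b in p.blocks:
            counts[b.key()] = counts.get(b.key(), 0) + 1
        for b in p.blocks:
            if counts[b.key()] > 1:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for fname, fn in fns.items():
                    col = feature_column(
                        b.test_type, fname, hand=b.hand, block_index=b.block_index
                    )
                    if col not in wanted:
                        continue
                    if fname == "acc" and adjacency is not None:
                        scheme = TargetScheme.for_block(b)
                        scheme = TargetScheme(targets=scheme.targets, adjacency=adjacency)
                        row[col] = accuracy_score(b, scheme)
                    else:
                        row[col] = fn(b)
        rows.append(row)
    table = pd.DataFrame(rows, columns=["participant_id"] + out_cols)
    return table.set_index("participant_id")
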
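"""Target-detection task design generator.

The task presents single characters of three types -- digits (DIG), letters
(LET) and false fonts (FF) -- in separate parts, each part consisting of
blocks of pseudorandomized items.  A small number of target trials (animal /
tool pictures requiring a button press) are interleaved; only non-target
trials enter the ERP analysis.  Defaults reproduce the study design: four
blocks of 15 items per condition with six targets, i.e. 54 non-target trials
per condition; stimuli last 613 ms followed by an ISI of 331 or 695 ms, with
fixation periods of 6 or 12 s between blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONDITIONS = ("DIG", "LET", "FF")


@dataclass
class DesignSpec:
    """Parameters of the three-condition target-detection task."""

    conditions: tuple[str, ...] = CONDITIONS
    blocks_per_condition: int = 4
    items_per_block: int = 15
    targets_per_condition: int = 6
    stimulus_duration_ms: float = 613.0
    isi_choices_ms: tuple[float, ...] = (331.0, 695.0)
    fixation_gaps_ms: tuple[float, ...] = (6000.0, 12000.0)

    def __post_init__(self) -> None:
        n_items = self.blocks_per_condition * self.items_per_block
        if self.targets_per_condition > n_items:
            raise ValueError("more targets than items per condition")
        durations = (self.stimulus_duration_ms, *self.isi_choices_ms, *self.fixation_gaps_ms)
        if any(d <= 0 for d in durations):
            raise ValueError("all durations must be positive")

    @property
    def nontargets_per_condition(self) -> int:
        return self.blocks_per_condition * self.items_per_block - self.targets_per_condition


def make_design(spec: DesignSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate an event table for one recording session.

    Returns a DataFrame with columns ``onset_ms`` (stimulus onset relative to
    recording start), ``condition``, ``is_target`` and ``block`` (global block
    id).  Condition parts are presented in pseudorandom order; within a block
    item order (target vs non-target slots) is pseudorandomized; consecutive
    onsets within a block are separated by the stimulus duration plus a
    sampled ISI.
    """
    spec = spec or DesignSpec()
    rng = np.random.default_rng(seed)

    rows = []
    t = float(rng.choice(spec.fixation_gaps_ms))  # initial fixation
    block_id = 0
    cond_order = list(spec.conditions)
    rng.shuffle(cond_order)
    for cond in cond_order:
        n_items = spec.blocks_per_condition * spec.items_per_block
        flags = np.zeros(n_items, dtype=bool)
        flags[rng.choice(n_items, size=spec.targets_per_condition, replace=False)] = True
        for b in range(spec.blocks_per_condition):
            block_flags = flags[b * spec.items_per_block : (b + 1) * spec.items_per_block]
            for is_target in block_flags:
                rows.append(
                    {
                        "onset_ms": t,
                        "condition": cond,
                        "is_target": bool(is_target),
                        "block": block_id,
                    }
                )
                t += spec.stimulus_duration_ms + float(rng.choice(spec.isi_choices_ms))
            t += float(rng.choice(spec.fixation_gaps_ms))
            block_id += 1
    return pd.DataFrame(rows)


def write_events(events: pd.DataFrame, path) -> None:
    """Write an event table as tab-separated text."""
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_target"] = df["is_target"].astype(bool)
    return df
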
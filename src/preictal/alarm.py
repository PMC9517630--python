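"""Two-step "k of n" smoothing of window predictions into segment alarms.

A 10-min segment yields 60 window-level 0/1 predictions.  Stage 1 partitions
them into consecutive non-overlapping groups of 6 and emits 1 for a group
with >= 3 ones; stage 2 emits the final segment decision, 1 iff >= 5 of the
10 group outputs are 1.  Both stages are monotone threshold functions, so a
window prediction flipping 0 -> 1 can never cancel an alarm.

Segment decisions are tallied against the true categories: an alarmed
pre-seizure (category A) segment is a predicted seizure, a silent one a
miss, and an alarmed interictal (category B) segment a false alarm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AlarmSpec", "AlarmReport", "kofn_stage1", "kofn_stage2",
           "decide_segment", "tally", "alarm_from_oof"]


@dataclass(frozen=True)
class AlarmSpec:
    k1: int = 3
    n1: int = 6
    k2: int = 5
    n2: int = 10


@dataclass
class AlarmReport:
    decisions: list[int]
    labels: list[int]
    n_seizures: int
    n_predicted: int
    n_missed: int
    n_false_alarms: int

    def to_dict(self) -> dict:
        return {"n_seizures": self.n_seizures,
                "n_predicted": self.n_predicted,
                "n_missed": self.n_missed,
                "n_false_alarms": self.n_false_alarms,
                "decisions": self.decisions,
                "labels": self.labels}

    def to_frame(self) -> pd.DataFrame:
        """One-row table in the shape of the per-patient results tables."""
        return pd.DataFrame([{
            "n_seizures": self.n_seizures,
            "n_predicted": self.n_predicted,
            "n_missed": self.n_missed,
            "n_false_alarms": self.n_false_alarms,
        }])


def _check_binary(seq: np.ndarray) -> np.ndarray:
    seq = np.asarray(seq, dtype=np.int64)
    if seq.ndim != 1 or not np.isin(seq, (0, 1)).all():
        raise ValueError("sequence must be 1-D with values in {0, 1}")
    return seq


def kofn_stage1(seq, group: int = 6, k: int = 3) -> np.ndarray:
    """Group-wise k-of-n over consecutive non-overlapping groups."""
    seq = _check_binary(seq)
    if len(seq) % group != 0:
        raise ValueError(f"length {len(seq)} not divisible by group {group}")
    sums = seq.reshape(-1, group).sum(axis=1)
    return (sums >= k).astype(np.int64)


def kofn_stage2(seq, k: int = 5, n: int = 10) -> int:
    """Final decision: 1 iff at least k of the n stage-1 outputs are 1."""
    seq = _check_binary(seq)
    if len(seq) != n:
        raise ValueError(f"stage-2 expects length {n}, got {len(seq)}")
    return int(seq.sum() >= k)


def decide_segment(window_preds, spec: AlarmSpec = AlarmSpec()) -> int:
    """Both stages composed over one segment's window predictions."""
    stage1 = kofn_stage1(window_preds, group=spec.n1, k=spec.k1)
    return kofn_stage2(stage1, k=spec.k2, n=spec.n2)


def tally(decisions, labels) -> AlarmReport:
    """Event-level bookkeeping from per-segment decisions and true labels."""
    decisions = [int(d) for d in decisions]
    labels = [int(l) for l in labels]
    if len(decisions) != len(labels):
        raise ValueError("decisions and labels must align")
    n_seiz = sum(1 for l in labels if l == 1)
    n_pred = sum(1 for d, l in zip(decisions, labels) if l == 1 and d == 1)
    n_missed = n_seiz - n_pred
    n_false = sum(1 for d, l in zip(decisions, labels) if l == 0 and d == 1)
    return AlarmReport(decisions=decisions, labels=labels, n_seizures=n_seiz,
                       n_predicted=n_pred, n_missed=n_missed,
                       n_false_alarms=n_false)


def alarm_from_oof(meta: pd.DataFrame, oof_pred: np.ndarray,
                   spec: AlarmSpec = AlarmSpec()) -> AlarmReport:
    """Reassemble out-of-fold window predictions per segment and decide.

    Each window is predicted exactly once across the CV folds, so grouping
    the row-aligned predictions by segment index and sorting by window index
    restores every segment's full 60-window sequence.
    """
    decisions, labels = [], []
    frame = meta.copy()
    frame["pred"] = np.asarray(oof_pred, dtype=np.int64)
    for seg_idx, grp in frame.groupby("segment_index", sort=True):
        grp = grp.sort_values("window_index")
        decisions.append(decide_segment(grp["pred"].to_numpy(), spec))
        labels.append(int(grp["label"].iloc[0]))
    return tally(decisions, labels)
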
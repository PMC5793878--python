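"""Scoring called regions against ground-truth intervals."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["match_intervals", "recovery_scores"]


def match_intervals(
    called: pd.DataFrame, truth: pd.DataFrame, min_reciprocal_overlap: float = 0.5
) -> pd.DataFrame:
    """Greedy matching of called to truth intervals by reciprocal overlap.

    A pair matches when the intersection covers at least
    ``min_reciprocal_overlap`` of BOTH intervals.  Returns the called
    frame with ``matched_truth`` (truth row index or -1).
    """
    matched = np.full(len(called), -1, dtype=int)
    for i, c in enumerate(called.itertuples(index=False)):
        for j, t in enumerate(truth.itertuples(index=False)):
            if t.chrom != c.chrom:
                continue
            ov = min(c.end, t.end) - max(c.start, t.start)
            if ov <= 0:
                continue
            ro = min(ov / (c.end - c.start), ov / (t.end - t.start))
            if ro >= min_reciprocal_overlap:
                matched[i] = j
                break
    out = called.reset_index(drop=True).copy()
    out["matched_truth"] = matched
    return out


def recovery_scores(
    called: pd.DataFrame, truth: pd.DataFrame, min_reciprocal_overlap: float = 0.5
) -> dict[str, float]:
    """Precision and recall of called intervals against planted truth."""
    if len(called) == 0:
        return {"precision": float("nan"), "recall": 0.0, "n_called": 0, "n_truth": len(truth)}
    m = match_intervals(called, truth, min_reciprocal_overlap)
    hit = m["matched_truth"].to_numpy()
    return {
        "precision": float((hit >= 0).mean()),
        "recall": float(len(set(hit[hit >= 0])) / max(len(truth), 1)),
        "n_called": len(called),
        "n_truth": len(truth),
    }
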
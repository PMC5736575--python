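"""Aggregate statistics and cohort summaries.

Saccade reaction times are summarized as sample mean/std with a 10 ms
histogram; cohort accuracy is averaged per patient first, then across
patients (mean +/- SEM over the 20-patient cohort).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SRTStats", "srt_statistics", "cohort_summary", "detection_gain"]


@dataclass(frozen=True)
class SRTStats:
    """Saccade reaction-time summary; ``empty`` marks a no-saccades run."""

    n: int
    mean: float | None
    std: float | None
    bin_edges: np.ndarray | None
    counts: np.ndarray | None

    @property
    def empty(self) -> bool:
        return self.n == 0


def srt_statistics(latencies, bin_width: float = 10.0) -> SRTStats:
    """Mean, std (ddof=1) and fixed-width histogram of saccade latencies (ms).

    An empty latency list yields an explicit no-saccades marker rather than
    zeros (a patient who never saccades is not a patient with 0 ms SRT).
    """
    lat = np.asarray(list(latencies), dtype=float)
    if lat.size == 0:
        return SRTStats(n=0, mean=None, std=None, bin_edges=None, counts=None)
    lo = bin_width * np.floor(lat.min() / bin_width)
    hi = bin_width * np.ceil(lat.max() / bin_width)
    if hi == lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(lat, bins=edges)
    return SRTStats(
        n=lat.size,
        mean=float(lat.mean()),
        std=float(lat.std(ddof=1)) if lat.size > 1 else 0.0,
        bin_edges=edges,
        counts=counts,
    )


def cohort_summary(summaries: list[dict]) -> pd.DataFrame:
    """Cohort table from per-patient test summaries.

    One row per (test, eye_condition): accuracy mean +/- SEM across
    patients, pooled triggered-saccade percentage and counts, and the
    restitution / saccade-mediated detection split.
    """
    if not summaries:
        return pd.DataFrame(
            columns=[
                "test", "eye_condition", "n_patients", "n_trials",
                "accuracy_mean_pct", "accuracy_sem_pct",
                "n_saccades", "saccade_pct", "n_restitution", "n_saccade_mediated",
                "srt_mean", "srt_std",
            ]
        )
    df = pd.DataFrame([{k: v for k, v in s.items() if k != "latencies"} for s in summaries])
    rows = []
    for (test, eye), grp in df.groupby(["test", "eye_condition"]):
        acc = grp["accuracy_pct"].to_numpy()
        pooled_lat = np.concatenate(
            [np.asarray(s["latencies"], dtype=float)
             for s in summaries
             if s["test"] == test and s["eye_condition"] == eye]
        ) if len(grp) else np.array([])
        stats = srt_statistics(pooled_lat)
        n_trials = int(grp["n_trials"].sum())
        rows.append(
            {
                "test": test,
                "eye_condition": eye,
                "n_patients": len(grp),
                "n_trials": n_trials,
                "accuracy_mean_pct": float(acc.mean()),
                "accuracy_sem_pct": float(acc.std(ddof=1) / np.sqrt(len(acc)))
                if len(acc) > 1
                else 0.0,
                "n_saccades": int(grp["n_saccades"].sum()),
                "saccade_pct": 100.0 * float(grp["n_saccades"].sum()) / n_trials,
                "n_restitution": int(grp["n_restitution"].sum()),
                "n_saccade_mediated": int(grp["n_saccade_mediated"].sum()),
                "srt_mean": stats.mean,
                "srt_std": stats.std,
            }
        )
    return pd.DataFrame(rows)


def detection_gain(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Delta = post - pre detection accuracy on matched (test, eye_condition)."""
    key = ["test", "eye_condition"]
    merged = pre.merge(post, on=key, suffixes=("_pre", "_post"))
    merged["delta_pct"] = (
        merged["accuracy_mean_pct_post"] - merged["accuracy_mean_pct_pre"]
    )
    return merged[key + ["accuracy_mean_pct_pre", "accuracy_mean_pct_post", "delta_pct"]]
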
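"""Cluster characterization: descriptive tables, day-state distributions, patterns.

Per cluster this module reproduces the standard trajectory-study descriptives:
follow-up duration, share discontinued, initiating / stopping / ever-used
states per channel, mean days spent in each state (state-day counts over all
states of a channel, DISC included, always sum to the 365-day window),
cumulative treatment steps, demographics, plus day-by-day state-proportion
matrices (the numeric content of stacked sequence-distribution plots) and
transition / subsequence pattern counts.

"Stopping" states are measured on the last treated day, not the first
discontinued day: they describe the regimen in place just before treatment
ended. Percentage shares of follow-up time are computed as mean state-days
divided by mean follow-up days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortPatient
from .mcsa import PartitionQuality, cut_tree, distance_matrix, scan_partitions, ward_cluster
from .sequences import CHANNEL_STATES, CHANNELS, MultiChannelSequence


def _channel_array(sequences: Sequence[MultiChannelSequence], channel: str) -> np.ndarray:
    return np.stack([getattr(s, f"{channel}_seq") for s in sequences])


def _disc_code(channel: str) -> int:
    return len(CHANNEL_STATES[channel]) - 1


def follow_up_days(sequences: Sequence[MultiChannelSequence]) -> np.ndarray:
    """Days before discontinuation per patient (the full window if never DISC)."""
    arr = _channel_array(sequences, "class")
    return (arr != _disc_code("class")).sum(axis=1)


def time_in_state(sequences: Sequence[MultiChannelSequence], channel: str) -> pd.DataFrame:
    """Mean and sd of days spent in each state of a channel, over patients."""
    if not sequences:
        raise ValueError("empty cluster")
    arr = _channel_array(sequences, channel)
    states = CHANNEL_STATES[channel]
    counts = np.stack([(arr == i).sum(axis=1) for i in range(len(states))], axis=1)
    return pd.DataFrame(
        {
            "state": states,
            "mean_days": counts.mean(axis=0),
            "sd_days": counts.std(axis=0, ddof=1) if counts.shape[0] > 1 else np.zeros(len(states)),
        }
    )


def endpoint_states(sequences: Sequence[MultiChannelSequence]) -> dict:
    """Initiating (day-0) and stopping (last treated day) state tables per channel."""
    if not sequences:
        raise ValueError("empty cluster")
    n = len(sequences)
    fu = follow_up_days(sequences)
    out: dict = {"n": n, "pct_discontinued": 100.0 * float((fu < len(sequences[0].class_seq)).mean())}
    for channel in CHANNELS:
        arr = _channel_array(sequences, channel)
        states = CHANNEL_STATES[channel][:-1]  # DISC cannot initiate or stop
        init = arr[:, 0]
        stop = arr[np.arange(n), fu - 1]
        for name, vec in (("initiating", init), ("stopping", stop)):
            counts = [(int((vec == i).sum())) for i in range(len(states))]
            out[f"{name}_{channel}"] = pd.DataFrame(
                {"state": states, "n": counts, "pct": [100.0 * c / n for c in counts]}
            )
    return out


def ever_used(sequences: Sequence[MultiChannelSequence], channel: str = "class") -> pd.DataFrame:
    """Share of patients with at least one day in each state (states may overlap)."""
    arr = _channel_array(sequences, channel)
    states = CHANNEL_STATES[channel][:-1]
    n = arr.shape[0]
    counts = [int(((arr == i).any(axis=1)).sum()) for i in range(len(states))]
    return pd.DataFrame({"state": states, "n": counts, "pct": [100.0 * c / n for c in counts]})


def _runs(arr_row: np.ndarray, disc: int) -> list[int]:
    vals = arr_row[arr_row != disc]
    if vals.size == 0:
        return []
    keep = np.concatenate(([True], vals[1:] != vals[:-1]))
    return list(vals[keep])


def mine_patterns(
    sequences: Sequence[MultiChannelSequence],
    channel: str,
    kind: str = "transition",
) -> pd.DataFrame:
    """Count ordered state-pair patterns over distinct-state runs, DISC excluded.

    ``transition``: adjacent run pairs a->b (immediate changes).
    ``subsequence``: ordered run pairs a...b allowing intervening runs (which
    also admits a...a returns). A patient counts once per distinct pattern.
    """
    if kind not in ("transition", "subsequence"):
        raise ValueError(f"kind must be 'transition' or 'subsequence', got {kind!r}")
    states = CHANNEL_STATES[channel]
    disc = _disc_code(channel)
    n = len(sequences)
    tally: dict[tuple[str, str], int] = {}
    for s in sequences:
        runs = _runs(getattr(s, f"{channel}_seq"), disc)
        found = set()
        if kind == "transition":
            for a, b in zip(runs, runs[1:]):
                found.add((states[a], states[b]))
        else:
            for i, a in enumerate(runs):
                for b in runs[i + 1 :]:
                    found.add((states[a], states[b]))
        for pat in found:
            tally[pat] = tally.get(pat, 0) + 1
    df = pd.DataFrame(
        [
            {"pattern": f"{a}>{b}" if kind == "transition" else f"{a}...{b}",
             "from_state": a, "to_state": b, "kind": kind, "n": c, "pct": 100.0 * c / n}
            for (a, b), c in tally.items()
        ]
    )
    if df.empty:
        return pd.DataFrame(columns=["pattern", "from_state", "to_state", "kind", "n", "pct"])
    return df.sort_values(["pct", "pattern"], ascending=[False, True], ignore_index=True)


def state_distribution(sequences: Sequence[MultiChannelSequence], channel: str) -> pd.DataFrame:
    """Day x state proportion matrix (rows sum to 1) for one channel."""
    if not sequences:
        raise ValueError("empty cluster")
    arr = _channel_array(sequences, channel)
    states = CHANNEL_STATES[channel]
    props = np.stack([(arr == i).mean(axis=0) for i in range(len(states))], axis=1)
    return pd.DataFrame(props, columns=list(states), index=pd.RangeIndex(arr.shape[1], name="day"))


@dataclass
class ClusterSummary:
    cluster: int
    n: int
    table: pd.DataFrame  # tidy block/state/statistic rows


def cluster_summaries(
    cohort: Sequence[CohortPatient],
    sequences: Sequence[MultiChannelSequence],
    labels: Sequence[int],
) -> pd.DataFrame:
    """Tidy per-cluster descriptive table (one row per cluster/block/state/stat).

    Raw unrounded values are retained; round for display only.
    """
    labels = np.asarray(labels)
    by_id = {c.patient_id: c for c in cohort}
    rows = []
    window = len(sequences[0].class_seq)
    for cl in np.unique(labels):
        idx = np.where(labels == cl)[0]
        seqs = [sequences[i] for i in idx]
        members = [by_id[s.patient_id] for s in seqs if s.patient_id in by_id]
        n = len(seqs)
        fu = follow_up_days(seqs)

        def add(block, state, stat, value):
            rows.append(
                {"cluster": int(cl), "n": n, "block": block, "state": state,
                 "statistic": stat, "value": float(value)}
            )

        add("follow_up", "days", "mean", fu.mean())
        add("follow_up", "days", "sd", fu.std(ddof=1) if n > 1 else 0.0)
        add("follow_up", "discontinued", "pct", 100.0 * (fu < window).mean())
        steps = np.array([int((s.step_seq[: max(f, 1) ]).max()) + 1 for s, f in zip(seqs, fu)])
        add("steps", "cumulative", "mean", steps.mean())
        add("steps", "cumulative", "sd", steps.std(ddof=1) if n > 1 else 0.0)
        ep = endpoint_states(seqs)
        for channel in CHANNELS:
            tis = time_in_state(seqs, channel)
            for _, r in tis.iterrows():
                add(f"time_{channel}", r["state"], "mean", r["mean_days"])
                add(f"time_{channel}", r["state"], "sd", r["sd_days"])
            for name in ("initiating", "stopping"):
                for _, r in ep[f"{name}_{channel}"].iterrows():
                    add(f"{name}_{channel}", r["state"], "n", r["n"])
                    add(f"{name}_{channel}", r["state"], "pct", r["pct"])
        for _, r in ever_used(seqs, "class").iterrows():
            add("ever_used_class", r["state"], "n", r["n"])
            add("ever_used_class", r["state"], "pct", r["pct"])
        if members:
            ages = np.array([m.age_at_index for m in members])
            add("demographics", "age", "mean", ages.mean())
            add("demographics", "age", "sd", ages.std(ddof=1) if len(ages) > 1 else 0.0)
            for lo, hi in ((18, 30), (31, 40), (41, 50), (51, 65)):
                share = 100.0 * ((ages >= lo) & (ages <= hi)).mean()
                add("demographics", f"age_{lo}_{hi}", "pct", share)
            add("demographics", "female", "pct",
                100.0 * np.mean([m.sex == "female" for m in members]))
    return pd.DataFrame(rows)


def time_share(mean_state_days: float, mean_follow_up: float) -> float:
    """Percent of follow-up time spent in a state: mean days / mean duration."""
    return 100.0 * mean_state_days / mean_follow_up


def stratified_run(
    cohort: Sequence[CohortPatient],
    sequences: Sequence[MultiChannelSequence],
    stratum_of: dict[str, str],
    k: int = 4,
    mode: str = "sum",
    k_min: int = 2,
    k_max: int = 8,
) -> dict[str, dict]:
    """Repeat distances -> Ward -> partition scan -> summaries per stratum.

    ``stratum_of`` maps patient_id to a stratum label (e.g. sex). Strata with
    fewer than 2 patients are skipped with a warning entry.
    """
    out: dict[str, dict] = {}
    for stratum in sorted(set(stratum_of.values())):
        idx = [i for i, s in enumerate(sequences) if stratum_of[s.patient_id] == stratum]
        if len(idx) < 2:
            out[stratum] = {"skipped": True, "reason": f"only {len(idx)} patient(s)"}
            continue
        seqs = [sequences[i] for i in idx]
        dm = distance_matrix(seqs, mode=mode)
        Z = ward_cluster(dm)
        kk = min(k, len(idx))
        labels = cut_tree(Z, kk)
        quality = scan_partitions(Z, dm, k_min, min(k_max, len(idx)))
        out[stratum] = {
            "skipped": False,
            "n": len(idx),
            "distance": dm,
            "linkage": Z,
            "labels": labels,
            "scan": quality,
            "summary": cluster_summaries(cohort, seqs, labels),
        }
    return out
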
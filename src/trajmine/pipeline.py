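"""End-to-end pipeline: cohort -> sequences -> clustering -> characterization.

`run_pipeline` executes every stage on CSV inputs (or a freshly simulated
cohort), writes all artifacts into a run directory, and records a manifest
with the config, input checksums and every method decision in effect, so a
rerun with the same inputs, config and seed is bit-for-bit reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .characterize import cluster_summaries, mine_patterns, state_distribution
from .cohort import build_cohort
from .config import RunConfig
from .data_model import read_class_map, read_ehr_tables
from .mcsa import cut_tree, distance_matrix, scan_partitions, ward_cluster
from .sequences import CHANNELS, build_patient_sequence, sequences_to_frame
from .synthetic_data import generate_cohort, write_cohort

log = logging.getLogger("trajmine")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_sequences_for_cohort(cohort, prescriptions, class_map, config: RunConfig):
    rx_by_pid: dict[str, list] = {}
    for p in prescriptions:
        rx_by_pid.setdefault(p.patient_id, []).append(p)
    sequences = []
    for cp in cohort:
        rx = [p for p in rx_by_pid.get(cp.patient_id, [])
              if p.dispense_date >= cp.index.index_date]
        seq, _events = build_patient_sequence(
            rx,
            cp.window,
            class_map,
            cp.index.index_date,
            refill_gap=config.refill_gap,
            min_supply=config.min_supply,
            switch_window=config.switch_window,
            follow_up_days=config.follow_up_days,
        )
        sequences.append(seq)
    return sequences


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    prescriptions_path: str | Path | None = None,
    diagnoses_path: str | Path | None = None,
    patients_path: str | Path | None = None,
    classmap_path: str | Path | None = None,
    simulate_n: int | None = None,
    k: int = 4,
) -> dict:
    """Run every stage and write artifacts + manifest.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    stage = "ingest"
    try:
        if simulate_n is not None:
            log.info("stage %s: simulating %d patients (seed %d)", stage, simulate_n, config.seed)
            syn = generate_cohort(simulate_n, seed=config.seed, study_year=config.study_year)
            write_cohort(syn, out / "simulated")
            prescriptions, diagnoses, patients = syn.prescriptions, syn.diagnoses, syn.patients
            class_map = syn.class_map
            for f in sorted((out / "simulated").glob("*.csv")):
                inputs[f.name] = _sha256(f)
        else:
            for p in (prescriptions_path, diagnoses_path, patients_path, classmap_path):
                if p is None:
                    raise ValueError("input paths required unless simulate_n is given")
                inputs[Path(p).name] = _sha256(Path(p))
            prescriptions, diagnoses, patients = read_ehr_tables(
                prescriptions_path, diagnoses_path, patients_path
            )
            class_map = read_class_map(classmap_path)

        stage = "build-cohort"
        cohort, attrition = build_cohort(prescriptions, diagnoses, patients, class_map, config)
        log.info("stage %s: %d candidates -> %d eligible", stage, len(patients), len(cohort))
        attrition.to_csv(out / "attrition.csv", index=False)
        pd.DataFrame(
            {
                "patient_id": [c.patient_id for c in cohort],
                "index_date": [c.index.index_date.isoformat() for c in cohort],
                "index_drug": [c.index.index_drug for c in cohort],
                "index_class": [c.index.index_class for c in cohort],
                "end_day": [c.window.end_day for c in cohort],
                "episode_ended": [int(c.window.episode_ended) for c in cohort],
                "sex": [c.sex for c in cohort],
                "age_at_index": [c.age_at_index for c in cohort],
            }
        ).to_csv(out / "cohort.csv", index=False)
        if len(cohort) < 2:
            raise ValueError("fewer than 2 eligible patients; nothing to cluster")

        stage = "build-sequences"
        sequences = build_sequences_for_cohort(cohort, prescriptions, class_map, config)
        sequences_to_frame(sequences).to_csv(out / "sequences.csv", index=False)
        log.info("stage %s: %d x %d-day multi-channel sequences", stage, len(sequences),
                 config.follow_up_days)

        stage = "cluster"
        dm = distance_matrix(sequences, mode=config.distance_mode, progress_logger=log.info)
        dm.save(out / "distances.npy")
        Z = ward_cluster(dm)
        np.save(out / "linkage.npy", Z)
        quality = scan_partitions(Z, dm, config.k_min, min(config.k_max, dm.n))
        pd.DataFrame(
            {
                "k": [q.k for q in quality],
                "asw": [q.asw for q in quality],
                "reasonable": [q.reasonable for q in quality],
                "sizes": [json.dumps(list(q.sizes)) for q in quality],
            }
        ).to_csv(out / "partition_scan.csv", index=False)
        kk = min(k, dm.n)
        labels = cut_tree(Z, kk)
        pd.DataFrame({"patient_id": dm.ids, "cluster": labels}).to_csv(
            out / "labels.csv", index=False
        )
        log.info("stage %s: cut at k=%d, sizes %s", stage,
                 kk, np.bincount(labels)[1:].tolist())

        stage = "characterize"
        summary = cluster_summaries(cohort, sequences, labels)
        summary.to_csv(out / "cluster_summary.csv", index=False)
        pattern_frames = []
        for channel in CHANNELS:
            for kind in ("transition", "subsequence"):
                for cl in np.unique(labels):
                    seqs = [s for s, l in zip(sequences, labels) if l == cl]
                    df = mine_patterns(seqs, channel, kind)
                    if df.empty:
                        continue
                    df.insert(0, "cluster", cl)
                    df.insert(1, "channel", channel)
                    pattern_frames.append(df)
        patterns = (
            pd.concat(pattern_frames, ignore_index=True)
            if pattern_frames
            else pd.DataFrame(columns=["cluster", "channel", "pattern", "kind", "n", "pct"])
        )
        patterns.to_csv(out / "patterns.csv", index=False)
        for cl in np.unique(labels):
            seqs = [s for s, l in zip(sequences, labels) if l == cl]
            for channel in CHANNELS:
                state_distribution(seqs, channel).to_csv(
                    out / f"distribution_{cl}_{channel}.csv"
                )
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e

    manifest = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "config_sha256": hashlib.sha256(config.model_dump_json().encode()).hexdigest(),
        "inputs": inputs,
        "decisions": config.decision_flags(),
        "n_eligible": len(cohort),
        "k": kk,
        "outputs": {
            f.name: _sha256(f) for f in sorted(out.glob("*.csv")) if f.is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
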
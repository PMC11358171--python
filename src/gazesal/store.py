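"""On-disk layout for synthetic datasets and feature tensors.

A dataset directory holds ``manifest.json`` (all specs and seeds),
``clips/<clip_id>.npz`` (frames + ground truth), ``gaze.csv`` (one row
per participant x clip x frame), and ``ratings.csv``. Feature tensors are
stored as ``features_<stream>.npz`` with a JSON sidecar for ids.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from gazesal.pipeline import ClipFeatures
from gazesal.synth import ClipSpec, CohortSpec, GazeTrace, VideoClip


def save_dataset(
    out_dir: Path | str,
    clips: list[VideoClip],
    traces: list[GazeTrace],
    ratings: pd.DataFrame,
    cohort: CohortSpec,
    seed: int,
) -> None:
    out = Path(out_dir)
    (out / "clips").mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "cohort": dataclasses.asdict(cohort),
        "clips": [dataclasses.asdict(c.spec) for c in clips],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for clip in clips:
        np.savez_compressed(
            out / "clips" / f"{clip.spec.clip_id}.npz",
            frames=clip.frames.astype(np.float32),
            agent_tracks=clip.agent_tracks,
            distractor_points=clip.distractor_points,
        )
    rows = []
    for tr in traces:
        for t in range(len(tr)):
            rows.append(
                (tr.participant_id, tr.group, tr.clip_id, t, tr.x[t], tr.y[t], int(tr.valid[t]))
            )
    pd.DataFrame(
        rows, columns=["participant_id", "group", "clip_id", "frame", "x", "y", "valid"]
    ).to_csv(out / "gaze.csv", index=False)
    ratings.to_csv(out / "ratings.csv", index=False)


def load_dataset(in_dir: Path | str) -> tuple[list[VideoClip], list[GazeTrace], pd.DataFrame]:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    clips = []
    for spec_dict in manifest["clips"]:
        spec = ClipSpec(**spec_dict)
        data = np.load(src / "clips" / f"{spec.clip_id}.npz")
        clips.append(
            VideoClip(
                frames=data["frames"],
                spec=spec,
                agent_tracks=data["agent_tracks"],
                distractor_points=data["distractor_points"],
            )
        )
    gaze = pd.read_csv(src / "gaze.csv")
    traces = []
    for (pid, group, cid), sub in gaze.groupby(
        ["participant_id", "group", "clip_id"], sort=False
    ):
        sub = sub.sort_values("frame")
        traces.append(
            GazeTrace(
                participant_id=pid,
                group=group,
                clip_id=cid,
                x=sub["x"].to_numpy(float),
                y=sub["y"].to_numpy(float),
                valid=sub["valid"].to_numpy(bool),
            )
        )
    ratings_path = src / "ratings.csv"
    ratings = pd.read_csv(ratings_path) if ratings_path.exists() else pd.DataFrame()
    return clips, traces, ratings


def save_features(out_dir: Path | str, stream: str, features: list[ClipFeatures]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {cf.clip_id: cf.tensor for cf in features}
    np.savez_compressed(out / f"features_{stream}.npz", **arrays)
    meta = [
        {
            "clip_id": cf.clip_id,
            "category": cf.category,
            "participant_ids": cf.participant_ids,
            "groups": cf.groups,
        }
        for cf in features
    ]
    (out / f"features_{stream}.json").write_text(json.dumps(meta, indent=2))


def save_frame_table(path: Path | str, features, clip_id: str, participant_id: str) -> None:
    """Per-frame CSV export of one saliency run: frame, six factors, index."""
    from gazesal.saliency import CHANNELS

    rows = []
    for t, f in enumerate(features):
        row = {"clip_id": clip_id, "participant_id": participant_id, "frame": t}
        row.update({name: f.norm_factors[i] for i, name in enumerate(CHANNELS)})
        row["saliency_index"] = f.saliency_index
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_features(in_dir: Path | str, stream: str) -> list[ClipFeatures]:
    src = Path(in_dir)
    data = np.load(src / f"features_{stream}.npz")
    meta = json.loads((src / f"features_{stream}.json").read_text())
    return [
        ClipFeatures(
            clip_id=m["clip_id"],
            category=m["category"],
            participant_ids=m["participant_ids"],
            groups=m["groups"],
            tensor=data[m["clip_id"]],
        )
        for m in meta
    ]
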
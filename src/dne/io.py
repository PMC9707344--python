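"""Readers and writers for the pose formats the pipeline touches.

Two pose inputs are supported:

* OpenPose-style per-frame JSON (one document per frame, flat
  ``[x, y, confidence] * K`` arrays per body part), via
  :func:`read_openpose_frames`;
* a flat tabular pose format (CSV with columns
  ``frame, tree, side, joint, x, y, z, confidence``), via
  :func:`read_pose_table` / :func:`write_pose_table`, which round-trips
  bit-exactly for finite values.

Raw 2D pose arrives in image coordinates (y grows downward); both readers flip
to mathematical y-up on load so that "vertical position of the wrist" means
what it says.  Keypoints with confidence below a threshold are stored as NaN
with confidence 0 and left to preprocessing to interpolate.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .featureset import FeatureSet
from .skeleton import (
    B2_SPEC,
    DEFAULT_SPECS,
    EmptyInputError,
    PoseFormatError,
    PoseSequence,
    Recording,
    Side,
    SkeletonSpec,
    Test,
    Tree,
)

#: OpenPose BODY_25 indices for the per-side B2 joints (pelvis, neck, shoulder,
#: elbow, wrist).  MidHip doubles as the pelvis for both sides.
BODY25_TO_B2 = {
    Side.RIGHT: {0: 8, 1: 1, 5: 2, 6: 3, 7: 4},
    Side.LEFT: {0: 8, 1: 1, 5: 5, 6: 6, 7: 7},
}

# OpenPose hand model: wrist 0, thumb tip 4, index PIP 6, index tip 8.  The H2
# tree pins wrist=0, thumb_tip=3, index_mid=5, index_tip=6; remaining source
# indices fill the remaining slots in order so all 21 keypoints survive.
def _hand_permutation() -> dict[int, int]:
    fixed = {0: 0, 3: 4, 5: 6, 6: 8}
    used_src = set(fixed.values())
    free_src = [i for i in range(21) if i not in used_src]
    free_dst = [i for i in range(21) if i not in fixed]
    fixed.update(dict(zip(free_dst, free_src)))
    return fixed


OPENPOSE_HAND_TO_H2 = _hand_permutation()

_PART_KEYS = {
    ("pose_keypoints_2d", None): (Tree.B2, None),
    ("hand_right_keypoints_2d", None): (Tree.H2, Side.RIGHT),
    ("hand_left_keypoints_2d", None): (Tree.H2, Side.LEFT),
}


def _frame_payload(doc: Mapping) -> Mapping:
    """Accept either the raw OpenPose document ({'people': [...]}) or a flat dict."""
    if "people" in doc:
        people = doc["people"]
        if not people:
            return {}
        return people[0]
    return doc


def _parse_flat(arr: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(arr, dtype=float).reshape(-1, 3)
    return a[:, :2], a[:, 2]


def read_openpose_frames(
    source: str | os.PathLike | Iterable[Mapping],
    fps: float,
    specs: Mapping[Tree, SkeletonSpec] | None = None,
    confidence_threshold: float = 0.1,
) -> Recording:
    """Build a Recording from per-frame OpenPose JSON documents.

    ``source`` is a directory of ``*.json`` files (sorted by name, one frame
    each) or an iterable of already-parsed frame dicts.  Keypoints below
    ``confidence_threshold`` become NaN/confidence-0.
    """
    specs = dict(DEFAULT_SPECS if specs is None else specs)
    if isinstance(source, (str, os.PathLike)):
        files = sorted(Path(source).glob("*.json"))
        frames = []
        for f in files:
            with open(f) as fh:
                frames.append(json.load(fh))
    else:
        frames = list(source)
    if not frames:
        raise EmptyInputError("no frames found")

    # per (tree, side): list of (xy, conf) per frame
    buffers: dict[tuple[Tree, Side], list[tuple[np.ndarray, np.ndarray]]] = {}

    def push(key, xy, conf, frame_no):
        buf = buffers.setdefault(key, [])
        if buf and buf[0][0].shape != xy.shape:
            raise PoseFormatError(
                f"inconsistent keypoint count for {key[0].value}/{key[1].value} "
                f"at frame {frame_no}: {xy.shape[0]} vs {buf[0][0].shape[0]}"
            )
        if len(buf) != frame_no:
            raise PoseFormatError(f"missing part {key} before frame {frame_no}")
        buf.append((xy, conf))

    for i, doc in enumerate(frames):
        payload = _frame_payload(doc)
        for part, raw in payload.items():
            if part == "pose_keypoints_2d":
                xy, conf = _parse_flat(raw)
                for side in (Side.RIGHT, Side.LEFT):
                    spec = specs[Tree.B2]
                    out_xy = np.full((spec.n_keypoints, 2), np.nan)
                    out_c = np.zeros(spec.n_keypoints)
                    for dst, src in BODY25_TO_B2[side].items():
                        if src < xy.shape[0]:
                            out_xy[dst] = xy[src]
                            out_c[dst] = conf[src]
                    push((Tree.B2, side), out_xy, out_c, i)
            elif part in ("hand_right_keypoints_2d", "hand_left_keypoints_2d"):
                side = Side.RIGHT if "right" in part else Side.LEFT
                xy, conf = _parse_flat(raw)
                if xy.shape[0] != 21:
                    raise PoseFormatError(
                        f"hand arrays must have 21 keypoints, got {xy.shape[0]} at frame {i}"
                    )
                out_xy = np.empty((21, 2))
                out_c = np.empty(21)
                for dst, src in OPENPOSE_HAND_TO_H2.items():
                    out_xy[dst] = xy[src]
                    out_c[dst] = conf[src]
                push((Tree.H2, side), out_xy, out_c, i)
            # unknown keys ignored

    if not buffers:
        raise EmptyInputError("frames contained no recognized pose arrays")

    sequences = {}
    for (tree, side), buf in buffers.items():
        if len(buf) != len(frames):
            raise PoseFormatError(
                f"part ({tree.value}, {side.value}) present in only {len(buf)}/{len(frames)} frames"
            )
        coords = np.stack([xy for xy, _ in buf])
        conf = np.stack([c for _, c in buf])
        coords[:, :, 1] *= -1.0  # image y-down -> math y-up
        low = conf < confidence_threshold
        coords[low] = np.nan
        conf[low] = 0.0
        sequences[(tree, side)] = PoseSequence(
            spec=specs[tree], side=side, coords=coords, fps=fps, confidence=conf
        )
    return Recording(subject_id="", test=Test.FT, sequences=sequences)


# ---------------------------------------------------------------------------
# flat pose table

_TABLE_COLUMNS = ["frame", "tree", "side", "joint", "x", "y", "z", "confidence"]


def write_pose_table(rec: Recording, path: str | os.PathLike) -> None:
    """Write a Recording as a flat CSV, one row per (frame, sequence, joint)."""
    rows = []
    for (tree, side), seq in sorted(rec.sequences.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)):
        n, k, d = seq.coords.shape
        frames = np.repeat(np.arange(n) + seq.frame_index_offset, k)
        joints = np.tile(np.arange(k), n)
        flat = seq.coords.reshape(n * k, d)
        df = pd.DataFrame(
            {
                "frame": frames,
                "tree": tree.value,
                "side": side.value,
                "joint": joints,
                "x": flat[:, 0],
                "y": flat[:, 1],
                "z": flat[:, 2] if d == 3 else np.nan,
                "confidence": seq.confidence.reshape(-1),
            }
        )
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# fps={rec.fps!r} subject={rec.subject_id} test={rec.test.value} "
                 f"label={rec.label} device={rec.device} view={rec.view}\n")
        table.to_csv(fh, index=False)  # str() floats: shortest exact round-trip


def read_pose_table(
    path: str | os.PathLike,
    specs: Mapping[Tree, SkeletonSpec] | None = None,
    fps: float | None = None,
) -> Recording:
    """Read a Recording from the flat CSV written by :func:`write_pose_table`."""
    specs = dict(DEFAULT_SPECS if specs is None else specs)
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            body_start = len(first)
        else:
            body_start = 0
        fh.seek(body_start)
        try:
            df = pd.read_csv(fh, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            raise EmptyInputError(f"{path}: empty pose table") from None
    if df.empty:
        raise EmptyInputError(f"{path}: pose table has no rows")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PoseFormatError(f"{path}: missing columns {missing}")
    if fps is None:
        if "fps" not in meta:
            raise PoseFormatError(f"{path}: no fps metadata and none supplied")
        fps = float(meta["fps"])

    sequences = {}
    for (tree_s, side_s), grp in df.groupby(["tree", "side"], sort=True):
        tree, side = Tree(tree_s), Side(side_s)
        spec = specs[tree]
        if grp.duplicated(["frame", "joint"]).any():
            raise PoseFormatError(f"{path}: duplicate (frame, joint) rows for {tree_s}/{side_s}")
        frames = np.sort(grp["frame"].unique())
        offset = int(frames[0])
        if not np.array_equal(frames, np.arange(offset, offset + len(frames))):
            raise PoseFormatError(f"{path}: non-contiguous frames for {tree_s}/{side_s}")
        n, k = len(frames), spec.n_keypoints
        if len(grp) != n * k:
            raise PoseFormatError(
                f"{path}: expected {n * k} rows for {tree_s}/{side_s}, got {len(grp)}"
            )
        grp = grp.sort_values(["frame", "joint"])
        if spec.ndim == 3 and grp["z"].isna().any():
            raise PoseFormatError(f"{path}: tree {tree_s} is 3-D but z has missing values")
        cols = ["x", "y", "z"][: spec.ndim]
        coords = grp[cols].to_numpy(dtype=float).reshape(n, k, spec.ndim)
        conf = grp["confidence"].to_numpy(dtype=float).reshape(n, k)
        sequences[(tree, side)] = PoseSequence(
            spec=spec, side=side, coords=coords, fps=fps,
            confidence=conf, frame_index_offset=offset,
        )
    return Recording(
        subject_id=meta.get("subject", ""),
        test=Test(meta["test"]) if "test" in meta else Test.FT,
        sequences=sequences,
        label=meta.get("label", "unknown"),
        device=meta.get("device", ""),
        view=meta.get("view", "frontal"),
    )


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(features: Sequence[FeatureSet], path: str | os.PathLike) -> None:
    """One row per recording, one column per feature; undefined cells are empty."""
    tests = {f.test for f in features}
    if len(tests) > 1:
        raise ValueError(f"mixed test types in one feature table: {sorted(t.value for t in tests)}")
    names: list[str] = []
    for f in features:
        for n in f.names():
            if n not in names:
                names.append(n)
    rows = []
    for f in features:
        row = {"subject_id": f.subject_id, "test": f.test.value, "label": f.label, "device": f.device}
        row.update({n: f.values.get(n, float("nan")) for n in names})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["subject_id", "test", "label", "device"] + names)
    df.to_csv(path, index=False)


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject_id", "test", "label"):
        if col not in df.columns:
            raise PoseFormatError(f"{path}: feature table missing column {col!r}")
    return df
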
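"""Skeleton trees and the pose-sequence data model.

Three skeleton trees are used throughout:

* ``H2`` — 2D hand keypoints (21 per hand, OpenPose-hand style layout with the
  joints this pipeline reads at fixed indices: thumb tip 3, index middle joint
  5, index tip 6).
* ``B2`` — 2D body keypoints stored per side; shared trunk joints (pelvis 0,
  neck 1) appear in both side sequences, limb joints (elbow 6, wrist 7) are
  the side's own.
* ``B3`` — 3D body keypoints per side, pelvis-relative (pelvis 0, foot 2,
  knee 3, hip 4).

Right and left body parts are stored as separate :class:`PoseSequence` objects
carrying a ``side`` label, all indexed identically, so "right wrist" is joint 7
of the right-side B2 sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Tree(str, Enum):
    H2 = "H2"
    B2 = "B2"
    B3 = "B3"


class Side(str, Enum):
    RIGHT = "right"
    LEFT = "left"
    CENTER = "center"


class Test(str, Enum):
    FT = "FT"    # finger tapping
    FTF = "FTF"  # finger to finger
    FR = "FR"    # forearm roll
    SAW = "SAW"  # stand-up and walk


Test.__test__ = False  # not a pytest class despite the name


class PoseFormatError(ValueError):
    """Malformed pose input (inconsistent keypoint counts, duplicate rows...)."""


class EmptyInputError(ValueError):
    """No frames / no rows where at least one was required."""


@dataclass(frozen=True)
class SkeletonSpec:
    """Semantic-name -> keypoint-index map plus tree edges for one skeleton."""

    tree: Tree
    n_keypoints: int
    name_to_index: dict[str, int]
    edges: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        idx = list(self.name_to_index.values())
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate keypoint indices in name_to_index")
        for i in idx:
            if not 0 <= i < self.n_keypoints:
                raise ValueError(f"index {i} outside [0, {self.n_keypoints})")
        if self.edges:
            # edges must form a forest: no repeated child, no self loops
            children = [c for _, c in self.edges]
            if len(set(children)) != len(children):
                raise ValueError("edges do not form a tree (repeated child)")
            if any(p == c for p, c in self.edges):
                raise ValueError("self-loop in skeleton edges")

    @property
    def ndim(self) -> int:
        return 3 if self.tree is Tree.B3 else 2

    def index(self, name: str) -> int:
        try:
            return self.name_to_index[name]
        except KeyError:
            raise KeyError(f"joint {name!r} not defined for tree {self.tree.value}") from None


# Default trees.  Only the joints the feature definitions touch are named; the
# remaining indices exist so real pose output (21-keypoint hands, full body
# arrays) round-trips without loss.
H2_SPEC = SkeletonSpec(
    tree=Tree.H2,
    n_keypoints=21,
    name_to_index={"wrist": 0, "thumb_tip": 3, "index_mid": 5, "index_tip": 6},
    edges=((0, 1), (1, 2), (2, 3), (0, 4), (4, 5), (5, 6)),
)

B2_SPEC = SkeletonSpec(
    tree=Tree.B2,
    n_keypoints=8,
    name_to_index={"pelvis": 0, "neck": 1, "shoulder": 5, "elbow": 6, "wrist": 7},
    edges=((0, 1), (1, 5), (5, 6), (6, 7)),
)

B3_SPEC = SkeletonSpec(
    tree=Tree.B3,
    n_keypoints=5,
    name_to_index={"pelvis": 0, "foot": 2, "knee": 3, "hip": 4},
    edges=((0, 4), (4, 3), (3, 2)),
)

DEFAULT_SPECS: dict[Tree, SkeletonSpec] = {
    Tree.H2: H2_SPEC,
    Tree.B2: B2_SPEC,
    Tree.B3: B3_SPEC,
}


@dataclass
class PoseSequence:
    """Time-indexed keypoint coordinates for one skeleton and one side.

    ``coords`` has shape (N, K, D) in the tree's dimensionality; invalid
    detections are NaN with confidence 0.  Frame ``i`` occurs at time
    ``(frame_index_offset + i) / fps`` seconds.
    """

    spec: SkeletonSpec
    side: Side
    coords: np.ndarray
    fps: float
    confidence: np.ndarray | None = None
    frame_index_offset: int = 0
    unreliable: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must be (N, K, D)")
        n, k, d = self.coords.shape
        if n < 2:
            raise ValueError("a pose sequence needs at least 2 frames")
        if k != self.spec.n_keypoints:
            raise PoseFormatError(
                f"expected {self.spec.n_keypoints} keypoints for {self.spec.tree.value}, got {k}"
            )
        if d != self.spec.ndim:
            raise PoseFormatError(f"tree {self.spec.tree.value} is {self.spec.ndim}-D, got D={d}")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.confidence is None:
            self.confidence = np.ones((n, k))
        else:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != (n, k):
                raise PoseFormatError("confidence shape must be (N, K)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        return (self.frame_index_offset + np.arange(self.n_frames)) / self.fps

    def joint(self, name: str) -> np.ndarray:
        """(N, D) track of a named joint."""
        return self.coords[:, self.spec.index(name), :]

    def copy(self) -> "PoseSequence":
        return PoseSequence(
            spec=self.spec,
            side=self.side,
            coords=self.coords.copy(),
            fps=self.fps,
            confidence=None if self.confidence is None else self.confidence.copy(),
            frame_index_offset=self.frame_index_offset,
            unreliable=self.unreliable,
        )


#: sequences each test requires, as (tree, side) keys
REQUIRED_SEQUENCES: dict[Test, tuple[tuple[Tree, Side], ...]] = {
    Test.FT: ((Tree.H2, Side.RIGHT), (Tree.H2, Side.LEFT), (Tree.B2, Side.RIGHT), (Tree.B2, Side.LEFT)),
    Test.FTF: ((Tree.H2, Side.RIGHT), (Tree.H2, Side.LEFT), (Tree.B2, Side.RIGHT), (Tree.B2, Side.LEFT)),
    Test.FR: ((Tree.B2, Side.RIGHT), (Tree.B2, Side.LEFT)),
    Test.SAW: ((Tree.B3, Side.RIGHT), (Tree.B3, Side.LEFT), (Tree.B2, Side.CENTER)),
}


@dataclass
class Recording:
    """One test recording: metadata plus its pose sequences keyed by (tree, side)."""

    subject_id: str
    test: Test
    sequences: dict[tuple[Tree, Side], PoseSequence] = field(default_factory=dict)
    label: str = "unknown"  # normal | abnormal | unknown
    device: str = ""
    view: str = "frontal"

    def __getitem__(self, key: tuple[Tree, Side]) -> PoseSequence:
        return self.sequences[key]

    def get(self, tree: Tree, side: Side) -> PoseSequence:
        try:
            return self.sequences[(tree, side)]
        except KeyError:
            raise KeyError(
                f"recording has no ({tree.value}, {side.value}) sequence"
            ) from None

    @property
    def fps(self) -> float:
        return next(iter(self.sequences.values())).fps

    @property
    def n_frames(self) -> int:
        return next(iter(self.sequences.values())).n_frames

    def validate(self) -> None:
        """Check the sequences this test's features need are all present."""
        missing = [k for k in REQUIRED_SEQUENCES[self.test] if k not in self.sequences]
        if missing:
            names = ", ".join(f"({t.value},{s.value})" for t, s in missing)
            raise PoseFormatError(f"{self.test.value} recording missing sequences: {names}")

    def map_sequences(self, fn) -> "Recording":
        """New Recording with ``fn`` applied to every PoseSequence."""
        return Recording(
            subject_id=self.subject_id,
            test=self.test,
            sequences={k: fn(seq) for k, seq in self.sequences.items()},
            label=self.label,
            device=self.device,
            view=self.view,
        )
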
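"""Pose I/O: write a recording to the flat pose-table format and read it back.

The pose table (CSV: frame, tree, side, joint, x, y, z, confidence) is the
interchange format between the simulator, the CLI, and external pose
estimators; the round trip is bit-exact for finite values.
"""

import tempfile
from pathlib import Path

import numpy as np

from dne import Side, SyntheticSpec, Tree, gen_ft
from dne.io import read_pose_table, write_pose_table

rec, _ = gen_ft(SyntheticSpec(duration_s=3.0, seed=1))
with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "recording.csv"
    write_pose_table(rec, path)
    back = read_pose_table(path)
    key = (Tree.H2, Side.RIGHT)
    same = np.array_equal(back.sequences[key].coords, rec.sequences[key].coords)
    print(f"wrote {path.stat().st_size/1024:.0f} KiB, "
          f"{rec.n_frames} frames, {len(rec.sequences)} sequences")
    print(f"bit-exact round trip: {same}")
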
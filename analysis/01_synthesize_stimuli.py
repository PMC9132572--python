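#!/usr/bin/env python
"""Generate the factorial stimulus catalog and summarize its structure.

Three skeletons (selected from a random pool by k-means over pairwise
skeletal distances) crossed with two surface forms, rendered as 60-frame
back-and-forth rotation videos at 64 x 64.  Writes per-video frame
directories and a design-check table: within-skeleton (different-form)
skeletal distances are zero by construction, between-skeleton distances are
well separated, confirming the factorial design the models are tested on.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from skelshape.metrics import skeletal_distance
from skelshape.stimuli import (build_skeleton_points, default_render_config,
                               generate_stimulus_set, save_frame_stack)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cat = generate_stimulus_set(3, 2, seed=SEED, cfg=default_render_config(64, 60))
    stim_dir = OUT / "stimuli"
    for (s, f), stack in cat.videos.items():
        save_frame_stack(stack, stim_dir / f"s{s}f{f}")
    pts = [build_skeleton_points(s, 20)[0] for s in cat.skeletons]
    rows = []
    for i in range(3):
        for j in range(i + 1, 3):
            rows.append({"skeleton_a": i, "skeleton_b": j,
                         "skeletal_distance": skeletal_distance(pts[i], pts[j])})
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "skeleton_distances.csv", index=False)
    print(f"wrote {len(cat.videos)} videos to {stim_dir}")
    print("pairwise skeletal distances between the selected skeletons:")
    print(df.to_string(index=False))
    print(f"minimum between-skeleton distance {df['skeletal_distance'].min():.3f} "
          "(object units); same-skeleton pairs differ only in surface form "
          "(distance 0 by construction).")


if __name__ == "__main__":
    sys.exit(main())
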
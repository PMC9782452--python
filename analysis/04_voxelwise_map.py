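#!/usr/bin/env python
"""Voxelwise HR-vs-LR comparison of the synthetic brain uptake maps.

Per-voxel two-sample t-tests across the subject maps, BH-FDR threshold
at q=0.05, and 26-connected cluster labelling; reports how well the
detected cluster recovers the regional elevation the generator planted
in the high-risk group.  Outputs: results/voxel_t_map.txt and a summary.
"""

from pathlib import Path

import numpy as np

from fdgclamp import io as cio
from fdgclamp.cohort import VOXEL_SIGNAL_BLOCK
from fdgclamp.config import PipelineConfig
from fdgclamp.stats import voxelwise_group_map

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PipelineConfig(seed=11)
    maps: dict[str, list[np.ndarray]] = {}
    for sub in sorted((ROOT / "cohort").glob("sub-*")):
        group = sub.name[4:6]
        maps.setdefault(group, []).append(cio.read_voxel_map(sub / "voxel_map.txt"))
    res = voxelwise_group_map(np.stack(maps["HR"]), np.stack(maps["LR"]),
                              q=cfg.fdr_q)
    cio.write_voxel_map(ROOT / "voxel_t_map.txt", res.t_map)

    truth = np.zeros(res.mask.shape, bool)
    truth[VOXEL_SIGNAL_BLOCK] = True
    jaccard = (res.mask & truth).sum() / max((res.mask | truth).sum(), 1)
    print(f"voxels tested: {res.mask.size}, significant: {res.mask.sum()}")
    print(f"clusters (26-connectivity): {res.cluster_sizes}")
    print(f"Jaccard overlap with the planted HR elevation: {jaccard:.2f}")
    print(f"t map written to {ROOT / 'voxel_t_map.txt'}")


if __name__ == "__main__":
    main()
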
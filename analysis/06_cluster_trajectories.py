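"""Cluster trajectories by DTW over code-description embeddings.

Each code's description is embedded as a unit 256-vector; trajectory
dissimilarity is dynamic time warping over the embedding sequences, and
average-linkage agglomeration cuts at k clusters.  Each cluster's RR pools
its members' prefixes as the exposure and their terminal codes as the
outcome set.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from config import run_config

from trajmine.pipeline import load_cohort, stage_cluster
from trajmine.trajectory_assembly import Trajectory


def main() -> None:
    cfg = run_config()
    cohort = load_cohort(cfg)
    path = Path(cfg.outdir) / "trajectories.jsonl"
    trajs = [Trajectory(tuple(d["codes"]), d["support"])
             for d in (json.loads(line)
                       for line in path.read_text().splitlines()
                       if not line.startswith("#"))]
    info = stage_cluster(cfg, cohort, trajs)
    payload = json.loads((Path(cfg.outdir) / "clusters.json").read_text())
    print(f"clusters at k={cfg.cluster_k}: {info['n_clusters']} "
          f"(embedding provider {payload['provider']})")
    for i, cluster in enumerate(payload["clusters"]):
        risk = cluster["risk"]
        print(f"  cluster {i}: RR {risk['rr']:.2f} "
              f"(95% CI {risk['ci_low']:.2f}-{risk['ci_high']:.2f})")
        for m in cluster["members"]:
            print(f"    {' -> '.join(m['codes'])}")


if __name__ == "__main__":
    main()
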
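"""Assemble multi-step trajectories ending in a dementia code.

Significant directed pairs form a DAG; codes that cannot reach an outcome
code are discarded, and paths of three or more codes traversed
sequentially (gaps within five years) by at least 500 patients are scored
with the same matched-cohort RR as individual pairs.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from config import run_config

from trajmine.pipeline import _read_table, load_cohort, stage_trajectories


def main() -> None:
    cfg = run_config()
    cohort = load_cohort(cfg)
    sig = _read_table(Path(cfg.outdir) / "significant_pairs.tsv").rename(
        columns={"source_code": "c1", "target_code": "c2",
                 "relative_risk": "rr"})
    trajectories, info = stage_trajectories(cfg, cohort,
                                            sig[["c1", "c2", "rr", "p_value"]])
    print(f"outcome-ancestor graph: {info['n_graph_nodes']} nodes, "
          f"{info['n_graph_edges']} edges "
          f"({info['n_cycle_edges_removed']} cycle edges removed)")
    print(f"trajectories with support >= {cfg.min_support}: "
          f"{info['n_trajectories']}")
    for t in trajectories:
        print(f"  {' -> '.join(t.codes)}  support {t.support}  "
              f"RR {t.risk.rr:.2f} (95% CI {t.risk.ci_low:.2f}-"
              f"{t.risk.ci_high:.2f})")


if __name__ == "__main__":
    main()
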
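"""Screen co-occurring code pairs and orient them temporally.

Step 1: two-sided Fisher exact test (positive association only) over every
pairwise code combination.  Step 2: exact binomial test on which code
comes first among carriers of both; pairs without significant temporal
asymmetry are dropped.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from config import run_config

from trajmine.pipeline import load_cohort, stage_pairs


def main() -> None:
    cfg = run_config()
    cohort = load_cohort(cfg)
    directed, info = stage_pairs(cfg, cohort)
    print(f"candidate co-occurring pairs: {info['n_candidate_pairs']}")
    print(f"temporally oriented pairs:    {info['n_directed_pairs']}")
    top = directed.sort_values("binom_p").head(8)
    for row in top.itertuples(index=False):
        print(f"  {row.c1:>7} -> {row.c2:<7} a={row.a:<5} "
              f"forward/backward {row.n_forward}/{row.n_backward} "
              f"(binomial p={row.binom_p:.2e})")


if __name__ == "__main__":
    main()
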
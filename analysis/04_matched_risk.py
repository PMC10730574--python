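"""Matched-cohort relative risk for each directed pair, Bonferroni control.

Each exposed patient is compared against up to 10,000 patients of the same
sex, race and decade of life (at the exposed patient's index event); RR > 1
with p below 0.05 / family-size survives.  Estimated RRs for the planted
pairs are printed next to the generator's closed-form expectation.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from config import OUTDIR, run_config

from trajmine.pipeline import _read_table, load_cohort, stage_risk


def main() -> None:
    cfg = run_config()
    cohort = load_cohort(cfg)
    directed = _read_table(Path(cfg.outdir) / "directed_pairs.tsv")
    sig, info = stage_risk(cfg, cohort, directed)
    print(f"Bonferroni family size: {info['bonferroni_family_size']}")
    print(f"significant directed pairs: {info['n_significant_pairs']}")

    truth = json.loads((Path(OUTDIR) / "input" / "truth.json").read_text())
    expected = {(p["trigger"][0], p["target"]): p["expected_rr"]
                for p in truth["planted_pairs"]}
    table = _read_table(Path(cfg.outdir) / "significant_pairs.tsv")
    for row in table.sort_values("relative_risk",
                                 ascending=False).itertuples(index=False):
        key = (row.source_code, row.target_code)
        note = (f"  [planted, expected {expected[key]:.2f}]"
                if key in expected else "")
        print(f"  {row.source_code:>7} -> {row.target_code:<7} "
              f"RR {row.relative_risk:6.2f} "
              f"(95% CI {row.ci_low:.2f}-{row.ci_high:.2f}){note}")


if __name__ == "__main__":
    main()
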
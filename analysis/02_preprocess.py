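"""Reduce raw event rows to analysis-ready first-occurrence timelines.

Duplicate occurrences, normal lab results and out-of-window events vanish
here; patients with incomplete demographics or under 18 are excluded with
per-reason accounting (exclusions.json).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from config import run_config

from trajmine.pipeline import stage_preprocess


def main() -> None:
    cohort, info = stage_preprocess(run_config())
    print(f"included patients: {info['n_included']}")
    print(f"timeline events (first occurrences): {info['n_events']}")
    print(f"raw rows loaded: {info['load']['n_loaded']} "
          f"(dropped: {info['load']})")
    print(f"exclusions: {info['exclusions']}")


if __name__ == "__main__":
    main()
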
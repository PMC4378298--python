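#!/usr/bin/env python
"""Brain-behavior analysis of the printed clinical tables.

Paired t-tests on the Fugl-Meyer change scores per intervention group and
Pearson correlations between dFMA and dGC for each tabulated connection.
Writes results/clinical_behavior.json.
"""

import json
from pathlib import Path

from lfo_gcnet.pipeline import clinical_behavior_block

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    block = clinical_behavior_block()
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "clinical_behavior.json").write_text(json.dumps(block, indent=1))
    for label in ("MP", "MPPT"):
        entry = block[label]
        verdict = "significant" if entry["paired_p"] < 0.05 else "not significant"
        print(f"{label}: dFMA gain {verdict} "
              f"(t = {entry['paired_t']:.2f}, p = {entry['paired_p']:.3f})")
        for key, val in entry.items():
            if key.startswith("pearson_"):
                conn = key.removeprefix("pearson_")
                print(f"  dFMA ~ dGC {conn}: r = {val['r']:.2f}, p = {val['p']:.2f}")
    print(f"\nwritten to {OUT / 'clinical_behavior.json'}")


if __name__ == "__main__":
    main()
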
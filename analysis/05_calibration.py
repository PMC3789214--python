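#!/usr/bin/env python
"""Monte-Carlo significance calibration of the outcome measures.

A classification only means something relative to what a coin-flipping
classifier achieves on the same cohort. This computes the 95% null
critical values of SE, SP, PPV, PLR and MCC (random classifier, 5000
iterations) at the reference size n=65 with 25 positives and at this
cohort's evaluation size n=64 with 25 positives, showing the sample-size
dependence of the thresholds.
"""

import argparse
import json
import sys
from pathlib import Path

from eegdx.classify import monte_carlo_thresholds


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/calibration.json"))
    args = ap.parse_args()

    out = {}
    for tag, n, npos in (("reference_n65", 65, 25),
                         ("cohort_evaluation_n64", 64, 25),
                         ("heldout_n30", 30, 8)):
        thr = monte_carlo_thresholds(n, npos, n_iterations=5000,
                                     seed=args.seed)
        out[tag] = {"n": n, "n_positive": npos,
                    "critical_values": {k: round(v, 3) for k, v in thr.items()}}
        print(f"{tag}: " + "  ".join(
            f"{k}>{v:.2f}" for k, v in thr.items()))

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2) + "\n")
    print(f"critical values -> {args.out}")


if __name__ == "__main__":
    sys.exit(main())
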
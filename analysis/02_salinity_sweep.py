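#!/usr/bin/env python
"""One-hour salinity sweep with polystyrene-bead controls.

Bead transparency should be indifferent to the suspending condition while
the algal conditions separate strongly: transparency dips toward moderate
salinity (membrane most permeable) and recovers at the extremes.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "src"))

from impedancyte.config import load_config
from impedancyte.features import group_transparency
from impedancyte.pipeline import run_pipeline


def main() -> None:
    cfg = load_config(REPO / "configs" / "salinity_sweep.yaml")
    outdir = REPO / cfg.output_dir
    run_pipeline(cfg, output_dir=outdir, write_traces=False)

    events = pd.read_csv(outdir / "events.csv")
    panel = cfg.panel.panel()

    print("== transparency(20 MHz), ratio-of-means ==")
    means = {}
    for group in sorted(events.group.unique()):
        res = group_transparency(events[events.group == group], panel, f_hi=2e7)
        means[group] = res["ratio_of_means"]
        print(f"{group:>12}: {res['ratio_of_means']:.3f} (n={res['n']})")
    beads = [v for g, v in means.items() if g.startswith("bead")]
    cells = [v for g, v in means.items() if g.startswith("salt")]
    print(f"bead spread across conditions: {max(beads) / min(beads) - 1:.2%}")
    print(f"algal spread across conditions: {max(cells) / min(cells) - 1:.2%}")
    print(f"tables in {outdir}")


if __name__ == "__main__":
    main()
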
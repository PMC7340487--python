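#!/usr/bin/env python
"""Generate the synthetic 31-province indicator panel.

Emits a long-format panel (province x indicator x sex x year,
1990-2016) from the default scenario: transform-space linear trends
with region and sex effects and mild observation noise, emulating the
statistical shape of provincial burden-of-disease series so the whole
pipeline can run without any external download.
"""

import argparse
from pathlib import Path

from sdgattain import default_scenario, generate_panel, load_registry
from sdgattain.io import write_panel

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()
args.results.mkdir(parents=True, exist_ok=True)

registry = load_registry()
panel = generate_panel(default_scenario(args.seed), registry)
out = args.results / "panel.csv"
write_panel(panel, out)

n_series = panel.groupby(["location_id", "indicator_id", "sex"]).ngroups
print(f"panel: {len(panel)} rows, {n_series} series "
      f"({panel.location_id.nunique()} locations x "
      f"{panel.indicator_id.nunique()} indicators x "
      f"{panel.sex.nunique()} sexes), years "
      f"{panel.year.min()}-{panel.year.max()} -> {out}")
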
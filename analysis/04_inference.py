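"""Group contrasts, breakpoint regressions, hub-gap and association tests.

Runs the statistical layer on the metrics produced by 03_network_metrics.py
and writes contrasts.tsv, breakpoints.tsv, associations.tsv.  Prints the
headline pattern: is FTD connection strength reduced, does normalized
efficiency hold up between carriers and FTD, is there an efficiency
breakpoint at expected onset (and none for strength), and is the
strength-volume association confined to FTD?
"""

import sys

import pandas as pd

from ftdnet.io import read_table
from ftdnet.pipeline import stage_analyze

sys.path.insert(0, "analysis")
from importlib import import_module

sim = import_module("01_simulate_cohort")


def pick(df, **keys):
    m = pd.Series(True, index=df.index)
    for k, v in keys.items():
        m &= df[k] == v
    return df[m].iloc[0]


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    stage_analyze(sim.config(seed))
    contrasts = read_table(sim.OUT / "contrasts.tsv")
    breaks = read_table(sim.OUT / "breakpoints.tsv")
    assoc = read_table(sim.OUT / "associations.tsv")

    s = pick(contrasts, outcome="connection_strength_total", term="carrier-vs-ftd")
    e = pick(contrasts, outcome="global_efficiency_normalized", term="carrier-vs-ftd")
    bs = pick(breaks, outcome="connection_strength_total")
    be = pick(breaks, outcome="global_efficiency_normalized")
    rf = pick(assoc, x="brain_volume_pct", y="connection_strength_total", term="r_ftd")
    rc = pick(assoc, x="brain_volume_pct", y="connection_strength_total", term="r_carrier")

    print(f"connection strength, carrier - FTD: {s.estimate:+.2f} (p = {s.p:.2g})")
    print(f"normalized efficiency, carrier - FTD: {e.estimate:+.4f} (p = {e.p:.2g})")
    print(f"efficiency breakpoint at onset: p = {be.p_breakpoint:.2g} "
          f"(post-onset slope {be.post_slope:+.4f}/yr vs pre {be.pre_slope:+.4f}/yr)")
    print(f"strength breakpoint at onset: p = {bs.p_breakpoint:.2g}")
    print(f"strength-volume correlation: FTD r = {rf.estimate:.2f} (p = {rf.p:.2g}); "
          f"carriers r = {rc.estimate:.2f} (p = {rc.p:.2g})")

    hub = contrasts[contrasts.analysis == "hub_gap_interaction"]
    for _, row in hub.iterrows():
        print(f"hub-gap interaction on {row.outcome}: {row.estimate:+.3f} (p = {row.p:.2g})")
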
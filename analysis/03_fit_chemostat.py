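#!/usr/bin/env python
"""Estimate (m_S, Y_X/S^max) by Pirt regression of synthetic chemostats.

Generates duplicate steady-state chemostats at D = 0.025-0.10 h^-1 with
3% CV measurement noise (seeded) and regresses q_S on mu: the intercept
is the maintenance coefficient, the reciprocal slope the maximum yield.

Writes results/chemostats.csv and results/pirt_fit.json.
"""

import json
import sys
from pathlib import Path

from pirtlab import SyntheticConfig, fit_pirt_chemostat, generate_chemostat_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SyntheticConfig(seed=SEED)
    table = generate_chemostat_table(cfg)
    table.to_csv(OUT / "chemostats.csv", index=False)
    res = fit_pirt_chemostat(table)
    (OUT / "pirt_fit.json").write_text(json.dumps({
        "m_S": res.m_S, "se_mS": res.se_mS, "Y_max": res.Y_max,
        "se_slope": res.se_slope, "r_squared": res.r_squared,
        "n_points": res.n_points, "seed": SEED,
        "truth": {"m_S": cfg.chemostat_pirt.m_S, "Y_max": cfg.chemostat_pirt.Y_max},
    }, indent=2))
    print(
        f"{res.n_points} chemostats (seed {SEED}): "
        f"m_S = {res.m_S:.4f} +/- {res.se_mS:.4f} g/g/h "
        f"({100 * res.se_mS / res.m_S:.0f}% relative SE), "
        f"Y_max = {res.Y_max:.3f} g/g, R^2 = {res.r_squared:.3f}"
    )
    print(f"generating truth: m_S = {cfg.chemostat_pirt.m_S}, Y_max = {cfg.chemostat_pirt.Y_max}")
    print("wrote", OUT / "chemostats.csv", "and", OUT / "pirt_fit.json")


if __name__ == "__main__":
    sys.exit(main())
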
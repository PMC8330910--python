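#!/usr/bin/env python
"""Report the calibration observables of the default rate constants.

The printed rate constants (700 (nmol/mg)^-1 s^-1 ubiquinol binding at
Qo, 175/131/88/70 succinate binding to complex II, 2e-5 s^-1 ROS
formation, proton leak 2 s^-1 mV^-1, uniporter P = 0.005, F/C = 500) are
fixed.  The remaining constants are free parameters whose defaults were
chosen once so that

  * the isolated complex II ROS-vs-succinate curve peaks near 50 uM, and
  * the glutamate up-sweep bifurcates below 100 uM.

This script recomputes both observables from the current defaults so the
calibration can be re-checked after any change to the rate sets.

Usage:  python scripts/calibrate.py [--quick]
"""

from __future__ import annotations

import argparse
import time

import numpy as np


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--quick", action="store_true",
                        help="coarser grids (about twice as fast)")
    args = parser.parse_args()

    from mitoros.mito import simulate_isolated_cii
    from mitoros.scenarios import glutamate_sweep

    n_scan = 15 if args.quick else 25
    t0 = time.time()
    grid = np.geomspace(1.0, 500.0, n_scan)
    df = simulate_isolated_cii(grid, 4e-8, normalize=False)
    peak = float(df.succinate_um[df.ros_rate.idxmax()])
    print(f"isolated complex II ROS peak: {peak:.1f} uM "
          f"(target ~50 uM; {time.time() - t0:.0f}s)")

    n_sweep = 21 if args.quick else 41
    for k_fad in (175.0, 70.0):
        t0 = time.time()
        _, up = glutamate_sweep(0.0, 100.0, n_sweep, "up", k_fad=k_fad)
        jp = up.jump_parameter
        where = "none" if jp is None else f"{1000.0 * jp:.1f} uM"
        print(f"bifurcation glutamate (k_fad={k_fad:g}): {where} "
              f"(target < 100 uM; {time.time() - t0:.0f}s)")


if __name__ == "__main__":
    main()
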
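#!/usr/bin/env python
"""Derive and verify the default parameters of the model potentials.

The three shipped surfaces are calibrated against their benchmark
constraints (minima locations, barrier heights in kT, basin widths,
substate separation).  The double-well constants follow in closed form from
(x_min, barrier, sigma); the 2-D surfaces are fixed by construction.  This
script re-derives everything, runs the full constraint verification, and
optionally writes the resulting flat-text config files.

Usage:  python scripts/calibrate_potentials.py [--write-configs DIR]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from resetfpt import default_spec, verify_constraints, write_potential_config
from resetfpt.potentials import default_constraints

FORMS = ["double_well_1d", "entropic_two_basin_2d", "modified_wolfe_quapp_2d"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--write-configs", type=Path, default=None,
                        metavar="DIR",
                        help="also write one <form>.cfg per potential")
    args = parser.parse_args()

    failures = 0
    for form in FORMS:
        spec = default_spec(form)
        print(f"== {form} ==")
        for name, value in spec.parameters.items():
            print(f"  {name} = {value:.10g}")
        report = verify_constraints(spec, default_constraints(form))
        print(report)
        failures += sum(not c.passed for c in report.checks)
        if args.write_configs:
            args.write_configs.mkdir(parents=True, exist_ok=True)
            path = args.write_configs / f"{form}.cfg"
            write_potential_config(spec, path)
            print(f"  wrote {path}")
        print()
    if failures:
        raise SystemExit(f"{failures} constraint check(s) failed")
    print("all constraints satisfied")


if __name__ == "__main__":
    main()
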
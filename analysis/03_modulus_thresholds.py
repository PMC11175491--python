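#!/usr/bin/env python
"""Wall-stiffness thresholds of the finite-strain model.

For each requested configuration the critical threshold walks the wall
Young's modulus down from 1.0 MPa in 0.01 MPa decrements (0.1 MPa floor)
until the follower-pressure equilibrium ceases to exist (Newton collapse);
the minimal threshold additionally requires the converged solution to keep
the maximum equivalent strain under a 0.2 cap.

Default scope: central configuration at fractions 0.20/0.40/0.60 (pass
--full for all positions; a search costs ~1-3 min).  Findings under the
default materials: the central case loses its solution branch well above
the 0.1 MPa floor (critical modulus 0.40 MPa at f=0.20, falling to
0.30 MPa at f=0.60 — more thrombus stabilizes the wall), and the 0.2
equivalent-strain cap binds at 0.95 MPa for f=0.20 and already at the
1.0 MPa baseline for higher fractions.
"""

import json
import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from aaa_ilt.errors import AaaIltError  # noqa: E402
from aaa_ilt.study import study_config  # noqa: E402
from aaa_ilt.sweep import critical_modulus, minimal_modulus  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    full = "--full" in sys.argv
    cases = (
        [(p, f) for p in ("center", "anterior", "posterior_spine", "left")
         for f in (0.25, 0.45, 0.65, 0.85)]
        if full
        else [("center", f) for f in (0.20, 0.40, 0.60)]
    )
    config = study_config()
    rows = []
    for position, fraction in cases:
        t0 = time.time()
        row = {"position": position, "fraction": fraction}
        try:
            row["critical_modulus_mpa"] = critical_modulus(config, position, fraction) / 1e6
            row["minimal_modulus_mpa"] = minimal_modulus(config, position, fraction) / 1e6
        except AaaIltError as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
        row["seconds"] = round(time.time() - t0, 1)
        rows.append(row)
        print(f"  {position:>15s} f={fraction:.2f}: "
              f"critical {row.get('critical_modulus_mpa', '-')} MPa, "
              f"minimal {row.get('minimal_modulus_mpa', '-')} MPa "
              f"({row['seconds']} s)")
    OUT.mkdir(exist_ok=True)
    (OUT / "modulus_thresholds.json").write_text(json.dumps(rows, indent=1) + "\n")
    print(f"wrote {OUT}/modulus_thresholds.json")
    return 0


if __name__ == "__main__":
    sys.exit(main())
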
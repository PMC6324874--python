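"""Selection coefficients of representative WS mutants from competition data.

Reads the (synthetic) 1:1 competition table, corrects for the GFP marker
cost using the isogenic control competitions, excludes destabilized
microcosms, and compares mutant classes by Welch t-tests.  The expected
picture: wspF/wspE-like mutants near the reference fitness, wspA slightly
below, wspR severely impaired, and all aws mutants clearly below the
reference — the fitness differences that explain why the under-selection
spectrum over-represents Wsp despite Aws's higher mutation rate.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from wsforecast import fitness as fit

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/fitness.json"))
    args = ap.parse_args()

    assays = fit.filter_destabilized(
        fit.assays_from_tsv(args.data_dir / "competitions.tsv"))
    controls = [fit.selection_coefficient(a) for a in assays if a.is_marker_control]
    control_s = float(np.mean(controls)) if controls else 0.0
    print(f"marker-cost control: s = {control_s:+.4f} "
          f"({len(controls)} control competitions)")

    groups: dict[str, list[float]] = {}
    for a in assays:
        if not a.is_marker_control:
            groups.setdefault(a.mutant, []).append(
                fit.marker_corrected_s(fit.selection_coefficient(a), control_s))
    for mutant, vals in sorted(groups.items()):
        print(f"{mutant:10s}: s = {np.mean(vals):+.3f} +/- {np.std(vals, ddof=1):.3f} "
              f"(n={len(vals)})")

    table = fit.group_compare(groups)
    sig = table[table.p_value < 0.05]
    print(f"\n{len(sig)} of {len(table)} pairwise comparisons significant at 0.05")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(
        {
            "marker_control_s": control_s,
            "selection_coefficients": {
                m: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)),
                    "n": len(v)}
                for m, v in sorted(groups.items())
            },
            "pairwise_tests": table.to_dict(orient="records"),
        },
        indent=2,
    ))
    print(f"wrote {args.out}")
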
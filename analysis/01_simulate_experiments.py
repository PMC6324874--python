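"""Generate the study-shaped synthetic data bundle.

Writes fluctuation-assay mutant counts for the three single-pathway strains
(C = 200 cultures for Wsp and Aws, 400 for Mws, at the measured rates
6.5 / 3.7 / 0.74 ×1e-9 per cell per generation), a no-selection mutation
spectrum with the Aws hotspot structure, and quadruplicate competition
assays per representative mutant.
"""

import argparse
from pathlib import Path

from wsforecast.synthetic_data import paper_like_bundle

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    paths = paper_like_bundle(args.outdir, seed=args.seed)
    print(f"wrote {len(paths)} files to {args.outdir}:")
    for name, path in paths.items():
        print(f"  {name}: {path}")
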
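"""Closed-form null models of pathway usage, with hotspot-factor fits.

Model I (bp as target size) predicts Wsp/Aws = 3.65; Model II (genes)
predicts 2.33 — both the wrong way around relative to the measured rates,
where Aws is about twice Wsp.  Model III (enabling/disabling reaction
counts from the network models) weights the pathways 6:4:3.  Solving the
Model II hotspot formula against the measured rates quantifies how strong a
single-site bias must be to reconcile model and data: k = 10.3 (Aws/Wsp)
and k = 6.8 (Aws/Mws); the Model III variant needs only k ≈ 4.
"""

import argparse
import json
from pathlib import Path

from wsforecast import networks as nw
from wsforecast import null_models as nm

MEASURED = {"Wsp": 3.7e-9, "Aws": 6.5e-9, "Mws": 0.74e-9}

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--probes", type=int, default=100,
                    help="parameter draws per reaction-classification probe")
    ap.add_argument("--out", type=Path, default=Path("results/null_models.json"))
    args = ap.parse_args()

    bp = {p: nw.PATHWAY_ANNOTATION[p][0] for p in nw.PATHWAY_NAMES}
    genes = {p: nw.PATHWAY_ANNOTATION[p][1] for p in nw.PATHWAY_NAMES}
    out = {}

    m1 = nm.model_i_usage(bp, 1e-9).ratios
    m2 = nm.model_ii_usage(genes, 1e-9).ratios
    print(f"Model I  (bp):    Wsp/Aws = {m1['Wsp/Aws']:.2f}, Aws/Mws = {m1['Aws/Mws']:.2f}")
    print(f"Model II (genes): Wsp/Aws = {m2['Wsp/Aws']:.2f}, Aws/Mws = {m2['Aws/Mws']:.2f}")
    out["model_i"], out["model_ii"] = m1, m2

    counts = {}
    for p in nw.PATHWAY_NAMES:
        en, dis = nw.classify_reactions(
            nw.build_pathway(p), n_probe_samples=args.probes, seed=args.seed
        )
        counts[p] = (len(dis), len(en))
        print(f"{p}: disabling {sorted(dis)}, enabling {sorted(en)}")
    out["model_iii_counts"] = {p: list(c) for p, c in counts.items()}
    for regime in ("equal", "disabling_only", "enabling_only"):
        weights = nm.model_iii_usage(counts, regime).approx
        print(f"Model III {regime}: " + ":".join(
            f"{weights[p]:g}" for p in nw.PATHWAY_NAMES))
        out[f"model_iii_{regime}"] = weights

    k_wsp = nm.solve_hotspot_factor(
        "II", MEASURED["Aws"] / MEASURED["Wsp"], {"n": 3}, {"n": 7})
    k_mws = nm.solve_hotspot_factor(
        "II", MEASURED["Aws"] / MEASURED["Mws"], {"n": 3}, {"n": 1})
    k3 = nm.solve_hotspot_factor(
        "III", MEASURED["Aws"] / MEASURED["Wsp"],
        {"n_disabling": 1, "n_enabling": 3, "p_d": 0.001, "p_e": 0.0001},
        {"n_disabling": 2, "n_enabling": 4, "p_d": 0.001, "p_e": 0.0001})
    print(f"Model II hotspot factors: k = {k_wsp:.1f} (Aws/Wsp), {k_mws:.1f} (Aws/Mws)")
    print(f"Model III hotspot factor (p_d=1e-3, p_e=1e-4): k = {k3:.2f} (Aws/Wsp)")
    out["hotspot_factors"] = {"model_ii_aws_wsp": k_wsp,
                              "model_ii_aws_mws": k_mws,
                              "model_iii_aws_wsp": k3}

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2))
    print(f"wrote {args.out}")
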
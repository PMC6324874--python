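"""Estimate per-pathway mutation rates to WS from the fluctuation data.

Fits the Ma-Sandri-Sarkar MLE to each pathway's mutant counts, compares the
pathways pairwise on the log scale, and checks that the three rates add up
to roughly the wild-type rate — the signature that Wsp, Aws and Mws are the
primary routes to WS.
"""

import argparse
import json
from pathlib import Path

from wsforecast.rates import FluctuationDataset, compare_rates, mss_mle, rate_sum

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/rates.json"))
    args = ap.parse_args()

    estimates = {}
    for path in sorted(args.data_dir.glob("fluctuation_*.tsv")):
        data = FluctuationDataset.from_tsv(path)
        est = mss_mle(data)
        estimates[data.label] = est
        lo, hi = est.ci95
        print(
            f"{data.label:4s}: mu = {est.mu_hat:.2e} per cell per generation "
            f"(95% CI {lo:.2e}-{hi:.2e}, m = {est.m_hat:.3f}, C = {est.n_cultures})"
        )

    names = sorted(estimates)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = compare_rates(estimates[a], estimates[b])
            note = " (N_t differ: interpret with caution)" if res.population_size_caveat else ""
            print(f"{a} vs {b}: z = {res.z:+.2f}, p = {res.p_value:.3g}{note}")

    total = rate_sum(estimates)
    print(f"sum of pathway rates: {total:.3e} (measured WT rate was ~1.12e-8)")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(
        {
            "pathways": {
                k: {"m_hat": e.m_hat, "mu_hat": e.mu_hat, "ci95": list(e.ci95)}
                for k, e in estimates.items()
            },
            "rate_sum": total,
        },
        indent=2,
    ))
    print(f"wrote {args.out}")
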
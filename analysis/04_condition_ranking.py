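#!/usr/bin/env python
"""Compare conditions non-parametrically on per-compound RSD ranks.

For each compound the RSD is ranked 1..6 across conditions (1 = most
repeatable), then a Kruskal–Wallis test is run on the condition columns of
the rank matrix followed by a Tukey–Kramer comparison of mean ranks.
Writes the rank matrix and the test results under results/ranking/.
"""

import argparse
import json
from pathlib import Path

import plateqc as pq

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--plate", type=Path,
                        default=ROOT / "results" / "plate.csv")
    parser.add_argument("--outdir", type=Path,
                        default=ROOT / "results" / "ranking")
    parser.add_argument("--missing", choices=["ignore", "worst_rank"],
                        default="ignore")
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()

    panel = pq.load_panel("p400")
    qc = pq.run_qc(pq.read_plate(args.plate, panel))
    summary = pq.summarize(qc)

    args.outdir.mkdir(parents=True, exist_ok=True)
    for mtype in (pq.LC, pq.FIA):
        names = [n for n in summary.rsd.index
                 if panel.measurement_type_of(n) == mtype]
        metric = summary.rsd.loc[names].dropna(how="all")
        result = pq.compare_conditions(metric, alpha=args.alpha,
                                       missing=args.missing)
        result.ranks.to_csv(args.outdir / f"ranks_{mtype}.csv")
        payload = {
            "H": result.H, "p": result.p, "alpha": result.alpha,
            "n_compounds": len(result.ranks),
            "pairwise": [
                {"pair": list(pair), "mean_rank_diff": r.diff, "q": r.q,
                 "p": r.p, "significant": r.significant}
                for pair, r in result.posthoc.items()],
        }
        (args.outdir / f"kruskal_tukey_{mtype}.json").write_text(
            json.dumps(payload, indent=1))
        sig = [p for p, r in result.posthoc.items() if r.significant]
        print(f"{mtype}: Kruskal–Wallis H = {result.H:.2f}, "
              f"p = {result.p:.3g} over {len(result.ranks)} compounds; "
              f"{len(sig)} significant pair(s)")
        for pair in sig:
            print(f"   {pair[0]} vs {pair[1]}")


if __name__ == "__main__":
    main()
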
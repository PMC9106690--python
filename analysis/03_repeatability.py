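#!/usr/bin/env python
"""Summarize repeatability across conditions.

Prints the per-condition median RSD per measurement type and the fraction
of detected compounds with RSD below the 15% tolerance, and writes the
class-level tables under results/repeatability/.
"""

import argparse
from pathlib import Path

import plateqc as pq

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--plate", type=Path,
                        default=ROOT / "results" / "plate.csv")
    parser.add_argument("--outdir", type=Path,
                        default=ROOT / "results" / "repeatability")
    args = parser.parse_args()

    panel = pq.load_panel("p400")
    qc = pq.run_qc(pq.read_plate(args.plate, panel))
    summary = pq.summarize(qc)

    args.outdir.mkdir(parents=True, exist_ok=True)
    summary.rsd.to_csv(args.outdir / "rsd_per_compound.csv")
    summary.median_rsd_by_class.to_csv(args.outdir / "median_rsd_by_class.csv")
    summary.detected_counts.to_csv(args.outdir / "detected_counts.csv")

    print("median RSD [%] per measurement type and condition:")
    print(summary.median_rsd_by_type.round(1).to_string())
    print("\ndetected compounds with RSD < 15%:")
    for (mtype, cond), (n_below, n_det) in summary.below_threshold.items():
        print(f"  {mtype:3s} {cond:10s} {pq.format_fraction(n_below, n_det)}")


if __name__ == "__main__":
    main()
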
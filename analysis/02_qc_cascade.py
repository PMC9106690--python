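#!/usr/bin/env python
"""Run the QC filter cascade on the simulated plate.

Reads results/plate.csv, applies LOD / detection / normalization / outlier /
sparsity filtering and writes the filtered matrix, the detected-count and
RSD tables and the JSON audit trail under results/qc/.
"""

import argparse
import json
from collections import Counter
from pathlib import Path

import plateqc as pq

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--plate", type=Path, default=ROOT / "results" / "plate.csv")
    parser.add_argument("--outdir", type=Path, default=ROOT / "results" / "qc")
    args = parser.parse_args()

    panel = pq.load_panel("p400")
    plate = pq.read_plate(args.plate, panel)
    qc = pq.run_qc(plate)
    summary = pq.summarize(qc)
    paths = pq.write_report(qc, summary, args.outdir)

    rules = Counter(e["rule"] for e in qc.rejected)
    n_input = int(plate.sample_values().notna().sum().sum())
    n_kept = sum(len(v) for v in qc.retained.values())
    print(f"input sample values: {n_input}; retained: {n_kept}")
    print(f"rejections by rule: {dict(rules)}")
    print(f"removed outlier injections: {qc.removed_injections()}")
    print(f"retained compounds: {len(qc.retained_compounds())}/{len(panel)}")
    print("report files:",
          json.dumps({k: str(v) for k, v in paths.items()}, indent=1))

    truth_path = ROOT / "results" / "ground_truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        lod_rejected = {e["compound"] for e in qc.rejected
                        if e["rule"] == "lod"}
        planted = set(truth["below_floor"])
        print(f"planted below-floor compounds LOD-rejected: "
              f"{len(lod_rejected & planted)}/{len(planted)}")


if __name__ == "__main__":
    main()
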
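"""Process simulated reads into a per-round variant count table.

Trims adapters, merges read pairs by best ungapped overlap, applies the
minimum-quality filter and dereplicates exact sequences, mirroring the
standard amplicon-counting path. Requires the FASTQ files written by
02_simulate_screen.py.

Writes scratch/screen/round_table.csv (input for 04) and
results/read_processing_report.csv (per-stage read fates).
"""

from pathlib import Path

import pandas as pd

from libscreen.reads import dereplicate, process_round
from libscreen.screen_sim import ReadErrorModel

SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "screen"
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pairs = sorted(SCRATCH.glob("*_R1.fastq"))
    if not pairs:
        raise SystemExit("no FASTQ input - run analysis/02_simulate_screen.py first")
    model = ReadErrorModel()
    reads, reports = {}, []
    for r1 in pairs:
        label = r1.name[: -len("_R1.fastq")]
        seqs, report = process_round(r1, SCRATCH / f"{label}_R2.fastq",
                                     adapters=(model.adapter_fwd, model.adapter_rev))
        reads[label] = seqs
        reports.append({"round": label, **report,
                        "unique_sequences": len(set(seqs))})
    table = dereplicate(reads)
    table.to_csv(SCRATCH / "round_table.csv")
    df = pd.DataFrame(reports)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "read_processing_report.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nround table with {table.n_unique():,} unique sequences -> "
          f"{SCRATCH / 'round_table.csv'}")


if __name__ == "__main__":
    main()
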
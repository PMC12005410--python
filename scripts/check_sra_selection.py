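"""Optional check of selection percentages on downloaded sequencing runs.

The published selection rates of the real libraries can only be reproduced
from the raw FASTQ files (BioProject PRJNA1158698), which are not shipped
with this package.  After downloading them (e.g. with sra-tools'
``fasterq-dump``), run:

    python scripts/check_sra_selection.py --mode tail --tail-base A polyA.fastq.gz
    python scripts/check_sra_selection.py --mode adapter adapter.fastq.gz

and compare the printed percentage with the published per-library values
(polyA 99.6%, polyC libraries 85.7% / 89.9%, 3'-adapter 84.6%).
"""

import argparse

import tailend as te
from tailend.trim import AdapterSpec, TailSpec


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("fastq", nargs="+")
    parser.add_argument("--mode", choices=["tail", "adapter"], default="tail")
    parser.add_argument("--tail-base", choices=list("ACGT"), default="A")
    parser.add_argument("--adapter-seed", default="AGATCGG")
    args = parser.parse_args()

    if args.mode == "tail":
        spec = TailSpec(tail_base=args.tail_base)
        trim_one = lambda rec: te.trim_tailed_read(rec, spec)
    else:
        spec = AdapterSpec(seed=args.adapter_seed)
        trim_one = lambda rec: te.trim_adapter_read(rec, spec)

    for path in args.fastq:
        stats = te.selection_stats(trim_one(rec) for rec in te.read_fastq(path))
        print(f"{path}: {stats}")


if __name__ == "__main__":
    main()
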
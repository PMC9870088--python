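#!/usr/bin/env python
"""Build the synthetic screen workspace with a planted secreted hepatokine.

Writes every pipeline input under results/workspace/ (gene annotation,
replicate peak BEDs with pseudoreplicates, per-peak counts, GWAS summary
statistics, expression matrix, secretome flags, gene-set library) plus the
ground-truth sidecar and a ready-to-run screen config.
"""

import argparse
import logging
import sys
from pathlib import Path

from hepascreen import synthdata as sd
from hepascreen.io import read_json

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "workspace")
    args = parser.parse_args()
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)

    paths = sd.simulate_workspace(args.out, seed=args.seed)
    truth = sd.SyntheticTruth.from_dict(read_json(paths["truth"]))
    print(f"workspace: {args.out}")
    print(f"planted hepatokine: {truth.planted_hepatokine} "
          f"(target set of {len(truth.target_gene_set)} genes, "
          f"GWAS effect {truth.gwas_effect})")
    print(f"markers (composite activity panel): {', '.join(truth.markers)}")
    print(f"config: {paths['config']}")


if __name__ == "__main__":
    main()
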
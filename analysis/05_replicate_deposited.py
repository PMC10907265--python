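"""Optional full-data replication against the deposited study data.

The anonymized woman-level CSV from the study's public OSF archive is not
redistributed here; download it manually, arrange the columns to the
package's dialect (or supply --column-map name=canonical pairs), add a
population metadata CSV, and run:

    python analysis/05_replicate_deposited.py --data path/to/deposited.csv \
        --meta path/to/populations.csv

This refits all eleven per-predictor models and the two group-level models
with long chains and writes pooled and per-population dCF~ tables to
results/replication/.  It is a long run on real data and is stochastic and
data-dependent; the synthetic pipeline in analyses 01-04 is the tested,
self-contained path.
"""

import argparse
from pathlib import Path

from fertgrowth.replication import run_replication

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, required=True, help="deposited anonymized CSV")
    ap.add_argument("--meta", type=Path, required=True, help="population metadata CSV")
    ap.add_argument("--out", type=Path, default=ROOT / "results/replication")
    ap.add_argument("--column-map", nargs="*", default=[],
                    metavar="FILECOL=CANONICAL")
    ap.add_argument("--chains", type=int, default=2)
    ap.add_argument("--warmup", type=int, default=1000)
    ap.add_argument("--samples", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cmap = dict(pair.split("=", 1) for pair in args.column_map) or None
    table = run_replication(
        args.data, args.meta, args.out, column_map=cmap,
        chains=args.chains, warmup=args.warmup, samples=args.samples, seed=args.seed,
    )
    pooled = table[(table.scope == "pooled") & (table.cf_or_delta == "delta_cf")]
    print(pooled.to_string(index=False))


if __name__ == "__main__":
    main()
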
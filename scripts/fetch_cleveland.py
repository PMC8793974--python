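#!/usr/bin/env python
"""Download the processed Cleveland heart-disease table from the UCI archive.

The library never downloads data on its own; run this once to place the
file where the optional real-data integration test and the CLI expect it:

    python scripts/fetch_cleveland.py [--dest data/processed.cleveland.data]

The file is a 303-row, 14-column comma-separated table ("?" = missing);
row-level cleaning drops six incomplete records, leaving n = 297.
"""

import argparse
import urllib.request
from pathlib import Path

URL = (
    "https://archive.ics.uci.edu/ml/machine-learning-databases/"
    "heart-disease/processed.cleveland.data"
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dest", default="data/processed.cleveland.data")
    args = ap.parse_args()
    dest = Path(args.dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    print(f"fetching {URL}")
    with urllib.request.urlopen(URL) as resp:
        dest.write_bytes(resp.read())
    n_rows = sum(1 for line in dest.read_text().splitlines() if line.strip())
    print(f"wrote {dest} ({n_rows} rows)")


if __name__ == "__main__":
    main()
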
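#!/usr/bin/env python
"""Download the two antithrombin crystal structures used by the real-data
checks (native repressed form 1T1F, pentasaccharide-activated form 1EO3)
into data/structures/. Needs network access to files.rcsb.org; run once.

    python scripts/fetch_structures.py
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

ENTRIES = ("1T1F", "1EO3")
DEST = Path(__file__).resolve().parents[1] / "data" / "structures"


def main() -> None:
    DEST.mkdir(parents=True, exist_ok=True)
    for code in ENTRIES:
        target = DEST / f"{code}.pdb"
        if target.exists():
            print(f"{target} already present, skipping")
            continue
        url = f"https://files.rcsb.org/download/{code}.pdb"
        print(f"fetching {url} -> {target}")
        with urllib.request.urlopen(url, timeout=60) as resp:
            target.write_bytes(resp.read())
    print("done")


if __name__ == "__main__":
    main()
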
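#!/usr/bin/env python
"""Cross-species conservation of the four bidirectional promoters.

Classifies each of BIP1-BIP4 in six gramineous species (O. sativa,
S. bicolor, S. italica, B. distachyon, Z. mays, T. aestivum) as regulated
by a conserved (c-BIP) or non-conserved (n-BIP) bidirectional promoter:
c-BIP when some ortholog of each member still forms a head-to-head
divergent pair in that species' annotation.  The published matrix gives
BIP1 and BIP3 conserved in 4 of 6 species, BIP4 in 3, BIP2 in 2.
"""

import argparse
from pathlib import Path

from bipscan.conservation import conservation_profile, profiles_to_frame
from bipscan.fixtures import table1_pairs, table3_scenario

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    inputs = table3_scenario()
    profiles = [conservation_profile(p, inputs) for p in table1_pairs()]
    report = profiles_to_frame(profiles)
    report.to_csv(results / "conservation.tsv", sep="\t", index=False)
    for prof in profiles:
        conserved = [c.species_id for c in prof.calls if c.call == "c-BIP"]
        print(f"{prof.pair_id}: c-BIP in {prof.n_conserved}/6 species "
              f"({', '.join(conserved)})")


if __name__ == "__main__":
    main()
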
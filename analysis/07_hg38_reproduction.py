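"""Optional full-genome reproduction of the genome-only ITR statistics.

Requires a locally available hg38 FASTA (not bundled, not downloaded): pass
its path with --genome.  Recomputes total ITR hits, per-mismatch-group
counts, MITE count and median length, solo-ITR counts per group, and the
1MM-solo substitution spectrum — both over the full assembly and restricted
to the primary chromosomes (chr1-22, chrX, chrY), since degenerate-match
counts depend on whether alt/unplaced scaffolds are included.

This script is NOT part of the test suite: a whole-genome scan takes minutes
and the assembly is ~3 GB.
"""

import argparse
from collections import Counter

import pyfaidx

from itrscan import (
    MotifSpec,
    element_length_summary,
    group_by_mismatch,
    pair_itrs,
    scan_motif,
    solo_itrs_by_group,
)

PRIMARY = {f"chr{i}" for i in range(1, 23)} | {"chrX", "chrY"}


def report(hits, label: str) -> None:
    print(f"\n== {label} ==")
    counts = group_by_mismatch(hits)
    print(f"total ITR hits: {len(hits)}  per group: {counts}")
    elements = pair_itrs(hits, max_gap=500)
    summary = element_length_summary(elements)
    solos = solo_itrs_by_group(elements)
    print(f"MITEs: {summary['n']} (median length {summary['median']} bp); "
          f"solo ITRs per group: {solos}")
    one_mm = [e.hits[0] for e in elements
              if e.kind == "solo" and e.hits[0].mismatch_count == 1]
    spectrum = Counter(
        (h.profile[0].position, h.profile[0].motif_base, h.profile[0].observed_base)
        for h in one_mm
    )
    print("top 1MM-solo substitutions (position, change, % of 1MM solos):")
    for (pos, frm, to), n in spectrum.most_common(10):
        print(f"  {frm}{pos}>{to}: {n} ({100 * n / len(one_mm):.1f}%)")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--genome", required=True,
                    help="path to a local hg38 FASTA (uncompressed or bgzipped)")
    args = ap.parse_args()

    fa = pyfaidx.Fasta(args.genome, as_raw=True, sequence_always_upper=True)
    motif = MotifSpec()
    all_hits, primary_hits = [], []
    for name in fa.keys():
        hits = scan_motif({name: str(fa[name][:])}, motif)
        all_hits.extend(hits)
        if name in PRIMARY:
            primary_hits.extend(hits)
    report(all_hits, "full assembly (incl. alt/unplaced scaffolds)")
    report(primary_hits, "primary chromosomes only (chr1-22, chrX, chrY)")


if __name__ == "__main__":
    main()
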
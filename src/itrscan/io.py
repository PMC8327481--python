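"""Readers and writers for the plain-text genomics formats the pipeline uses.

FASTA is read through pyfaidx and GTF through gffutils; BED/narrowPeak/
bedGraph/chrom.sizes/FPKM tables are simple tab-separated files written and
parsed here.  All genomic intervals are 0-based half-open except GTF, which
is 1-based inclusive on disk.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import gffutils
import pyfaidx

from .affinity_analysis import SignalTrack
from .element_annotation import MITE, ItrElement
from .genome_scan import ItrHit, MismatchEntry, MotifSpec, mismatch_profile
from .peak_analysis import GeneModel, Interval, Peak


# -- FASTA ---------------------------------------------------------------------

def read_fasta(path: str) -> Dict[str, str]:
    fa = pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- ITR hits (BED6 + matched_seq + profile) ------------------------------------

def write_hits_bed(hits: Sequence[ItrHit], path: str) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\tITR_{h.mismatch_count}MM\t"
                f"{h.mismatch_count}\t{h.strand}\t{h.matched_seq}\t{h.profile_string()}\n"
            )


def _parse_profile(text: str) -> Tuple[MismatchEntry, ...]:
    if text in (".", ""):
        return ()
    entries = []
    for item in text.split(","):
        pos, change = item.split(":")
        frm, to = change.split(">")
        entries.append(MismatchEntry(int(pos), frm, to))
    return tuple(entries)


def read_hits_bed(path: str) -> List[ItrHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, _name, score, strand = f[:6]
            matched = f[6]
            profile = _parse_profile(f[7]) if len(f) > 7 else ()
            hits.append(
                ItrHit(chrom, int(start), int(end), strand, int(score), profile, matched)
            )
    return hits


# -- elements -------------------------------------------------------------------

def write_elements_bed(elements: Sequence[ItrElement], path: str) -> None:
    with open(path, "w") as fh:
        for e in sorted(elements, key=lambda e: (e.chrom, e.span_start)):
            name = "MITE" if e.kind == MITE else f"sITR_{e.min_mismatch}MM"
            fh.write(
                f"{e.chrom}\t{e.span_start}\t{e.span_end}\t{name}\t"
                f"{e.min_mismatch}\t.\n"
            )


# -- peaks ----------------------------------------------------------------------

def write_narrowpeak(peaks: Sequence[Peak], path: str) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name if p.name != "." else f"peak_{i + 1}"
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t0\t.\t"
                f"{p.score:.4g}\t-1\t-1\t{p.summit - p.start}\n"
            )


def read_narrowpeak(path: str) -> List[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            if len(f) >= 10 and int(f[9]) >= 0:
                summit = start + int(f[9])
            else:
                summit = (start + end) // 2
            score = float(f[6]) if len(f) >= 7 else 0.0
            peaks.append(Peak(chrom, start, end, summit, score, name))
    return peaks


def read_bed6_peaks(path: str) -> List[Peak]:
    """BED intervals as peaks; the summit defaults to the interval midpoint."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            peaks.append(Peak(chrom, start, end, (start + end) // 2, score, name))
    return peaks


# -- generic BED / chrom.sizes ----------------------------------------------------

def read_bed(path: str) -> List[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bed(intervals: Sequence[Interval], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_chrom_sizes(path: str) -> Dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            out[name] = int(size)
    return out


def write_chrom_sizes(sizes: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for name in sizes:
            fh.write(f"{name}\t{sizes[name]}\n")


# -- bedGraph ---------------------------------------------------------------------

def read_bedgraph(path: str) -> SignalTrack:
    intervals: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split()[:4]
            intervals.setdefault(chrom, []).append((int(s), int(e), float(v)))
    return SignalTrack(intervals)


def write_bedgraph(track: SignalTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in track.to_intervals().items():
            for s, e, v in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# -- GTF ----------------------------------------------------------------------------

def read_gtf(path: str) -> List[GeneModel]:
    """Gene models (gene span + exons) from a GTF file, via gffutils."""
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: List[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = tuple(
            sorted(
                (e.start - 1, e.end)
                for e in db.children(g, featuretype="exon")
            )
        )
        genes.append(
            GeneModel(
                g.attributes["gene_id"][0], g.seqid, g.strand, g.start - 1, g.end, exons
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gtf(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tsynthetic\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for a, b in g.exons:
                fh.write(
                    f"{g.chrom}\tsynthetic\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# -- FPKM table ------------------------------------------------------------------------

def read_fpkm(path: str) -> Dict[str, float]:
    """gene_id -> FPKM.  Duplicate gene ids keep the maximum FPKM."""
    out: Dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("gene_id"):
            fh.seek(0)
        for line in fh:
            if not line.strip():
                continue
            gid, val = line.split("\t")[:2]
            v = float(val)
            if v < 0:
                raise ValueError(f"negative FPKM for {gid}")
            out[gid] = max(out.get(gid, 0.0), v)
    return out


def write_fpkm(fpkm: Mapping[str, float], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfpkm\n")
        for gid in fpkm:
            fh.write(f"{gid}\t{fpkm[gid]:.6g}\n")
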
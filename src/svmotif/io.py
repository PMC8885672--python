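"""Readers and writers for SV junction and copy-number formats.

Supported formats: VCF 4.x breakend (BND) records paired through MATEID,
10-column BEDPE junction files, tab-delimited copy-number segment tables and
sample -> cancer-type maps.  Internally all coordinates are 1-based
inclusive; BEDPE's 0-based half-open starts are converted on read/write.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .model import (
    Adjacency,
    Breakend,
    CancerTypeMap,
    CopyNumberSegment,
    Side,
    validate_cancer_map,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A record or file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# VCF breakends
# ---------------------------------------------------------------------------

_BND_RE = re.compile(
    r"^(?P<seq_before>[A-Za-z.*]*)"
    r"(?P<b1>[\[\]])(?P<mchrom>[^\[\]:]+):(?P<mpos>\d+)(?P<b2>[\[\]])"
    r"(?P<seq_after>[A-Za-z.*]*)$"
)


def parse_breakend_alt(
    alt: str, chrom: str, pos: int
) -> tuple[tuple[str, int], Side, Side]:
    """Decode a VCF 4.x BND bracket ALT string.

    Returns ``((mate_chrom, mate_pos), side_here, side_mate)``.

    The four bracket forms decode as follows (``t`` = replacement sequence,
    ``p`` = mate locus):

    ========  ==============  ==============
    ALT       side here       side mate
    ========  ==============  ==============
    ``t[p[``  extends_left    extends_right
    ``t]p]``  extends_left    extends_left
    ``]p]t``  extends_right   extends_left
    ``[p[t``  extends_right   extends_right
    ========  ==============  ==============

    Sequence-first ALTs keep the local left flank (the junction continues
    rightward into the mate); bracket-first ALTs keep the local right flank.
    A ``[`` bracket means the mate's right flank is joined, ``]`` its left.
    """
    m = _BND_RE.match(alt)
    if m is None:
        raise FormatError(f"malformed BND ALT {alt!r} at {chrom}:{pos}")
    if m["b1"] != m["b2"]:
        raise FormatError(f"mismatched brackets in BND ALT {alt!r} at {chrom}:{pos}")
    seq_before, seq_after = m["seq_before"], m["seq_after"]
    if bool(seq_before) == bool(seq_after):
        raise FormatError(
            f"BND ALT {alt!r} at {chrom}:{pos} must carry sequence on exactly one side"
        )
    side_here = Side.EXTENDS_LEFT if seq_before else Side.EXTENDS_RIGHT
    side_mate = Side.EXTENDS_RIGHT if m["b1"] == "[" else Side.EXTENDS_LEFT
    return (m["mchrom"], int(m["mpos"])), side_here, side_mate


def _bnd_alt(here: Breakend, mate: Breakend, ref: str = "N") -> str:
    locus = f"{mate.chrom}:{mate.pos}"
    bracket = "[" if mate.side is Side.EXTENDS_RIGHT else "]"
    core = f"{bracket}{locus}{bracket}"
    if here.side is Side.EXTENDS_LEFT:
        return f"{ref}{core}"
    return f"{core}{ref}"


def read_vcf_breakends(path: str | Path, sample_id: str) -> list[Adjacency]:
    """Read BND records from a VCF, pairing mates via the MATEID INFO field.

    Each mate pair yields exactly one :class:`Adjacency`.  Records without a
    MATEID, with a malformed ALT, or whose mate never appears in the file are
    reported via the module logger and dropped.
    """
    pending: dict[str, tuple[str, Breakend, Side, tuple[str, int]]] = {}
    adjacencies: list[Adjacency] = []
    n_dropped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.id is None or not rec.alts:
                continue
            alt = rec.alts[0]
            if "[" not in alt and "]" not in alt:
                continue  # not a breakend record
            try:
                (mchrom, mpos), side_here, side_mate = parse_breakend_alt(
                    alt, rec.chrom, rec.pos
                )
            except FormatError as exc:
                logger.warning("dropping record %s: %s", rec.id, exc)
                n_dropped += 1
                continue
            mateid = rec.info.get("MATEID")
            if mateid is None:
                logger.warning("dropping BND record %s: no MATEID", rec.id)
                n_dropped += 1
                continue
            if isinstance(mateid, tuple):
                mateid = mateid[0]
            here = Breakend(sample_id, rec.chrom, rec.pos, side_here)
            if mateid in pending:
                mate_rec_id, mate_end, mate_decl_side, mate_locus = pending.pop(mateid)
                # sanity: the two records must point at each other
                if mate_locus != (rec.chrom, rec.pos):
                    logger.warning(
                        "mate pair %s/%s: loci disagree, keeping record coordinates",
                        rec.id,
                        mate_rec_id,
                    )
                adjacencies.append(
                    Adjacency(
                        id=f"{min(rec.id, mate_rec_id)}",
                        sample_id=sample_id,
                        end_a=mate_end,
                        end_b=here,
                    )
                )
            else:
                pending[rec.id] = (rec.id, here, side_mate, (mchrom, mpos))
    for rec_id, *_ in pending.values():
        logger.warning("dropping BND record %s: mate not found in file", rec_id)
    n_dropped += len(pending)
    if n_dropped:
        logger.warning("%s: dropped %d unpaired/invalid BND records", path, n_dropped)
    return adjacencies


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=MATEID,Number=.,Type=String,Description="ID of mate breakend">
"""


def write_vcf_breakends(
    adjacencies: Iterable[Adjacency],
    genome: dict[str, int],
    path: str | Path,
) -> None:
    """Write adjacencies as paired VCF BND records (two records per junction)."""
    lines = [_VCF_HEADER]
    for chrom, length in genome.items():
        lines.append(f"##contig=<ID={chrom},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for adj in adjacencies:
        ids = (f"{adj.id}_1", f"{adj.id}_2")
        ends = adj.ends
        for i, (end, mate) in enumerate(zip(ends, ends[::-1])):
            alt = _bnd_alt(end, mate)
            lines.append(
                f"{end.chrom}\t{end.pos}\t{ids[i]}\tN\t{alt}\t.\t.\t"
                f"SVTYPE=BND;MATEID={ids[1 - i]}\n"
            )
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

_STRAND_TO_SIDE = {"+": Side.EXTENDS_RIGHT, "-": Side.EXTENDS_LEFT}
_SIDE_TO_STRAND = {v: k for k, v in _STRAND_TO_SIDE.items()}


def read_bedpe(path: str | Path, sample_id: str) -> list[Adjacency]:
    """Read a 10-column BEDPE junction file.

    Columns: chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2.
    BEDPE starts are 0-based half-open; the breakend position is taken as
    ``start + 1`` (the 1-based base).  Strands map to sides:
    ``+`` -> extends_right, ``-`` -> extends_left.  Duplicate names are made
    unique by suffixing the line number.
    """
    adjacencies: list[Adjacency] = []
    seen_names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 BEDPE columns, got {len(fields)}"
                )
            c1, s1, _e1, c2, s2, _e2, name, _score, st1, st2 = fields
            try:
                side1, side2 = _STRAND_TO_SIDE[st1], _STRAND_TO_SIDE[st2]
            except KeyError as exc:
                raise FormatError(f"{path}:{lineno}: bad strand {exc}") from None
            adj_id = name if name not in seen_names else f"{name}.{lineno}"
            seen_names.add(adj_id)
            adjacencies.append(
                Adjacency(
                    id=adj_id,
                    sample_id=sample_id,
                    end_a=Breakend(sample_id, c1, int(s1) + 1, side1),
                    end_b=Breakend(sample_id, c2, int(s2) + 1, side2),
                )
            )
    return adjacencies


def write_bedpe(adjacencies: Iterable[Adjacency], path: str | Path) -> None:
    """Write adjacencies as 10-column BEDPE (inverse of :func:`read_bedpe`)."""
    with open(path, "w") as fh:
        for adj in adjacencies:
            a, b = adj.ends
            fh.write(
                "\t".join(
                    [
                        a.chrom, str(a.pos - 1), str(a.pos),
                        b.chrom, str(b.pos - 1), str(b.pos),
                        adj.id, ".",
                        _SIDE_TO_STRAND[a.side], _SIDE_TO_STRAND[b.side],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Copy-number segments & cancer-type map
# ---------------------------------------------------------------------------

CN_COLUMNS = ["sample", "chrom", "start", "end", "total_cn"]


def read_cn_segments(path: str | Path) -> list[CopyNumberSegment]:
    """Read a tab-delimited copy-number table (header: sample chrom start end total_cn).

    Segments are returned grouped by (sample, chrom) and sorted by start;
    overlap within one sample/chromosome or a negative copy number raises.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(CN_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    segments: list[CopyNumberSegment] = []
    for (sample_id, chrom), group in df.groupby(["sample", "chrom"], sort=True):
        group = group.sort_values("start")
        prev_end = 0
        for row in group.itertuples():
            seg = CopyNumberSegment(
                sample_id=str(sample_id),
                chrom=str(chrom),
                start=int(row.start),
                end=int(row.end),
                total_cn=float(row.total_cn),
            )
            if seg.start <= prev_end:
                raise FormatError(
                    f"{path}: overlapping segments in {sample_id}/{chrom} at {seg.start}"
                )
            prev_end = seg.end
            segments.append(seg)
    return segments


def write_cn_segments(segments: Sequence[CopyNumberSegment], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.chrom, s.start, s.end, s.total_cn) for s in segments],
        columns=CN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_cancer_map(path: str | Path) -> CancerTypeMap:
    """Read a 2-column tab-delimited sample -> cancer-type table (header: sample cancer_type)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"sample", "cancer_type"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns 'sample' and 'cancer_type'")
    return validate_cancer_map(dict(zip(df["sample"], df["cancer_type"])))


def write_cancer_map(mapping: CancerTypeMap, path: str | Path) -> None:
    pd.DataFrame(
        sorted(mapping.items()), columns=["sample", "cancer_type"]
    ).to_csv(path, sep="\t", index=False)
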
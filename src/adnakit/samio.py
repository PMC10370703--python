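"""Minimal text-SAM layer for damage profiling and read counting.

Reference bases are reconstructed from CIGAR + MD tag alone (no FASTA is
ever consulted), via pysam's aligned-pairs machinery.  Soft-clipped bases
are excluded from both the read and reference strings, so downstream
per-position statistics never see them.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, TextIO

import pysam

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SamError(ValueError):
    """Raised for records that violate the SAM subset this layer accepts."""


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read with its reconstructed reference.

    ``read_sequence`` and ``reference_sequence`` cover the aligned
    (match/mismatch) columns only and are equal in length; ``start`` is
    1-based; ``strand`` is '+' or '-' in reference orientation.
    """

    name: str
    flags: int
    chromosome: str
    start: int
    mapq: int
    read_sequence: str
    reference_sequence: str
    strand: str

    def __post_init__(self) -> None:
        if len(self.read_sequence) != len(self.reference_sequence):
            raise SamError(
                f"read {self.name}: read/reference spans differ in length"
            )
        if not 0 <= self.mapq <= 255:
            raise SamError(f"read {self.name}: MAPQ {self.mapq} out of range")
        if self.strand not in "+-":
            raise SamError(f"read {self.name}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return len(self.read_sequence)

    def molecule_sequences(self) -> tuple[str, str]:
        """(read, reference) in original-molecule orientation.

        Reverse-strand alignments are reverse-complemented so that index 0
        is the molecule's 5' terminus — the frame deamination acts in.
        """
        if self.strand == "+":
            return self.read_sequence, self.reference_sequence
        return (
            self.read_sequence[::-1].translate(_COMPLEMENT),
            self.reference_sequence[::-1].translate(_COMPLEMENT),
        )

    def mask_ends(self, t: int) -> "AlignedRead":
        """Return a copy with t bases at each end replaced by N."""
        if t < 0:
            raise ValueError("mask length must be non-negative")
        if t == 0:
            return self
        n = self.length
        seq = "".join(
            "N" if (i < t or i >= n - t) else b
            for i, b in enumerate(self.read_sequence)
        )
        return replace(self, read_sequence=seq)


def _ensure_header(text: str) -> str:
    """Synthesize an @SQ header when the stream has none.

    pysam cannot resolve reference names from a headerless SAM, so the
    reference names seen in the records are declared with a generous
    length before parsing.
    """
    lines = text.splitlines()
    if any(line.startswith("@SQ") for line in lines):
        return text
    refs: list[str] = []
    for line in lines:
        if line.startswith("@") or not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) > 2 and fields[2] != "*" and fields[2] not in refs:
            refs.append(fields[2])
    header = ["@HD\tVN:1.6\tSO:unknown"]
    header += [f"@SQ\tSN:{r}\tLN:536870911" for r in refs]
    body = [line for line in lines if not line.startswith("@HD")]
    return "\n".join(header + body) + "\n"


def parse_sam(
    source: str | Path | TextIO, require_md: bool = True
) -> list[AlignedRead]:
    """Parse a text SAM stream into AlignedRead records.

    Unmapped records (FLAG 0x4) are skipped and counted in the log.  When
    ``require_md`` the reference is reconstructed from the MD tag and a
    record lacking one raises :class:`SamError` naming the read; with
    ``require_md=False`` such records get a reference of 'N's.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    text = _ensure_header(text)
    reads: list[AlignedRead] = []
    n_unmapped = 0
    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as tf:
        tf.write(text)
        tmp_path = tf.name
    try:
        with pysam.AlignmentFile(tmp_path, "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped:
                    n_unmapped += 1
                    continue
                read_cols: list[str] = []
                ref_cols: list[str] = []
                if rec.has_tag("MD"):
                    pairs = rec.get_aligned_pairs(matches_only=True, with_seq=True)
                    qseq = rec.query_sequence or ""
                    for qpos, _rpos, ref_base in pairs:
                        read_cols.append(qseq[qpos])
                        ref_cols.append(ref_base.upper())
                elif require_md:
                    raise SamError(
                        f"read {rec.query_name}: MD tag required for "
                        "reference reconstruction but absent"
                    )
                else:
                    aligned = rec.query_alignment_sequence or ""
                    read_cols = list(aligned)
                    ref_cols = ["N"] * len(aligned)
                reads.append(
                    AlignedRead(
                        name=rec.query_name,
                        flags=rec.flag,
                        chromosome=rec.reference_name,
                        start=rec.reference_start + 1,
                        mapq=rec.mapping_quality,
                        read_sequence="".join(read_cols).upper(),
                        reference_sequence="".join(ref_cols),
                        strand="-" if rec.is_reverse else "+",
                    )
                )
    finally:
        Path(tmp_path).unlink(missing_ok=True)
    if n_unmapped:
        logger.info("parse_sam: skipped %d unmapped records", n_unmapped)
    return reads


def _md_string(read: str, ref: str) -> str:
    """MD:Z value for an all-M alignment of equal-length read/ref."""
    out: list[str] = []
    run = 0
    for rb, fb in zip(read, ref):
        if rb == fb:
            run += 1
        else:
            out.append(str(run))
            out.append(fb)
            run = 0
    out.append(str(run))
    return "".join(out)


def write_sam(
    reads: Iterable[AlignedRead],
    dest: str | Path | TextIO,
    reference_lengths: dict[str, int] | None = None,
) -> None:
    """Write AlignedRead records as text SAM (all-M CIGAR, MD tag).

    Only gapless records can be serialized this way; the simulator emits
    exactly those.
    """
    reads = list(reads)
    if reference_lengths is None:
        reference_lengths = {}
        for r in reads:
            end = r.start + r.length
            reference_lengths[r.chromosome] = max(
                reference_lengths.get(r.chromosome, 0), end + 1
            )
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    lines += [f"@SQ\tSN:{c}\tLN:{n}" for c, n in reference_lengths.items()]
    for r in reads:
        flags = r.flags | (0x10 if r.strand == "-" else 0)
        nm = sum(a != b for a, b in zip(r.read_sequence, r.reference_sequence))
        lines.append(
            "\t".join(
                [
                    r.name,
                    str(flags),
                    r.chromosome,
                    str(r.start),
                    str(r.mapq),
                    f"{r.length}M",
                    "*",
                    "0",
                    "0",
                    r.read_sequence,
                    "*",
                    f"MD:Z:{_md_string(r.read_sequence, r.reference_sequence)}",
                    f"NM:i:{nm}",
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)
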
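"""Six-frame translation and protein<->nucleotide coordinate mapping.

Frames are numbered +1,+2,+3 (forward strand, starting at offsets 0,1,2) and
-1,-2,-3 (same offsets on the reverse complement).  All externally reported
nucleotide coordinates are 1-based inclusive on the forward strand; minus
frames report forward-strand intervals with strand '-'.

Any codon containing a non-ACGT base translates to 'X'; stop codons are kept
as '*' (the profile-HMM engine scores both neutrally).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .records import SequenceRecord

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class TranslatedFrame:
    """One reading-frame translation of a parent nucleotide sequence.

    ``nt_offset`` is the 0-based offset of the first codon base in the
    coordinate system the frame reads in (forward sequence for + frames,
    reverse complement for - frames).
    """

    parent_id: str
    frame: int
    protein: str
    nt_offset: int


def _translate(nt: str, table: int) -> str:
    # Biopython resolves some ambiguous codons (e.g. GGN -> G); the contract
    # here is stricter: any codon containing a non-ACGT base is 'X'.
    protein = list(str(Seq(nt).translate(table=table)))
    for i in range(len(protein)):
        if set(nt[3 * i:3 * i + 3]) - {"A", "C", "G", "T"}:
            protein[i] = "X"
    return "".join(protein)


def translate_six_frames(rec: SequenceRecord, genetic_code: int = 1) -> list[TranslatedFrame]:
    """Translate a record in all six frames.

    Sequences shorter than 3 nt yield six frames with empty proteins.
    """
    fwd = rec.seq
    rev = str(Seq(fwd).reverse_complement())
    frames: list[TranslatedFrame] = []
    for frame in FRAMES:
        offset = abs(frame) - 1
        template = fwd if frame > 0 else rev
        n_codons = max(0, (len(template) - offset) // 3)
        sub = template[offset:offset + 3 * n_codons]
        frames.append(
            TranslatedFrame(
                parent_id=rec.id,
                frame=frame,
                protein=_translate(sub, genetic_code) if sub else "",
                nt_offset=offset,
            )
        )
    return frames


def map_aa_to_nt(frame: int, aa_start: int, aa_end: int, seq_len: int) -> tuple[int, int, str]:
    """Map a 1-based inclusive amino-acid interval on a frame to forward-strand
    nucleotide coordinates.

    Returns ``(nt_start, nt_end, strand)`` with a 1-based inclusive interval of
    length ``3 * (aa_end - aa_start + 1)``.
    """
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    if not (1 <= aa_start <= aa_end):
        raise ValueError(f"need 1 <= aa_start <= aa_end, got {aa_start}..{aa_end}")
    offset = abs(frame) - 1
    # coordinates on the strand the frame reads (0-based inclusive)
    lo = offset + 3 * (aa_start - 1)
    hi = offset + 3 * aa_end - 1
    if hi >= seq_len:
        raise ValueError(
            f"aa interval {aa_start}..{aa_end} in frame {frame:+d} extends past "
            f"the sequence (length {seq_len})"
        )
    if frame > 0:
        return lo + 1, hi + 1, "+"
    # flip reverse-complement coordinates onto the forward strand
    return seq_len - hi, seq_len - lo, "-"


def extract_nt(seq: str, nt_start: int, nt_end: int, strand: str) -> str:
    """Extract a 1-based inclusive forward-strand interval, oriented by strand."""
    if not (1 <= nt_start <= nt_end <= len(seq)):
        raise ValueError(
            f"interval {nt_start}..{nt_end} outside sequence of length {len(seq)}"
        )
    sub = seq[nt_start - 1:nt_end]
    if strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return sub
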
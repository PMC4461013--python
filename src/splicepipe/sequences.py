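"""Small sequence-source helpers: plain dicts or pyfaidx.Fasta behave alike."""

from __future__ import annotations

from .errors import SequenceSourceError

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def chrom_length(genome, chrom: str) -> int:
    try:
        return len(genome[chrom])
    except KeyError as exc:
        raise SequenceSourceError(f"chromosome {chrom} absent from genome") from exc


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Extract genome[chrom][start:end] (0-based half-open, + strand).

    Works for ``{chrom: str}`` dicts and for ``pyfaidx.Fasta`` objects.
    Out-of-bounds requests raise a consistency error rather than silently
    truncating.
    """
    n = chrom_length(genome, chrom)
    if start < 0 or end > n:
        raise SequenceSourceError(
            f"requested {chrom}:[{start},{end}) outside chromosome of length {n}"
        )
    return str(genome[chrom][start:end]).upper()


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
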
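"""Small shared sequence helpers (reverse complement, FASTA I/O)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}, case-preserving."""
    return seq.translate(_COMP)[::-1]


def open_text(path, mode: str = "rt"):
    """Open a text file, transparently decompressing ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    # magic-byte sniff so mislabelled gzip files still work
    if "r" in mode and path.exists():
        with open(path, "rb") as fh:
            if fh.read(2) == b"\x1f\x8b":
                return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into an ordered ``{name: sequence}`` dict."""
    from Bio import SeqIO

    with open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Mapping[str, str] | Iterable[tuple[str, str]], path, width: int = 80) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
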
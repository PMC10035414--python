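"""Small shared helpers."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal


def natural_key(label: str) -> tuple:
    """Sort key ordering embedded integers numerically ("chr2" < "chr10")."""
    parts = re.split(r"(\d+)", label)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (school rounding, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (order preserving)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
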
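"""Model-frame domain alignment, consensus profiling and binding-class calls.

Every member domain is anchored to the fixed 79-column model frame.  A
consensus profile reports the most frequent residue and its ratio per
column, region labels partition the frame into basic / helix 1 / loop /
helix 2, and the DNA-binding class of each member is read off four
basic-region residues.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .errors import InputError
from .family_identification import MODEL_LENGTH, DomainHit, ProteinRecord

GAP = "-"

G_BOX = "G-box"
E_BOX = "E-box"
NON_E_BOX = "non-E-box"
BINDING_CLASSES = (G_BOX, E_BOX, NON_E_BOX)

#: 1-based model positions whose residues determine the binding class.
BINDING_POSITIONS = (9, 13, 16, 17)

#: Default region boundaries, 1-based inclusive column ranges.
DEFAULT_REGIONS = (
    ("basic", 1, 17),
    ("helix1", 18, 42),
    ("loop", 43, 64),
    ("helix2", 65, 79),
)


@dataclass(frozen=True)
class ConsensusColumn:
    position: int  # 1-based model column
    residue: str
    ratio: float
    region: str

    @property
    def highly_conserved(self) -> bool:
        return self.ratio > 0.5  # strict

    @property
    def extremely_conserved(self) -> bool:
        return self.ratio > 0.75  # strict


@dataclass(frozen=True)
class BindingCall:
    member: str
    residues: tuple[str, str, str, str]  # at model positions 9, 13, 16, 17
    klass: str


def align_to_model(hit: DomainHit, protein: ProteinRecord | str) -> str:
    """Project a hit onto the model frame.

    Column c holds the protein residue aligned to model column c, '-' where
    the model column is deleted.  Insertions relative to the model are
    discarded by construction of ``DomainHit.columns``.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    return "".join(GAP if c is None else seq[c] for c in hit.columns)


def _region_of(position: int, regions) -> str:
    for name, lo, hi in regions:
        if lo <= position <= hi:
            return name
    raise InputError(f"region boundaries do not cover column {position}")


def build_consensus(
    alignment: Mapping[str, str],
    regions=DEFAULT_REGIONS,
) -> list[ConsensusColumn]:
    """Per-column consensus residue and ratio.

    The consensus residue is the most frequent non-gap residue (ties broken
    alphabetically); the ratio divides its count by the total number of
    rows, gap rows included.
    """
    rows = list(alignment.values())
    if not rows:
        raise InputError("alignment has no rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise InputError("alignment rows differ in length")
    n = len(rows)
    out = []
    for c in range(width):
        counts = Counter(r[c] for r in rows if r[c] != GAP)
        if counts:
            residue, count = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            ratio = count / n
        else:
            residue, ratio = GAP, 0.0
        out.append(
            ConsensusColumn(
                position=c + 1,
                residue=residue,
                ratio=ratio,
                region=_region_of(c + 1, regions),
            )
        )
    return out


def call_conserved_residues(
    profile: Iterable[ConsensusColumn],
) -> tuple[list[tuple[int, str]], list[tuple[int, str]]]:
    """(position, residue) lists conserved at >50% and >75% (strict)."""
    highly, extremely = [], []
    for col in sorted(profile, key=lambda c: c.position):
        if col.highly_conserved:
            highly.append((col.position, col.residue))
        if col.extremely_conserved:
            extremely.append((col.position, col.residue))
    return highly, extremely


def classify_binding(row: str, member: str = "") -> BindingCall:
    """Classify a model-frame domain row by its basic-region residues.

    E-core := Glu at 13 AND Arg at 16.  With the E-core present, His/Lys at
    9 plus Arg at 17 gives G-box, otherwise E-box; without the E-core the
    row is non-E-box.  A G-box site being a special E-box, the G-box test
    requires the E-core, which makes the three classes a partition.
    Gaps fail every positional test.
    """
    if len(row) != MODEL_LENGTH:
        raise InputError(
            f"model-frame row must have {MODEL_LENGTH} columns, got {len(row)}"
        )
    r9, r13, r16, r17 = (row[p - 1] for p in BINDING_POSITIONS)
    e_core = r13 == "E" and r16 == "R"
    if e_core and r9 in ("H", "K") and r17 == "R":
        klass = G_BOX
    elif e_core:
        klass = E_BOX
    else:
        klass = NON_E_BOX
    return BindingCall(member=member, residues=(r9, r13, r16, r17), klass=klass)


def binding_census(calls: Iterable[BindingCall]) -> dict[str, int]:
    """Counts per class; always reports all three classes."""
    calls = list(calls)
    if not calls:
        raise InputError("no binding calls")
    census = {k: 0 for k in BINDING_CLASSES}
    for call in calls:
        census[call.klass] += 1
    return census


def classify_alignment(
    alignment: Mapping[str, str]
) -> tuple[list[BindingCall], dict[str, int]]:
    """Convenience: classify every row and tally the census."""
    calls = [classify_binding(row, member=name) for name, row in alignment.items()]
    return calls, binding_census(calls)
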
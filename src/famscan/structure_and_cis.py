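"""Gene-model structure statistics and promoter cis-element scanning.

GFF3 is read 1-based inclusive and stored 0-based half-open.  The
cis-element scanner matches IUPAC degenerate patterns on both strands,
counting overlapping occurrences; reverse-strand hits are reported at
their forward-coordinate offset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from ._util import natural_key, round_half_up
from .errors import ConfigurationError, FormatError, InputError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

CIS_CATEGORIES = ("growth_development", "phytohormone", "stress")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its primary transcript's exons (0-based half-open)."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]  # sorted by genomic coordinate

    def __post_init__(self):
        if not self.exons:
            raise InputError(f"gene {self.gene_id!r}: needs >= 1 exon")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise InputError(f"gene {self.gene_id!r}: empty exon ({s}, {e})")
            if s < prev_end:
                raise InputError(f"gene {self.gene_id!r}: overlapping exons")
            prev_end = e

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    @property
    def exons_5to3(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcription order (descending coords on '-')."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))


@dataclass(frozen=True)
class ExonIntronSummary:
    per_gene: dict
    family_size: int
    n_intronless: int
    pct_intronless: float
    n_one_intron: int
    pct_one_intron: float
    min_exons: int
    max_exons: int
    intronless_genes: tuple


@dataclass(frozen=True)
class CisCatalogEntry:
    name: str
    pattern: str
    category: str
    description: str = ""

    def __post_init__(self):
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ConfigurationError(
                f"element {self.name!r}: invalid IUPAC code(s) {sorted(bad)}"
            )
        if self.category not in CIS_CATEGORIES:
            raise ConfigurationError(
                f"element {self.name!r}: unknown category {self.category!r}"
            )


@dataclass(frozen=True)
class CisHit:
    gene_id: str
    element: str
    offset: int  # 0-based from the promoter 5' end (forward coordinates)
    strand: str
    length: int


# ---------------------------------------------------------------------------
# GFF3 parsing
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r"([^;=]+)=([^;]*)")


def _parse_attributes(text: str) -> dict[str, str]:
    return {k.strip(): v.strip() for k, v in _ATTR_RE.findall(text)}


def parse_gene_models(source) -> dict[str, GeneModel]:
    """Parse gene/mRNA/exon(/CDS) features into one GeneModel per gene.

    The primary transcript is the one with the longest CDS (total exon
    length when no CDS is annotated); ties go to the first transcript
    encountered.  Malformed lines are reported with their line numbers.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)

    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}
    bad_lines: list[int] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            bad_lines.append(lineno)
            continue
        seqid, _, ftype, start_s, end_s, _, strand, _, attrs_s = fields
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            bad_lines.append(lineno)
            continue
        if start1 < 1 or end1 < start1 or strand not in "+-.":
            bad_lines.append(lineno)
            continue
        attrs = _parse_attributes(attrs_s)
        start, end = start1 - 1, end1  # to 0-based half-open
        if ftype == "gene":
            gid = attrs.get("ID")
            if not gid:
                bad_lines.append(lineno)
                continue
            genes[gid] = {
                "chromosome": seqid, "strand": strand,
                "start": start, "end": end, "transcripts": [],
            }
        elif ftype == "mRNA":
            tid, parent = attrs.get("ID"), attrs.get("Parent")
            if not tid or not parent:
                bad_lines.append(lineno)
                continue
            transcripts[tid] = {"gene": parent, "exons": [], "cds_len": 0}
            genes.setdefault(parent, {
                "chromosome": seqid, "strand": strand,
                "start": start, "end": end, "transcripts": [],
            })["transcripts"].append(tid)
        elif ftype in ("exon", "CDS"):
            parent = attrs.get("Parent")
            if not parent or parent not in transcripts:
                bad_lines.append(lineno)
                continue
            if ftype == "exon":
                transcripts[parent]["exons"].append((start, end))
            else:
                transcripts[parent]["cds_len"] += end - start
    if bad_lines:
        raise FormatError(f"malformed GFF3 lines: {bad_lines}")

    models: dict[str, GeneModel] = {}
    for gid, g in genes.items():
        candidates = []
        for tid in g["transcripts"]:
            t = transcripts[tid]
            if not t["exons"]:
                continue
            exon_len = sum(e - s for s, e in t["exons"])
            cds_len = t["cds_len"] or exon_len
            candidates.append((cds_len, tid))
        if not candidates:
            # gene without annotated transcripts: treat the span as 1 exon
            exons = ((g["start"], g["end"]),)
        else:
            best_len = max(c[0] for c in candidates)
            tid = next(t for length, t in candidates if length == best_len)
            exons = tuple(sorted(transcripts[tid]["exons"]))
        models[gid] = GeneModel(
            gene_id=gid,
            chromosome=g["chromosome"],
            strand=g["strand"],
            start=g["start"],
            end=g["end"],
            exons=exons,
        )
    return models


# ---------------------------------------------------------------------------
# exon/intron statistics
# ---------------------------------------------------------------------------

def exon_intron_summary(
    models: Mapping[str, GeneModel],
    members: Iterable[str],
    subfamilies: Optional[Mapping[str, str]] = None,
) -> ExonIntronSummary:
    """Family-level exon/intron statistics over ``members``.

    Percentages use the family size as the denominator and are rounded
    half-up to one decimal.
    """
    members = list(members)
    missing = [m for m in members if m not in models]
    if missing:
        raise InputError(f"members without gene models: {sorted(missing)}")
    per_gene = {
        m: (models[m].exon_count, models[m].intron_count) for m in members
    }
    n = len(members)
    if n == 0:
        raise InputError("empty member set")
    intronless = sorted(
        (m for m in members if models[m].exon_count == 1),
        key=lambda m: natural_key(m),
    )
    one_intron = [m for m in members if models[m].exon_count == 2]
    subfamilies = subfamilies or {}
    return ExonIntronSummary(
        per_gene=per_gene,
        family_size=n,
        n_intronless=len(intronless),
        pct_intronless=round_half_up(100.0 * len(intronless) / n, 1),
        n_one_intron=len(one_intron),
        pct_one_intron=round_half_up(100.0 * len(one_intron) / n, 1),
        min_exons=min(c for c, _ in per_gene.values()),
        max_exons=max(c for c, _ in per_gene.values()),
        intronless_genes=tuple(
            (m, subfamilies.get(m, "")) for m in intronless
        ),
    )


# ---------------------------------------------------------------------------
# cis-element scanning
# ---------------------------------------------------------------------------

def load_cis_catalog(path=None) -> list[CisCatalogEntry]:
    """Load the element catalog TSV (name, pattern, category, description)."""
    if path is None:
        ref = resources.files("famscan") / "data" / "cis_catalog.tsv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    entries = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "name":
            continue
        if len(parts) < 3:
            raise ConfigurationError(f"bad catalog line: {line!r}")
        entries.append(
            CisCatalogEntry(
                name=parts[0],
                pattern=parts[1].upper(),
                category=parts[2],
                description=parts[3] if len(parts) > 3 else "",
            )
        )
    if not entries:
        raise ConfigurationError("empty cis-element catalog")
    return entries


def reverse_complement(pattern: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(pattern.upper()))


def _iupac_regex(pattern: str) -> re.Pattern:
    body = "".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in pattern.upper()
    )
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


def scan_cis_elements(
    promoters: Mapping[str, str],
    catalog: Sequence[CisCatalogEntry],
    *,
    both_strands: bool = True,
    dedup_palindromic: bool = True,
) -> tuple[list[CisHit], dict[str, int], dict[str, int]]:
    """Scan promoters for catalog elements.

    Returns (hits, per-element counts, per-category counts).  An 'N' in a
    promoter sequence matches nothing.  Identical (offset, length) hits on
    both strands collapse to one '+' occurrence when ``dedup_palindromic``.
    """
    if not catalog:
        raise ConfigurationError("catalog is empty")
    category_of = {e.name: e.category for e in catalog}
    hits: list[CisHit] = []
    for gene in sorted(promoters, key=natural_key):
        seq = promoters[gene].upper()
        for entry in catalog:
            length = len(entry.pattern)
            found: dict[tuple[int, str], CisHit] = {}
            for m in _iupac_regex(entry.pattern).finditer(seq):
                found[(m.start(), "+")] = CisHit(gene, entry.name, m.start(), "+", length)
            if both_strands:
                rc = reverse_complement(entry.pattern)
                for m in _iupac_regex(rc).finditer(seq):
                    key = (m.start(), "-")
                    if dedup_palindromic and (m.start(), "+") in found:
                        continue
                    found[key] = CisHit(gene, entry.name, m.start(), "-", length)
            hits.extend(found[k] for k in sorted(found))
    element_counts: dict[str, int] = {e.name: 0 for e in catalog}
    category_counts: dict[str, int] = {c: 0 for c in CIS_CATEGORIES}
    for h in hits:
        element_counts[h.element] += 1
        category_counts[category_of[h.element]] += 1
    return hits, element_counts, category_counts
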
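"""Synthetic genome/transcriptome/qPCR fixtures with known ground truth.

Every fixture bundles proteins with planted 79-residue domains, gene
models on named pseudo-chromosomes, promoters with planted cis-elements,
a four-treatment expression matrix with planted cluster and fold-change
structure, a GO table and a replicated Ct table — plus truth labels for
every stage.  The versioned "cp159" preset mirrors a published survey's
headline composition: 174 putative proteins reducing to 159 validated
members on 21 pseudo-chromosomes, a 93/43/23 binding-class census,
20 intronless genes (12.6%), 4 planted unexpressed members (155 retained
by the abundance filter) and a 12-gene candidate union.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import natural_key, write_fasta
from .domain_conservation import (
    BINDING_POSITIONS,
    E_BOX,
    G_BOX,
    NON_E_BOX,
    classify_binding,
)
from .errors import ConfigurationError
from .family_identification import AMINO_ACIDS, MODEL_LENGTH, ProteinRecord
from .structure_and_cis import (
    CisCatalogEntry,
    GeneModel,
    load_cis_catalog,
    scan_cis_elements,
)

# ---------------------------------------------------------------------------
# the 79-column domain model frame
# ---------------------------------------------------------------------------

#: 1-based model positions with a conserved template residue (basic region
#: 9-17, helix 1 at 20-32, loop at 64, helix 2 at 65-79).
CONSERVED_RESIDUES = {
    9: "H", 12: "A", 13: "E", 14: "R", 16: "R", 17: "R",
    20: "I", 21: "N", 23: "R", 27: "L", 30: "L", 31: "V", 32: "P",
    64: "D",
    65: "K", 66: "A", 67: "S", 69: "L", 72: "A", 73: "I", 75: "Y",
    76: "V", 77: "K", 79: "L",
}

#: The subset of conserved positions planted at very low mutation rates.
EXTREME_POSITIONS = frozenset({13, 16, 17, 23, 27, 64, 65, 69})

#: Interior positions carrying subfamily signatures (never conserved,
#: never binding, away from the domain edges).
SIGNATURE_POSITIONS = (34, 36, 38, 41, 45, 48, 52, 56, 60, 62)

#: Positions anchored at a low mutation rate so local alignments reliably
#: reach the domain boundaries (leading edge, plus the free positions in
#: the trailing stretch).
EDGE_POSITIONS = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 70, 71, 74, 78})

#: Number of trailing model columns removed from truncated decoys.
TRUNCATION_COLUMNS = 25


def _build_template() -> str:
    chars = []
    for pos in range(1, MODEL_LENGTH + 1):
        if pos in CONSERVED_RESIDUES:
            chars.append(CONSERVED_RESIDUES[pos])
        else:
            chars.append(AMINO_ACIDS[(7 * pos + 3) % 20])
    return "".join(chars)


DOMAIN_TEMPLATE = _build_template()

SUBFAMILY_LABELS = (
    "Ia", "Ib1", "Ib2", "II", "IIIac", "IIIb", "IIId", "IIIe", "IIIf",
    "IVa", "IVb", "IVc", "IVd", "Va", "Vb", "VI", "VIIab", "VIIIa",
    "VIIIb", "VIIIc1", "VIIIc2", "IX", "X", "XI", "XII", "XIII",
)


@dataclass(frozen=True)
class DomainNoise:
    """Per-site mutation rates by column class (mutations pick one of the
    19 non-template residues uniformly)."""

    extreme_rate: float = 0.12
    conserved_rate: float = 0.35
    free_rate: float = 0.6
    edge_rate: float = 0.12

    def rate_for(self, pos: int) -> float:
        if pos in BINDING_POSITIONS or pos in SIGNATURE_POSITIONS:
            return 0.0  # set explicitly elsewhere
        if pos in EXTREME_POSITIONS:
            return self.extreme_rate
        if pos in EDGE_POSITIONS:
            return self.edge_rate
        if pos in CONSERVED_RESIDUES:
            return self.conserved_rate
        return self.free_rate


NOISE_FREE = DomainNoise(0.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# presets and designs
# ---------------------------------------------------------------------------

CLUSTER_SHAPES = {
    "A1": (0.0, 0.0, 0.8, 1.0),
    "A2": (0.0, 0.1, 0.1, 1.0),
    "A3": (0.0, 0.3, -1.0, 0.2),
    "A4": (0.0, -0.5, -0.75, -1.0),
    "A5": (0.0, 0.4, 0.1, -1.0),
    "A6": (0.0, 0.9, 0.0, -0.8),
    "A7": (0.0, 1.0, 0.9, -0.9),
    "A8": (0.0, 0.5, -0.5, -1.0),
}


@dataclass(frozen=True)
class ClusterSpec:
    cluster_id: str
    log2_profile: tuple[float, ...]
    genes: tuple[str, ...] | int


@dataclass(frozen=True)
class ExpressionDesign:
    treatments: tuple[str, ...]
    clusters: tuple[ClusterSpec, ...]
    noise_sd: float = 0.1
    baseline_log2_range: tuple[float, float] = (2.0, 7.0)
    overrides: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    unexpressed: tuple[str, ...] | int = ()


@dataclass(frozen=True)
class QpcrDesign:
    ratios: Mapping[str, Mapping[str, float]]  # gene -> treatment -> ratio
    treatments: tuple[str, ...] = ("CK", "T1", "T2")
    calibrator: str = "CK"
    reference_gene: str = "18sRNA"
    reference_ct: float = 12.0
    base_ct: float = 26.0
    n_bio: int = 3
    n_tech: int = 3
    noise_sd: float = 0.0


@dataclass(frozen=True)
class FixturePreset:
    name: str
    n_valid: int
    n_chromosomes: int
    binding_composition: Mapping[str, int]
    exon_distribution: Mapping[int, int]
    n_duplicate_decoys: int = 0
    n_truncated_decoys: int = 0
    unexpressed_member_ranks: tuple[int, ...] = ()
    go_salt_member_ranks: tuple[int, ...] = ()
    deg_profiles: Mapping[int, tuple[str, tuple[float, ...]]] = field(
        default_factory=dict
    )
    subfamily_sizes: Optional[Mapping[str, int]] = None
    n_clusters: int = 8
    cluster_ids: tuple[str, ...] = tuple(CLUSTER_SHAPES)
    treatments: tuple[str, ...] = ("CK", "LS", "MS", "HS")
    name_prefix: str = "CpbHLH"
    promoter_length: int = 2000
    noise: DomainNoise = DomainNoise()
    expression_noise_sd: float = 0.04
    qpcr_noise_sd: float = 0.15

    @property
    def n_putative(self) -> int:
        return self.n_valid + self.n_duplicate_decoys + self.n_truncated_decoys

    @property
    def n_unexpressed(self) -> int:
        """Rows of the expression table failing the >1 abundance filter
        (planted unexpressed members plus every decoy row)."""
        return (
            len(self.unexpressed_member_ranks)
            + self.n_duplicate_decoys
            + self.n_truncated_decoys
        )

    def validate(self) -> None:
        comp_sum = sum(self.binding_composition.values())
        if comp_sum != self.n_valid:
            raise ConfigurationError(
                f"binding composition sums to {comp_sum}, expected n_valid="
                f"{self.n_valid}"
            )
        if set(self.binding_composition) - {G_BOX, E_BOX, NON_E_BOX}:
            raise ConfigurationError("unknown binding class in composition")
        exon_sum = sum(self.exon_distribution.values())
        if exon_sum != self.n_valid:
            raise ConfigurationError(
                f"exon distribution sums to {exon_sum}, expected n_valid="
                f"{self.n_valid}"
            )
        if any(k < 1 for k in self.exon_distribution):
            raise ConfigurationError("exon counts must be >= 1")
        if self.n_valid < self.n_chromosomes:
            raise ConfigurationError("more chromosomes than valid members")
        for rank in (
            *self.unexpressed_member_ranks,
            *self.go_salt_member_ranks,
            *self.deg_profiles,
        ):
            if not 1 <= rank <= self.n_valid:
                raise ConfigurationError(f"member rank {rank} out of range")
        if self.subfamily_sizes is not None:
            if sum(self.subfamily_sizes.values()) != self.n_valid:
                raise ConfigurationError("subfamily sizes must sum to n_valid")
        deg_clusters = {c for c, _ in self.deg_profiles.values()}
        if deg_clusters - set(self.cluster_ids):
            raise ConfigurationError("DEG profile references unknown cluster")


def preset_cp159() -> FixturePreset:
    """The versioned headline preset (see module docstring)."""
    exon_distribution = {
        1: 20, 2: 13, 3: 22, 4: 20, 5: 18, 6: 16, 7: 14, 8: 12,
        9: 9, 10: 6, 11: 4, 12: 3, 13: 2,
    }
    subfamily_sizes = {}
    special = {"XII": 35, "VI": 1, "X": 0}
    rest = [l for l in SUBFAMILY_LABELS if l not in special]
    for i, label in enumerate(rest):
        subfamily_sizes[label] = 6 if i < 8 else 5
    subfamily_sizes.update(special)
    # planted expression effects (log2 profiles over CK/LS/MS/HS);
    # ranks follow the salt-screen candidates of the emulated survey.
    deg_profiles = {
        36: ("A4", (0.0, -1.9, -1.95, -2.1)),
        74: ("A4", (0.0, -1.9, -2.4, -3.17)),   # ~3.7x down LS, 9x down HS
        75: ("A4", (0.0, -1.9, -2.0, -2.2)),
        68: ("A5", (0.0, 0.8, 0.2, -2.2)),
        69: ("A5", (0.0, 0.8, 0.2, -2.0)),
        71: ("A6", (0.0, 2.2, 0.0, -2.0)),
        108: ("A6", (0.0, 2.0, 0.0, -1.8)),
        146: ("A7", (0.0, 2.5, 2.2, -2.2)),
        152: ("A7", (0.0, 2.2, 2.0, -2.0)),
        158: ("A7", (0.0, 2.0, 1.8, -2.4)),
    }
    return FixturePreset(
        name="cp159",
        n_valid=159,
        n_chromosomes=21,
        binding_composition={G_BOX: 93, E_BOX: 43, NON_E_BOX: 23},
        exon_distribution=exon_distribution,
        n_duplicate_decoys=8,
        n_truncated_decoys=7,
        unexpressed_member_ranks=(119, 121, 138, 151),
        go_salt_member_ranks=(38, 68, 109),
        deg_profiles=deg_profiles,
        subfamily_sizes=subfamily_sizes,
    )


def preset_tiny(
    n_valid: int = 6,
    n_chromosomes: int = 2,
    n_duplicate_decoys: int = 0,
    n_truncated_decoys: int = 0,
    unexpressed_member_ranks: tuple[int, ...] = (),
    go_salt_member_ranks: tuple[int, ...] = (),
    deg_profiles: Optional[Mapping[int, tuple[str, tuple[float, ...]]]] = None,
    noise: DomainNoise = DomainNoise(),
    expression_noise_sd: float = 0.04,
    qpcr_noise_sd: float = 0.1,
    n_clusters: int = 2,
    promoter_length: int = 600,
    name: str = "tiny",
) -> FixturePreset:
    """Small configurable preset for tests and examples."""
    comp = {G_BOX: 0, E_BOX: 0, NON_E_BOX: 0}
    classes = (G_BOX, E_BOX, NON_E_BOX)
    for i in range(n_valid):
        comp[classes[i % 3]] += 1
    exon_dist: dict[int, int] = {}
    for i in range(n_valid):
        c = (i % 3) + 1
        exon_dist[c] = exon_dist.get(c, 0) + 1
    n_sub = min(3, n_valid)
    sizes = {}
    for i, label in enumerate(SUBFAMILY_LABELS[:n_sub]):
        sizes[label] = n_valid // n_sub + (1 if i < n_valid % n_sub else 0)
    return FixturePreset(
        name=name,
        n_valid=n_valid,
        n_chromosomes=n_chromosomes,
        binding_composition=comp,
        exon_distribution=exon_dist,
        n_duplicate_decoys=n_duplicate_decoys,
        n_truncated_decoys=n_truncated_decoys,
        unexpressed_member_ranks=unexpressed_member_ranks,
        go_salt_member_ranks=go_salt_member_ranks,
        deg_profiles=dict(deg_profiles or {}),
        subfamily_sizes=sizes,
        n_clusters=n_clusters,
        cluster_ids=tuple(CLUSTER_SHAPES)[:n_clusters],
        promoter_length=promoter_length,
        noise=noise,
        expression_noise_sd=expression_noise_sd,
        qpcr_noise_sd=qpcr_noise_sd,
    )


# ---------------------------------------------------------------------------
# truth labels
# ---------------------------------------------------------------------------

@dataclass
class GeneTruth:
    gene_id: str
    kind: str  # "member" | "duplicate" | "truncated"
    is_family_member: bool
    is_redundant_decoy: bool
    domain_start: int
    domain_row: str  # 79 chars, '-' padded where columns are missing
    binding_class: str
    subfamily: Optional[str]
    member_rank: Optional[int]
    member_name: Optional[str]
    exon_count: int
    cis_planted: list
    cis_implied: list
    cluster: Optional[str]
    is_expressed: bool
    fold_change: Optional[dict]
    qpcr_ratios: Optional[dict]
    dup_source: Optional[str] = None


@dataclass
class FixtureBundle:
    preset: FixturePreset
    seed: int
    proteins: list[ProteinRecord]
    gene_models: dict[str, GeneModel]
    promoters: dict[str, str]
    expression: pd.DataFrame
    go_table: pd.DataFrame
    ct_table: pd.DataFrame
    truth: dict[str, GeneTruth]
    seed_alignment: dict[str, str]  # member gene id -> truth domain row
    reference_alignment: dict[str, str]
    reference_labels: dict[str, str]
    qpcr_design: QpcrDesign

    @property
    def member_ids(self) -> list[str]:
        ranked = [t for t in self.truth.values() if t.is_family_member]
        ranked.sort(key=lambda t: t.member_rank)
        return [t.gene_id for t in ranked]

    @property
    def name_of(self) -> dict[str, str]:
        return {
            t.gene_id: t.member_name
            for t in self.truth.values()
            if t.member_name
        }

    def write(self, outdir) -> dict[str, str]:
        """Write all fixture artifacts as plain-text files (deterministic)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        order = sorted(
            self.gene_models.values(),
            key=lambda g: (natural_key(g.chromosome), g.start, g.gene_id),
        )
        write_fasta(
            outdir / "proteins.faa",
            {p.id: p.sequence for p in sorted(self.proteins, key=lambda p: p.id)},
        )
        with open(outdir / "genes.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for gm in order:
                attrs = f"ID={gm.gene_id}"
                fh.write(
                    f"{gm.chromosome}\tfamscan\tgene\t{gm.start + 1}\t{gm.end}\t"
                    f".\t{gm.strand}\t.\t{attrs}\n"
                )
                tid = f"{gm.gene_id}.t1"
                fh.write(
                    f"{gm.chromosome}\tfamscan\tmRNA\t{gm.start + 1}\t{gm.end}\t"
                    f".\t{gm.strand}\t.\tID={tid};Parent={gm.gene_id}\n"
                )
                for s, e in gm.exons:
                    fh.write(
                        f"{gm.chromosome}\tfamscan\texon\t{s + 1}\t{e}\t.\t"
                        f"{gm.strand}\t.\tParent={tid}\n"
                    )
        write_fasta(outdir / "promoters.fa", dict(sorted(self.promoters.items())))
        self.expression.sort_index().to_csv(
            outdir / "expression.tsv", sep="\t", float_format="%.6f"
        )
        self.go_table.to_csv(outdir / "go.tsv", sep="\t", index=False)
        self.ct_table.to_csv(
            outdir / "qpcr.tsv", sep="\t", index=False, float_format="%.6f"
        )
        write_fasta(outdir / "seed_domains.fasta", dict(sorted(self.seed_alignment.items())))
        write_fasta(outdir / "reference_domains.fasta", dict(sorted(self.reference_alignment.items())))
        with open(outdir / "reference_labels.tsv", "w") as fh:
            fh.write("taxon\tsubfamily\n")
            for taxon in sorted(self.reference_labels):
                fh.write(f"{taxon}\t{self.reference_labels[taxon]}\n")
        truth_obj = {
            "preset": self.preset.name,
            "seed": self.seed,
            "genes": {
                gid: dataclasses.asdict(t) for gid, t in sorted(self.truth.items())
            },
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth_obj, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return {
            "proteins": str(outdir / "proteins.faa"),
            "gff3": str(outdir / "genes.gff3"),
            "promoters": str(outdir / "promoters.fa"),
            "expression": str(outdir / "expression.tsv"),
            "go": str(outdir / "go.tsv"),
            "qpcr": str(outdir / "qpcr.tsv"),
            "truth": str(outdir / "truth.json"),
            "seed_alignment": str(outdir / "seed_domains.fasta"),
            "reference_alignment": str(outdir / "reference_domains.fasta"),
            "reference_labels": str(outdir / "reference_labels.tsv"),
        }


# ---------------------------------------------------------------------------
# domain synthesis
# ---------------------------------------------------------------------------

def _mutate(residue: str, rng: np.random.Generator) -> str:
    others = AMINO_ACIDS.replace(residue, "")
    return others[rng.integers(0, len(others))]


def _random_flank(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, 20, size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _edges_intact(chars: Sequence[str]) -> bool:
    """Edge-integrity guard: both outermost column pairs match the template
    and each edge window carries at most 3 mutations, so local alignments
    never trim into the domain."""
    t = DOMAIN_TEMPLATE
    if chars[0] != t[0] or chars[1] != t[1]:
        return False
    if chars[77] != t[77] or chars[78] != t[78]:
        return False
    lead = sum(chars[i] != t[i] for i in range(2, 8))
    tail = sum(chars[i] != t[i] for i in range(69, 77))
    return lead <= 3 and tail <= 3


def synth_domain_row(
    binding_class: str,
    rng: np.random.Generator,
    *,
    noise: DomainNoise = DomainNoise(),
    signature: Optional[Mapping[int, str]] = None,
) -> str:
    """A 79-residue model-frame domain of the requested binding class."""
    if binding_class not in (G_BOX, E_BOX, NON_E_BOX):
        raise ConfigurationError(f"unknown binding class {binding_class!r}")
    for _ in range(500):
        chars = list(DOMAIN_TEMPLATE)
        for pos in range(1, MODEL_LENGTH + 1):
            rate = noise.rate_for(pos)
            if rate > 0 and rng.random() < rate:
                chars[pos - 1] = _mutate(chars[pos - 1], rng)
        if _edges_intact(chars):
            break
    else:  # pragma: no cover - guard cannot starve at sane rates
        raise ConfigurationError("domain edge-integrity guard did not converge")
    for pos, res in (signature or {}).items():
        chars[pos - 1] = res
    # binding-determining residues (model positions 9, 13, 16, 17)
    if binding_class == G_BOX:
        chars[8] = "H" if rng.random() < 0.9 else "K"
        chars[12], chars[15], chars[16] = "E", "R", "R"
    elif binding_class == E_BOX:
        chars[12], chars[15] = "E", "R"
        if rng.random() < 0.5:
            non_hk = [a for a in AMINO_ACIDS if a not in "HK"]
            chars[8] = non_hk[rng.integers(0, len(non_hk))]
            chars[16] = "R"
        else:
            chars[8] = "H"
            chars[16] = _mutate("R", rng)
    else:  # non-E-box: break the E-core
        chars[8], chars[16] = "H", "R"
        if rng.random() < 0.5:
            chars[12] = _mutate("E", rng)
            chars[15] = "R"
        else:
            chars[12] = "E"
            chars[15] = _mutate("R", rng)
    row = "".join(chars)
    assert classify_binding(row).klass == binding_class
    return row


def synth_domain_sequence(
    binding_class: str,
    rng: np.random.Generator,
    *,
    noise: DomainNoise = DomainNoise(),
    signature: Optional[Mapping[int, str]] = None,
    flank_range: tuple[int, int] = (20, 120),
) -> tuple[str, int, str]:
    """Protein sequence containing one planted domain.

    Returns (sequence, domain_start, 79-char domain row); flanks are drawn
    from a uniform residue background.
    """
    row = synth_domain_row(binding_class, rng, noise=noise, signature=signature)
    left = int(rng.integers(*flank_range))
    right = int(rng.integers(*flank_range))
    seq = _random_flank(rng, left) + row + _random_flank(rng, right)
    return seq, left, row


# ---------------------------------------------------------------------------
# expression synthesis
# ---------------------------------------------------------------------------

def synth_expression(
    design: ExpressionDesign, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, str], dict[str, dict[str, float]]]:
    """Expression table plus truth (gene -> cluster, gene -> planted FC).

    Planted fold changes are linear ratios vs the first treatment
    (the control); unexpressed genes have all values < 1.
    """
    treatments = list(design.treatments)
    control = treatments[0]
    rows = {}
    clusters: dict[str, str] = {}
    folds: dict[str, dict[str, float]] = {}
    for spec in design.clusters:
        if isinstance(spec.genes, int):
            genes = [f"{spec.cluster_id}_g{i + 1}" for i in range(spec.genes)]
        else:
            genes = list(spec.genes)
        for gene in genes:
            profile = design.overrides.get(gene, spec.log2_profile)
            if len(profile) != len(treatments):
                raise ConfigurationError(
                    f"profile for {gene!r} has {len(profile)} entries, "
                    f"expected {len(treatments)}"
                )
            baseline = rng.uniform(*design.baseline_log2_range)
            noise = rng.normal(0.0, design.noise_sd, size=len(treatments))
            values = np.power(2.0, baseline + np.asarray(profile) + noise)
            rows[gene] = values
            clusters[gene] = spec.cluster_id
            folds[gene] = {
                t: float(2.0 ** (profile[i] - profile[0]))
                for i, t in enumerate(treatments)
            }
    if isinstance(design.unexpressed, int):
        unexpressed = [f"unexpr_g{i + 1}" for i in range(design.unexpressed)]
    else:
        unexpressed = list(design.unexpressed)
    for gene in unexpressed:
        rows[gene] = rng.uniform(0.05, 0.9, size=len(treatments))
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=treatments)
    frame.index.name = "gene"
    assert (frame.values >= 0).all()
    return frame, clusters, folds


# ---------------------------------------------------------------------------
# qPCR synthesis
# ---------------------------------------------------------------------------

def synth_qpcr(design: QpcrDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Replicated Ct table with reference-gene rows for every sample.

    With noise_sd = 0 the 2^-ddCt pipeline recovers the designed ratios
    exactly.
    """
    records = []
    for t in design.treatments:
        for b in range(1, design.n_bio + 1):
            for k in range(1, design.n_tech + 1):
                ct = design.reference_ct + rng.normal(0.0, design.noise_sd)
                records.append((design.reference_gene, t, b, k, ct))
    for gene in sorted(design.ratios):
        per_treatment = design.ratios[gene]
        for t in design.treatments:
            ratio = per_treatment.get(t, 1.0)
            if ratio <= 0:
                raise ConfigurationError(f"ratio for {gene!r}/{t!r} must be > 0")
            for b in range(1, design.n_bio + 1):
                bio_shift = rng.normal(0.0, design.noise_sd)
                for k in range(1, design.n_tech + 1):
                    ct = (
                        design.base_ct
                        - np.log2(ratio)
                        + bio_shift
                        + rng.normal(0.0, design.noise_sd / 2.0 if design.noise_sd else 0.0)
                    )
                    records.append((gene, t, b, k, ct))
    return pd.DataFrame(
        records, columns=["gene", "treatment", "bio_rep", "tech_rep", "ct"]
    )


# ---------------------------------------------------------------------------
# promoter synthesis
# ---------------------------------------------------------------------------

_NUCS = "ACGT"


def _realize_pattern(pattern: str, rng: np.random.Generator) -> str:
    from .structure_and_cis import IUPAC

    return "".join(
        c if len(IUPAC[c]) == 1 else IUPAC[c][rng.integers(0, len(IUPAC[c]))]
        for c in pattern
    )


def _synth_promoter(
    gene_id: str,
    planted_elements: Sequence[str],
    catalog: Sequence[CisCatalogEntry],
    length: int,
    rng: np.random.Generator,
) -> tuple[str, list, list]:
    """Random promoter with planted elements and no stray catalog matches
    outside the planted spans.

    Returns (sequence, planted hits, implied hits); implied hits are
    catalog matches unavoidably created inside planted spans (e.g. a
    reverse-complement element pair).
    """
    by_name = {e.name: e for e in catalog}
    seq = list(_NUCS[i] for i in rng.integers(0, 4, size=length))
    slot_step = 60
    slots = list(range(20, length - 20, slot_step))
    chosen = rng.choice(len(slots), size=len(planted_elements), replace=False)
    planted = []
    spans = []
    for slot_i, name in zip(sorted(int(c) for c in chosen), planted_elements):
        entry = by_name[name]
        offset = slots[slot_i]
        realization = _realize_pattern(entry.pattern, rng)
        seq[offset : offset + len(realization)] = list(realization)
        planted.append({"element": name, "offset": offset, "strand": "+"})
        spans.append((offset, offset + len(realization)))

    planted_keys = {(p["element"], p["offset"]) for p in planted}
    implied = []
    for _ in range(60):
        text = "".join(seq)
        hits, _, _ = scan_cis_elements({gene_id: text}, catalog)
        implied = []
        mutated = False
        for h in hits:
            if (h.element, h.offset) in planted_keys:
                continue
            outside = [
                p
                for p in range(h.offset, h.offset + h.length)
                if not any(s <= p < e for s, e in spans)
            ]
            if not outside:
                implied.append(
                    {"element": h.element, "offset": h.offset, "strand": h.strand}
                )
                continue
            p = outside[rng.integers(0, len(outside))]
            seq[p] = _mutate_base(seq[p], rng)
            mutated = True
        if not mutated:
            break
    else:  # pragma: no cover - cleanup failed to converge
        raise RuntimeError(f"promoter cleanup did not converge for {gene_id}")
    return "".join(seq), planted, implied


def _mutate_base(base: str, rng: np.random.Generator) -> str:
    others = _NUCS.replace(base, "")
    return others[rng.integers(0, 3)]


# ---------------------------------------------------------------------------
# the full bundle
# ---------------------------------------------------------------------------

def _subfamily_signatures(
    labels: Sequence[str], rng: np.random.Generator
) -> dict[str, dict[int, str]]:
    signatures: dict[str, dict[int, str]] = {}
    seen = set()
    for label in labels:
        while True:
            combo = tuple(
                AMINO_ACIDS[i]
                for i in rng.integers(0, 20, size=len(SIGNATURE_POSITIONS))
            )
            if combo not in seen:
                seen.add(combo)
                break
        signatures[label] = dict(zip(SIGNATURE_POSITIONS, combo))
    return signatures


def make_fixture(
    preset: FixturePreset,
    seed: int,
    catalog: Optional[Sequence[CisCatalogEntry]] = None,
) -> FixtureBundle:
    """Generate a complete fixture bundle; identical (preset, seed) pairs
    produce byte-identical files."""
    preset.validate()
    rng = np.random.default_rng(seed)
    catalog = list(catalog) if catalog is not None else load_cis_catalog()
    chroms = [f"Chr{i + 1:02d}" for i in range(preset.n_chromosomes)]

    # ---- placement ------------------------------------------------------
    n_valid = preset.n_valid
    member_chrom_idx = list(range(preset.n_chromosomes)) + [
        int(i) for i in rng.integers(0, preset.n_chromosomes, n_valid - preset.n_chromosomes)
    ]
    n_decoys = preset.n_duplicate_decoys + preset.n_truncated_decoys
    decoy_chrom_idx = [int(i) for i in rng.integers(0, preset.n_chromosomes, n_decoys)]
    genes_plan: list[dict] = []
    for ci in member_chrom_idx:
        genes_plan.append({"kind": "member", "chrom": chroms[ci]})
    for k, ci in enumerate(decoy_chrom_idx):
        kind = "duplicate" if k < preset.n_duplicate_decoys else "truncated"
        genes_plan.append({"kind": kind, "chrom": chroms[ci]})
    # assign slot order per chromosome (random permutation of its genes)
    for chrom in chroms:
        idxs = [i for i, g in enumerate(genes_plan) if g["chrom"] == chrom]
        perm = rng.permutation(len(idxs))
        for slot, j in enumerate(perm):
            g = genes_plan[idxs[int(j)]]
            g["start"] = 1000 + slot * 15000 + int(rng.integers(0, 2000))

    ordered = sorted(
        range(len(genes_plan)),
        key=lambda i: (natural_key(genes_plan[i]["chrom"]), genes_plan[i]["start"]),
    )
    for counter, i in enumerate(ordered, start=1):
        genes_plan[i]["gene_id"] = f"CPA{counter:04d}"
    member_order = [i for i in ordered if genes_plan[i]["kind"] == "member"]
    for rank, i in enumerate(member_order, start=1):
        genes_plan[i]["rank"] = rank
        genes_plan[i]["name"] = f"{preset.name_prefix}{rank}"

    # ---- subfamilies, classes, exon counts over member ranks ------------
    labels = (
        list(preset.subfamily_sizes)
        if preset.subfamily_sizes is not None
        else list(SUBFAMILY_LABELS[: min(len(SUBFAMILY_LABELS), n_valid)])
    )
    if preset.subfamily_sizes is not None:
        sizes = dict(preset.subfamily_sizes)
    else:
        sizes = {
            l: n_valid // len(labels) + (1 if i < n_valid % len(labels) else 0)
            for i, l in enumerate(labels)
        }
    signatures = _subfamily_signatures(labels, rng)
    subfamily_of_rank: dict[int, str] = {}
    shuffled_ranks = [int(r) + 1 for r in rng.permutation(n_valid)]
    pos = 0
    for label in labels:
        for r in shuffled_ranks[pos : pos + sizes[label]]:
            subfamily_of_rank[r] = label
        pos += sizes[label]

    class_list: list[str] = []
    for klass in (G_BOX, E_BOX, NON_E_BOX):
        class_list += [klass] * preset.binding_composition.get(klass, 0)
    class_of_rank = {
        int(r) + 1: class_list[i]
        for i, r in enumerate(rng.permutation(n_valid))
    }

    exon_counts: list[int] = []
    for count, n_genes in sorted(preset.exon_distribution.items()):
        exon_counts += [count] * n_genes
    exon_of_rank = {
        int(r) + 1: exon_counts[i] for i, r in enumerate(rng.permutation(n_valid))
    }

    # ---- proteins -------------------------------------------------------
    truth: dict[str, GeneTruth] = {}
    proteins: list[ProteinRecord] = []
    seed_alignment: dict[str, str] = {}
    member_plans = [genes_plan[i] for i in member_order]
    for g in member_plans:
        rank = g["rank"]
        subfam = subfamily_of_rank[rank]
        klass = class_of_rank[rank]
        seq, start, row = synth_domain_sequence(
            klass, rng, noise=preset.noise, signature=signatures[subfam]
        )
        g.update(sequence=seq, domain_start=start, domain_row=row,
                 binding_class=klass, subfamily=subfam)
        seed_alignment[g["gene_id"]] = row

    dup_sources = rng.choice(
        len(member_plans), size=preset.n_duplicate_decoys, replace=False
    )
    dup_iter = iter(sorted(int(i) for i in dup_sources))
    for i in ordered:
        g = genes_plan[i]
        if g["kind"] == "duplicate":
            src = member_plans[next(dup_iter)]
            g["gene_id"] = src["gene_id"] + "d"
            g.update(
                sequence=src["sequence"],
                domain_start=src["domain_start"],
                domain_row=src["domain_row"],
                binding_class=src["binding_class"],
                subfamily=src["subfamily"],
                dup_source=src["gene_id"],
            )
        elif g["kind"] == "truncated":
            klass = (G_BOX, E_BOX, NON_E_BOX)[int(rng.integers(0, 3))]
            subfam = labels[int(rng.integers(0, len(labels)))]
            seq, start, row = synth_domain_sequence(
                klass, rng, noise=preset.noise, signature=signatures[subfam]
            )
            keep = MODEL_LENGTH - TRUNCATION_COLUMNS
            dom_end = start + MODEL_LENGTH
            # anti-consensus pad: the residues that replace the removed
            # columns avoid every high-frequency residue of those columns,
            # so a local alignment cannot extend past the truncation point.
            pad = []
            for pos in range(keep + 1, MODEL_LENGTH + 1):
                avoid = {DOMAIN_TEMPLATE[pos - 1]}
                if pos in SIGNATURE_POSITIONS:
                    avoid |= {sig[pos] for sig in signatures.values()}
                if pos in BINDING_POSITIONS:
                    avoid |= {"H", "K", "E", "R"}
                allowed = [a for a in AMINO_ACIDS if a not in avoid]
                pad.append(allowed[int(rng.integers(0, len(allowed)))])
            seq = seq[: start + keep] + "".join(pad) + seq[dom_end + len(pad):]
            g.update(
                sequence=seq,
                domain_start=start,
                domain_row=row[:keep] + "-" * TRUNCATION_COLUMNS,
                binding_class=klass,
                subfamily=subfam,
            )

    # ---- gene models ----------------------------------------------------
    gene_models: dict[str, GeneModel] = {}
    for i in ordered:
        g = genes_plan[i]
        if g["kind"] == "member":
            n_exons = exon_of_rank[g["rank"]]
        else:
            n_exons = int(rng.integers(1, 6))
        g["exon_count"] = n_exons
        exon_lens = rng.integers(80, 301, size=n_exons)
        intron_lens = rng.integers(80, 601, size=max(n_exons - 1, 0))
        exons = []
        cursor = g["start"]
        for k in range(n_exons):
            exons.append((cursor, cursor + int(exon_lens[k])))
            cursor = exons[-1][1]
            if k < n_exons - 1:
                cursor += int(intron_lens[k])
        strand = "+" if rng.random() < 0.5 else "-"
        gene_models[g["gene_id"]] = GeneModel(
            gene_id=g["gene_id"],
            chromosome=g["chrom"],
            strand=strand,
            start=g["start"],
            end=exons[-1][1],
            exons=tuple(exons),
        )

    # ---- promoters ------------------------------------------------------
    element_names = [e.name for e in catalog]
    deg_gene_ids = {
        g["gene_id"] for g in member_plans if g["rank"] in preset.deg_profiles
    }
    promoters: dict[str, str] = {}
    cis_truth: dict[str, tuple[list, list]] = {}
    for i in ordered:
        g = genes_plan[i]
        n_elem = int(rng.integers(1, 4))
        chosen = [
            element_names[int(k)]
            for k in rng.choice(len(element_names), size=n_elem, replace=False)
        ]
        if g["gene_id"] in deg_gene_ids:
            for extra in ("ABRE", "MBS"):
                if extra in element_names and extra not in chosen:
                    chosen.append(extra)
        seq, planted, implied = _synth_promoter(
            g["gene_id"], chosen, catalog, preset.promoter_length, rng
        )
        promoters[g["gene_id"]] = seq
        cis_truth[g["gene_id"]] = (planted, implied)

    # ---- expression -----------------------------------------------------
    unexpr_ranks = set(preset.unexpressed_member_ranks)
    expressed_members = [g for g in member_plans if g["rank"] not in unexpr_ranks]
    cluster_ids = list(preset.cluster_ids)
    assignment: dict[str, list[str]] = {c: [] for c in cluster_ids}
    overrides: dict[str, tuple[float, ...]] = {}
    free_members = []
    for g in expressed_members:
        deg = preset.deg_profiles.get(g["rank"])
        if deg is not None:
            cluster_id, profile = deg
            assignment[cluster_id].append(g["gene_id"])
            overrides[g["gene_id"]] = tuple(profile)
            g["cluster"] = cluster_id
        else:
            free_members.append(g)
    perm = rng.permutation(len(free_members))
    for j, pi in enumerate(perm):
        g = free_members[int(pi)]
        cluster_id = cluster_ids[j % len(cluster_ids)]
        assignment[cluster_id].append(g["gene_id"])
        g["cluster"] = cluster_id
    unexpressed_ids = [
        g["gene_id"] for g in member_plans if g["rank"] in unexpr_ranks
    ] + [genes_plan[i]["gene_id"] for i in ordered if genes_plan[i]["kind"] != "member"]
    design = ExpressionDesign(
        treatments=preset.treatments,
        clusters=tuple(
            ClusterSpec(c, CLUSTER_SHAPES[c], tuple(assignment[c]))
            for c in cluster_ids
        ),
        noise_sd=preset.expression_noise_sd,
        overrides=overrides,
        unexpressed=tuple(unexpressed_ids),
    )
    expression, cluster_truth, fold_truth = synth_expression(design, rng)

    # ---- GO table -------------------------------------------------------
    go_rows = []
    salt_ids = {
        g["gene_id"] for g in member_plans if g["rank"] in preset.go_salt_member_ranks
    }
    for g in member_plans:
        gid = g["gene_id"]
        if gid in salt_ids:
            go_rows.append((gid, "GO:0009651", "response to salt stress", "BP"))
        if rng.random() < 0.8:
            go_rows.append((gid, "GO:0003677", "DNA binding", "MF"))
        if rng.random() < 0.6:
            go_rows.append(
                (gid, "GO:0006355", "regulation of transcription, DNA-templated", "BP")
            )
    go_table = pd.DataFrame(
        sorted(go_rows), columns=["gene", "term_id", "term_name", "aspect"]
    )

    # ---- qPCR -----------------------------------------------------------
    candidate_ranks = sorted(set(preset.deg_profiles) | set(preset.go_salt_member_ranks))
    if not candidate_ranks:
        candidate_ranks = [1]
    rank_to_gid = {g["rank"]: g["gene_id"] for g in member_plans}
    qpcr_ratios: dict[str, dict[str, float]] = {}
    for rank in candidate_ranks:
        gid = rank_to_gid[rank]
        up = rng.random() < 0.5
        r1 = float(rng.uniform(1.5, 3.0)) if up else float(rng.uniform(0.2, 0.6))
        r2 = float(rng.uniform(2.0, 4.5)) if up else float(rng.uniform(0.1, 0.5))
        qpcr_ratios[gid] = {"CK": 1.0, "T1": round(r1, 3), "T2": round(r2, 3)}
    qpcr_design = QpcrDesign(
        ratios=qpcr_ratios,
        noise_sd=preset.qpcr_noise_sd,
    )
    ct_table = synth_qpcr(qpcr_design, rng)

    # ---- truth labels ---------------------------------------------------
    for i in ordered:
        g = genes_plan[i]
        gid = g["gene_id"]
        planted, implied = cis_truth[gid]
        is_member = g["kind"] == "member"
        truth[gid] = GeneTruth(
            gene_id=gid,
            kind=g["kind"],
            is_family_member=is_member,
            is_redundant_decoy=g["kind"] == "duplicate",
            domain_start=g["domain_start"],
            domain_row=g["domain_row"],
            binding_class=g["binding_class"],
            subfamily=g.get("subfamily"),
            member_rank=g.get("rank"),
            member_name=g.get("name"),
            exon_count=g["exon_count"],
            cis_planted=planted,
            cis_implied=implied,
            cluster=g.get("cluster"),
            is_expressed=gid not in set(unexpressed_ids),
            fold_change=fold_truth.get(gid),
            qpcr_ratios=qpcr_ratios.get(gid),
            dup_source=g.get("dup_source"),
        )
        proteins.append(ProteinRecord(id=gid, sequence=g["sequence"]))

    reference_alignment = {
        f"REF_{label}": _reference_row(signatures[label]) for label in labels
    }
    reference_labels = {name: name[4:] for name in reference_alignment}

    bundle = FixtureBundle(
        preset=preset,
        seed=seed,
        proteins=proteins,
        gene_models=gene_models,
        promoters=promoters,
        expression=expression,
        go_table=go_table,
        ct_table=ct_table,
        truth=truth,
        seed_alignment=seed_alignment,
        reference_alignment=reference_alignment,
        reference_labels=reference_labels,
        qpcr_design=qpcr_design,
    )
    _check_bundle(bundle)
    return bundle


def _reference_row(signature: Mapping[int, str]) -> str:
    chars = list(DOMAIN_TEMPLATE)
    for pos, res in signature.items():
        chars[pos - 1] = res
    return "".join(chars)


def _check_bundle(bundle: FixtureBundle) -> None:
    """Enforce bundle invariants at construction time."""
    gene_ids = set(bundle.gene_models)
    assert gene_ids == {p.id for p in bundle.proteins}
    assert gene_ids == set(bundle.promoters)
    assert gene_ids == set(bundle.expression.index)
    assert gene_ids == set(bundle.truth)
    for t in bundle.truth.values():
        assert len(t.domain_row) == MODEL_LENGTH
        assert t.exon_count >= 1
        if t.kind != "truncated":
            assert classify_binding(t.domain_row).klass == t.binding_class
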
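"""Expression filtering, clustering, fold-change screening and candidate
selection against GO annotations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import InputError

DEFAULT_SALT_TERMS = ("response to salt stress",)


@dataclass(frozen=True)
class ClusterAssignment:
    labels: "pd.Series"  # gene -> cluster id (1..k)
    linkage_matrix: np.ndarray
    k: int


@dataclass(frozen=True)
class DegRecord:
    gene: str
    log2_fold_changes: dict  # treatment -> log2 FC vs control
    max_abs_log2fc: float
    direction: str  # "up" | "down"


@dataclass(frozen=True)
class CandidateSet:
    genes: tuple[str, ...]
    provenance: dict  # gene -> "expression" | "GO" | "both"

    def __len__(self) -> int:
        return len(self.genes)


def _validate_matrix(matrix: pd.DataFrame) -> None:
    if (matrix.values < 0).any():
        raise InputError("expression matrix contains negative values")


def filter_and_normalize(
    matrix: pd.DataFrame, min_abundance: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep genes exceeding ``min_abundance`` (strict) in >= 1 treatment and
    return (filtered matrix, log2(x + 1) matrix)."""
    _validate_matrix(matrix)
    keep = (matrix > min_abundance).any(axis=1)
    filtered = matrix.loc[keep]
    return filtered, np.log2(filtered + 1.0)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores; zero-variance rows map to all-zero profiles."""
    values = matrix.values.astype(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    z = np.divide(values - mean, sd, out=np.zeros_like(values), where=sd > 0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def cluster_expression(log2_matrix: pd.DataFrame, k: int = 8) -> ClusterAssignment:
    """Average-linkage Euclidean clustering of per-gene z-score profiles,
    cut to exactly ``k`` clusters.  Deterministic."""
    if len(log2_matrix) < k:
        raise InputError(
            f"need at least {k} genes to form {k} clusters, got {len(log2_matrix)}"
        )
    z = zscore_rows(log2_matrix)
    lm = linkage(z.values, method="average", metric="euclidean")
    raw = fcluster(lm, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=log2_matrix.index, name="cluster")
    return ClusterAssignment(labels=labels, linkage_matrix=lm, k=k)


def screen_degs(
    matrix: pd.DataFrame,
    control: str = "CK",
    fc_threshold: float = 3.0,
    pseudocount: float = 0.01,
    *,
    return_all: bool = False,
) -> list[DegRecord]:
    """Fold-change screen vs the control column.

    A gene is differentially expressed iff the max over treatments of
    |log2((t + eps) / (control + eps))| reaches log2(fc_threshold); the
    direction is the sign at the maximizing treatment.  The comparison
    allows a log2(1 + eps) tolerance, the largest distortion the
    pseudo-count can introduce for abundances >= 1, so an exact
    fc_threshold-fold change always qualifies.
    """
    _validate_matrix(matrix)
    if control not in matrix.columns:
        raise InputError(f"control column {control!r} not present")
    treatments = [c for c in matrix.columns if c != control]
    cutoff = np.log2(fc_threshold) - np.log2(1.0 + pseudocount)
    records = []
    for gene, row in matrix.iterrows():
        ck = row[control] + pseudocount
        lfc = {t: float(np.log2((row[t] + pseudocount) / ck)) for t in treatments}
        t_max = max(lfc, key=lambda t: (abs(lfc[t]), t))
        rec = DegRecord(
            gene=gene,
            log2_fold_changes=lfc,
            max_abs_log2fc=abs(lfc[t_max]),
            direction="up" if lfc[t_max] > 0 else "down",
        )
        if return_all or rec.max_abs_log2fc >= cutoff - 1e-12:
            records.append(rec)
    return records


def salt_annotated_genes(
    go_table: pd.DataFrame, salt_terms: Sequence[str] = DEFAULT_SALT_TERMS
) -> set[str]:
    """Genes annotated with any of the given term names or term ids."""
    if go_table.empty:
        return set()
    terms = {t.lower() for t in salt_terms}
    mask = go_table["term_name"].str.lower().isin(terms)
    if "term_id" in go_table.columns:
        mask |= go_table["term_id"].str.lower().isin(terms)
    return set(go_table.loc[mask, "gene"])


def select_candidates(
    degs: Iterable[DegRecord | str],
    go_table: Optional[pd.DataFrame] = None,
    salt_terms: Sequence[str] = DEFAULT_SALT_TERMS,
) -> CandidateSet:
    """Union of the DEG gene set with GO salt-annotated genes.

    Provenance per gene: "expression", "GO", or "both".
    """
    if not salt_terms:
        raise InputError("salt_terms must be non-empty")
    deg_genes = {d.gene if isinstance(d, DegRecord) else d for d in degs}
    if go_table is None:
        go_table = pd.DataFrame(columns=["gene", "term_id", "term_name", "aspect"])
    go_genes = salt_annotated_genes(go_table, salt_terms)
    provenance = {}
    for g in deg_genes | go_genes:
        if g in deg_genes and g in go_genes:
            provenance[g] = "both"
        elif g in deg_genes:
            provenance[g] = "expression"
        else:
            provenance[g] = "GO"
    genes = tuple(sorted(provenance))
    return CandidateSet(genes=genes, provenance=provenance)
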
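"""Phosphosite set comparison, functional grouping, and kinase enrichment.

Phosphoproteomic comparisons between stress conditions (e.g. hydrogen
peroxide vs. arsenite) operate on site keys ``(gene, residue, position)``:

- significant up-/down-regulated site sets are selected by p-value and
  fold-change sign;
- condition sets are compared by exact key intersection;
- proteins are mapped to microtubule-related functional groups (tubulin
  isoforms, nucleators, MT-binding, tubulin-sequestering, end-binding,
  MT-severing);
- upstream-kinase substrate sets are tested for overrepresentation with the
  one-sided hypergeometric test and Benjamini-Hochberg adjustment.  The
  kinase-substrate resource itself is user-supplied (term -> substrate gene
  sets); only the counting is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PhosphoSiteRecord",
    "SiteSet",
    "OverlapResult",
    "EnrichmentResult",
    "DEFAULT_FUNCTIONAL_GROUPS",
    "build_group_map",
    "filter_significant",
    "compare_conditions",
    "assign_groups",
    "count_sites_per_protein",
    "enrich_terms",
    "site_windows",
]

VALID_RESIDUES = frozenset("STY")


@dataclass(frozen=True)
class PhosphoSiteRecord:
    """One phosphosite observation: gene symbol, S/T/Y residue, 1-based position."""

    gene: str
    residue: str
    position: int
    log2_fold_change: float
    p_value: float
    condition: str

    def __post_init__(self) -> None:
        if self.residue not in VALID_RESIDUES:
            raise ValueError(f"residue must be one of S/T/Y, got {self.residue!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.gene, self.residue, self.position)


@dataclass
class SiteSet:
    """Unique site keys of one condition and regulation direction."""

    keys: frozenset
    condition: str = ""
    direction: str = ""  # "up" | "down" | ""

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def genes(self) -> frozenset:
        return frozenset(k[0] for k in self.keys)


@dataclass
class OverlapResult:
    intersection: frozenset
    n_a: int
    n_b: int
    n_shared: int
    fraction_of_b_shared: float


@dataclass
class EnrichmentResult:
    term: str
    overlap: int  # k
    term_size: int  # K
    query_size: int  # n
    background_size: int  # N
    p_value: float
    p_adjusted: float = float("nan")


#: microtubule-related functional groups and their member genes
DEFAULT_FUNCTIONAL_GROUPS: dict[str, tuple[str, ...]] = {
    "tubulin isoforms": (
        "TUBA1A", "TUBA1B", "TUBA1C", "TUBA3A", "TUBA3B", "TUBA4A", "TUBA8",
        "TUBB", "TUBB1", "TUBB2A", "TUBB2B", "TUBB3", "TUBB4A", "TUBB4B",
        "TUBB5", "TUBB6",
    ),
    "nucleators": (
        "TUBG1", "TUBG2", "TUBGCP2", "TUBGCP3", "TUBGCP4", "TUBGCP5", "TUBGCP6",
    ),
    "MT-binding": ("MAP1A", "MAP1B", "MAP1S", "MAP2", "MAPT", "MAP4", "MAP6", "MAP7"),
    "tubulin-sequestering": ("STMN1", "STMN2", "STMN3", "STMN4"),
    "end-binding": ("MAPRE1", "MAPRE2", "MAPRE3", "CLASP1", "CLASP2"),
    "MT-severing": ("KATNA1", "KATNB1", "FIGN", "SPAST"),
}

UNCLASSIFIED = "unclassified"


def build_group_map(groups: dict[str, tuple[str, ...]] | None = None) -> dict[str, str]:
    """Flatten a group -> genes mapping to gene -> group.

    A gene may belong to at most one group; duplicates are rejected.
    """
    groups = groups or DEFAULT_FUNCTIONAL_GROUPS
    gene_to_group: dict[str, str] = {}
    for group, genes in groups.items():
        for gene in genes:
            if gene in gene_to_group:
                raise ValueError(f"gene {gene} assigned to more than one group")
            gene_to_group[gene] = group
    return gene_to_group


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        required = ("gene", "residue", "position", "log2_fold_change", "p_value", "condition")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"site table missing columns: {missing}")
        return df
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "residue": r.residue,
                "position": r.position,
                "log2_fold_change": r.log2_fold_change,
                "p_value": r.p_value,
                "condition": r.condition,
            }
            for r in records
        ]
    )


def filter_significant(
    records,
    p_threshold: float = 0.05,
    min_abs_log2fc: float = 0.0,
) -> tuple[SiteSet, SiteSet]:
    """Split records into significant up- and down-regulated site sets.

    Up: ``p <= p_threshold`` (boundary included) and
    ``log2_fold_change > min_abs_log2fc``; down analogously with negative
    sign.  Accepts a sequence of :class:`PhosphoSiteRecord` or a DataFrame
    with the same fields.
    """
    df = _records_frame(records)
    sig = df[df["p_value"] <= p_threshold]
    condition = str(df["condition"].iloc[0]) if len(df) else ""
    up = sig[sig["log2_fold_change"] > min_abs_log2fc]
    down = sig[sig["log2_fold_change"] < -min_abs_log2fc]

    def to_set(sub: pd.DataFrame, direction: str) -> SiteSet:
        keys = frozenset(
            (str(g), str(r), int(p))
            for g, r, p in zip(sub["gene"], sub["residue"], sub["position"])
        )
        return SiteSet(keys=keys, condition=condition, direction=direction)

    return to_set(up, "up"), to_set(down, "down")


def compare_conditions(set_a: SiteSet, set_b: SiteSet) -> OverlapResult:
    """Exact key intersection of two condition site sets.

    ``fraction_of_b_shared`` is |A intersect B| / |B| — e.g. the fraction of
    arsenite-upregulated sites that are also upregulated with peroxide.
    """
    inter = set_a.keys & set_b.keys
    n_b = len(set_b.keys)
    return OverlapResult(
        intersection=frozenset(inter),
        n_a=len(set_a.keys),
        n_b=n_b,
        n_shared=len(inter),
        fraction_of_b_shared=len(inter) / n_b if n_b else float("nan"),
    )


def assign_groups(genes, group_map: dict[str, str] | None = None) -> dict[str, str]:
    """Map genes to functional groups; unknown genes become "unclassified"."""
    gm = group_map if group_map is not None else build_group_map()
    return {g: gm.get(g, UNCLASSIFIED) for g in genes}


def count_sites_per_protein(siteset: SiteSet, group_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Sites per protein with functional-group assignment, sorted descending.

    Returns a DataFrame with columns gene, group, n_sites, sorted by
    descending site count (ties by gene name).
    """
    counts: dict[str, int] = {}
    for gene, _, _ in siteset.keys:
        counts[gene] = counts.get(gene, 0) + 1
    groups = assign_groups(counts.keys(), group_map)
    df = pd.DataFrame(
        [{"gene": g, "group": groups[g], "n_sites": n} for g, n in counts.items()],
        columns=["gene", "group", "n_sites"],
    )
    return df.sort_values(["n_sites", "gene"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )


def enrich_terms(
    query_genes,
    term_map: dict[str, set],
    background_genes,
) -> list[EnrichmentResult]:
    """Hypergeometric overrepresentation of term (kinase-substrate) gene sets.

    For each term with substrate set of size K in a background of size N, the
    one-sided upper-tail hypergeometric p-value of observing >= k query hits
    among n query genes is computed, followed by Benjamini-Hochberg
    adjustment across terms.  Results are sorted by adjusted p, ties by term
    name.  The query must be a subset of the background.
    """
    query = set(query_genes)
    background = set(background_genes)
    stray = query - background
    if stray:
        raise ValueError(f"query genes not in background: {sorted(stray)}")
    for term, genes in term_map.items():
        stray = set(genes) - background
        if stray:
            raise ValueError(f"term {term!r} has genes not in background: {sorted(stray)}")
    n_bg = len(background)
    n_query = len(query)
    results = []
    for term in sorted(term_map):
        term_genes = set(term_map[term]) & background
        k = len(query & term_genes)
        big_k = len(term_genes)
        # upper tail P(X >= k) includes the observed count; k = 0 gives p = 1
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_query))
        results.append(
            EnrichmentResult(
                term=term,
                overlap=k,
                term_size=big_k,
                query_size=n_query,
                background_size=n_bg,
                p_value=min(p, 1.0),
            )
        )
    if results:
        adjusted = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, adj in zip(results, adjusted):
            r.p_adjusted = float(adj)
    results.sort(key=lambda r: (r.p_adjusted, r.term))
    return results


def site_windows(
    sites: list[tuple[str, int]],
    sequences: dict[str, str],
    flank: int = 15,
) -> pd.DataFrame:
    """Extract +-``flank`` residue windows around sites for external tools.

    For each ``(gene, position)`` with a known protein sequence, the
    31-residue window (15 before, 15 after) is returned, padded with '-'
    where the window extends past the sequence ends.  This is an export
    helper; phosphatase-site prediction itself is out of scope.
    """
    rows = []
    for gene, pos in sites:
        seq = sequences.get(gene)
        if seq is None or not 1 <= pos <= len(seq):
            continue
        i = pos - 1
        left = seq[max(0, i - flank) : i].rjust(flank, "-")
        right = seq[i + 1 : i + 1 + flank].ljust(flank, "-")
        rows.append({"gene": gene, "position": pos, "window": left + seq[i] + right})
    return pd.DataFrame(rows, columns=["gene", "position", "window"])
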
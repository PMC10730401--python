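"""GO keyword gene-set construction, Fisher-exact overrepresentation and DEG calls."""

from __future__ import annotations

import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GeneSet, GeneSetCollection

__all__ = [
    "ANNOTATION_COLUMNS",
    "validate_annotation_table",
    "filter_genes_by_keyword",
    "term_gene_sets",
    "fisher_overrepresentation",
    "identify_degs",
]

ANNOTATION_COLUMNS = ("gene", "go_id", "go_name", "ontology")
ONTOLOGIES = ("BP", "MF", "CC")


def validate_annotation_table(annotations: pd.DataFrame) -> pd.DataFrame:
    """Check the flat (gene, go_id, go_name, ontology) annotation table."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if annotations.duplicated(subset=["gene", "go_id"]).any():
        raise ValueError("duplicate (gene, term) pairs in annotation table")
    if annotations["go_name"].isna().any() or (annotations["go_name"].astype(str) == "").any():
        raise ValueError("empty GO term names in annotation table")
    bad = set(annotations["ontology"]) - set(ONTOLOGIES)
    if bad:
        raise ValueError(f"unknown ontologies: {sorted(bad)}")
    return annotations


def filter_genes_by_keyword(annotations: pd.DataFrame, keyword: str, name: str | None = None) -> GeneSet:
    """Genes annotated to at least one term whose name contains *keyword*.

    Matching is case-insensitive substring (so "autophag" catches both
    "autophagy" and "macroautophagy").  An empty result is returned with a
    warning rather than an error.
    """
    if not keyword:
        raise ValueError("keyword must be non-empty")
    validate_annotation_table(annotations)
    hit = annotations["go_name"].str.contains(keyword, case=False, regex=False)
    genes = frozenset(annotations.loc[hit, "gene"].astype(str))
    if not genes:
        warnings.warn(f"keyword {keyword!r} matched no annotated genes", stacklevel=2)
    return GeneSet(name=name or keyword, members=genes)


def term_gene_sets(annotations: pd.DataFrame, by: str = "go_name") -> GeneSetCollection:
    """One gene set per GO term, keyed by term name (or id)."""
    validate_annotation_table(annotations)
    collection = GeneSetCollection()
    for term, sub in annotations.groupby(by, sort=True):
        collection.add(GeneSet(name=str(term), members=frozenset(sub["gene"].astype(str))))
    return collection


def fisher_overrepresentation(
    deg_set: GeneSet | Iterable[str],
    term_sets: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher exact overrepresentation of DEGs in each term.

    Per term the 2x2 table is (in-term & DEG, in-term not DEG, DEG not
    in-term, rest of universe); the p-value is the enrichment-direction
    (greater) tail.  Adjusted values are Bonferroni, ``min(1, p * n_terms)``,
    significant when adjusted <= *alpha*.
    """
    universe = frozenset(str(g) for g in universe)
    if not universe:
        raise ValueError("empty universe")
    degs = deg_set.members if isinstance(deg_set, GeneSet) else frozenset(str(g) for g in deg_set)
    outside = degs - universe
    if outside:
        raise ValueError(f"DEGs outside the universe: {sorted(outside)[:5]}")

    rows = []
    n_terms = len(term_sets)
    for term in term_sets:
        members = term.members & universe
        overlap = len(members & degs)
        table = [
            [overlap, len(members) - overlap],
            [len(degs) - overlap, len(universe) - len(members) - len(degs) + overlap],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "term": term.name,
                "term_size": len(members),
                "deg_size": len(degs),
                "overlap": overlap,
                "p": float(p),
                "p_bonferroni": min(1.0, float(p) * n_terms),
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["p_bonferroni"] <= alpha
    return out


def identify_degs(de_table: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Flag differentially expressed genes by adjusted p below *threshold*.

    Genes with missing padj are never DEGs (mirrors independent-filtering NA
    semantics).  Direction comes from the sign of log2fc.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    padj = pd.to_numeric(de_table["padj"], errors="coerce")
    lfc = pd.to_numeric(de_table["log2fc"], errors="raise")
    is_deg = padj.notna() & (padj < threshold)
    return pd.DataFrame(
        {
            "gene": de_table["gene"].astype(str),
            "padj": padj,
            "is_deg": is_deg.to_numpy(dtype=bool),
            "direction": np.where(lfc.to_numpy(dtype=float) >= 0, "up", "down"),
        }
    )
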
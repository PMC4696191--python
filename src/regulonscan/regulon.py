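"""Join differential expression with promoter-motif hits into regulon records.

A significant gene whose promoter window carries a qualifying consensus
match is a candidate *direct* target of the regulator; significant genes
without a match are *indirect* (their regulation presumably flows through
intermediate regulators). The fraction of direct targets that are
up-regulated in the regulator mutant measures whether the regulator acts
mainly as a repressor.
"""

from __future__ import annotations

import pandas as pd

from .io import GenomeAnnotation, ValidationError

__all__ = ["integrate", "repressor_score"]

REGULON_COLUMNS = [
    "gene_id", "product", "cog_class", "log2fc", "status",
    "match_strand", "distance_nt", "matched_sequence", "identity_pct",
    "regulation_class",
]


def integrate(
    de: pd.DataFrame, hits: pd.DataFrame, genome: GenomeAnnotation
) -> pd.DataFrame:
    """One record per significant gene, classified direct/indirect.

    ``hits`` is the best-hit-per-gene table from the promoter scan; a gene is
    direct iff it appears there. Output is sorted by COG class then
    descending |log2fc|. Duplicate gene ids in ``hits`` are an error.
    """
    if hits["gene_id"].duplicated().any():
        dups = sorted(hits.loc[hits["gene_id"].duplicated(), "gene_id"])
        raise ValidationError(f"duplicate gene_id in hits: {dups}")
    sig = de[de["status"].isin(("up", "down"))].copy()
    ann = {g.gene_id: g for g in genome.genes}
    missing = sorted(set(sig["gene_id"]) - set(ann))
    if missing:
        raise ValidationError(f"significant genes absent from genome: {missing}")
    merged = sig.merge(
        hits[["gene_id", "match_strand", "distance_nt", "matched_sequence",
              "identity_pct"]],
        on="gene_id",
        how="left",
    )
    merged["product"] = merged["gene_id"].map(lambda g: ann[g].product)
    merged["cog_class"] = merged["gene_id"].map(lambda g: ann[g].cog_class or "")
    merged["regulation_class"] = merged["matched_sequence"].map(
        lambda s: "indirect" if pd.isna(s) else "direct"
    )
    merged["_abs"] = merged["log2fc"].abs()
    merged = merged.sort_values(
        ["cog_class", "_abs", "gene_id"], ascending=[True, False, True]
    ).drop(columns="_abs")
    return merged[REGULON_COLUMNS].reset_index(drop=True)


def repressor_score(records: pd.DataFrame) -> float:
    """Fraction of direct targets up-regulated in the mutant.

    A value above 0.5 labels the regulator predominantly repressing (loss of
    a repressor de-represses its direct targets).
    """
    direct = records[records["regulation_class"] == "direct"]
    if direct.empty:
        raise ValidationError("repressor_score needs at least one direct target")
    return float((direct["status"] == "up").mean())
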
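"""Functional (COG) breakdown of the differentially expressed gene set.

Compound classes such as "NT" count once per constituent letter, so a gene
annotated NT contributes to both the N (motility) and T (signal
transduction) bars; genes without a COG are the unclassified pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import GenomeAnnotation, ValidationError

__all__ = ["CogBreakdown", "breakdown_by_cog", "dominant_direction"]

COG_CLASSES = set("JAKLBDVTMNUOCGEFHIPQRS")


@dataclass
class CogBreakdown:
    """Per-class up/down counts plus the overall classification rate."""

    per_class: pd.DataFrame  # cog_class, n_up, n_down, pct_of_significant
    n_classified: int
    n_unclassified: int

    @property
    def classification_rate_pct(self) -> float:
        total = self.n_classified + self.n_unclassified
        return round(100.0 * self.n_classified / total, 2) if total else 0.0


def breakdown_by_cog(
    results: pd.DataFrame, genome: GenomeAnnotation
) -> CogBreakdown:
    """Count up-/down-regulated significant genes per COG letter.

    A compound class increments every constituent letter; percentages are of
    the total number of significant genes, to 2 decimals.
    """
    sig = results[results["status"].isin(("up", "down"))]
    known = {g.gene_id for g in genome.genes}
    missing = sorted(set(sig["gene_id"]) - known)
    if missing:
        raise ValidationError(f"genes in results absent from genome: {missing}")
    counts: dict[str, dict[str, int]] = {}
    n_classified = 0
    n_unclassified = 0
    for row in sig.itertuples(index=False):
        cog = genome.gene(row.gene_id).cog_class
        if not cog:
            n_unclassified += 1
            continue
        n_classified += 1
        for letter in cog:
            d = counts.setdefault(letter, {"n_up": 0, "n_down": 0})
            d["n_up" if row.status == "up" else "n_down"] += 1
    n_sig = len(sig)
    rows = [
        {
            "cog_class": letter,
            "n_up": d["n_up"],
            "n_down": d["n_down"],
            "pct_of_significant": round(
                100.0 * (d["n_up"] + d["n_down"]) / n_sig, 2
            )
            if n_sig
            else 0.0,
        }
        for letter, d in sorted(counts.items())
    ]
    per_class = pd.DataFrame(
        rows, columns=["cog_class", "n_up", "n_down", "pct_of_significant"]
    )
    return CogBreakdown(
        per_class=per_class, n_classified=n_classified, n_unclassified=n_unclassified
    )


def dominant_direction(breakdown: CogBreakdown, cog: str) -> str:
    """'mostly_up', 'mostly_down' or 'balanced' for one COG letter."""
    match = breakdown.per_class[breakdown.per_class["cog_class"] == cog]
    if match.empty:
        raise ValidationError(f"COG class {cog!r} not present in breakdown")
    n_up = int(match["n_up"].iloc[0])
    n_down = int(match["n_down"].iloc[0])
    total = n_up + n_down
    if total == 0:
        raise ValidationError(f"COG class {cog!r} has no classified genes")
    frac = n_up / total
    if frac > 0.5:
        return "mostly_up"
    if frac < 0.5:
        return "mostly_down"
    return "balanced"
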
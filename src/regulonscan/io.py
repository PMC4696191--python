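"""Readers, writers and the shared coordinate conventions.

Genome positions are 1-based inclusive throughout; gene-local distances
(promoter scanning) put the first base of the start codon at 0, negative
values upstream. Gene tables may arrive as GFF3 or as a flat TSV with the
columns ``gene_id, contig_id, strand, cds_start, cds_end, cog_class,
product``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "CountMatrix",
    "ValidationError",
    "read_genome",
    "read_counts",
    "write_table",
    "write_genome",
    "FLOAT_FORMATS",
]

VALID_STRANDS = frozenset({"+", "-"})
_DNA = frozenset("ACGT")

#: column -> decimal places used by :func:`write_table`
FLOAT_FORMATS = {
    "log2fc": 3,
    "identity_pct": 1,
    "pwm_logodds": 3,
    "fpkm_wt_mean": 3,
    "fpkm_mut_mean": 3,
    "pct_of_significant": 2,
}


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """A single-CDS bacterial gene.

    ``cds_start``/``cds_end`` are 1-based inclusive contig coordinates with
    ``cds_start <= cds_end`` regardless of strand; for minus-strand genes the
    translation start (first base of the start codon) is at ``cds_end``.
    """

    gene_id: str
    contig_id: str
    strand: str
    cds_start: int
    cds_end: int
    cog_class: str | None = None
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (1 <= self.cds_start <= self.cds_end):
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid CDS interval "
                f"[{self.cds_start}, {self.cds_end}]"
            )

    @property
    def translation_start(self) -> int:
        """1-based contig position of the first base of the start codon."""
        return self.cds_start if self.strand == "+" else self.cds_end

    @property
    def length_nt(self) -> int:
        return self.cds_end - self.cds_start + 1


@dataclass
class GenomeAnnotation:
    """Contig sequences plus strand-aware gene records."""

    contigs: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)
    allow_n: bool = False

    def __post_init__(self) -> None:
        cleaned = {}
        for cid, seq in self.contigs.items():
            seq = seq.upper()
            allowed = _DNA | {"N"} if self.allow_n else _DNA
            bad = set(seq) - allowed
            if bad:
                raise ValidationError(
                    f"contig {cid!r}: non-ACGT characters {sorted(bad)}"
                )
            cleaned[cid] = seq
        self.contigs = cleaned
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.contig_id not in self.contigs:
                raise ValidationError(
                    f"gene {g.gene_id!r} references missing contig {g.contig_id!r}"
                )
            if g.cds_end > len(self.contigs[g.contig_id]):
                raise ValidationError(
                    f"gene {g.gene_id!r}: cds_end {g.cds_end} exceeds contig "
                    f"{g.contig_id!r} length {len(self.contigs[g.contig_id])}"
                )
        self._by_id = {g.gene_id: g for g in self.genes}

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "contig_id": g.contig_id,
                    "strand": g.strand,
                    "cds_start": g.cds_start,
                    "cds_end": g.cds_end,
                    "cog_class": g.cog_class if g.cog_class is not None else "",
                    "product": g.product,
                }
                for g in self.genes
            ],
            columns=[
                "gene_id", "contig_id", "strand", "cds_start", "cds_end",
                "cog_class", "product",
            ],
        )


@dataclass
class CountMatrix:
    """Genes x samples integer read counts with gene lengths and a design."""

    counts: pd.DataFrame  # genes x samples, nonneg int
    gene_length_nt: pd.Series  # indexed by gene_id
    condition_of: dict[str, str]  # sample_id -> "wt" | "mut"

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise ValidationError("counts must be nonnegative")
        if not all(pd.api.types.is_integer_dtype(t) for t in c.dtypes):
            raise ValidationError("counts must be integers")
        missing = set(c.columns) - set(self.condition_of)
        if missing:
            raise ValidationError(f"samples without condition: {sorted(missing)}")
        bad = {s: v for s, v in self.condition_of.items() if v not in ("wt", "mut")}
        if bad:
            raise ValidationError(f"conditions must be wt/mut, got {bad}")
        conds = {self.condition_of[s] for s in c.columns}
        if conds != {"wt", "mut"}:
            raise ValidationError("need at least one sample per condition (wt and mut)")
        self.gene_length_nt = self.gene_length_nt.reindex(c.index)
        if self.gene_length_nt.isna().any():
            missing_len = list(self.gene_length_nt.index[self.gene_length_nt.isna()])
            raise ValidationError(f"genes without length: {missing_len[:5]}")
        if (self.gene_length_nt < 1).any():
            raise ValidationError("gene lengths must be >= 1 nt")
        self.gene_length_nt = self.gene_length_nt.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of[s] == condition]


# ---------------------------------------------------------------------------
# readers


def _genes_from_tsv(path: str | os.PathLike) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "contig_id", "strand", "cds_start", "cds_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"gene table missing columns {sorted(missing)}")
    recs = []
    for row in df.itertuples(index=False):
        cog = getattr(row, "cog_class", "") or None
        recs.append(
            GeneRecord(
                gene_id=row.gene_id,
                contig_id=row.contig_id,
                strand=row.strand,
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                cog_class=cog,
                product=getattr(row, "product", ""),
            )
        )
    return recs


def _genes_from_gff3(path: str | os.PathLike) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    recs = []
    for feat in db.features_of_type("CDS"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        cog = feat.attributes.get("cog_class", [None])[0]
        product = feat.attributes.get("product", [""])[0]
        recs.append(
            GeneRecord(
                gene_id=gid,
                contig_id=feat.seqid,
                strand=feat.strand,
                cds_start=feat.start,
                cds_end=feat.end,
                cog_class=cog,
                product=product,
            )
        )
    return recs


def read_genome(
    fasta_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    dialect: str = "tsv",
    allow_n: bool = False,
) -> GenomeAnnotation:
    """Load contigs (FASTA) and a gene table (GFF3 or TSV) into one object.

    GFF3 CDS features are mapped one feature per gene; the translation start
    is the strand-aware 5' end of the CDS interval.
    """
    contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not contigs:
        raise ValidationError(f"no contigs parsed from {fasta_path}")
    if dialect == "tsv":
        genes = _genes_from_tsv(genes_path)
    elif dialect == "gff3":
        genes = _genes_from_gff3(genes_path)
    else:
        raise ValidationError(f"unknown gene-table dialect {dialect!r}")
    return GenomeAnnotation(contigs=contigs, genes=genes, allow_n=allow_n)


def read_counts(
    tsv_path: str | os.PathLike, design_path: str | os.PathLike
) -> CountMatrix:
    """Read a genes x samples count TSV plus a design TSV.

    The counts TSV has a ``gene_id`` column, a ``length_nt`` column and one
    column per sample. The design TSV maps ``sample_id`` to ``condition``
    (wt or mut).
    """
    df = pd.read_csv(tsv_path, sep="\t")
    if "gene_id" not in df.columns or "length_nt" not in df.columns:
        raise ValidationError("counts TSV needs gene_id and length_nt columns")
    df = df.set_index("gene_id")
    lengths = df.pop("length_nt")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValidationError(f"non-numeric count at gene {row!r}, sample {col!r}")
        if (vals < 0).any():
            row = df.index[vals < 0][0]
            raise ValidationError(f"negative count at gene {row!r}, sample {col!r}")
        if (vals != vals.round()).any():
            row = df.index[vals != vals.round()][0]
            raise ValidationError(
                f"non-integer count at gene {row!r}, sample {col!r}"
            )
        df[col] = vals.astype(int)
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    if not {"sample_id", "condition"} <= set(design.columns):
        raise ValidationError("design TSV needs sample_id and condition columns")
    condition_of = dict(zip(design.sample_id, design.condition))
    return CountMatrix(counts=df, gene_length_nt=lengths, condition_of=condition_of)


# ---------------------------------------------------------------------------
# writers


def write_table(records, path: str | os.PathLike) -> None:
    """Write a result table as TSV with stable column order.

    Accepts a DataFrame or an iterable of dataclasses/dicts. Floats named in
    :data:`FLOAT_FORMATS` are rounded to their configured precision.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for r in records:
            if hasattr(r, "as_row"):
                rows.append(r.as_row())
            elif hasattr(r, "__dataclass_fields__"):
                from dataclasses import asdict

                rows.append(asdict(r))
            else:
                rows.append(dict(r))
        df = pd.DataFrame(rows)
    for col, ndec in FLOAT_FORMATS.items():
        if col in df.columns:
            df[col] = df[col].map(
                lambda v, n=ndec: "" if pd.isna(v) else f"{v:.{n}f}"
            )
    df.to_csv(path, sep="\t", index=False)


def write_genome(genome: GenomeAnnotation, fasta_path, genes_path) -> None:
    """Write contigs as FASTA and the gene table as TSV (round-trips with
    :func:`read_genome`)."""
    with open(fasta_path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    genome.gene_table().to_csv(genes_path, sep="\t", index=False)
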
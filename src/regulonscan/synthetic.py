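"""Synthetic genomes, planted motifs and NB count matrices.

Every generator is a pure function of (parameters, seed), so each pipeline
stage can be validated against planted truth without any external data. The
defaults emulate the shape of a rhizobial regulator-mutant RNA-Seq study:
a multi-contig GC-rich genome (60.6 %) with genes on both strands, 3+3
replicates, log-normal base means with median 1000 reads per CDS, NB
dispersion (var = mu + phi*mu^2), ~63 % of true DE genes up-regulated in
the mutant, and consensus-box motifs planted at controlled identity and
distance to the translation start.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneRecord, GenomeAnnotation, write_genome
from .motif import ConsensusMotif, reverse_complement

__all__ = [
    "generate_genome",
    "make_degenerate_motif",
    "plant_motif",
    "simulate_counts",
    "make_scenario",
    "DEFAULT_SCENARIO",
]

_BASES = np.array(list("ACGT"))

#: COG letters used for synthetic assignment (functional classes observed in
#: bacterial genome annotation).
COG_POOL = list("JKLDVTMNUOCGEFHIPQRS")

DEFAULT_SCENARIO: dict = {
    # genome shape
    "n_contigs": 4,
    "genes_per_contig": 30,
    "intergenic_nt": 600,
    "gene_nt": 900,
    "gc": 0.606,
    # expression
    "n_reps": 3,
    "dispersion": 0.05,
    "fraction_de": 0.25,
    "fraction_up": 0.632,
    "lfc_min": 2.0,
    "lfc_max": 5.0,
    "base_mean_median": 1000.0,
    "base_mean_sigma": 1.0,
    "min_de_base_mean": 200.0,
    "library_size_sd": 0.1,
    # annotation
    "classified_fraction": 0.895,
    # planted motifs
    "fraction_direct": 0.18,
    "max_planted_mismatches": 2,
    "window_upstream": 300,
    "window_downstream": 150,
}


def generate_genome(
    n_contigs: int = 4,
    genes_per_contig: int = 30,
    intergenic_nt: int = 600,
    gene_nt: int = 900,
    gc: float = 0.606,
    seed: int = 0,
) -> GenomeAnnotation:
    """Random multi-contig genome with evenly spaced genes on both strands.

    Bases are i.i.d. with the requested GC content; genes alternate strand
    (+, -, +, ...) and are separated by ``intergenic_nt`` so the default
    promoter window always fits inside the contig.
    """
    if min(n_contigs, genes_per_contig, intergenic_nt, gene_nt) <= 0:
        raise ValueError("all genome parameters must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contig_len = (genes_per_contig + 1) * intergenic_nt + genes_per_contig * gene_nt
    contigs: dict[str, str] = {}
    genes: list[GeneRecord] = []
    gene_index = 0
    for ci in range(1, n_contigs + 1):
        cid = f"contig_{ci}"
        contigs[cid] = "".join(
            rng.choice(_BASES, size=contig_len, p=probs)
        )
        for gi in range(genes_per_contig):
            start = intergenic_nt + gi * (gene_nt + intergenic_nt) + 1
            strand = "+" if gene_index % 2 == 0 else "-"
            genes.append(
                GeneRecord(
                    gene_id=f"g{ci}_{gi + 1}",
                    contig_id=cid,
                    strand=strand,
                    cds_start=start,
                    cds_end=start + gene_nt - 1,
                )
            )
            gene_index += 1
    return GenomeAnnotation(contigs=contigs, genes=genes)


def make_degenerate_motif(
    consensus: ConsensusMotif, n_mismatches_outside: int, seed: int = 0
) -> str:
    """Mutate exactly n distinct non-excluded consensus positions.

    The result scores identity 100*(n_compared - n)/n_compared exactly.
    """
    if not 0 <= n_mismatches_outside <= consensus.n_compared:
        raise ValueError(
            f"n_mismatches_outside must be in [0, {consensus.n_compared}]"
        )
    rng = np.random.default_rng(seed)
    seq = list(consensus.sequence)
    positions = rng.choice(
        consensus.scored_indices, size=n_mismatches_outside, replace=False
    )
    for p in positions:
        alternatives = [b for b in "ACGT" if b != seq[p]]
        seq[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def plant_motif(
    genome: GenomeAnnotation,
    gene_id: str,
    motif: str,
    distance_nt: int,
    strand: str = "+",
) -> GenomeAnnotation:
    """Overwrite genome bases so the gene's window carries ``motif``.

    ``distance_nt`` is the gene-local coordinate of the motif's 5'-most base
    in gene orientation (start codon = 0); ``strand`` is the match strand
    relative to the gene, so '-' plants the reverse complement in the
    gene-oriented frame. Only placement within the contig is checked.
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    gene = genome.gene(gene_id)
    contig = genome.contigs[gene.contig_id]
    L = len(motif)
    segment = motif if strand == "+" else reverse_complement(motif)
    ts = gene.translation_start
    if gene.strand == "+":
        lo = ts + distance_nt  # 1-based
        hi = lo + L - 1
        plus_segment = segment
    else:
        hi = ts - distance_nt
        lo = hi - L + 1
        plus_segment = reverse_complement(segment)
    if lo < 1 or hi > len(contig):
        raise ValueError(
            f"motif at gene-local {distance_nt} of {gene_id!r} falls outside "
            f"contig {gene.contig_id!r} ([{lo}, {hi}] vs 1..{len(contig)})"
        )
    new_contig = contig[: lo - 1] + plus_segment + contig[hi:]
    contigs = dict(genome.contigs)
    contigs[gene.contig_id] = new_contig
    return GenomeAnnotation(contigs=contigs, genes=list(genome.genes))


def simulate_counts(
    truth: pd.DataFrame,
    n_reps_per_condition: int = 3,
    dispersion: float = 0.05,
    library_sizes=None,
    seed: int = 0,
) -> CountMatrix:
    """NB counts for a wt/mut replicate design from a truth table.

    ``truth`` needs columns gene_id, base_mean, true_log2fc, length_nt.
    count(g, s) ~ NB(mu, var = mu + phi*mu^2) with
    mu = lib_factor(s) * base_mean(g) * 2^(true_log2fc(g) * [s is mut]);
    dispersion 0 degenerates to Poisson. Sampled via gamma-Poisson mixing.
    """
    if n_reps_per_condition < 2:
        raise ValueError("need >=2 replicates per condition")
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    rng = np.random.default_rng(seed)
    n_samples = 2 * n_reps_per_condition
    if library_sizes is None:
        library_sizes = np.ones(n_samples)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if len(library_sizes) != n_samples:
        raise ValueError("library_sizes must have one entry per sample")
    sample_ids = [f"wt_{i + 1}" for i in range(n_reps_per_condition)] + [
        f"mut_{i + 1}" for i in range(n_reps_per_condition)
    ]
    is_mut = np.array([0] * n_reps_per_condition + [1] * n_reps_per_condition)
    base = truth["base_mean"].to_numpy(dtype=float)[:, None]
    lfc = truth["true_log2fc"].to_numpy(dtype=float)[:, None]
    mu = library_sizes[None, :] * base * 2.0 ** (lfc * is_mut[None, :])
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=truth["gene_id"].values, columns=sample_ids)
    df.index.name = "gene_id"
    condition_of = {s: ("mut" if m else "wt") for s, m in zip(sample_ids, is_mut)}
    return CountMatrix(
        counts=df,
        gene_length_nt=pd.Series(
            truth["length_nt"].to_numpy(dtype=float), index=truth["gene_id"].values
        ),
        condition_of=condition_of,
    )


def make_scenario(
    config: dict | None = None,
    seed: int = 0,
    consensus: ConsensusMotif = ConsensusMotif(),
    outdir: str | os.PathLike | None = None,
) -> tuple[GenomeAnnotation, CountMatrix, pd.DataFrame]:
    """Build a fully consistent (genome, counts, truth) triple.

    ``config`` overrides :data:`DEFAULT_SCENARIO` keys. True DE genes get
    |log2fc| uniform in [lfc_min, lfc_max]; exactly
    round(fraction_up * n_de) of them are up-regulated (the configured
    fraction is a design quantity, not a random draw). A ``fraction_direct``
    subset of DE genes receives a planted consensus-like motif at controlled
    identity, uniform distance inside the scan window, and random strand.
    Optionally writes FASTA/TSV fixtures to ``outdir``.
    """
    cfg = dict(DEFAULT_SCENARIO)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        cfg.update(config)
    rng = np.random.default_rng(seed)
    genome = generate_genome(
        n_contigs=cfg["n_contigs"],
        genes_per_contig=cfg["genes_per_contig"],
        intergenic_nt=cfg["intergenic_nt"],
        gene_nt=cfg["gene_nt"],
        gc=cfg["gc"],
        seed=int(rng.integers(2**31)),
    )
    n_genes = len(genome.genes)

    # COG labels
    labels: list[str | None] = []
    for _ in range(n_genes):
        if rng.random() < cfg["classified_fraction"]:
            labels.append(COG_POOL[rng.integers(len(COG_POOL))])
        else:
            labels.append(None)
    genome = GenomeAnnotation(
        contigs=genome.contigs,
        genes=[
            dataclasses.replace(g, cog_class=lab, product=f"synthetic protein {g.gene_id}")
            for g, lab in zip(genome.genes, labels)
        ],
    )

    # expression truth
    gene_ids = [g.gene_id for g in genome.genes]
    base_mean = rng.lognormal(
        mean=np.log(cfg["base_mean_median"]), sigma=cfg["base_mean_sigma"], size=n_genes
    )
    n_de = int(round(cfg["fraction_de"] * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True
    base_mean[is_de] = np.maximum(base_mean[is_de], cfg["min_de_base_mean"])
    lfc = np.zeros(n_genes)
    n_up = int(round(cfg["fraction_up"] * n_de))
    up_idx = rng.choice(de_idx, size=n_up, replace=False)
    sign = np.where(np.isin(np.arange(n_genes), up_idx), 1.0, -1.0)
    mag = rng.uniform(cfg["lfc_min"], cfg["lfc_max"], size=n_genes)
    lfc[is_de] = (sign * mag)[is_de]

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "base_mean": base_mean,
            "true_log2fc": lfc,
            "is_de": is_de,
            "cog_class": [lab or "" for lab in labels],
            "length_nt": [g.length_nt for g in genome.genes],
            "planted_motif": "",
            "planted_distance": pd.array([pd.NA] * n_genes, dtype="Int64"),
            "planted_strand": "",
            "planted_identity_pct": np.nan,
        }
    )

    # planted motifs for a subset of the DE genes (direct targets)
    n_direct = int(round(cfg["fraction_direct"] * n_de))
    direct_idx = rng.choice(de_idx, size=n_direct, replace=False)
    L = consensus.length
    d_lo = -cfg["window_upstream"]
    d_hi = cfg["window_downstream"] - L
    for gi in direct_idx:
        n_mm = int(rng.integers(0, cfg["max_planted_mismatches"] + 1))
        motif = make_degenerate_motif(consensus, n_mm, seed=int(rng.integers(2**31)))
        distance = int(rng.integers(d_lo, d_hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genome = plant_motif(genome, gene_ids[gi], motif, distance, strand)
        truth.loc[gi, "planted_motif"] = motif
        truth.loc[gi, "planted_distance"] = distance
        truth.loc[gi, "planted_strand"] = strand
        truth.loc[gi, "planted_identity_pct"] = round(
            100.0 * (consensus.n_compared - n_mm) / consensus.n_compared, 1
        )

    lib = np.exp(rng.normal(0.0, cfg["library_size_sd"], size=2 * cfg["n_reps"]))
    counts = simulate_counts(
        truth,
        n_reps_per_condition=cfg["n_reps"],
        dispersion=cfg["dispersion"],
        library_sizes=lib,
        seed=int(rng.integers(2**31)),
    )

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_genome(
            genome,
            os.path.join(outdir, "genome.fasta"),
            os.path.join(outdir, "genes.tsv"),
        )
        counts_df = counts.counts.copy()
        counts_df.insert(0, "length_nt", counts.gene_length_nt.astype(int))
        counts_df.index.name = "gene_id"
        counts_df.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
        pd.DataFrame(
            {
                "sample_id": counts.sample_ids,
                "condition": [counts.condition_of[s] for s in counts.sample_ids],
            }
        ).to_csv(os.path.join(outdir, "design.tsv"), sep="\t", index=False)
        truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)

    return genome, counts, truth
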
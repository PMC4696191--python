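"""Promoter scanning for a regulator-binding consensus box.

The search emulates how bacterial regulon studies annotate candidate direct
targets: every gene's translation-start-relative window (default 300 nt
upstream to 150 nt downstream, start codon first base = position 0) is
scanned on both strands with an L-nt consensus (default the 22-nt RosR-box,
5'-CGGAATCTAGGGGTGGATTTCG-3'). The reported statistic is percent identity
over the consensus positions outside an excluded central block (default the
middle 4, i.e. 1-based 10-13, leaving 18 scored positions); a PWM log-odds
score is carried alongside as a secondary score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io import GenomeAnnotation

__all__ = [
    "ROSR_BOX",
    "ConsensusMotif",
    "PromoterWindow",
    "MotifHit",
    "identity_score",
    "reverse_complement",
    "extract_promoter_window",
    "scan_gene",
    "scan_genome",
    "build_pwm",
    "pwm_score",
    "gapped_identity",
]

ROSR_BOX = "CGGAATCTAGGGGTGGATTTCG"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{ndigits}"), ROUND_HALF_UP))


def _default_excluded(length: int) -> frozenset[int]:
    # central 4 positions, 1-based: 10-13 for a 22-mer
    mid = length // 2
    return frozenset(range(mid - 1, mid + 3))


@dataclass(frozen=True)
class ConsensusMotif:
    """A binding-site consensus with an excluded central block.

    ``excluded_positions`` are 1-based positions that never contribute to the
    identity denominator (``n_compared = L - |excluded|``, 18 by default).
    """

    sequence: str = ROSR_BOX
    name: str = "RosR-box"
    excluded_positions: frozenset[int] = None  # type: ignore[assignment]
    pseudocount: float = 0.25
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - set(_BASES):
            raise ValueError(f"consensus contains non-ACGT bases: {self.sequence!r}")
        object.__setattr__(self, "sequence", seq)
        if self.excluded_positions is None:
            object.__setattr__(
                self, "excluded_positions", _default_excluded(len(seq))
            )
        else:
            object.__setattr__(
                self, "excluded_positions", frozenset(self.excluded_positions)
            )
        L = len(seq)
        if not self.excluded_positions <= set(range(1, L + 1)):
            raise ValueError("excluded_positions outside 1..L")
        if len(self.excluded_positions) >= L:
            raise ValueError("cannot exclude every position")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_compared(self) -> int:
        return self.length - len(self.excluded_positions)

    @property
    def scored_indices(self) -> list[int]:
        """0-based indices of the scored (non-excluded) positions."""
        return [i for i in range(self.length) if (i + 1) not in self.excluded_positions]


@dataclass(frozen=True)
class PromoterWindow:
    """Translation-start-relative scan window (start codon first base = 0)."""

    upstream_nt: int = 300
    downstream_nt: int = 150

    def __post_init__(self) -> None:
        if self.upstream_nt < 0 or self.downstream_nt < 0:
            raise ValueError("window extents must be nonnegative")

    @property
    def span(self) -> int:
        return self.upstream_nt + self.downstream_nt


@dataclass(frozen=True)
class MotifHit:
    """A scored window match.

    ``distance_nt`` is the gene-local coordinate of the match's 5'-most base
    (start codon = 0, negative upstream). ``matched_sequence`` is stored in
    consensus orientation so that re-scoring it with :func:`identity_score`
    reproduces ``identity_pct``; for ``match_strand`` '-' it is the reverse
    complement of the gene-oriented frame.
    """

    gene_id: str
    matched_sequence: str
    match_strand: str
    distance_nt: int
    n_compared: int
    n_matches: int
    identity_pct: float
    pwm_logodds: float

    def as_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "match_strand": self.match_strand,
            "distance_nt": self.distance_nt,
            "matched_sequence": self.matched_sequence,
            "n_matches": self.n_matches,
            "identity_pct": self.identity_pct,
            "pwm_logodds": self.pwm_logodds,
        }


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (strict ACGT)."""
    if set(seq) - set(_BASES):
        raise ValueError(f"non-ACGT base in {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def identity_score(
    query: str, consensus: ConsensusMotif, denominator: str = "excluded"
) -> tuple[int, float]:
    """Ungapped identity of ``query`` against the consensus.

    Counts matches at the non-excluded positions only. With the default
    ``denominator='excluded'`` the percentage is over ``L - |excluded|``
    positions (18 for the 22-nt box); ``denominator='full'`` divides by L
    instead. Rounded half-up to one decimal.
    """
    query = query.upper()
    if len(query) != consensus.length:
        raise ValueError(
            f"query length {len(query)} != consensus length {consensus.length}"
        )
    n_matches = sum(
        1 for i in consensus.scored_indices if query[i] == consensus.sequence[i]
    )
    if denominator == "excluded":
        denom = consensus.n_compared
    elif denominator == "full":
        denom = consensus.length
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    return n_matches, _round_half_up(100.0 * n_matches / denom)


def extract_promoter_window(
    genome: GenomeAnnotation, gene_id: str, window: PromoterWindow = PromoterWindow()
) -> tuple[str, int]:
    """Gene-oriented promoter window sequence and its left-edge offset.

    Covers gene-local positions ``-upstream_nt .. downstream_nt - 1``,
    truncated at contig ends; minus-strand genes return the reverse
    complement of the mirrored contig slice. The returned offset is the
    gene-local coordinate of the first returned base.
    """
    gene = genome.gene(gene_id)
    contig = genome.contigs[gene.contig_id]
    n = len(contig)
    ts = gene.translation_start  # 1-based
    if gene.strand == "+":
        lo = max(1, ts - window.upstream_nt)
        hi = min(n, ts + window.downstream_nt - 1)
        return contig[lo - 1 : hi], lo - ts
    # minus strand: gene-local d maps to contig coord ts - d
    lo = max(1, ts - window.downstream_nt + 1)
    hi = min(n, ts + window.upstream_nt)
    return reverse_complement(contig[lo - 1 : hi]), ts - hi


def build_pwm(consensus: ConsensusMotif) -> np.ndarray:
    """L x 4 log2-odds matrix from the single-sequence consensus.

    Cell (p, b) = log2(((count_b(p) + pseudocount) / (1 + 4*pseudocount)) /
    background_b) with count 1 at the consensus base and 0 elsewhere.
    """
    if any(b <= 0 for b in consensus.background):
        raise ValueError("background probabilities must be positive")
    if consensus.pseudocount <= 0:
        raise ValueError("pseudocount must be positive for a single sequence")
    pc = consensus.pseudocount
    mat = np.empty((consensus.length, 4))
    for p, base in enumerate(consensus.sequence):
        for b in range(4):
            count = 1.0 if b == _BASE_INDEX[base] else 0.0
            freq = (count + pc) / (1.0 + 4.0 * pc)
            mat[p, b] = np.log2(freq / consensus.background[b])
    return mat


def pwm_score(query: str, consensus: ConsensusMotif, pwm: np.ndarray | None = None) -> float:
    """Sum of log-odds over the non-excluded positions."""
    if pwm is None:
        pwm = build_pwm(consensus)
    query = query.upper()
    if len(query) != consensus.length:
        raise ValueError("query/consensus length mismatch")
    return float(sum(pwm[i, _BASE_INDEX[query[i]]] for i in consensus.scored_indices))


def scan_gene(
    window_seq: str,
    offset: int,
    consensus: ConsensusMotif,
    min_identity_pct: float = 50.0,
    search_both_strands: bool = True,
    gene_id: str = "",
    denominator: str = "excluded",
) -> list[MotifHit]:
    """Slide the consensus frame across a window and keep qualifying frames.

    Every L-nt frame is scored forward and, if ``search_both_strands``, as
    its reverse complement; frames at identity >= ``min_identity_pct`` become
    hits. Hits sort by descending identity, then ascending |distance|, then
    strand ('+' first).
    """
    if not 0.0 <= min_identity_pct <= 100.0:
        raise ValueError("min_identity_pct must be in [0, 100]")
    L = consensus.length
    window_seq = window_seq.upper()
    pwm = build_pwm(consensus)
    hits: list[MotifHit] = []
    for i in range(len(window_seq) - L + 1):
        frame = window_seq[i : i + L]
        candidates = [("+", frame)]
        if search_both_strands:
            candidates.append(("-", reverse_complement(frame)))
        for strand, seq in candidates:
            n_matches, pct = identity_score(seq, consensus, denominator=denominator)
            if pct >= min_identity_pct:
                hits.append(
                    MotifHit(
                        gene_id=gene_id,
                        matched_sequence=seq,
                        match_strand=strand,
                        distance_nt=offset + i,
                        n_compared=consensus.n_compared,
                        n_matches=n_matches,
                        identity_pct=pct,
                        pwm_logodds=round(pwm_score(seq, consensus, pwm), 6),
                    )
                )
    hits.sort(
        key=lambda h: (-h.identity_pct, abs(h.distance_nt), h.match_strand)
    )
    return hits


def scan_genome(
    genome: GenomeAnnotation,
    consensus: ConsensusMotif = ConsensusMotif(),
    window: PromoterWindow = PromoterWindow(),
    min_identity_pct: float = 50.0,
    search_both_strands: bool = True,
    denominator: str = "excluded",
) -> pd.DataFrame:
    """Best qualifying hit per gene across the whole annotation.

    Returns a table (gene_id, match_strand, distance_nt, matched_sequence,
    n_matches, identity_pct, pwm_logodds); genes with no qualifying hit are
    omitted. Deterministic given inputs.
    """
    rows = []
    for gene in genome.genes:
        seq, offset = extract_promoter_window(genome, gene.gene_id, window)
        if len(seq) < consensus.length:
            continue
        hits = scan_gene(
            seq,
            offset,
            consensus,
            min_identity_pct=min_identity_pct,
            search_both_strands=search_both_strands,
            gene_id=gene.gene_id,
            denominator=denominator,
        )
        if hits:
            rows.append(hits[0].as_row())
    cols = [
        "gene_id", "match_strand", "distance_nt", "matched_sequence",
        "n_matches", "identity_pct", "pwm_logodds",
    ]
    return pd.DataFrame(rows, columns=cols)


def gapped_identity(
    query: str, consensus: ConsensusMotif, max_indels: int = 1
) -> tuple[tuple[str, str], int, float]:
    """Identity allowing up to ``max_indels`` single-base gaps.

    Global alignment with match +1, mismatch 0, gap -1 (ties broken by the
    leftmost gap). Identity is then computed exactly as in
    :func:`identity_score` over the L consensus columns, a gap column
    counting as a mismatch; the denominator stays ``L - |excluded|``.
    Returns ((aligned_query, aligned_consensus), n_matches, identity_pct).
    """
    query = query.upper()
    L = consensus.length
    diff = len(query) - L
    if abs(diff) > max_indels:
        raise ValueError(
            f"query length {len(query)} differs from consensus length {L} "
            f"by more than max_indels={max_indels}"
        )
    cons = consensus.sequence
    if diff == 0:
        n_matches, pct = identity_score(query, consensus)
        return (query, cons), n_matches, pct

    def _score(aq: str, ac: str) -> int:
        # alignment score over all columns: match +1, gap -1
        s = 0
        for a, b in zip(aq, ac):
            if a == "-" or b == "-":
                s -= 1
            elif a == b:
                s += 1
        return s

    best = None
    if diff < 0:  # deletion in query: place |diff| gaps in the query row
        for c in range(L):
            aq = query[:c] + "-" + query[c:]
            ac = cons
            sc = _score(aq, ac)
            if best is None or sc > best[0]:
                best = (sc, aq, ac)
    else:  # insertion in query: gap in the consensus row
        for c in range(L + 1):
            aq = query
            ac = cons[:c] + "-" + cons[c:]
            sc = _score(aq, ac)
            if best is None or sc > best[0]:
                best = (sc, aq, ac)
    _, aq, ac = best
    # identity over the consensus columns (skip the consensus-gap column)
    n_matches = 0
    cons_pos = 0  # 1-based consensus position counter
    for a, b in zip(aq, ac):
        if b == "-":
            continue
        cons_pos += 1
        if cons_pos in consensus.excluded_positions:
            continue
        if a != "-" and a == b:
            n_matches += 1
    pct = _round_half_up(100.0 * n_matches / consensus.n_compared)
    return (aq, ac), n_matches, pct
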
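"""Negative-binomial differential expression between wild type and mutant.

The pipeline mirrors the standard bulk RNA-Seq workflow at desk scale:
median-of-ratios size factors, FPKM for reporting, a per-gene
method-of-moments dispersion pooled across conditions (var = mu + phi*mu^2),
a two-sided Wald test of equal NB means on normalized counts, and
Benjamini-Hochberg FDR. Fold changes are mutant over wild type.

Results live in a plain DataFrame with columns gene_id, fpkm_wt_mean,
fpkm_mut_mean, log2fc, p_value, q_value, status ({up, down, ns}).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, ValidationError

__all__ = [
    "compute_fpkm",
    "size_factors",
    "estimate_dispersion",
    "common_dispersion",
    "de_test",
    "bh_fdr",
    "classify_de",
    "summarize_direction",
    "top_n_by_abs_lfc",
    "DirectionSummary",
]


def compute_fpkm(counts: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of CDS per million mapped fragments.

    FPKM(g, s) = count(g, s) * 1e9 / (length_nt(g) * total(s)).
    """
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"sample(s) with zero total counts: {list(zero.index)}")
    return counts.counts * 1e9 / np.outer(counts.gene_length_nt, totals)


def size_factors(counts: CountMatrix, min_reference_genes: int = 10) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples, restricted to
    genes with no zero count; falls back to total-count scaling when fewer
    than ``min_reference_genes`` genes qualify.
    """
    c = counts.counts.astype(float)
    nonzero = (c > 0).all(axis=1)
    if nonzero.sum() < min_reference_genes:
        totals = c.sum(axis=0)
        return totals / totals.mean()
    logc = np.log(c.loc[nonzero])
    ref = logc.mean(axis=1)
    sf = np.exp((logc.sub(ref, axis=0)).median(axis=0))
    return sf


def _per_gene_phi(
    counts: CountMatrix, conds: list[str], clip: bool
) -> pd.Series:
    """Raw per-gene MoM dispersion (s^2 - m) / m^2 on normalized counts,
    pooled over the given conditions weighted by residual df."""
    sf = size_factors(counts)
    norm = counts.counts / sf
    num = pd.Series(0.0, index=norm.index)
    den = 0.0
    for cond in conds:
        samples = counts.samples(cond)
        if len(samples) < 2:
            raise ValidationError(
                f"need >=2 replicates in condition {cond!r}, got {len(samples)}"
            )
        sub = norm[samples]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = ((v - m) / m**2).where(m > 0, 0.0)
        if clip:
            phi = phi.clip(lower=0.0)
        w = len(samples) - 1
        num = num + w * phi
        den += w
    return num / den


def estimate_dispersion(
    counts: CountMatrix, condition: str | None = None, floor: float = 1e-8
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion on normalized counts.

    phi_hat = max(0, (s^2 - m) / m^2) within a condition; with
    ``condition=None`` the two within-condition estimates are pooled,
    weighted by residual degrees of freedom. Floored at ``floor``.
    """
    conds = [condition] if condition is not None else ["wt", "mut"]
    return _per_gene_phi(counts, conds, clip=True).clip(lower=floor)


def common_dispersion(counts: CountMatrix, floor: float = 1e-8) -> float:
    """One dispersion shared by all genes: the across-genes mean of the raw
    (unclipped) per-gene MoM estimates.

    With 3+3 replicates the per-gene estimate has only 4 residual df and is
    far too noisy to plug into a Wald test gene by gene; averaging across
    genes before clipping removes both the noise and the truncation bias.
    """
    raw = _per_gene_phi(counts, ["wt", "mut"], clip=False)
    return float(max(floor, raw.mean()))


def de_test(
    counts: CountMatrix,
    pseudo_fpkm: float = 0.5,
    dispersion_floor: float = 1e-8,
    dispersion_mode: str = "common",
) -> pd.DataFrame:
    """Per-gene Wald test of equal NB means plus FPKM fold change.

    log2fc = log2((mean FPKM_mut + pseudo) / (mean FPKM_wt + pseudo)).
    The Wald statistic compares the log of the per-condition means of
    size-factor-normalized counts, with the delta-method variance under
    var = mu + phi*mu^2; genes with zero counts everywhere get p = 1.
    ``dispersion_mode`` is "common" (one across-genes pooled phi, the
    default at few replicates) or "per-gene".
    """
    wt = counts.samples("wt")
    mut = counts.samples("mut")
    if len(wt) < 2 or len(mut) < 2:
        raise ValidationError("de_test needs >=2 replicates per condition")
    fpkm = compute_fpkm(counts)
    fpkm_wt = fpkm[wt].mean(axis=1)
    fpkm_mut = fpkm[mut].mean(axis=1)
    log2fc = np.log2((fpkm_mut + pseudo_fpkm) / (fpkm_wt + pseudo_fpkm))

    sf = size_factors(counts)
    norm = counts.counts / sf
    if dispersion_mode == "common":
        phi = common_dispersion(counts, floor=dispersion_floor)
    elif dispersion_mode == "per-gene":
        phi = estimate_dispersion(counts, floor=dispersion_floor)
    else:
        raise ValidationError(f"unknown dispersion_mode {dispersion_mode!r}")

    for_stats = {}
    for label, samples in (("wt", wt), ("mut", mut)):
        sub = norm[samples]
        mu = sub.mean(axis=1)
        n = len(samples)
        # Var(mean of count_s/sf_s) under var(count) = sf*mu + phi*(sf*mu)^2
        var_mean = sum((mu / sf[s] + phi * mu**2) for s in samples) / n**2
        for_stats[label] = (mu, var_mean)
    mu_wt, v_wt = for_stats["wt"]
    mu_mut, v_mut = for_stats["mut"]
    # continuity floor so one-sided zeros stay finite
    eps_wt = 0.5 / len(wt)
    eps_mut = 0.5 / len(mut)
    mw = mu_wt.clip(lower=eps_wt)
    mm = mu_mut.clip(lower=eps_mut)
    vw = v_wt.clip(lower=eps_wt / len(wt))
    vm = v_mut.clip(lower=eps_mut / len(mut))
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = (np.log(mm) - np.log(mw)) / np.sqrt(vm / mm**2 + vw / mw**2)
    p = pd.Series(2.0 * stats.norm.sf(np.abs(wald)), index=norm.index)
    all_zero = (counts.counts == 0).all(axis=1)
    identical_means = mu_wt == mu_mut
    p[all_zero | identical_means] = 1.0
    return pd.DataFrame(
        {
            "gene_id": counts.counts.index,
            "fpkm_wt_mean": fpkm_wt.values,
            "fpkm_mut_mean": fpkm_mut.values,
            "log2fc": log2fc.values,
            "p_value": p.values,
        }
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_de(
    results: pd.DataFrame, alpha: float = 0.05, lfc_threshold: float = 0.0
) -> pd.DataFrame:
    """Attach q-values and up/down/ns status.

    up: q < alpha and log2fc > lfc_threshold; down: q < alpha and
    log2fc < -lfc_threshold; otherwise ns.
    """
    out = results.copy()
    if "q_value" not in out.columns:
        out["q_value"] = bh_fdr(out["p_value"].values)
    sig = out["q_value"] < alpha
    out["status"] = "ns"
    out.loc[sig & (out["log2fc"] > lfc_threshold), "status"] = "up"
    out.loc[sig & (out["log2fc"] < -lfc_threshold), "status"] = "down"
    return out


class DirectionSummary(NamedTuple):
    n_significant: int
    pct_up: float
    pct_down: float
    empty: bool


def summarize_direction(results: pd.DataFrame) -> DirectionSummary:
    """Share of significant genes up- vs down-regulated (percent, 2 dp)."""
    sig = results[results["status"].isin(("up", "down"))]
    n = len(sig)
    if n == 0:
        return DirectionSummary(0, 0.0, 0.0, True)
    n_up = int((sig["status"] == "up").sum())
    return DirectionSummary(
        n, round(100.0 * n_up / n, 2), round(100.0 * (n - n_up) / n, 2), False
    )


def top_n_by_abs_lfc(
    results: pd.DataFrame, fpkm: pd.DataFrame, n: int = 100
) -> pd.DataFrame:
    """FPKM submatrix of the n significant genes with largest |log2fc|.

    Ties break by lexical gene_id; if fewer than n genes are significant the
    full set is returned.
    """
    sig = results[results["status"].isin(("up", "down"))].copy()
    sig["_abs"] = sig["log2fc"].abs()
    sig = sig.sort_values(["_abs", "gene_id"], ascending=[False, True])
    genes = list(sig["gene_id"].head(n))
    return fpkm.loc[genes]
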
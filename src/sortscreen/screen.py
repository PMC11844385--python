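"""Hit calling for FACS-bin CRISPRi screens (the iNC procedure).

The screen sorts cells into high and low fluorescence-ratio bins and
sequences the sgRNA cassette from each bin. Hit calling proceeds:

1. depth-normalize counts (counts-per-million with pseudocount),
2. per-sgRNA log2 fold change (high over low bin),
3. per-gene Mann-Whitney U test of the gene's sgRNA fold changes against
   the pooled non-targeting-control (NTC) sgRNA fold changes, and a
   "Gene Score" = gene-level LFC x -log10(p),
4. empirical FDR calibration with *quasi-genes* — pseudo-genes built by
   sampling k NTC sgRNAs with replacement and scored exactly like real
   genes — choosing the largest p cutoff whose estimated FDR
   (quasi discovery fraction over real discovery fraction) stays at or
   below the target, and
5. direction of each hit read off the sign of its gene-level LFC.

Because quasi-genes traverse the identical scoring path as real genes,
the ratio of their discovery rates estimates the false discovery rate
without any distributional assumption on the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .counting import BinCountMatrix
from .library import SgRNALibrary

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300  # keep p in (0, 1] so -log10 p is finite


@dataclass(frozen=True)
class QuasiGene:
    """A pseudo-gene of k NTC sgRNA ids sampled with replacement."""

    id: str
    members: tuple[str, ...]


@dataclass
class FdrContext:
    """Outcome of empirical-FDR calibration.

    ``curve`` has one row per observed real p-value threshold with the raw
    FDR estimate and its monotonized version (minimum over thresholds at
    or above t, so the hit set is nested in alpha). ``p_cutoff`` is None
    when no threshold meets alpha.
    """

    alpha: float
    p_cutoff: float | None
    curve: pd.DataFrame = field(repr=False)


# ---------------------------------------------------------------------------
# normalization and fold changes
# ---------------------------------------------------------------------------

def normalize_counts(
    counts: BinCountMatrix | pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Counts-per-million with pseudocount; each sample sums to 1e6.

    value = (count + pc) / sum(count + pc) * 1e6. The pseudocount keeps
    downstream log fold changes finite for dropout elements.
    """
    frame = counts.counts if isinstance(counts, BinCountMatrix) else counts
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if (frame.sum(axis=0) == 0).any():
        bad = [s for s in frame.columns if frame[s].sum() == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    shifted = frame.astype(float) + pseudocount
    return shifted / shifted.sum(axis=0) * 1e6


def sgrna_lfc(
    norm_high: pd.Series | np.ndarray,
    norm_low: pd.Series | np.ndarray,
    lib: SgRNALibrary,
) -> pd.DataFrame:
    """Per-sgRNA log2(high/low) of normalized counts, in library order.

    NTC elements are included — they are the raw material for both the
    pooled null and the quasi-genes.
    """
    high = np.asarray(norm_high, dtype=float)
    low = np.asarray(norm_low, dtype=float)
    if len(high) != lib.n_elements or len(low) != lib.n_elements:
        raise ValueError(
            f"vector lengths ({len(high)}, {len(low)}) do not match "
            f"library size {lib.n_elements}"
        )
    lfc = np.log2(high / low)
    return pd.DataFrame(
        {
            "sgrna": lib.ids,
            "gene": [e.target_gene for e in lib.elements],
            "is_ntc": [e.is_ntc for e in lib.elements],
            "lfc": lfc,
        }
    )


# ---------------------------------------------------------------------------
# quasi-genes
# ---------------------------------------------------------------------------

def make_quasi_genes(
    ntc_ids: Sequence[str], k: int = 5, n_quasi: int = 1000, seed: int = 0
) -> list[QuasiGene]:
    """Sample quasi-genes of size k uniformly with replacement from NTCs.

    Seeded and bit-reproducible. Repeated members within one quasi-gene
    are allowed by design (sampling is with replacement).
    """
    if len(ntc_ids) == 0:
        raise ValueError("cannot build quasi-genes from an empty NTC set")
    if k < 1 or n_quasi < 1:
        raise ValueError("k and n_quasi must be >= 1")
    rng = np.random.default_rng(seed)
    ids = np.asarray(ntc_ids, dtype=object)
    width = len(str(n_quasi))
    draws = rng.integers(0, len(ids), size=(n_quasi, k))
    return [
        QuasiGene(id=f"quasi_{i:0{width}d}", members=tuple(ids[row]))
        for i, row in enumerate(draws)
    ]


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _exact_u_counts(n: int, m: int) -> np.ndarray:
    """Null distribution of U (counts over 0..n*m) for tie-free samples.

    Classic recurrence N(u; n, m) = N(u - m; n-1, m) + N(u; n, m-1):
    the largest observation belongs either to x (contributing m pairs)
    or to y.
    """
    size = n * m + 1
    # table[j] = counts for (i, j) as i advances
    table = [np.zeros(size) for _ in range(m + 1)]
    for j in range(m + 1):
        table[j][0] = 1.0  # i = 0: only U = 0
    for i in range(1, n + 1):
        new = [np.zeros(size) for _ in range(m + 1)]
        new[0][0] = 1.0  # j = 0: only U = 0
        for j in range(1, m + 1):
            shifted = np.zeros(size)
            shifted[j:] = table[j][: size - j]
            new[j] = shifted + new[j - 1]
        table = new
    return table[m]


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["auto", "exact", "asymptotic"] = "auto",
    exact_limit: int = 25,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of x versus y.

    U counts pairs (x_i, y_j) with x_i > y_j, plus one half per tie. The
    exact p enumerates the tie-free permutation null (used when
    n + m <= ``exact_limit`` and there are no ties); otherwise a
    tie-corrected normal approximation with continuity correction is
    used. Returns (U, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u = float(ranks[:n].sum() - n * (n + 1) / 2)

    has_ties = len(np.unique(combined)) < n + m
    if method == "exact" or (method == "auto" and n + m <= exact_limit and not has_ties):
        if has_ties:
            raise ValueError("exact method is only defined for tie-free samples")
        counts = _exact_u_counts(n, m)
        total = comb(n + m, n)
        ui = int(round(u))
        cdf = counts[: ui + 1].sum() / total
        sf = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mu = n * m / 2.0
        nt = n + m
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (nt * (nt - 1))
        var = n * m / 12.0 * (nt + 1 - tie_term)
        if var <= 0:  # all observations identical
            return u, 1.0
        num = u - mu
        num -= 0.5 * np.sign(num)  # continuity correction toward the mean
        z = num / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return u, max(p, _P_FLOOR)


# ---------------------------------------------------------------------------
# gene-level statistics
# ---------------------------------------------------------------------------

def gene_stats(
    phenotypes: pd.DataFrame,
    quasi: Sequence[QuasiGene],
    aggregate: Literal["mean", "median"] = "mean",
    method: Literal["auto", "exact", "asymptotic"] = "auto",
) -> pd.DataFrame:
    """Score every real gene and every quasi-gene against the pooled NTCs.

    ``phenotypes`` is the sgrna_lfc output (sgrna, gene, is_ntc, lfc).
    For each gene the two-sided Mann-Whitney p of its member LFCs versus
    all NTC sgRNA LFCs is combined with the aggregate member LFC into
    gene_score = lfc_gene * -log10(p). Quasi-genes are scored by the
    identical path and flagged ``is_quasi``.
    """
    agg_fn = {"mean": np.mean, "median": np.median}[aggregate]
    ntc_mask = phenotypes["is_ntc"].to_numpy()
    ntc_lfcs = phenotypes.loc[ntc_mask, "lfc"].to_numpy()
    if ntc_lfcs.size == 0:
        raise ValueError("phenotype table contains no NTC sgRNAs")
    lfc_by_sgrna = dict(zip(phenotypes["sgrna"], phenotypes["lfc"]))

    rows = []
    for gene, sub in phenotypes.loc[~ntc_mask].groupby("gene", sort=True):
        member_lfcs = sub["lfc"].to_numpy()
        if member_lfcs.size == 0:
            raise ValueError(f"gene {gene!r} has no sgRNAs in the phenotype table")
        rows.append((gene, member_lfcs, False))
    for q in quasi:
        try:
            member_lfcs = np.array([lfc_by_sgrna[s] for s in q.members])
        except KeyError as exc:
            raise ValueError(
                f"quasi-gene {q.id!r} member {exc.args[0]!r} not in phenotype table"
            ) from None
        rows.append((q.id, member_lfcs, True))

    out = {"gene": [], "lfc_gene": [], "p_value": [], "gene_score": [],
           "is_quasi": [], "n_sgrnas": []}
    for name, member_lfcs, is_quasi in rows:
        lfc_gene = float(agg_fn(member_lfcs))
        _, p = mann_whitney_u(member_lfcs, ntc_lfcs, method=method)
        out["gene"].append(name)
        out["lfc_gene"].append(lfc_gene)
        out["p_value"].append(p)
        out["gene_score"].append(lfc_gene * -np.log10(p))
        out["is_quasi"].append(is_quasi)
        out["n_sgrnas"].append(len(member_lfcs))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# empirical FDR
# ---------------------------------------------------------------------------

def empirical_fdr_hits(
    results: pd.DataFrame, alpha: float = 0.10
) -> tuple[FdrContext, pd.DataFrame]:
    """Call hits at the p cutoff whose empirical FDR estimate is <= alpha.

    For each observed real-gene p-value t,
    FDR(t) = [#quasi p <= t / #quasi] / [#real p <= t / #real]; the curve
    is monotonized by taking the running minimum over thresholds >= t so
    hit sets are nested in alpha. The cutoff is the largest t with
    monotonized FDR <= alpha; real genes at or below it become hits with
    direction given by the sign of their gene-level LFC.
    """
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must be in [0, 1]")
    real = results.loc[~results["is_quasi"]]
    n_quasi = int(results["is_quasi"].sum())
    if n_quasi == 0:
        raise ValueError("no quasi-gene entries; cannot estimate empirical FDR")
    real_p = np.sort(real["p_value"].to_numpy())
    quasi_p = np.sort(results.loc[results["is_quasi"], "p_value"].to_numpy())
    thresholds = np.unique(real_p)
    frac_real = np.searchsorted(real_p, thresholds, side="right") / len(real_p)
    frac_quasi = np.searchsorted(quasi_p, thresholds, side="right") / n_quasi
    fdr_raw = frac_quasi / frac_real  # frac_real > 0 at observed real p
    fdr_mono = np.minimum.accumulate(fdr_raw[::-1])[::-1]
    ok = np.nonzero(fdr_mono <= alpha)[0]
    p_cutoff = float(thresholds[ok[-1]]) if ok.size else None

    curve = pd.DataFrame(
        {"threshold": thresholds, "fdr_raw": fdr_raw, "fdr": fdr_mono}
    )
    annotated = results.copy()
    is_hit = (
        (~annotated["is_quasi"])
        & (annotated["p_value"] <= p_cutoff)
        if p_cutoff is not None
        else pd.Series(False, index=annotated.index)
    )
    direction = np.where(annotated["lfc_gene"] > 0, "increase", "decrease")
    annotated["hit_direction"] = np.where(is_hit, direction, "none")
    n_hits = int(is_hit.sum())
    logger.info(
        "empirical FDR %.3g: p_cutoff=%s, %d hits / %d real genes",
        alpha, p_cutoff, n_hits, len(real),
    )
    return FdrContext(alpha=alpha, p_cutoff=p_cutoff, curve=curve), annotated


def replicate_concordance(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Pearson r of gene scores over real genes shared by two replicates."""
    ra = a.loc[~a["is_quasi"]].set_index("gene")["gene_score"]
    rb = b.loc[~b["is_quasi"]].set_index("gene")["gene_score"]
    shared = ra.index.intersection(rb.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    r, _ = sps.pearsonr(ra.loc[shared], rb.loc[shared])
    return float(r)


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------

def call_hits(
    counts: BinCountMatrix,
    lib: SgRNALibrary,
    high_sample: str,
    low_sample: str,
    pseudocount: float = 1.0,
    k: int = 5,
    n_quasi: int | None = None,
    alpha: float = 0.10,
    aggregate: Literal["mean", "median"] = "mean",
    seed: int = 0,
) -> tuple[pd.DataFrame, FdrContext, pd.DataFrame]:
    """Full hit-calling pass: counts in, annotated gene results out.

    ``n_quasi`` defaults to 10x the number of real genes: the FDR
    estimate is unbiased at any family size (it uses discovery
    fractions), but its noise feeds a selection bias in the data-chosen
    cutoff, so a family much larger than the gene set keeps the realized
    false-discovery proportion at the nominal level. Returns (annotated
    gene results, FdrContext, sgRNA phenotype table).
    """
    norm = normalize_counts(counts, pseudocount=pseudocount)
    phen = sgrna_lfc(norm[high_sample], norm[low_sample], lib)
    ntc_ids = [e.id for e in lib.ntc_elements]
    if n_quasi is None:
        n_quasi = 10 * lib.n_genes
    quasi = make_quasi_genes(ntc_ids, k=k, n_quasi=n_quasi, seed=seed)
    results = gene_stats(phen, quasi, aggregate=aggregate)
    ctx, annotated = empirical_fdr_hits(results, alpha=alpha)
    return annotated, ctx, phen
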
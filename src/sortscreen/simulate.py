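"""Seeded generators for every input the pipeline consumes.

These emulate the statistical structure the analyses assume — not the
biology. A sorted-bin screen is modeled as a Gaussian latent activity
phenotype per cell (gene effects shift the mean in units of the noise
SD), exact-quantile FACS gates collecting fixed tails, and multinomial
sequencing of each bin. Guide capture mixes a cell's own guide with
ambient molecules; cluster labels are multinomial draws over a baseline
occupancy with optional planted replacement vectors; flow events are
log-normal in the red/green ratio around a per-condition shift. Every
generator is a pure function of its config and seed and returns a truth
record alongside the data it emits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import BinCountMatrix, ExtractionSpec
from .library import SgRNAElement, SgRNALibrary

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# synthetic libraries
# ---------------------------------------------------------------------------

def random_library(
    n_genes: int,
    sgrnas_per_gene: int = 5,
    n_ntc: int = 250,
    protospacer_length: int = 20,
    seed: int = 0,
    name: str = "synthetic",
    ntc_sentinel: str = "NTC",
) -> SgRNALibrary:
    """A library of random distinct protospacers with the study's shape:
    ``sgrnas_per_gene`` guides per gene plus ``n_ntc`` non-targeting
    controls."""
    rng = np.random.default_rng(seed)
    n_total = n_genes * sgrnas_per_gene + n_ntc
    seqs: set[str] = set()
    while len(seqs) < n_total:
        block = rng.integers(0, 4, size=(n_total - len(seqs), protospacer_length))
        seqs.update("".join(_BASES[row]) for row in block)
    seq_list = sorted(seqs)
    rng.shuffle(seq_list)
    elements = []
    i = 0
    for g in range(n_genes):
        gene = f"G{g:04d}"
        for s in range(sgrnas_per_gene):
            elements.append(
                SgRNAElement(
                    id=f"{gene}_sg{s + 1}", protospacer=seq_list[i], target_gene=gene
                )
            )
            i += 1
    for s in range(n_ntc):
        elements.append(
            SgRNAElement(
                id=f"{ntc_sentinel}_sg{s + 1:03d}",
                protospacer=seq_list[i],
                target_gene=ntc_sentinel,
                is_ntc=True,
            )
        )
        i += 1
    return SgRNALibrary(
        elements=tuple(elements), name=name, ntc_sentinel=ntc_sentinel
    )


# ---------------------------------------------------------------------------
# sorted-bin screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions for a simulated sorted-bin screen.

    The latent per-cell phenotype is beta(gene) + Normal(0, noise_sd)
    with beta in units of the noise SD; gates collect the top and bottom
    ``bin_fraction`` of cells by exact sample quantile (35% tails by
    default, matching the sort design); each bin is sequenced as one
    multinomial draw of ``reads_per_bin`` reads over its sgRNA tallies.
    """

    n_genes: int = 500
    sgrnas_per_gene: int = 5
    n_ntc: int = 250
    effect_gene_fraction: float = 0.10
    effect_size: float = 2.0
    cells_per_sgrna: int = 300
    noise_sd: float = 1.0
    bin_fraction: float = 0.35
    reads_per_bin: int = 5_000_000
    overdispersion: float | None = None  # Dirichlet concentration scale, None = pure multinomial
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.bin_fraction <= 0.5):
            raise ValueError("bin_fraction must be in (0, 0.5]")
        if min(self.n_genes, self.sgrnas_per_gene, self.n_ntc,
               self.cells_per_sgrna, self.reads_per_bin) < 1:
            raise ValueError("all counts must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulated screen: per-gene effects and bin tallies."""

    effects: pd.Series  # gene -> beta (units of noise SD)
    effect_genes: list[str]
    bin_cell_tallies: pd.DataFrame = field(repr=False)  # element x {high, low}


def simulate_screen(
    cfg: ScreenSimConfig, lib: SgRNALibrary | None = None
) -> tuple[SgRNALibrary, BinCountMatrix, SimTruth]:
    """Simulate one FACS-sorted screen; returns (library, counts, truth).

    The effect genes (``effect_gene_fraction`` of genes, alternating sign
    of ``effect_size``) are chosen by the seeded RNG, so the full object
    is reproducible from the config alone.
    """
    rng = np.random.default_rng(cfg.seed)
    if lib is None:
        lib = random_library(
            cfg.n_genes, cfg.sgrnas_per_gene, cfg.n_ntc,
            seed=rng.integers(0, 2**31),
        )
    genes = sorted({e.target_gene for e in lib.targeting_elements})
    n_effect = int(round(cfg.effect_gene_fraction * len(genes)))
    effect_genes = sorted(rng.choice(genes, size=n_effect, replace=False))
    beta = pd.Series(0.0, index=pd.Index(genes, name="gene"))
    signs = np.where(np.arange(n_effect) % 2 == 0, 1.0, -1.0)
    beta.loc[effect_genes] = signs * cfg.effect_size * cfg.noise_sd

    element_gene = np.array(
        [e.target_gene if not e.is_ntc else None for e in lib.elements]
    )
    element_beta = np.array(
        [0.0 if g is None else beta[g] for g in element_gene]
    )
    n_elem = lib.n_elements
    n_cells = n_elem * cfg.cells_per_sgrna
    sgrna_of_cell = np.repeat(np.arange(n_elem), cfg.cells_per_sgrna)
    latent = element_beta[sgrna_of_cell] + rng.normal(0, cfg.noise_sd, size=n_cells)

    k = int(round(cfg.bin_fraction * n_cells))
    order = np.argsort(latent, kind="stable")
    low_cells = order[:k]
    high_cells = order[-k:]
    tallies = pd.DataFrame(
        {
            "high": np.bincount(sgrna_of_cell[high_cells], minlength=n_elem),
            "low": np.bincount(sgrna_of_cell[low_cells], minlength=n_elem),
        },
        index=pd.Index(lib.ids, name="id"),
    )

    counts = {}
    for bin_name in ("high", "low"):
        probs = tallies[bin_name].to_numpy(dtype=float)
        probs = probs / probs.sum()
        if cfg.overdispersion is not None:
            probs = rng.dirichlet(probs * cfg.overdispersion)
        counts[bin_name] = rng.multinomial(cfg.reads_per_bin, probs)
    frame = pd.DataFrame(counts, index=pd.Index(lib.ids, name="id"))
    stats = {
        b: {"total": cfg.reads_per_bin, "mapped": cfg.reads_per_bin, "unmapped": 0}
        for b in ("high", "low")
    }
    truth = SimTruth(
        effects=beta, effect_genes=list(effect_genes), bin_cell_tallies=tallies
    )
    return lib, BinCountMatrix(counts=frame, stats=stats), truth


# ---------------------------------------------------------------------------
# raw screen reads
# ---------------------------------------------------------------------------

def simulate_reads(
    lib: SgRNALibrary,
    multiplicities: Sequence[int] | Mapping[str, int],
    spec: ExtractionSpec,
    out_path: str | Path,
    error_rate: float = 0.0,
    tail_length: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Write a FASTQ of amplicon reads with known per-element multiplicities.

    Reads are built to satisfy ``spec``: slice mode puts random stuffer
    bases in the first ``offset`` positions; anchor mode prepends the
    anchor. ``error_rate`` applies independent per-base substitutions over
    the whole read. Returns the truth multiplicities (per element id).
    Read order is shuffled so counting must not rely on grouping.
    """
    rng = np.random.default_rng(seed)
    if isinstance(multiplicities, Mapping):
        mult = pd.Series(multiplicities).reindex(lib.ids, fill_value=0)
    else:
        mult = pd.Series(list(multiplicities), index=lib.ids)
    if (mult < 0).any():
        raise ValueError("multiplicities must be nonnegative")

    reads: list[tuple[str, str]] = []
    for e, n in zip(lib.elements, mult.to_numpy()):
        for j in range(int(n)):
            if spec.mode == "slice":
                prefix = "".join(_BASES[rng.integers(0, 4, size=spec.offset)])
            else:
                prefix = spec.anchor.upper()
            tail = "".join(_BASES[rng.integers(0, 4, size=tail_length)])
            seq = prefix + e.protospacer + tail
            if error_rate > 0:
                arr = np.array(list(seq))
                hit = rng.random(len(arr)) < error_rate
                if hit.any():
                    shift = rng.integers(1, 4, size=int(hit.sum()))
                    idx = np.array([_BASES.tolist().index(b) for b in arr[hit]])
                    arr[hit] = _BASES[(idx + shift) % 4]
                    seq = "".join(arr)
            reads.append((f"{e.id}_read{j}", seq))
    order = rng.permutation(len(reads))
    with open(out_path, "w") as fh:
        for i in order:
            name, seq = reads[i]
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return mult.rename("true_count")


# ---------------------------------------------------------------------------
# guide capture
# ---------------------------------------------------------------------------

def simulate_guide_capture(
    n_cells: int,
    guide_abundance: pd.Series | Sequence[float],
    singlet_fraction: float = 0.90,
    doublet_fraction: float = 0.05,
    ambient_rate: float = 0.02,
    mean_umis: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cell x guide UMI matrix with ambient noise and multiplets.

    Each cell's UMI depth is 1 + Poisson(mean_umis - 1). Singlets draw
    each UMI from their own guide with probability 1 - ambient_rate, else
    from the library-wide abundance vector; doublets split non-ambient
    UMIs evenly between two distinct guides; the remaining cells are
    ambient-only (no true guide). Returns (counts, truth) where truth has
    barcode, status in {singlet, doublet, ambient}, guide_1, guide_2.
    """
    if singlet_fraction + doublet_fraction > 1:
        raise ValueError("singlet + doublet fractions exceed 1")
    rng = np.random.default_rng(seed)
    if not isinstance(guide_abundance, pd.Series):
        guide_abundance = pd.Series(
            list(guide_abundance),
            index=[f"guide_{i:03d}" for i in range(len(guide_abundance))],
        )
    probs = guide_abundance.to_numpy(dtype=float)
    probs = probs / probs.sum()
    guides = guide_abundance.index.to_numpy()
    n_guides = len(guides)

    status = rng.choice(
        ["singlet", "doublet", "ambient"],
        size=n_cells,
        p=[singlet_fraction, doublet_fraction,
           1 - singlet_fraction - doublet_fraction],
    )
    depths = 1 + rng.poisson(max(mean_umis - 1, 0), size=n_cells)
    counts = np.zeros((n_cells, n_guides), dtype=np.int64)
    truth_rows = []
    for i in range(n_cells):
        barcode = f"cell_{i:05d}"
        depth = int(depths[i])
        n_ambient = int(rng.binomial(depth, ambient_rate))
        counts[i] += rng.multinomial(n_ambient, probs)
        own = depth - n_ambient
        if status[i] == "singlet":
            g1 = int(rng.choice(n_guides, p=probs))
            counts[i, g1] += own
            truth_rows.append((barcode, "singlet", guides[g1], None))
        elif status[i] == "doublet":
            g1, g2 = rng.choice(n_guides, size=2, replace=False, p=probs)
            split = int(rng.binomial(own, 0.5))
            counts[i, g1] += split
            counts[i, g2] += own - split
            truth_rows.append((barcode, "doublet", guides[g1], guides[g2]))
        else:
            counts[i] += rng.multinomial(own, probs)
            truth_rows.append((barcode, "ambient", None, None))
    barcodes = [r[0] for r in truth_rows]
    counts_df = pd.DataFrame(counts, index=barcodes, columns=guides)
    truth = pd.DataFrame(
        truth_rows, columns=["barcode", "status", "guide_1", "guide_2"]
    )
    return counts_df, truth


# ---------------------------------------------------------------------------
# cluster labels
# ---------------------------------------------------------------------------

def simulate_cluster_labels(
    n_groups: int,
    n_ntc_groups: int,
    cells_per_group: int,
    baseline_occupancy: Sequence[float],
    planted_shifts: Mapping[str, Sequence[float]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-cell cluster labels with optional planted shifts.

    Knockdown groups are named KD000..; NTC groups NTC00... Each group's
    cells are a multinomial draw over ``baseline_occupancy`` unless
    ``planted_shifts`` replaces that group's occupancy vector. Returns
    (labels, truth) where truth lists each group's occupancy vector and a
    shifted flag.
    """
    base = np.asarray(baseline_occupancy, dtype=float)
    if not np.isclose(base.sum(), 1.0):
        raise ValueError("baseline occupancy must sum to 1")
    if (base < 0).any():
        raise ValueError("occupancy entries must be nonnegative")
    planted_shifts = dict(planted_shifts or {})
    rng = np.random.default_rng(seed)
    groups = [f"KD{i:03d}" for i in range(n_groups)] + [
        f"NTC{i:02d}" for i in range(n_ntc_groups)
    ]
    unknown = set(planted_shifts) - set(groups)
    if unknown:
        raise ValueError(f"planted shifts for unknown groups: {sorted(unknown)}")
    rows = []
    truth_rows = []
    n_clusters = len(base)
    for g in groups:
        occ = np.asarray(planted_shifts.get(g, base), dtype=float)
        if (occ < 0).any() or not np.isclose(occ.sum(), 1.0):
            raise ValueError(f"invalid occupancy vector for group {g!r}")
        draws = rng.multinomial(cells_per_group, occ)
        cluster_of_cell = np.repeat(np.arange(n_clusters), draws)
        for j, cl in enumerate(cluster_of_cell):
            rows.append((f"{g}_cell{j:05d}", int(cl), g, g.startswith("NTC")))
        truth_rows.append((g, occ.tolist(), g in planted_shifts))
    labels = pd.DataFrame(rows, columns=["barcode", "cluster", "group", "is_ntc"])
    truth = pd.DataFrame(truth_rows, columns=["group", "occupancy", "shifted"])
    return labels, truth


# ---------------------------------------------------------------------------
# flow events
# ---------------------------------------------------------------------------

def simulate_flow_events(
    wells: Mapping[str, str],
    events_per_well: int,
    condition_effects: Mapping[str, float],
    baseline_log2_ratio: float = 0.0,
    noise_sd: float = 0.5,
    green_level: float = 1000.0,
    marker_levels: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a flow event table (well, condition, green, red, marker).

    Per event, log2(R/G) ~ Normal(baseline + effect(condition), noise_sd);
    green is held at ``green_level`` and red reconstructed as
    green * ratio. ``marker_levels`` sets the marker channel per condition
    (default 0).
    """
    rng = np.random.default_rng(seed)
    marker_levels = dict(marker_levels or {})
    rows = []
    for well, condition in wells.items():
        effect = condition_effects.get(condition, 0.0)
        log2_ratio = rng.normal(
            baseline_log2_ratio + effect, noise_sd, size=events_per_well
        )
        ratio = 2.0 ** log2_ratio
        marker = marker_levels.get(condition, 0.0)
        for r in ratio:
            rows.append((well, condition, green_level, green_level * r, marker))
    return pd.DataFrame(
        rows, columns=["well", "condition", "green", "red", "marker"]
    )
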
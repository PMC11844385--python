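"""Protospacer extraction and read counting for pooled screen samples.

Screen amplicons contain the sgRNA variable region flanked by constant
vector sequence. The counting stage crops each read down to the candidate
protospacer (either a fixed slice or the window following a constant
anchor), maps it against the library — exactly, or optionally tolerating
one substitution with a unique-best-match requirement — and tallies
per-sample counts. Reads that fail extraction, match nothing, or match
ambiguously are unmapped; the per-sample conservation ``mapped + unmapped
== total`` always holds.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .library import SgRNALibrary

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(frozen=True)
class ExtractionSpec:
    """How to crop reads down to candidate protospacers.

    mode="slice": take ``length`` bases starting at ``offset``.
    mode="anchor": take the ``length``-base window immediately after the
    first exact occurrence of ``anchor`` (a constant vector sequence).
    ``max_mismatches`` (0 or 1) controls library matching tolerance;
    ``scan_revcomp`` additionally tries the reverse complement of reads
    whose forward extraction fails to map.
    """

    mode: str = "slice"
    offset: int = 0
    length: int = 20
    anchor: str | None = None
    max_mismatches: int = 0
    scan_revcomp: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("slice", "anchor"):
            raise ValueError(f"unknown extraction mode {self.mode!r}")
        if self.offset < 0 or self.length < 1:
            raise ValueError("offset must be >= 0 and length >= 1")
        if self.mode == "anchor" and not self.anchor:
            raise ValueError("anchor mode requires a non-empty anchor sequence")
        if self.max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")


@dataclass
class BinCountMatrix:
    """Nonnegative integer counts, library elements x screen samples.

    ``counts`` is indexed by element id in library order with one column
    per sample; ``stats`` holds per-sample mapping totals satisfying
    ``mapped + unmapped == total`` and ``mapped == column sum``.
    """

    counts: pd.DataFrame
    stats: dict[str, dict[str, int]]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        for sample in self.counts.columns:
            s = self.stats.get(sample)
            if s is None:
                continue
            col = int(self.counts[sample].sum())
            if s["mapped"] != col or s["mapped"] + s["unmapped"] != s["total"]:
                raise ValueError(
                    f"sample {sample!r}: mapping stats inconsistent with counts"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def element_ids(self) -> list[str]:
        return list(self.counts.index)

    def write(self, counts_path: str | Path, stats_path: str | Path | None = None) -> None:
        counts_path = Path(counts_path)
        self.counts.to_csv(counts_path, sep="\t", index_label="id")
        if stats_path is None:
            stats_path = counts_path.with_suffix(counts_path.suffix + ".stats.json")
        Path(stats_path).write_text(json.dumps(self.stats, indent=2, sort_keys=True))

    @classmethod
    def read(cls, counts_path: str | Path, stats_path: str | Path | None = None) -> "BinCountMatrix":
        counts_path = Path(counts_path)
        counts = pd.read_csv(counts_path, sep="\t", index_col="id")
        if stats_path is None:
            candidate = counts_path.with_suffix(counts_path.suffix + ".stats.json")
            stats_path = candidate if candidate.exists() else None
        if stats_path is not None:
            stats = json.loads(Path(stats_path).read_text())
        else:
            stats = {
                s: {"total": int(counts[s].sum()),
                    "mapped": int(counts[s].sum()),
                    "unmapped": 0}
                for s in counts.columns
            }
        return cls(counts=counts, stats=stats)


def extract_protospacer(read_sequence: str, spec: ExtractionSpec) -> str | None:
    """Crop one read to its candidate protospacer, or None.

    Slice mode returns the window when fully in bounds. Anchor mode
    returns the window after the first exact anchor occurrence. ``None``
    signals a failed extraction — a value, not an error.
    """
    if not read_sequence:
        raise ValueError("empty read sequence")
    seq = read_sequence.upper()
    if spec.mode == "slice":
        start = spec.offset
    else:
        hit = seq.find(spec.anchor.upper())  # first occurrence wins
        if hit < 0:
            return None
        start = hit + len(spec.anchor)
    end = start + spec.length
    if end > len(seq):
        return None
    return seq[start:end]


def _hamming1_neighbors(seq: str) -> Iterator[str]:
    for i, base in enumerate(seq):
        for alt in _BASES:
            if alt != base:
                yield seq[:i] + alt + seq[i + 1 :]


class _LibraryMatcher:
    """Exact and unique Hamming-1 protospacer lookup against a library."""

    def __init__(self, lib: SgRNALibrary, max_mismatches: int):
        self.exact = {e.protospacer: i for i, e in enumerate(lib.elements)}
        self.max_mismatches = max_mismatches

    def match(self, seq: str) -> int | None:
        idx = self.exact.get(seq)
        if idx is not None:
            return idx
        if self.max_mismatches == 0:
            return None
        hits = {
            self.exact[n] for n in _hamming1_neighbors(seq) if n in self.exact
        }
        if len(hits) == 1:
            return hits.pop()
        return None  # no hit, or ambiguous between >=2 elements


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(path: Path) -> Iterator[str]:
    """Yield read sequences; errors name the file and record index."""
    with _open_text(path) as handle:
        record = 0
        while True:
            header = handle.readline()
            if not header:
                return
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            qual = handle.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(
                    f"{path}: ill-formed FASTQ record at index {record}"
                )
            yield seq
            record += 1


def count_reads(
    sample_fastqs: Mapping[str, str | Path | Sequence[str | Path]],
    lib: SgRNALibrary,
    spec: ExtractionSpec,
) -> BinCountMatrix:
    """Count library-mapped reads per sample from FASTQ files.

    ``sample_fastqs`` maps sample name to one path or a sequence of paths
    (plain or gzipped FASTQ). Matching is deterministic and independent of
    read order; ambiguous 1-mismatch matches are discarded as unmapped.
    """
    matcher = _LibraryMatcher(lib, spec.max_mismatches)
    n_elem = lib.n_elements
    counts: dict[str, np.ndarray] = {}
    stats: dict[str, dict[str, int]] = {}
    for sample, paths in sample_fastqs.items():
        if isinstance(paths, (str, Path)):
            paths = [paths]
        vec = np.zeros(n_elem, dtype=np.int64)
        total = 0
        for p in paths:
            p = Path(p)
            if not p.exists():
                raise FileNotFoundError(p)
            for seq in _iter_fastq(p):
                total += 1
                ps = extract_protospacer(seq, spec) if seq else None
                idx = matcher.match(ps) if ps is not None else None
                if idx is None and spec.scan_revcomp:
                    rc = reverse_complement(seq)
                    ps = extract_protospacer(rc, spec)
                    idx = matcher.match(ps) if ps is not None else None
                if idx is not None:
                    vec[idx] += 1
        counts[sample] = vec
        mapped = int(vec.sum())
        stats[sample] = {
            "total": total,
            "mapped": mapped,
            "unmapped": total - mapped,
        }
        logger.info(
            "sample %s: %d/%d reads mapped (%.1f%%)",
            sample, mapped, total, 100 * mapped / total if total else 0.0,
        )
    frame = pd.DataFrame(counts, index=pd.Index(lib.ids, name="id"))
    return BinCountMatrix(counts=frame, stats=stats)


def rank_counts_qc(counts: BinCountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Rank-order log10 counts per sample, for library-representation QC.

    Returns a long table (sample, rank, id, count, log10_count) with
    elements sorted by descending count within each sample; the curve is
    non-increasing by construction. A flat curve indicates even library
    representation; a cliff indicates dropout.
    """
    rows = []
    for sample in counts.samples:
        col = counts.counts[sample].sort_values(ascending=False, kind="mergesort")
        with np.errstate(divide="ignore"):  # pseudocount 0 + zero counts -> -inf
            log10 = np.log10(col.values + pseudocount)
        rows.append(
            pd.DataFrame(
                {
                    "sample": sample,
                    "rank": np.arange(1, len(col) + 1),
                    "id": col.index,
                    "count": col.values,
                    "log10_count": log10,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
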
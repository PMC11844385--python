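"""sgRNA library representation, validation, and I/O.

A pooled CRISPRi library is an ordered catalog of guide constructs. Each
element carries a unique id, the variable protospacer sequence that is
counted in screen reads, and its target gene; non-targeting controls (NTCs)
are flagged and carry a sentinel in place of a gene symbol. Downstream
modules rely on the invariants enforced here: unique ids, unique
protospacers (counting would otherwise be ambiguous), and a consistent NTC
flag.
"""

from __future__ import annotations

import collections
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_NTC_SENTINEL = "NTC"
_VALID_BASES = frozenset("ACGT")
_MIN_PROTOSPACER_LEN = 18
_MAX_PROTOSPACER_LEN = 21


class LibraryError(ValueError):
    """Raised when a library violates a structural invariant."""


@dataclass(frozen=True)
class SgRNAElement:
    """One guide construct: id, protospacer, target gene, NTC flag."""

    id: str
    protospacer: str
    target_gene: str
    is_ntc: bool = False

    def __post_init__(self) -> None:
        ps = self.protospacer
        if ps != ps.upper() or not set(ps) <= _VALID_BASES:
            raise LibraryError(
                f"element {self.id!r}: protospacer {ps!r} is not an "
                "uppercase A/C/G/T string"
            )
        if not _MIN_PROTOSPACER_LEN <= len(ps) <= _MAX_PROTOSPACER_LEN:
            raise LibraryError(
                f"element {self.id!r}: protospacer length {len(ps)} outside "
                f"[{_MIN_PROTOSPACER_LEN}, {_MAX_PROTOSPACER_LEN}]"
            )


@dataclass(frozen=True)
class SgRNALibrary:
    """An ordered, validated collection of :class:`SgRNAElement`.

    Duplicate ids or protospacers are rejected at construction. The NTC
    sentinel ties the ``is_ntc`` flag to the ``target_gene`` field:
    ``is_ntc`` is true exactly when ``target_gene == ntc_sentinel``.
    """

    elements: tuple[SgRNAElement, ...]
    name: str = "library"
    ntc_sentinel: str = DEFAULT_NTC_SENTINEL
    metadata: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        self._check_unique("id", [e.id for e in self.elements])
        self._check_unique("protospacer", [e.protospacer for e in self.elements])
        for e in self.elements:
            if e.is_ntc != (e.target_gene == self.ntc_sentinel):
                raise LibraryError(
                    f"element {e.id!r}: is_ntc={e.is_ntc} inconsistent with "
                    f"target_gene={e.target_gene!r} "
                    f"(sentinel {self.ntc_sentinel!r})"
                )

    def _check_unique(self, what: str, values: Sequence[str]) -> None:
        seen: dict[str, list[str]] = collections.defaultdict(list)
        for e, v in zip(self.elements, values):
            seen[v].append(e.id)
        dups = {v: ids for v, ids in seen.items() if len(ids) > 1}
        if dups:
            detail = "; ".join(
                f"{what} {v!r} shared by {ids}" for v, ids in sorted(dups.items())
            )
            raise LibraryError(f"duplicate {what}s in library {self.name!r}: {detail}")

    # -- derived counts -------------------------------------------------
    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_ntc(self) -> int:
        return sum(e.is_ntc for e in self.elements)

    @property
    def n_genes(self) -> int:
        """Number of distinct targeted genes (NTCs excluded)."""
        return len({e.target_gene for e in self.elements if not e.is_ntc})

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.elements]

    @property
    def ntc_elements(self) -> list[SgRNAElement]:
        return [e for e in self.elements if e.is_ntc]

    @property
    def targeting_elements(self) -> list[SgRNAElement]:
        return [e for e in self.elements if not e.is_ntc]

    def elements_by_gene(self) -> dict[str, list[SgRNAElement]]:
        out: dict[str, list[SgRNAElement]] = collections.defaultdict(list)
        for e in self.targeting_elements:
            out[e.target_gene].append(e)
        return dict(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [e.id for e in self.elements],
                "protospacer": [e.protospacer for e in self.elements],
                "gene": [e.target_gene for e in self.elements],
            }
        )


def _sep_for(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gz"):
        name = name[: -len(".gz")]
    return "," if name.endswith(".csv") else "\t"


def read_library(
    path: str | Path,
    ntc_sentinel: str = DEFAULT_NTC_SENTINEL,
    name: str | None = None,
) -> SgRNALibrary:
    """Load a library from a TSV/CSV table (gzip transparent).

    The table must have ``id``, ``protospacer`` and ``gene`` columns.
    Protospacers are upper-cased before validation. Duplicate ids or
    protospacers and non-ACGT sequences raise :class:`LibraryError` naming
    the offending elements.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    missing = {"id", "protospacer", "gene"} - set(table.columns)
    if missing:
        raise LibraryError(f"{path}: missing required columns {sorted(missing)}")
    elements = [
        SgRNAElement(
            id=str(row.id),
            protospacer=str(row.protospacer).strip().upper(),
            target_gene=str(row.gene),
            is_ntc=(str(row.gene) == ntc_sentinel),
        )
        for row in table.itertuples(index=False)
    ]
    lib = SgRNALibrary(
        elements=tuple(elements),
        name=name if name is not None else path.stem,
        ntc_sentinel=ntc_sentinel,
    )
    logger.info(
        "loaded library %r: %d elements, %d genes, %d NTCs",
        lib.name, lib.n_elements, lib.n_genes, lib.n_ntc,
    )
    return lib


def write_library(lib: SgRNALibrary, path: str | Path) -> None:
    """Write a library to TSV/CSV (gzip by suffix); inverse of read_library."""
    path = Path(path)
    lib.to_frame().to_csv(path, sep=_sep_for(path), index=False)


def library_summary(lib: SgRNALibrary) -> dict:
    """Counts plus a guides-per-gene histogram.

    The histogram maps number-of-guides to number-of-genes with exactly
    that many guides; its weighted sum equals the number of targeting
    elements.
    """
    per_gene = collections.Counter(
        e.target_gene for e in lib.elements if not e.is_ntc
    )
    hist = collections.Counter(per_gene.values())
    return {
        "name": lib.name,
        "n_elements": lib.n_elements,
        "n_genes": lib.n_genes,
        "n_ntc": lib.n_ntc,
        "guides_per_gene": dict(sorted(hist.items())),
    }


def build_cropseq_library(
    source: SgRNALibrary,
    phenotypes: pd.DataFrame,
    selected_genes: Sequence[str],
    guides_per_gene: int = 2,
    ntc_elements: Iterable[SgRNAElement] = (),
    name: str = "cropseq",
) -> SgRNALibrary:
    """Assemble a focused sub-library from top-performing screen guides.

    For each selected gene the guides are ranked by absolute sgRNA-level
    log2 fold change from the source screen (``phenotypes`` needs columns
    ``sgrna`` and ``lfc``), ties broken by id, and the top
    ``guides_per_gene`` taken. NTC elements are appended after all
    targeting elements. The ranking rule is recorded in the returned
    library's metadata.
    """
    if guides_per_gene < 1:
        raise ValueError("guides_per_gene must be >= 1")
    lfc_by_sgrna = dict(zip(phenotypes["sgrna"], phenotypes["lfc"]))
    by_gene = source.elements_by_gene()
    chosen: list[SgRNAElement] = []
    for gene in selected_genes:
        candidates = [
            e for e in by_gene.get(gene, []) if e.id in lfc_by_sgrna
        ]
        if len(candidates) < guides_per_gene:
            raise LibraryError(
                f"gene {gene!r} has only {len(candidates)} ranked guides; "
                f"{guides_per_gene} required"
            )
        ranked = sorted(
            candidates, key=lambda e: (-abs(lfc_by_sgrna[e.id]), e.id)
        )
        chosen.extend(ranked[:guides_per_gene])
    chosen.extend(ntc_elements)
    return SgRNALibrary(
        elements=tuple(chosen),
        name=name,
        ntc_sentinel=source.ntc_sentinel,
        metadata={
            "ranking": "abs(sgRNA log2 fold change), descending; ties by id",
            "guides_per_gene": guides_per_gene,
            "source": source.name,
        },
    )
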
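"""Guide library data model, synthetic library designs, and table I/O.

A library is an ordered collection of guides, each targeting a gene (or a
non-targeting control, gene symbol ``NTC``) through a fixed-length
protospacer. Everything downstream — counting, normalization, both hit
callers — references guides by the identifiers defined here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

CONTROL_GENE = "NTC"
_BASES = np.array(list("ACGT"))
_LIBRARY_COLUMNS = ("guide_id", "gene", "protospacer", "is_control")


class LibraryError(ValueError):
    """Raised when a library violates its invariants."""


@dataclass(frozen=True)
class Guide:
    """A single sgRNA record.

    Attributes
    ----------
    guide_id : str
        Unique identifier within the library.
    gene : str
        Target gene symbol, or ``"NTC"`` for non-targeting controls.
    protospacer : str
        DNA sequence over {A, C, G, T}; length fixed per library.
    is_control : bool
        True iff the guide is a non-targeting control.
    """

    guide_id: str
    gene: str
    protospacer: str
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.is_control != (self.gene == CONTROL_GENE):
            raise LibraryError(
                f"guide {self.guide_id!r}: is_control={self.is_control} "
                f"inconsistent with gene={self.gene!r} (controls must use gene={CONTROL_GENE!r})"
            )
        bad = set(self.protospacer) - set("ACGT")
        if bad:
            raise LibraryError(
                f"guide {self.guide_id!r}: protospacer contains non-ACGT characters {sorted(bad)}"
            )


@dataclass
class GuideLibrary:
    """An ordered, validated collection of :class:`Guide` records."""

    guides: list[Guide]
    protospacer_length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.guides and self.protospacer_length == 0:
            self.protospacer_length = len(self.guides[0].protospacer)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        seen_ids: set[str] = set()
        seen_spacers: set[str] = set()
        for g in self.guides:
            if g.guide_id in seen_ids:
                raise LibraryError(f"duplicate guide_id {g.guide_id!r}")
            seen_ids.add(g.guide_id)
            if len(g.protospacer) != self.protospacer_length:
                raise LibraryError(
                    f"guide {g.guide_id!r}: protospacer length {len(g.protospacer)} "
                    f"!= library length {self.protospacer_length}"
                )
            if g.protospacer in seen_spacers:
                raise LibraryError(
                    f"duplicate protospacer {g.protospacer!r} (guide {g.guide_id!r})"
                )
            seen_spacers.add(g.protospacer)

    # -- derived counts -------------------------------------------------
    @property
    def n_total(self) -> int:
        return len(self.guides)

    @property
    def n_control(self) -> int:
        return sum(g.is_control for g in self.guides)

    @property
    def n_targeting(self) -> int:
        return self.n_total - self.n_control

    @property
    def n_genes(self) -> int:
        return len({g.gene for g in self.guides if not g.is_control})

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides]

    @property
    def genes(self) -> dict[str, str]:
        """Mapping guide_id -> gene symbol."""
        return {g.guide_id: g.gene for g in self.guides}

    def __len__(self) -> int:
        return self.n_total

    def __iter__(self) -> Iterator[Guide]:
        return iter(self.guides)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GuideLibrary):
            return NotImplemented
        # protospacer_length is derived from the guides whenever any exist
        if self.guides or other.guides:
            if self.protospacer_length != other.protospacer_length:
                return False
        return self.guides == other.guides

    def canonical_order(self) -> "GuideLibrary":
        """Targeting guides sorted by (gene, guide_id), then controls by guide_id."""
        targeting = sorted(
            (g for g in self.guides if not g.is_control),
            key=lambda g: (g.gene, g.guide_id),
        )
        controls = sorted(
            (g for g in self.guides if g.is_control), key=lambda g: g.guide_id
        )
        return GuideLibrary(targeting + controls, self.protospacer_length)

    def spacer_index(self) -> dict[str, str]:
        """Protospacer -> guide_id lookup for exact-match counting."""
        return {g.protospacer: g.guide_id for g in self.guides}


def _random_spacers(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Draw n distinct random DNA strings of the given length."""
    if n == 0:
        return []
    if 4.0**length < n:
        raise LibraryError(
            f"cannot draw {n} distinct protospacers of length {length} (4^{length} < {n})"
        )
    spacers: list[str] = []
    seen: set[str] = set()
    while len(spacers) < n:
        batch = rng.integers(0, 4, size=(n - len(spacers) + 8, length))
        for row in batch:
            s = "".join(_BASES[row])
            if s not in seen:
                seen.add(s)
                spacers.append(s)
                if len(spacers) == n:
                    break
    return spacers


def build_synthetic_library(
    n_genes: int,
    guides_per_gene: int,
    n_controls: int,
    protospacer_length: int = 20,
    seed: int = 0,
) -> GuideLibrary:
    """Generate a synthetic library: ``n_genes`` x ``guides_per_gene`` targeting
    guides named ``<geneK>_gJ`` plus ``n_controls`` controls named ``NTC_J``,
    with distinct seeded random protospacers.

    The default screen design (2195 genes x 5 guides + 250 controls = 11,225
    guides) is available via :func:`default_library`.
    """
    if min(n_genes, guides_per_gene, n_controls) < 0:
        raise LibraryError("counts must be non-negative")
    if protospacer_length < 8:
        raise LibraryError("protospacer_length must be >= 8")
    n_total = n_genes * guides_per_gene + n_controls
    rng = np.random.default_rng(seed)
    spacers = _random_spacers(n_total, protospacer_length, rng)
    guides: list[Guide] = []
    width = len(str(max(n_genes, 1)))
    i = 0
    for k in range(1, n_genes + 1):
        gene = f"gene{k:0{width}d}"
        for j in range(1, guides_per_gene + 1):
            guides.append(Guide(f"{gene}_g{j}", gene, spacers[i]))
            i += 1
    for j in range(1, n_controls + 1):
        guides.append(Guide(f"NTC_{j}", CONTROL_GENE, spacers[i], is_control=True))
        i += 1
    return GuideLibrary(guides, protospacer_length)


def default_library(seed: int = 0) -> GuideLibrary:
    """The default screen design: 2195 genes x 5 guides + 250 NTC = 11,225."""
    return build_synthetic_library(2195, 5, 250, protospacer_length=20, seed=seed)


_TRUE = {"1", "true", "True", "TRUE"}
_FALSE = {"0", "false", "False", "FALSE"}


def read_library(path: str | Path) -> GuideLibrary:
    """Read a guide library table (CSV or TSV, auto-detected).

    Required header: ``guide_id,gene,protospacer,is_control`` with
    ``is_control`` in {0, 1, true, false}. Protospacers are upper-cased on
    read so that exact-match counting is case-insensitive.
    """
    path = Path(path)
    with open(path, "rt", encoding="utf-8") as fh:
        return _parse_library(fh, str(path))


def _parse_library(fh: io.TextIOBase, source: str) -> GuideLibrary:
    header_line = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header_line else ","
    header = tuple(header_line.split(sep))
    if header != _LIBRARY_COLUMNS:
        raise LibraryError(
            f"{source}: expected header {','.join(_LIBRARY_COLUMNS)!r}, got {header_line!r}"
        )
    guides: list[Guide] = []
    lengths: set[int] = set()
    for lineno, line in enumerate(fh, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split(sep)
        if len(parts) != 4:
            raise LibraryError(f"{source}:{lineno}: expected 4 fields, got {len(parts)}")
        guide_id, gene, spacer, flag = parts
        spacer = spacer.upper()
        if set(spacer) - set("ACGT"):
            raise LibraryError(f"{source}:{lineno}: non-ACGT protospacer {spacer!r}")
        if flag in _TRUE:
            is_control = True
        elif flag in _FALSE:
            is_control = False
        else:
            raise LibraryError(f"{source}:{lineno}: bad is_control value {flag!r}")
        lengths.add(len(spacer))
        guides.append(Guide(guide_id, gene, spacer, is_control))
    if len(lengths) > 1:
        raise LibraryError(f"{source}: inconsistent protospacer lengths {sorted(lengths)}")
    length = lengths.pop() if lengths else 0
    return GuideLibrary(guides, length)


def write_library(lib: GuideLibrary, path: str | Path, sep: str = ",") -> None:
    """Write a library table in canonical order (byte-stable)."""
    ordered = lib.canonical_order()
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(sep.join(_LIBRARY_COLUMNS) + "\n")
        for g in ordered.guides:
            fh.write(sep.join([g.guide_id, g.gene, g.protospacer, "1" if g.is_control else "0"]) + "\n")
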
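"""Signed gene sets: the packaged SenSkin set plus GMT I/O and overlap utilities.

A *signed* gene set splits its members into genes expected to go up and genes
expected to go down under the condition of interest (here: cellular senescence
in human skin). Standard GMT has no direction field, so a small dialect is
used on disk: a set named ``S`` is written as two lines ``S_UP`` and ``S_DN``;
a lone line without suffix is an unsigned (all-up) set.

Gene symbols are matched case-insensitively and whitespace-stripped throughout;
no alias or HGNC resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

_DATA_FILE = "senskin_genes.tsv"


class GmtParseError(ValueError):
    """Raised for a malformed GMT line; carries the 1-based line number."""


@dataclass(frozen=True)
class SignedGeneSet:
    """A named gene set split into up- and down-regulated members.

    Invariants (checked on construction): symbols unique within each list,
    the two lists disjoint (case-insensitive), and the union non-empty.
    """

    name: str
    up_genes: tuple[str, ...] = ()
    down_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        up = tuple(g.strip() for g in self.up_genes)
        dn = tuple(g.strip() for g in self.down_genes)
        object.__setattr__(self, "up_genes", up)
        object.__setattr__(self, "down_genes", dn)
        up_l = [g.casefold() for g in up]
        dn_l = [g.casefold() for g in dn]
        if len(set(up_l)) != len(up_l):
            raise ValueError(f"{self.name}: duplicate symbols in up_genes")
        if len(set(dn_l)) != len(dn_l):
            raise ValueError(f"{self.name}: duplicate symbols in down_genes")
        if set(up_l) & set(dn_l):
            raise ValueError(f"{self.name}: up_genes and down_genes overlap")
        if not up and not dn:
            raise ValueError(f"{self.name}: gene set is empty")

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.up_genes + self.down_genes

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


@dataclass(frozen=True)
class CoverageReport:
    """How much of a gene set a given expression universe covers."""

    n_total: int
    n_present: int
    missing_genes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        assert self.n_present + len(self.missing_genes) == self.n_total


def builtin_senskin() -> SignedGeneSet:
    """Return the packaged skin-senescence signature: 164 up genes + LMNB1 down.

    The set is read from a version-controlled data file transcribed from the
    published table; a checksum test guards against transcription drift.
    """
    text = resources.files("senskin").joinpath("data", _DATA_FILE).read_text()
    up, down = [], []
    for line in text.splitlines()[1:]:
        gene, direction = line.split("\t")
        (up if direction == "up" else down).append(gene)
    return SignedGeneSet(name="SenSkin", up_genes=tuple(up), down_genes=tuple(down))


def _dedup(genes: Iterable[str], where: str) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    dropped = 0
    for g in genes:
        g = g.strip()
        if not g:
            continue
        key = g.casefold()
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        out.append(g)
    if dropped:
        logger.warning("%s: dropped %d duplicate symbol(s)", where, dropped)
    return out


def read_signed_gmt(path: str | Path) -> list[SignedGeneSet]:
    """Read signed gene sets from a GMT file using the ``_UP``/``_DN`` dialect.

    ``<NAME>_UP`` / ``<NAME>_DN`` line pairs merge into one :class:`SignedGeneSet`;
    a line without either suffix yields a set with empty ``down_genes``.
    Duplicate symbols within a line are dropped with a warning.
    """
    path = Path(path)
    ordered: list[str] = []
    ups: dict[str, list[str]] = {}
    downs: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected at least 3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name, _desc, *genes = fields
            genes = _dedup(genes, f"{path}:{lineno}")
            if name.endswith("_UP"):
                base, bucket = name[:-3], ups
            elif name.endswith("_DN"):
                base, bucket = name[:-3], downs
            else:
                base, bucket = name, ups
            if base not in ups and base not in downs:
                ordered.append(base)
            bucket.setdefault(base, []).extend(genes)
    return [
        SignedGeneSet(
            name=base,
            up_genes=tuple(ups.get(base, [])),
            down_genes=tuple(downs.get(base, [])),
        )
        for base in ordered
    ]


def write_signed_gmt(sets: Sequence[SignedGeneSet], path: str | Path) -> Path:
    """Write signed gene sets in the ``_UP``/``_DN`` GMT dialect.

    Round-trips exactly through :func:`read_signed_gmt`. A set with an empty
    down list is written as a single ``_UP`` line.
    """
    path = Path(path)
    with path.open("w") as fh:
        for s in sets:
            if s.up_genes:
                fh.write("\t".join([f"{s.name}_UP", "na", *s.up_genes]) + "\n")
            if s.down_genes:
                fh.write("\t".join([f"{s.name}_DN", "na", *s.down_genes]) + "\n")
    return path


def overlap(a: SignedGeneSet, b: SignedGeneSet) -> tuple[int, list[str]]:
    """Case-insensitive intersection of the unions (up + down) of two sets.

    Returns ``(count, shared)`` with symbols spelled as in ``a`` and ordered
    as in ``a``.
    """
    b_keys = {g.casefold() for g in b.all_genes}
    shared = [g for g in a.all_genes if g.casefold() in b_keys]
    return len(shared), shared


def coverage(gene_set: SignedGeneSet, universe: Iterable[str]) -> CoverageReport:
    """Report which set genes appear in a measurement universe (case-insensitive)."""
    uni = {str(g).strip().casefold() for g in universe}
    missing = tuple(g for g in gene_set.all_genes if g.casefold() not in uni)
    total = len(gene_set)
    return CoverageReport(
        n_total=total, n_present=total - len(missing), missing_genes=missing
    )
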
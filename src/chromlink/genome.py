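"""Chromosome name/length bookkeeping.

A :class:`Genome` is an ordered mapping from chromosome name to length in
bp.  The file order defines the canonical sort order for every interval
container in the package, so reports are reproducible run to run.
"""

from __future__ import annotations

from collections.abc import Mapping
from pathlib import Path
from typing import Iterator


class Genome(Mapping[str, int]):
    """Ordered chromosome name -> length (bp) map."""

    def __init__(self, lengths: Mapping[str, int] | list[tuple[str, int]]):
        items = list(lengths.items()) if isinstance(lengths, Mapping) else list(lengths)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in items:
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._lengths: dict[str, int] = {n: int(v) for n, v in items}
        self._rank: dict[str, int] = {n: i for i, n in enumerate(self._lengths)}

    # Mapping interface -------------------------------------------------
    def __getitem__(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    # ------------------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    def rank(self, chrom: str) -> int:
        """Sort rank of *chrom* (file order)."""
        return self._rank[chrom]

    def __contains__(self, chrom: object) -> bool:
        return chrom in self._lengths

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Genome({len(self)} chromosomes, {sum(self._lengths.values()):,} bp)"

    # I/O ---------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path: str | Path) -> "Genome":
        """Read a two-column (chrom, length) tab-separated genome file."""
        items: list[tuple[str, int]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
                try:
                    items.append((fields[0], int(fields[1])))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
        return cls(items)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self._lengths.items():
                fh.write(f"{name}\t{length}\n")


def mouse_like_order(genome: Genome) -> list[str]:
    """Chromosome ordering used by the study's heat-maps.

    For a mouse-style genome (chr1..chr19 plus chrX) the rows run
    chr1..chr9, chrX, chr10..chr19.  Any other naming falls back to the
    genome-file order.
    """
    names = genome.names
    wanted = [f"chr{i}" for i in range(1, 10)] + ["chrX"] + [f"chr{i}" for i in range(10, 20)]
    if set(names) == set(wanted):
        return wanted
    return names
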
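"""Genome model: an ordered set of named chromosomes with lengths."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes, each a ``(name, length_bp)`` pair.

    Coordinates throughout the package are 1-based inclusive in memory;
    BED-style files on disk are 0-based half-open.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def length_of(self, name: str) -> int:
        for chrom, length in self.chromosomes:
            if chrom == name:
                return length
        raise KeyError(name)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


def default_genome(n_chromosomes: int = 12, chrom_length: int = 1_000_000) -> GenomeModel:
    """Desk-scale stand-in for a 12-chromosome plant genome."""
    return GenomeModel(
        tuple((f"chr{i + 1}", chrom_length) for i in range(n_chromosomes))
    )
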
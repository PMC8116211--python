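"""Genome assembly description: ordered chromosomes with lengths."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomeAssembly:
    """An ordered set of named chromosomes with lengths in bp.

    Parameters
    ----------
    name
        Assembly label, e.g. ``"dm6"``.
    chromosomes
        Ordered ``(name, length)`` tuples; names unique, lengths positive.
    """

    name: str
    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for c, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length {length}")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def length(self, chrom: str) -> int:
        try:
            return self.sizes[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in assembly {self.name!r}") from None


def toy_assembly(n_chrom: int = 2, length: int = 10_000_000, prefix: str = "chr") -> GenomeAssembly:
    """Small synthetic assembly used by generators and tests."""
    return GenomeAssembly(
        name=f"toy{n_chrom}",
        chromosomes=tuple((f"{prefix}{i + 1}", length) for i in range(n_chrom)),
    )
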
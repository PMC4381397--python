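"""Genome layout: named contigs with lengths and control-contig flags.

A layout carries the ordinary chromosomes plus, optionally, an unmethylated
spike-in contig (lambda phage in the study design this package emulates) used
to estimate bisulphite conversion, and a transgene contig treated as one more
chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Contig:
    name: str
    length: int
    is_spike_in: bool = False
    is_transgene: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.name!r} has non-positive length {self.length}")


@dataclass
class GenomeLayout:
    """Ordered collection of contigs; at most one spike-in."""

    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        if sum(c.is_spike_in for c in self.contigs) > 1:
            raise ValueError("at most one spike-in contig allowed")
        self._by_name = {c.name: c for c in self.contigs}

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Contig:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.contigs]

    @property
    def spike_in(self) -> Contig | None:
        for c in self.contigs:
            if c.is_spike_in:
                return c
        return None

    def chrom_length(self, name: str) -> int:
        return self._by_name[name].length

    def main_contigs(self) -> list[Contig]:
        """Contigs that are neither spike-in nor transgene."""
        return [c for c in self.contigs if not (c.is_spike_in or c.is_transgene)]

    def total_length(self, include_controls: bool = False) -> int:
        cs = self.contigs if include_controls else self.main_contigs()
        return sum(c.length for c in cs)
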
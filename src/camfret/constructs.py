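"""Biosensor construct catalog.

A construct is a donor–acceptor fluorescent-protein pair flanking a candidate
CaM-binding linker from one of the receptor's four submembrane domains
(SMD1–3 = intracellular loops, SMD4 = C-terminal tail).  Residue coordinates
are 1-based inclusive in the receptor's own numbering.  Linker amino-acid
sequences are not carried here; constructs are ranges plus optional glycine
flanks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ConfigurationError, OutOfRangeError


@dataclass(frozen=True)
class BiosensorConstruct:
    """A named biosensor linker: residue range plus glycine flanks."""

    linker_start: int
    linker_end: int
    smd: int
    n_flank_gly: int = 0
    c_flank_gly: int = 0
    name: str = ""

    def __post_init__(self):
        if self.linker_start > self.linker_end:
            raise ConfigurationError("linker_start must be <= linker_end")
        if self.n_flank_gly < 0 or self.c_flank_gly < 0:
            raise ConfigurationError("glycine flank counts must be >= 0")
        if not self.name:
            object.__setattr__(self, "name", self.default_name())

    def default_name(self) -> str:
        """Naming convention: BSGPER{GGG}{start}-{end}{GGG}."""
        return (
            "BSGPER"
            + "G" * self.n_flank_gly
            + f"{self.linker_start}-{self.linker_end}"
            + "G" * self.c_flank_gly
        )

    @property
    def linker_length(self) -> int:
        return self.linker_end - self.linker_start + 1


def enumerate_constructs(base: BiosensorConstruct,
                         truncation_ends: Sequence[int] = (),
                         gly_flank_options: Sequence[int] = (0,),
                         ) -> list[BiosensorConstruct]:
    """Expand a base linker into truncated / glycine-flanked variants.

    Each truncation end (which must lie within the base range) combined with
    each flank count yields one uniquely named construct.  An empty truncation
    list returns the base (with the requested flank options).
    """
    ends = list(truncation_ends) or [base.linker_end]
    for end in ends:
        if not base.linker_start <= end <= base.linker_end:
            raise OutOfRangeError(
                f"truncation end {end} outside base range "
                f"{base.linker_start}-{base.linker_end}"
            )
    out = []
    seen = set()
    for end in ends:
        for gly in gly_flank_options:
            c = BiosensorConstruct(
                linker_start=base.linker_start, linker_end=end, smd=base.smd,
                n_flank_gly=gly, c_flank_gly=gly,
            )
            if c.name not in seen:
                seen.add(c.name)
                out.append(c)
    return out


#: The four full submembrane domains used as initial screening linkers.
SMD_BASES = (
    BiosensorConstruct(83, 93, smd=1),
    BiosensorConstruct(150, 175, smd=2),
    BiosensorConstruct(242, 259, smd=3),
    BiosensorConstruct(330, 375, smd=4),
)
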
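"""Quadripartite plastome model.

A chloroplast genome is circular and canonically laid out as four regions:
the large single-copy region (LSC), inverted repeat b (IRb), the small
single-copy region (SSC) and inverted repeat a (IRa), where IRa is the
reverse complement of IRb.  We linearize at LSC base 1, giving the region
order LSC-IRb-SSC-IRa.  All coordinates are 1-based inclusive (GenBank
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Region:
    """1-based inclusive interval with a label."""

    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class QuadripartiteGenome:
    """Circular plastome linearized as LSC + IRb + SSC + IRa.

    Only the three distinct region sequences are stored; IRb is ``ir`` and
    IRa is its reverse complement, so the inverted-repeat identity holds by
    construction.
    """

    lsc: str
    ssc: str
    ir: str
    id: str = "genome"

    def __post_init__(self) -> None:
        for name, seq in (("lsc", self.lsc), ("ssc", self.ssc), ("ir", self.ir)):
            if not seq:
                raise ValueError(f"{name} must be non-empty")
            if set(seq) - set(DNA_ALPHABET):
                raise ValueError(f"{name} contains non-ACGT characters")

    @property
    def irb(self) -> str:
        return self.ir

    @property
    def ira(self) -> str:
        return revcomp(self.ir)

    @property
    def sequence(self) -> str:
        return self.lsc + self.irb + self.ssc + self.ira

    def __len__(self) -> int:
        return len(self.lsc) + len(self.ssc) + 2 * len(self.ir)

    @property
    def regions(self) -> dict[str, Region]:
        l, i, s = len(self.lsc), len(self.ir), len(self.ssc)
        return {
            "LSC": Region("LSC", 1, l),
            "IRb": Region("IRb", l + 1, l + i),
            "SSC": Region("SSC", l + i + 1, l + i + s),
            "IRa": Region("IRa", l + i + s + 1, l + 2 * i + s),
        }

    @property
    def junctions(self) -> dict[str, tuple[int, int]]:
        """Junction boundaries as (last base of left region, first of right).

        The IRa/LSC junction wraps the circular origin, hence (L, 1).
        """
        r = self.regions
        return {
            "J(LSC,IRb)": (r["LSC"].end, r["IRb"].start),
            "J(IRb,SSC)": (r["IRb"].end, r["SSC"].start),
            "J(SSC,IRa)": (r["SSC"].end, r["IRa"].start),
            "J(IRa,LSC)": (r["IRa"].end, 1),
        }


@dataclass
class RegionAnnotation:
    """Quadripartite annotation of a linear consensus sequence.

    Empty (``irb is None``) when no inverted repeat was detected.
    """

    irb: Region | None = None
    ira: Region | None = None
    lsc: Region | None = None
    ssc: Region | None = None
    junctions: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.irb is None

    def region_lengths(self) -> dict[str, int]:
        if self.empty:
            return {}
        return {
            "LSC": self.lsc.length if self.lsc else 0,
            "IRb": self.irb.length,
            "SSC": self.ssc.length if self.ssc else 0,
            "IRa": self.ira.length,
        }
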
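"""Leading/lagging-strand assignment on a circular genome.

Given a user-supplied OriC interval, the replication terminus is placed
half a genome away from the OriC midpoint (the half-genome rule); the two
replichores partition the chromosome, and within replichore 1 (OriC -> ter,
ascending coordinates modulo length) the top strand is the leading strand.
OriC inference itself is out of scope: the interval is an input.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CoordinateError
from .seq_core import Interval


@dataclass
class ReplicationContext:
    """Replichore geometry derived from an OriC interval."""

    genome_length: int
    oric: Interval
    oric_mid: int
    ter_position: int
    replichore1_len: int   # ceil(L/2): odd-length remainder goes here

    @classmethod
    def from_oric(cls, genome_length: int, oric_start: int, oric_end: int,
                  seq_id: str = "genome") -> "ReplicationContext":
        if not (0 <= oric_start < oric_end <= genome_length):
            raise CoordinateError("OriC interval outside the genome")
        oric = Interval(seq_id, oric_start, oric_end)
        mid = oric.midpoint
        half1 = (genome_length + 1) // 2
        return cls(genome_length=genome_length, oric=oric, oric_mid=mid,
                   ter_position=(mid + half1) % genome_length,
                   replichore1_len=half1)

    def replichore_of(self, pos: int) -> int:
        if not (0 <= pos < self.genome_length):
            raise CoordinateError(f"position {pos} outside [0, {self.genome_length})")
        rel = (pos - self.oric_mid) % self.genome_length
        return 1 if rel < self.replichore1_len else 2


@dataclass
class StrandCall:
    role: str            # "leading" | "lagging"
    replichore: int
    spans_ter: bool


def assign_strand(ctx: ReplicationContext, feature: Interval) -> StrandCall:
    """Leading/lagging call for a stranded feature by its midpoint.

    Replichore 1: '+' is leading; replichore 2: '-' is leading.  Features
    spanning the terminus are flagged.
    """
    if feature.end > ctx.genome_length or feature.start < 0:
        raise CoordinateError("feature outside the genome coordinate line")
    mid = (feature.start + feature.end) // 2
    repl = ctx.replichore_of(mid % ctx.genome_length)
    if repl == 1:
        role = "leading" if feature.strand == "+" else "lagging"
    else:
        role = "leading" if feature.strand == "-" else "lagging"
    spans_ter = feature.start <= ctx.ter_position < feature.end
    return StrandCall(role=role, replichore=repl, spans_ter=spans_ter)
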
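"""Duplex sequences: the three 13-mer lesion environments and their mismatches.

The Watson strand carries the lesion base X at the central position; the
Crick partner opposite X is free to be any base, so all 12 non-Watson-Crick
combinations (and the four canonical controls) can be planted.  Pairs are
addressed either by 0-based absolute index along the Watson strand or by the
relative coordinate used throughout reporting, with the lesion pair at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from .bases import COMPLEMENT

__all__ = ["DuplexSequence", "ENVIRONMENTS", "sequence_for"]

#: Watson-strand templates, 5'->3', X at the lesion position.
#: f1 and f2 are globally flexible sequence contexts; r is rigid.
ENVIRONMENTS = {
    "f1": "CCATACXATACGG",
    "f2": "CCAATTXAATTGG",
    "r": "CCCAGTXCTTTGG",
}


@dataclass(frozen=True)
class DuplexSequence:
    """An antiparallel duplex with at most one non-complementary pair.

    Both strands are stored 5'->3'.  ``crick[j]`` pairs with
    ``watson[n-1-j]``; ``mm_position`` is the 0-based Watson index of the
    lesion pair (which may in fact be canonical, for controls).
    """

    watson: str
    crick: str
    mm_position: int

    def __post_init__(self):
        if len(self.watson) != len(self.crick):
            raise ValueError("strands must have equal length")
        bad = [b for b in self.watson + self.crick if b not in "ACGT"]
        if bad:
            raise ValueError(f"non-ACGT bases: {bad}")
        if not 0 <= self.mm_position < len(self.watson):
            raise ValueError("mm_position out of range")
        for i in range(len(self.watson)):
            if i == self.mm_position:
                continue
            if self.crick_base(i) != COMPLEMENT[self.watson[i]]:
                raise ValueError(
                    f"pair {i} ({self.watson[i]}-{self.crick_base(i)}) is not "
                    "Watson-Crick and is not the declared lesion position"
                )

    def __len__(self) -> int:
        return len(self.watson)

    def crick_base(self, pair_index: int) -> str:
        """Crick base paired with Watson position ``pair_index``."""
        return self.crick[len(self) - 1 - pair_index]

    def pair(self, pair_index: int) -> tuple[str, str]:
        return self.watson[pair_index], self.crick_base(pair_index)

    @property
    def mismatch(self) -> tuple[str, str]:
        return self.pair(self.mm_position)

    @property
    def is_canonical(self) -> bool:
        w, c = self.mismatch
        return COMPLEMENT[w] == c

    def relative_position(self, pair_index: int) -> int:
        """Relative coordinate of a pair (lesion pair = 0)."""
        return pair_index - self.mm_position

    def absolute_position(self, relative: int) -> int:
        return relative + self.mm_position

    @classmethod
    def from_watson(cls, watson: str, mm_position: int,
                    crick_partner: str | None = None) -> "DuplexSequence":
        """Build the duplex complementary to ``watson`` except at the lesion."""
        partners = [COMPLEMENT[b] for b in watson]
        if crick_partner is not None:
            partners[mm_position] = crick_partner
        crick = "".join(reversed(partners))
        return cls(watson=watson, crick=crick, mm_position=mm_position)


def sequence_for(environment: str, watson_base: str,
                 crick_base: str) -> DuplexSequence:
    """The 13-mer duplex for one lesion environment and one X-opposite pair.

    ``environment`` is one of ``f1``, ``f2`` (flexible) or ``r`` (rigid);
    the central X of the template is replaced by ``watson_base`` and its
    Crick partner set to ``crick_base`` (a canonical partner gives a control
    duplex).
    """
    try:
        template = ENVIRONMENTS[environment]
    except KeyError:
        raise ValueError(
            f"unknown environment {environment!r}; expected one of "
            f"{sorted(ENVIRONMENTS)}"
        ) from None
    for b in (watson_base, crick_base):
        if b not in "ACGT":
            raise ValueError(f"invalid base {b!r}")
    pos = template.index("X")
    watson = template.replace("X", watson_base)
    return DuplexSequence.from_watson(watson, pos, crick_base)
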
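"""The 96-channel trinucleotide classification of single-base substitutions.

Every SNV, together with its immediate 5' and 3' reference neighbours, is
mapped to one of 96 channels: six pyrimidine-reference substitution types
(C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 4 x 4 flanking-base
combinations. Substitutions reported with a purine reference (G or A) are
first reflected onto the opposite strand by reverse complement, so the
mapping is total over the 192 stranded possibilities.

Channel order is substitution-major, then 5' base A,C,G,T, then 3' base
A,C,G,T — the de facto community convention, so that bundled reference
profiles align with external signature tables by index.
"""

from __future__ import annotations

from dataclasses import dataclass

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES: str = "ACGT"
PYRIMIDINES: frozenset[str] = frozenset("CT")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Transition substitutions in pyrimidine-reference notation. G>A and A>G
#: fold onto C>T and T>C respectively under strand reflection.
TRANSITIONS: frozenset[str] = frozenset({"C>T", "T>C"})

CHANNEL_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

_LABEL_TO_INDEX = {label: i for i, label in enumerate(CHANNEL_LABELS)}

#: Channels attributed to the platinum mutational process: C>A transversions
#: at CpCpA and CpCpG (the "CCR" context, R = purine), the footprint of
#: error-prone translesion bypass of cisplatin Pt-GpG intrastrand adducts.
PLATINUM_CHANNELS: tuple[str, str] = ("C[C>A]A", "C[C>A]G")


class AmbiguousBaseError(ValueError):
    """A base outside {A, C, G, T} (typically N) makes a record unmappable."""


@dataclass(frozen=True)
class Channel:
    """One of the 96 substitution-in-context classes."""

    index: int
    substitution: str
    five_prime: str
    three_prime: str

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.substitution}]{self.three_prime}"

    @classmethod
    def from_label(cls, label: str) -> "Channel":
        idx = _LABEL_TO_INDEX[label]
        return cls(idx, label[2:5], label[0], label[6])


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, context: str) -> Channel:
    """Map a stranded SNV to its pyrimidine-reference channel.

    Parameters
    ----------
    ref, alt : str
        Single reference and alternate bases; must differ.
    context : str
        Trinucleotide on the reference strand centred on the mutated base,
        so ``context[1] == ref``.

    Raises
    ------
    AmbiguousBaseError
        If any base is outside {A, C, G, T}.
    ValueError
        If the context is malformed or inconsistent with ``ref``.
    """
    if len(context) != 3:
        raise ValueError(f"context must be a trinucleotide, got {context!r}")
    for b in (ref, alt, *context):
        if b not in BASES:
            raise AmbiguousBaseError(f"unmappable base {b!r} in ({ref}>{alt}, {context})")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} != ref {ref!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ for an SNV")
    if ref not in PYRIMIDINES:
        ref, alt = complement(ref), complement(alt)
        context = reverse_complement(context)
    sub = f"{ref}>{alt}"
    index = (
        SUBSTITUTIONS.index(sub) * 16
        + BASES.index(context[0]) * 4
        + BASES.index(context[2])
    )
    return Channel(index, sub, context[0], context[2])


def is_transition(ref: str, alt: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine substitutions."""
    if ref not in BASES or alt not in BASES:
        raise AmbiguousBaseError(f"unmappable base in {ref}>{alt}")
    return (ref in PYRIMIDINES) == (alt in PYRIMIDINES)
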
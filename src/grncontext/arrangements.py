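"""Transcriptional-unit arrangements of the three-repressor cassette.

The cassette carries three transcriptional units (TUs): *lacI* and *tetR*
driven by P_lac (repressed by LacI, induced by IPTG) and *cI* driven by
P_tet (repressed by TetR, induced by aTc).  The regulatory topology is
fixed; what varies is the *local genetic context* — the order of the three
TUs along the cassette, the orientation of each TU, and the transcriptional
terminator sitting at each of the two internal junctions.  With three slots
and two orientations per TU there are 3!·2³ = 48 arrangements, which fall
into 24 pairs related by reversing the whole cassette.

Labels follow the single-letter convention L = lacI, T = tetR, C = cI, with
an ``_r`` suffix for a TU in reverse orientation, read from slot 1 to
slot 3 (e.g. ``TLC``, ``CTL_r``, ``LT_rC_r``).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product
from typing import Iterable, Sequence

GENES = ("lacI", "tetR", "cI")

FORWARD = "forward"
REVERSE = "reverse"
ORIENTATIONS = (FORWARD, REVERSE)

LETTER_BY_GENE = {"lacI": "L", "tetR": "T", "cI": "C"}
GENE_BY_LETTER = {v: k for k, v in LETTER_BY_GENE.items()}

#: Fixed gene -> promoter wiring (the network topology never varies).
PROMOTER_BY_GENE = {"lacI": "P_lac", "tetR": "P_lac", "cI": "P_tet"}
#: Which repressor binds each promoter.
REPRESSOR_BY_PROMOTER = {"P_lac": "lacI", "P_tet": "tetR"}
#: Which inducer lifts repression at each promoter (I1 = IPTG, I2 = aTc).
INDUCER_BY_PROMOTER = {"P_lac": "IPTG", "P_tet": "aTc"}


class LabelError(ValueError):
    """Raised for malformed arrangement labels."""


@dataclass(frozen=True)
class TranscriptionalUnit:
    """One promoter + repressor gene + terminator block of the network."""

    gene: str

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValueError(f"unknown gene {self.gene!r}")

    @property
    def promoter(self) -> str:
        return PROMOTER_BY_GENE[self.gene]

    @property
    def repressed_by(self) -> str:
        return REPRESSOR_BY_PROMOTER[self.promoter]


@dataclass(frozen=True)
class TerminatorSpec:
    """A junction terminator and the read-through it permits.

    The effective read-through rate of the junction is
    ``readthrough_rate * mu**mu_power`` where ``mu`` is the model-wide free
    read-through parameter.  ``readthrough_rate=None`` means a coefficient
    of 1, so the stock T1 terminator (``mu_power=1``) simply tracks the
    model ``mu``; a fixed-efficiency terminator uses ``mu_power=0``; two
    terminators in series multiply (coefficients multiply, powers add).
    """

    name: str = "T1"
    readthrough_rate: float | None = None
    mu_power: int = 1

    def __post_init__(self) -> None:
        if self.readthrough_rate is not None and not 0.0 <= self.readthrough_rate <= 1.0:
            raise ValueError(f"readthrough_rate must be in [0, 1], got {self.readthrough_rate}")
        if self.mu_power < 0:
            raise ValueError("mu_power must be non-negative")

    def rate(self, mu: float) -> float:
        coeff = 1.0 if self.readthrough_rate is None else self.readthrough_rate
        return coeff * mu**self.mu_power

    def combined(self, other: "TerminatorSpec") -> "TerminatorSpec":
        """Two terminators in series: read-through probabilities multiply."""
        if self.readthrough_rate is None and other.readthrough_rate is None:
            coeff = None
        else:
            a = 1.0 if self.readthrough_rate is None else self.readthrough_rate
            b = 1.0 if other.readthrough_rate is None else other.readthrough_rate
            coeff = a * b
        return TerminatorSpec(
            name=f"{self.name}-{other.name}",
            readthrough_rate=coeff,
            mu_power=self.mu_power + other.mu_power,
        )


T1 = TerminatorSpec("T1")

#: Stock terminators.  Only the qualitative efficiency ordering
#: T1T2 < T1 < Tcrp ~ TtonB is constrained by the system; the fixed rates
#: for the weak terminators are package defaults (see docs/methods.md).
TERMINATORS = {
    "T1": T1,
    "T1T2": TerminatorSpec("T1T2", mu_power=2),
    "Tcrp": TerminatorSpec("Tcrp", readthrough_rate=0.80, mu_power=0),
    "TtonB": TerminatorSpec("TtonB", readthrough_rate=0.85, mu_power=0),
}

DEFAULT_JUNCTIONS = (T1, T1)


@dataclass(frozen=True)
class Arrangement:
    """An ordered 3-slot cassette: (gene, orientation) per slot + 2 junction terminators.

    The cassette is a linear segment; the plasmid backbone is not part of
    the arrangement and there is no wraparound adjacency.
    """

    slots: tuple[tuple[str, str], ...]
    junctions: tuple[TerminatorSpec, TerminatorSpec] = DEFAULT_JUNCTIONS

    def __post_init__(self) -> None:
        slots = tuple((g, o) for g, o in self.slots)
        object.__setattr__(self, "slots", slots)
        object.__setattr__(self, "junctions", tuple(self.junctions))
        if len(slots) != 3 or sorted(g for g, _ in slots) != sorted(GENES):
            raise ValueError(f"slots must contain each of {GENES} exactly once, got {slots}")
        for _, ori in slots:
            if ori not in ORIENTATIONS:
                raise ValueError(f"unknown orientation {ori!r}")
        if len(self.junctions) != 2:
            raise ValueError("exactly 2 junction terminators required")

    @property
    def label(self) -> str:
        return format_label(self)

    def with_junction(self, index: int, spec: TerminatorSpec) -> "Arrangement":
        if index not in (0, 1):
            raise ValueError("junction index must be 0 or 1")
        junctions = list(self.junctions)
        junctions[index] = spec
        return Arrangement(self.slots, tuple(junctions))

    def slot_of(self, gene: str) -> int:
        for i, (g, _) in enumerate(self.slots):
            if g == gene:
                return i
        raise KeyError(gene)

    def __repr__(self) -> str:  # compact, label-based
        return f"Arrangement({self.label!r})"


def format_label(a: Arrangement) -> str:
    return "".join(
        LETTER_BY_GENE[g] + ("_r" if o == REVERSE else "") for g, o in a.slots
    )


def parse_label(text: str, junctions: tuple[TerminatorSpec, TerminatorSpec] = DEFAULT_JUNCTIONS) -> Arrangement:
    """Parse a label like ``"TLC"`` or ``"LT_rC_r"`` into an Arrangement.

    Raises :class:`LabelError` naming the offending token on malformed input.
    """
    slots: list[tuple[str, str]] = []
    seen: set[str] = set()
    i = 0
    while i < len(text):
        ch = text[i]
        if ch not in GENE_BY_LETTER:
            raise LabelError(f"unknown gene letter {ch!r} in label {text!r}")
        gene = GENE_BY_LETTER[ch]
        if gene in seen:
            raise LabelError(f"duplicate gene letter {ch!r} in label {text!r}")
        seen.add(gene)
        i += 1
        ori = FORWARD
        if text[i : i + 2] == "_r":
            ori = REVERSE
            i += 2
        slots.append((gene, ori))
    if len(slots) != 3:
        raise LabelError(f"label {text!r} must name exactly 3 TUs, got {len(slots)}")
    return Arrangement(tuple(slots), junctions)


def enumerate_slot_assignments(
    genes: Sequence[str], allow_reverse: bool = True
) -> list[tuple[tuple[str, str], ...]]:
    """All (gene, orientation) slot tuples over ``genes``: n!·2^n (or n!)."""
    oris = ORIENTATIONS if allow_reverse else (FORWARD,)
    out = []
    for order in permutations(genes):
        for pattern in product(oris, repeat=len(genes)):
            out.append(tuple(zip(order, pattern)))
    return out


def enumerate_arrangements(
    allow_reverse: bool = True,
    junctions: tuple[TerminatorSpec, TerminatorSpec] = DEFAULT_JUNCTIONS,
) -> list[Arrangement]:
    """All distinct cassette arrangements, sorted by label (deterministic).

    48 with both orientations allowed, 6 all-forward.
    """
    arrs = [
        Arrangement(slots, junctions)
        for slots in enumerate_slot_assignments(GENES, allow_reverse)
    ]
    return sorted(arrs, key=lambda a: a.label)


def flip_arrangement(a: Arrangement) -> Arrangement:
    """Whole-cassette reversal: slot order reversed, orientations inverted,
    junction list reversed.  An involution with no fixed points."""
    flipped = tuple(
        (g, REVERSE if o == FORWARD else FORWARD) for g, o in reversed(a.slots)
    )
    return Arrangement(flipped, tuple(reversed(a.junctions)))


def pair_id(a: Arrangement) -> str:
    """Canonical id of the orientation pair {a, flip(a)}: the smaller label."""
    return min(a.label, flip_arrangement(a).label)


def orientation_pairs(
    arrangements: Iterable[Arrangement],
) -> list[tuple[Arrangement, Arrangement]]:
    """Partition a flip-closed set into {a, flip(a)} pairs.

    Raises ``ValueError`` if the input is not closed under flipping.
    """
    by_label = {a.label: a for a in arrangements}
    pairs: dict[str, tuple[Arrangement, Arrangement]] = {}
    for a in by_label.values():
        b = flip_arrangement(a)
        if b.label not in by_label:
            raise ValueError(
                f"input not closed under flip: {a.label} has no partner {b.label}"
            )
        pid = pair_id(a)
        if pid not in pairs:
            first, second = sorted((a, b), key=lambda x: x.label)
            pairs[pid] = (first, second)
    return [pairs[k] for k in sorted(pairs)]
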
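"""Combining two haplotype calls and CNV evidence into a diplotype.

Whole-gene deletions (*5) and duplications (*1x2 etc.) are detected in the
wet lab by a separate diagnostic amplicon, so they arrive here as
per-sample structural evidence rather than as small variants: a deletion
replaces the carrier haplotype's star call outright, and a duplication
suffixes the carrier's label with "xN".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .calling import StarCall
from .defs import StructuralKind, star_number

__all__ = [
    "StructuralStatus",
    "Diplotype",
    "call_diplotype",
    "count_haplotypes",
    "parse_allele_label",
]

_LABEL_RE = re.compile(r"^(\*\d+)(?:x(\d+))?$")


def parse_allele_label(label: str) -> tuple[str, int]:
    """Split a diplotype allele label into (star allele, copy number).

    ``"*1x2"`` -> ``("*1", 2)``; ``"*4"`` -> ``("*4", 1)``.
    """
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"not an allele label: {label!r}")
    return m.group(1), int(m.group(2) or 1)


def _label_sort_key(label: str) -> tuple[int, int]:
    name, copies = parse_allele_label(label)
    # at equal star number a duplicated label precedes the plain one (*1x2/*1)
    return star_number(name), -copies


@dataclass(frozen=True)
class StructuralStatus:
    """One structural event (deletion or duplication) on one haplotype."""

    kind: StructuralKind
    carrier_hap: int
    multiplicity: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind is StructuralKind.NONE:
            return
        if self.carrier_hap not in (1, 2):
            raise ValueError(f"carrier_hap must be 1 or 2, got {self.carrier_hap}")
        if self.kind is StructuralKind.DUPLICATION:
            if self.multiplicity is None or self.multiplicity < 2:
                raise ValueError("duplication requires multiplicity >= 2")
        elif self.multiplicity is not None:
            raise ValueError(f"{self.kind.value} takes no multiplicity")


@dataclass(frozen=True)
class Diplotype:
    """An ordered pair of star-allele labels for one sample."""

    sample_id: str
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        a, b = sorted((self.allele_a, self.allele_b), key=_label_sort_key)
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)

    @property
    def display(self) -> str:
        return f"{self.allele_a}/{self.allele_b}"

    @property
    def labels(self) -> tuple[str, str]:
        return self.allele_a, self.allele_b


def call_diplotype(
    call_a: StarCall,
    call_b: StarCall,
    structural: Union[StructuralStatus, Sequence[StructuralStatus], None] = None,
    deletion_allele: str = "*5",
) -> Diplotype:
    """Merge two per-haplotype star calls with structural evidence.

    ``structural`` may be a single event, a sequence of events (at most one
    per haplotype), or None.  A deletion replaces the carrier haplotype's
    label with ``deletion_allele``; a duplication of multiplicity N suffixes
    the carrier's label with ``xN``.  A deletion whose carrier haplotype
    shows variants is an inconsistency (a deleted gene cannot be sequenced)
    and raises ``ValueError``.
    """
    if call_a.sample_id != call_b.sample_id:
        raise ValueError(
            f"calls from different samples: {call_a.sample_id} / {call_b.sample_id}"
        )
    events: list[StructuralStatus]
    if structural is None:
        events = []
    elif isinstance(structural, StructuralStatus):
        events = [] if structural.kind is StructuralKind.NONE else [structural]
    else:
        events = [e for e in structural if e.kind is not StructuralKind.NONE]
    seen_haps = [e.carrier_hap for e in events]
    if len(seen_haps) != len(set(seen_haps)):
        raise ValueError("more than one structural event on the same haplotype")

    labels = {1: call_a.allele, 2: call_b.allele}
    cores = {1: call_a.matched_core | call_a.unexplained,
             2: call_b.matched_core | call_b.unexplained}
    for event in events:
        if event.kind is StructuralKind.DELETION:
            if cores[event.carrier_hap]:
                raise ValueError(
                    f"sample {call_a.sample_id}: deletion on haplotype "
                    f"{event.carrier_hap} but variants were called on it"
                )
            labels[event.carrier_hap] = deletion_allele
        else:
            labels[event.carrier_hap] += f"x{event.multiplicity}"
    return Diplotype(call_a.sample_id, labels[1], labels[2])


def count_haplotypes(diplotypes: Iterable[Diplotype]) -> int:
    """Number of haplotypes a cohort contributes to a frequency denominator.

    Exactly two per individual: a deletion still occupies one haplotype
    slot, and a duplicated allele ("xN") is denominated as one haplotype,
    not N.
    """
    return 2 * sum(1 for _ in diplotypes)
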
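"""Step distances, modal haplotypes, related-haplotype search, diversity.

The step distance between two 15-locus haplotypes is the sum of absolute
allele differences — the natural metric under single-step mutation. When
either haplotype carries a duplicated DYS19, that locus is excluded from
the comparison and the number of loci actually compared is reported by
:func:`step_distance_detail`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from ystr.data_io import DYS19_INDEX, StrHaplotype


@dataclass(frozen=True)
class ModalHaplotype:
    """A 15-locus profile observed in more than ``threshold`` samples (N*)."""

    haplotype: StrHaplotype
    count: int
    threshold: int


@dataclass
class RelatedSet:
    """Haplotypes within ``radius`` steps of a modal, same haplogroup (N**)."""

    modal: ModalHaplotype
    members: list[StrHaplotype]
    radius: int

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class LineageStats:
    HD: float  # haplotype diversity over distinct profiles
    PD: float  # mean pairwise step differences
    n: int


def step_distance_detail(a: StrHaplotype, b: StrHaplotype) -> tuple[int, int]:
    """(step distance, number of loci compared).

    DYS19 is dropped when either haplotype is flagged as duplicated; the
    reduced divisor is surfaced so downstream per-locus rates can adjust.
    """
    if len(a.alleles) != len(b.alleles):
        raise ValueError("haplotypes have mismatched locus sets")
    skip = (a.dys19_duplicated or b.dys19_duplicated)
    dist = 0
    n_loci = 0
    for i, (x, y) in enumerate(zip(a.alleles, b.alleles)):
        if skip and i == DYS19_INDEX:
            continue
        dist += abs(x - y)
        n_loci += 1
    return dist, n_loci


def step_distance(a: StrHaplotype, b: StrHaplotype) -> int:
    """Sum of absolute allele differences over compared loci."""
    return step_distance_detail(a, b)[0]


def find_modal_haplotypes(
    haplotypes: Sequence[StrHaplotype],
    threshold: int = 10,
) -> list[ModalHaplotype]:
    """Identical-profile groups within a haplogroup carried by more than
    ``threshold`` samples, sorted by descending count then allele vector."""
    if not haplotypes:
        raise ValueError("empty haplotype list")
    counter: Counter = Counter(
        (h.alleles, h.haplogroup, h.dys19_duplicated) for h in haplotypes
    )
    modals = [
        ModalHaplotype(
            haplotype=StrHaplotype(
                alleles=key[0], haplogroup=key[1], dys19_duplicated=key[2]
            ),
            count=count,
            threshold=threshold,
        )
        for key, count in counter.items()
        if count > threshold
    ]
    modals.sort(key=lambda m: (-m.count, m.haplotype.alleles))
    return modals


def related_search(
    modal: ModalHaplotype,
    database: Iterable[StrHaplotype],
    radius: int = 4,
) -> RelatedSet:
    """All database haplotypes of the modal's haplogroup within ``radius``
    mutational steps (inclusive; exact matches count).

    "Fewer than 5 steps" is implemented as distance <= 4. The result is
    sorted by (distance, alleles) so it is invariant to database order.
    """
    target = modal.haplotype
    members = [
        h for h in database
        if h.haplogroup == target.haplogroup
        and step_distance(h, target) <= radius
    ]
    members.sort(key=lambda h: (step_distance(h, target), h.alleles))
    return RelatedSet(modal=modal, members=members, radius=radius)


def lineage_stats(haplotypes: Sequence[StrHaplotype]) -> LineageStats:
    """Haplotype diversity and mean pairwise step differences for a lineage."""
    n = len(haplotypes)
    if n < 2:
        raise ValueError("lineage statistics require n >= 2")
    counts = Counter(h.alleles for h in haplotypes)
    sq = sum((c / n) ** 2 for c in counts.values())
    hd = n * (1.0 - sq) / (n - 1)
    pairs = list(combinations(haplotypes, 2))
    pd_ = sum(step_distance(a, b) for a, b in pairs) / len(pairs)
    return LineageStats(HD=hd, PD=pd_, n=n)
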
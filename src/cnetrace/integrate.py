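"""Integration of per-pair conserved intervals into named CNEs.

Pairwise comparisons against a single reference species leave one interval
set per query species.  Elements are the connected components of overlap
of the union of those intervals.  When different query species conserve
different sub-regions of one element, the element is partitioned at the
distinct interval endpoints into maximal sub-intervals of constant
supporting-species set; sub-intervals are labelled ``a``, ``b``, ... left
to right, and the full element carries the concatenated label (``ab``).
Elements whose sub-intervals all share identical support carry no
sub-label.

Names follow the ``I``/``F`` convention: prefix ``I`` for intergenic and
``F`` for flanking elements, then the cluster code and a serial assigned
in ascending start order (``I12.1``, ``F56.9``, ``I12.3b`` ...).  The
reference species is always counted in every element's support, since
conservation is defined relative to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .detect import ConservedInterval
from .io import CharacterMatrix

__all__ = [
    "SubElement",
    "CNE",
    "integrate_pairs",
    "assign_names",
    "presence_matrix",
]


@dataclass(frozen=True)
class SubElement:
    """A maximal constant-support sub-interval of an element."""

    name: str
    start: int
    end: int
    support: frozenset[str]
    mean_identity: float


@dataclass(frozen=True)
class CNE:
    """A named conserved element on reference coordinates."""

    name: str
    ref_species: str
    start: int
    end: int
    support: frozenset[str]
    mean_identity: float
    sub_elements: tuple[SubElement, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def has_sub_structure(self) -> bool:
        return len(self.sub_elements) > 0


def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def integrate_pairs(
    intervals: Sequence[ConservedInterval],
    min_jaccard_same: float = 0.0,
    tolerance: int = 0,
) -> list[CNE]:
    """Group per-pair conserved intervals into (unnamed) elements.

    Two intervals belong to the same element when they overlap (strictly;
    merely touching intervals stay separate) with interval Jaccard at
    least ``min_jaccard_same``.  Within an element, sub-structure is
    derived by partitioning at the distinct interval endpoints; endpoints
    closer than ``tolerance`` bases to an already-accepted breakpoint are
    snapped onto it.

    Returned elements carry placeholder names ``""``; use
    :func:`assign_names` for the I/F serial naming.
    """
    if not intervals:
        return []
    refs = {iv.ref_species for iv in intervals}
    if len(refs) > 1:
        raise ValueError(f"mixed reference species: {sorted(refs)}")
    ref_species = next(iter(refs))

    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].start, intervals[i].end))
    # single-linkage components under the overlap predicate
    components: list[list[ConservedInterval]] = []
    comp_end = -1
    for idx in order:
        iv = intervals[idx]
        if components and iv.start < comp_end and _overlaps_any(iv, components[-1], min_jaccard_same):
            components[-1].append(iv)
            comp_end = max(comp_end, iv.end)
        else:
            components.append([iv])
            comp_end = iv.end
    elements = [
        _build_element(ref_species, member, tolerance) for member in components
    ]
    return elements


def _overlaps_any(
    iv: ConservedInterval,
    members: list[ConservedInterval],
    min_jaccard_same: float,
) -> bool:
    for m in members:
        if iv.start < m.end and m.start < iv.end:
            if _jaccard((iv.start, iv.end), (m.start, m.end)) >= min_jaccard_same:
                return True
    return False


def _build_element(
    ref_species: str, members: list[ConservedInterval], tolerance: int
) -> CNE:
    start = min(iv.start for iv in members)
    end = max(iv.end for iv in members)
    support = frozenset({ref_species} | {iv.qry_species for iv in members})
    mean_identity = float(np.mean([iv.mean_identity for iv in members]))

    breakpoints = _snapped_breakpoints(members, tolerance)
    # support per atomic segment, then merge adjacent equal-support segments
    segments: list[tuple[int, int, frozenset[str]]] = []
    for seg_start, seg_end in zip(breakpoints[:-1], breakpoints[1:]):
        seg_support = frozenset(
            {ref_species}
            | {
                iv.qry_species
                for iv in members
                if iv.start < seg_end and seg_start < iv.end
            }
        )
        if segments and segments[-1][2] == seg_support:
            segments[-1] = (segments[-1][0], seg_end, seg_support)
        else:
            segments.append((seg_start, seg_end, seg_support))

    sub_elements: tuple[SubElement, ...] = ()
    if len({s[2] for s in segments}) > 1:
        subs = []
        for (s, e, supp) in segments:
            ids = [
                iv.mean_identity
                for iv in members
                if iv.start < e and s < iv.end
            ]
            subs.append(
                SubElement(
                    name="",
                    start=s,
                    end=e,
                    support=supp,
                    mean_identity=float(np.mean(ids)) if ids else 0.0,
                )
            )
        sub_elements = tuple(subs)
    return CNE(
        name="",
        ref_species=ref_species,
        start=start,
        end=end,
        support=support,
        mean_identity=mean_identity,
        sub_elements=sub_elements,
    )


def _snapped_breakpoints(
    members: list[ConservedInterval], tolerance: int
) -> list[int]:
    raw = sorted({p for iv in members for p in (iv.start, iv.end)})
    if tolerance <= 0:
        return raw
    snapped = [raw[0]]
    for p in raw[1:]:
        if p - snapped[-1] <= tolerance:
            continue
        snapped.append(p)
    return snapped


_SUB_LABELS = "abcdefghijklmnopqrstuvwxyz"


def _sub_label(i: int) -> str:
    """a, b, ..., z, aa, ab, ... (spreadsheet-style) for sub-interval i."""
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = _SUB_LABELS[rem] + label
    return label


def assign_names(
    elements: Iterable[CNE],
    cluster_id: str,
    region_class: str,
) -> list[CNE]:
    """Name elements ``I<cluster>.<serial>`` / ``F<cluster>.<serial>``.

    Serials increase with start coordinate.  An element with sub-structure
    gets the concatenated sub-labels appended (e.g. ``I12.3ab``) and its
    sub-elements are named ``I12.3a``, ``I12.3b``, ... left to right.
    """
    prefix = "I" if region_class == "intergenic" else "F"
    named: list[CNE] = []
    for serial, element in enumerate(
        sorted(elements, key=lambda e: (e.start, e.end)), start=1
    ):
        base = f"{prefix}{cluster_id}.{serial}"
        if element.has_sub_structure:
            labels = [_sub_label(i) for i in range(len(element.sub_elements))]
            subs = tuple(
                SubElement(
                    name=f"{base}{lab}",
                    start=s.start,
                    end=s.end,
                    support=s.support,
                    mean_identity=s.mean_identity,
                )
                for lab, s in zip(labels, element.sub_elements)
            )
            name = f"{base}{''.join(labels)}"
        else:
            subs = ()
            name = base
        named.append(
            CNE(
                name=name,
                ref_species=element.ref_species,
                start=element.start,
                end=element.end,
                support=element.support,
                mean_identity=element.mean_identity,
                sub_elements=subs,
            )
        )
    return named


def presence_matrix(
    cnes: Sequence[CNE],
    species_universe: Sequence[str],
    availability: Mapping[str, Sequence[tuple[int, int]]],
    missing_fraction: float = 0.5,
    min_sub_length: int = 0,
) -> CharacterMatrix:
    """Presence/absence/missing matrix over named elements and sub-elements.

    ``availability`` maps each species to the reference-coordinate
    intervals across which its orthologous region is sequenced (non-N).
    A species scores ``1`` when it supports the element (the reference
    always does), ``0`` when its region is sequenced across the element
    but unsupported, and ``?`` when the region is absent or at least
    ``missing_fraction`` of the element's span is unsequenced.

    Sub-elements shorter than ``min_sub_length`` are not promoted to
    characters of their own (boundary slivers between interval endpoints
    are not conserved elements in any meaningful sense); the spanning
    element is always a character.
    """
    for sp in species_universe:
        if sp not in availability:
            raise ValueError(f"taxon {sp!r} missing from availability")

    characters: list[tuple[str, int, int, frozenset[str], str]] = []
    for cne in cnes:
        for sub in cne.sub_elements:
            if sub.end - sub.start >= min_sub_length:
                characters.append(
                    (sub.name, sub.start, sub.end, sub.support, cne.ref_species)
                )
        characters.append((cne.name, cne.start, cne.end, cne.support, cne.ref_species))

    states: dict[str, dict[str, str]] = {}
    for name, start, end, support, ref_species in characters:
        col: dict[str, str] = {}
        for sp in species_universe:
            if sp == ref_species or sp in support:
                col[sp] = "1"
                continue
            covered = 0
            for a, b in availability[sp]:
                covered += max(0, min(b, end) - max(a, start))
            if (end - start) == 0 or covered / (end - start) <= 1 - missing_fraction:
                col[sp] = "?"
            else:
                col[sp] = "0"
        states[name] = col
    return CharacterMatrix.from_dict(
        states,
        taxa=list(species_universe),
        characters=[c[0] for c in characters],
    )
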
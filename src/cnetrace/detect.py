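"""Windowed percent-identity profiles and conserved-interval calling.

A candidate cis-regulatory element is called wherever a sliding window of
``W`` reference bases (default 100) reaches at least ``threshold`` percent
identity (default 70) against a query species.  The window is anchored on
reference bases: it spans the alignment columns from the column of
reference position ``p`` through the column of ``p + W - 1`` inclusive, so
query insertions inside the window enter the denominator.  A column counts
as matching only when both rows carry the same base in {A,C,G,T} — ``N``
(and masked exon bases) never match.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .align import PairwiseAlignment
from .io import RegionSequence

__all__ = [
    "IdentityProfile",
    "ConservedInterval",
    "windowed_identity",
    "call_conserved_intervals",
    "mask_exons",
    "plot_profiles",
]

DEFAULT_WINDOW = 100
DEFAULT_THRESHOLD = 70.0


@dataclass(frozen=True)
class IdentityProfile:
    """Windowed identity track along the reference.

    ``identity[p]`` is the percent identity of the window starting at
    reference position ``p``; the array has ``L - W + 1`` entries for a
    reference of ungapped length ``L``, or zero entries when ``L < W``
    (flagged via :attr:`empty`).
    """

    ref_species: str
    qry_species: str
    window: int
    identity: np.ndarray

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window length must be >= 1")
        ident = np.asarray(self.identity, dtype=float)
        if ident.size and (ident.min() < 0 or ident.max() > 100):
            raise ValueError("identity values must lie in [0, 100]")
        object.__setattr__(self, "identity", ident)

    @property
    def empty(self) -> bool:
        """True when the reference was shorter than the window."""
        return self.identity.size == 0


@dataclass(frozen=True)
class ConservedInterval:
    """A merged run of qualifying windows on reference coordinates."""

    ref_species: str
    qry_species: str
    start: int
    end: int
    mean_identity: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def windowed_identity(
    aln: PairwiseAlignment, window: int = DEFAULT_WINDOW
) -> IdentityProfile:
    """Percent identity of each reference-anchored window of the alignment."""
    if window < 1:
        raise ValueError("window length must be >= 1")
    col_of_ref = aln.column_of_ref()
    L = col_of_ref.size
    if L < window:
        return IdentityProfile(
            aln.ref_species, aln.qry_species, window, np.zeros(0)
        )
    match = aln.match_columns()
    cum = np.concatenate([[0], np.cumsum(match)])
    first_col = col_of_ref[: L - window + 1]
    last_col = col_of_ref[window - 1 :]
    matches = cum[last_col + 1] - cum[first_col]
    span = last_col - first_col + 1
    identity = 100.0 * matches / span
    return IdentityProfile(aln.ref_species, aln.qry_species, window, identity)


def call_conserved_intervals(
    profile: IdentityProfile,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[ConservedInterval]:
    """Merged union of qualifying windows.

    A start ``p`` qualifies iff ``identity[p] >= threshold``; the output is
    the merged union of ``[p, p + W)`` over qualifying starts, each merged
    run scored by the mean identity of the qualifying windows it contains.
    """
    if not (0 < threshold <= 100):
        raise ValueError("threshold must lie in (0, 100]")
    if profile.empty:
        return []
    W = profile.window
    starts = np.flatnonzero(profile.identity >= threshold)
    intervals: list[ConservedInterval] = []
    if starts.size == 0:
        return intervals
    run_start = int(starts[0])
    run_scores = [profile.identity[starts[0]]]
    prev = int(starts[0])
    for p in starts[1:]:
        p = int(p)
        if p <= prev + W:  # windows [prev, prev+W) and [p, p+W) overlap or touch
            run_scores.append(profile.identity[p])
        else:
            intervals.append(
                ConservedInterval(
                    profile.ref_species,
                    profile.qry_species,
                    run_start,
                    prev + W,
                    float(np.mean(run_scores)),
                )
            )
            run_start = p
            run_scores = [profile.identity[p]]
        prev = p
    intervals.append(
        ConservedInterval(
            profile.ref_species,
            profile.qry_species,
            run_start,
            prev + W,
            float(np.mean(run_scores)),
        )
    )
    return intervals


def mask_exons(
    region: RegionSequence, exon_intervals: list[tuple[int, int]]
) -> RegionSequence:
    """Replace exon bases with ``N`` so no element can be called there.

    Intervals are 0-based half-open on the region's own coordinates and
    must lie within bounds.
    """
    L = len(region.seq)
    seq = list(region.seq)
    for start, end in exon_intervals:
        if not (0 <= start < end <= L):
            raise ValueError(
                f"exon interval [{start}, {end}) out of bounds for region of length {L}"
            )
        seq[start:end] = "N" * (end - start)
    return replace(region, seq="".join(seq))


def plot_profiles(
    profiles: list[IdentityProfile],
    path: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> None:
    """VISTA-style stacked identity tracks (one panel per query species)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = max(len(profiles), 1)
    fig, axes = plt.subplots(n, 1, figsize=(10, 1.6 * n), sharex=True, squeeze=False)
    for ax, prof in zip(axes.ravel(), profiles):
        x = np.arange(prof.identity.size)
        ax.fill_between(x, 50, np.maximum(prof.identity, 50), color="#7b4fa6", alpha=0.7)
        ax.axhline(threshold, color="red", lw=0.6, ls="--")
        ax.set_ylim(50, 100)
        ax.set_ylabel(prof.qry_species, rotation=0, ha="right", fontsize=8)
    axes.ravel()[-1].set_xlabel(f"position in {profiles[0].ref_species} (bp)" if profiles else "position")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
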
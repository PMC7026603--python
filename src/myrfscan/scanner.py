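"""Both-strand heptamer scanning and composite-site assembly.

High-affinity Myrf binding engages a trimer on two heptamers whose
central nucleotides sit 10 bp (one helical turn) or 14 bp (1.5 turns)
apart, i.e. spacers of 3 or 7 bp between the heptamers; orientation of
the two motifs relative to each other matters far less than spacing.
This module finds heptamer matches on both strands, pairs them into
composite sites by spacing, scores sites by summed mismatch penalty,
and merges sites sharing a heptamer into clusters (a third in-phase
motif adds no affinity, so cluster scoring is max, never additive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motif import (
    IUPAC,
    ConsensusModel,
    InvalidSequenceError,
    MotifMatch,
    reverse_complement,
)

__all__ = [
    "CompositeSite",
    "SiteCluster",
    "ScanResult",
    "scan_heptamers",
    "pair_composites",
    "classify_affinity",
    "cluster_sites",
    "scan_region",
    "bed_score",
]

_AFFINITY_RANK = {"none": 0, "weak": 1, "strong": 2}

SCAN_ALPHABET = "ACGTN"  # N is a universal mismatch during scanning


@dataclass(frozen=True)
class CompositeSite:
    """A pair of heptamer matches forming a candidate Myrf trimer site."""

    sequence_id: str
    match_a: MotifMatch  # upstream on forward coordinates
    match_b: MotifMatch
    spacer: int  # bp strictly between the two heptamers
    center_distance: int  # = spacer + 7
    spacing_class: str  # one_turn | one_and_a_half_turns | other
    orientation_class: str  # head_to_tail | head_to_head | tail_to_tail
    total_mismatches: int
    total_penalty: float
    affinity_class: str  # strong | weak | none
    flags: tuple[str, ...] = ()

    @property
    def start(self) -> int:
        return self.match_a.start

    @property
    def end(self) -> int:
        return self.match_b.end


@dataclass(frozen=True)
class SiteCluster:
    """Composite sites merged on shared heptamers; affinity is the best member's."""

    sequence_id: str
    sites: tuple[CompositeSite, ...]
    start: int
    end: int
    affinity_class: str
    score: int  # BED-style 0..1000, from the best member
    flags: tuple[str, ...] = ()

    @property
    def best_site(self) -> CompositeSite:
        return max(
            self.sites,
            key=lambda s: (_AFFINITY_RANK[s.affinity_class], -s.total_penalty),
        )


@dataclass(frozen=True)
class ScanResult:
    sequence_id: str
    matches: tuple[MotifMatch, ...]
    sites: tuple[CompositeSite, ...]
    clusters: tuple[SiteCluster, ...]

    def best_affinity(self) -> str:
        """Best cluster affinity, or ``none`` when no cluster exists."""
        if not self.clusters:
            return "none"
        return max((c.affinity_class for c in self.clusters), key=_AFFINITY_RANK.get)


def _allowed_matrix(pattern: str) -> np.ndarray:
    """(7, 128) boolean lookup: allowed[p, ord(base)] for motif position p+1."""
    allowed = np.zeros((len(pattern), 128), dtype=bool)
    for p, sym in enumerate(pattern):
        for base in IUPAC[sym]:
            allowed[p, ord(base)] = True
    return allowed


def scan_heptamers(
    sequence: str,
    model: ConsensusModel | None = None,
    sequence_id: str = "seq",
) -> list[MotifMatch]:
    """Report every heptamer window on either strand within the mismatch budget.

    Minus-strand matches are reported in forward coordinates with strand
    ``-``; mismatch positions are always motif-local (5'->3' of the
    motif).  ``N`` counts as a mismatch at every position.  Output is
    sorted by start, then strand (``+`` before ``-``).
    """
    model = model or ConsensusModel()
    seq = sequence.upper()
    bad = set(seq) - set(SCAN_ALPHABET)
    if bad:
        pos = next(i for i, b in enumerate(seq) if b in bad)
        raise InvalidSequenceError(
            f"invalid character {seq[pos]!r} at position {pos + 1} of {sequence_id}"
        )
    k = model.length
    if len(seq) < k:
        return []

    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)  # (n, 7)

    fwd_allowed = _allowed_matrix(model.pattern)
    rc_allowed = _allowed_matrix(reverse_complement(model.pattern))

    # mismatch boolean per (window, window-column)
    cols = np.arange(k)
    fwd_mm = ~fwd_allowed[cols, windows]  # (n, 7)
    rc_mm = ~rc_allowed[cols, windows]

    budget = model.max_total_mismatches
    matches: list[MotifMatch] = []
    for strand, mm in (("+", fwd_mm), ("-", rc_mm)):
        counts = mm.sum(axis=1)
        for start in np.nonzero(counts <= budget)[0]:
            cols_mm = np.nonzero(mm[start])[0]
            if strand == "+":
                positions = tuple(int(c) + 1 for c in cols_mm)
            else:
                # window column j holds motif-local position 7-j (1-based)
                positions = tuple(sorted(k - int(c) for c in cols_mm))
            matches.append(
                MotifMatch(
                    sequence_id=sequence_id,
                    start=int(start),
                    strand=strand,
                    mismatch_positions=positions,
                    penalty=model.penalty_of(positions),
                )
            )
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


def classify_affinity(
    site_or_spacer,
    model: ConsensusModel | None = None,
    total_penalty: float | None = None,
) -> str:
    """Affinity class of a composite site.

    A spacer outside the high-affinity set (default {3, 7}) yields
    ``none`` regardless of penalty; otherwise the total penalty is
    compared against the strong and weak thresholds.
    """
    model = model or ConsensusModel()
    if isinstance(site_or_spacer, CompositeSite):
        spacer = site_or_spacer.spacer
        penalty = site_or_spacer.total_penalty
    else:
        spacer = int(site_or_spacer)
        if total_penalty is None:
            raise TypeError("total_penalty required when passing a bare spacer")
        penalty = float(total_penalty)
    if spacer not in model.allowed_spacers_high_affinity:
        return "none"
    if penalty <= model.strong_threshold:
        return "strong"
    if penalty <= model.weak_threshold:
        return "weak"
    return "none"


def _orientation(a: MotifMatch, b: MotifMatch) -> tuple[str, tuple[str, ...]]:
    if a.strand == b.strand:
        return "head_to_tail", ()
    if b.strand == "-":  # downstream motif reverse-complemented
        return "head_to_head", ()
    # upstream motif on the minus strand: never tested in vitro
    return "tail_to_tail", ("untested_orientation",)


def pair_composites(
    matches: list[MotifMatch],
    model: ConsensusModel | None = None,
    mode: str = "candidate",
) -> list[CompositeSite]:
    """Pair heptamer matches into composite sites by centre distance.

    ``candidate`` mode admits spacers in the model's candidate range
    (default 3..8 bp, i.e. 1 to 1.5 helical turns); ``high_affinity``
    mode restricts to the in-vitro validated spacer set (default
    {3, 7}).  Orientation never filters.  Total mismatches over both
    heptamers must stay within the budget.
    """
    model = model or ConsensusModel()
    if mode not in ("candidate", "high_affinity"):
        raise ValueError(f"mode must be 'candidate' or 'high_affinity', got {mode!r}")
    ids = {m.sequence_id for m in matches}
    if len(ids) > 1:
        raise ValueError(f"matches come from multiple sequences: {sorted(ids)}")
    lo, hi = model.candidate_spacer_range
    ordered = sorted(matches, key=lambda m: (m.center, m.strand))
    sites: list[CompositeSite] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            dist = b.center - a.center
            if dist <= 0:
                continue
            spacer = dist - model.length
            if mode == "candidate":
                if not lo <= spacer <= hi:
                    continue
            else:
                if spacer not in model.allowed_spacers_high_affinity:
                    continue
            total_mm = a.n_mismatches + b.n_mismatches
            if total_mm > model.max_total_mismatches:
                continue
            orientation, flags = _orientation(a, b)
            spacing_class = {3: "one_turn", 7: "one_and_a_half_turns"}.get(spacer, "other")
            penalty = a.penalty + b.penalty
            sites.append(
                CompositeSite(
                    sequence_id=a.sequence_id,
                    match_a=a,
                    match_b=b,
                    spacer=spacer,
                    center_distance=dist,
                    spacing_class=spacing_class,
                    orientation_class=orientation,
                    total_mismatches=total_mm,
                    total_penalty=penalty,
                    affinity_class=classify_affinity(spacer, model, penalty),
                    flags=flags,
                )
            )
    sites.sort(key=lambda s: (s.start, s.end, s.match_a.strand, s.match_b.strand))
    return sites


def bed_score(total_penalty: float, model: ConsensusModel | None = None) -> int:
    """Scale a penalty to a BED score: 1000 at zero penalty, 0 at/above the none-threshold."""
    model = model or ConsensusModel()
    return int(round(1000 * max(0.0, 1.0 - total_penalty / model.weak_threshold)))


def cluster_sites(
    sites: list[CompositeSite],
    model: ConsensusModel | None = None,
) -> list[SiteCluster]:
    """Merge composite sites sharing at least one heptamer into clusters.

    Cluster affinity and score come from the best member (max, never
    additive): a third in-phase consensus motif does not increase
    binding.  Ties broken by leftmost start, then strand ``+`` before
    ``-`` — deterministic output ordering.
    """
    model = model or ConsensusModel()
    if not sites:
        return []
    parent = list(range(len(sites)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_match: dict[tuple[int, str], list[int]] = {}
    for idx, s in enumerate(sites):
        for m in (s.match_a, s.match_b):
            by_match.setdefault((m.start, m.strand), []).append(idx)
    for idxs in by_match.values():
        for j in idxs[1:]:
            union(idxs[0], j)

    groups: dict[int, list[CompositeSite]] = {}
    for idx, s in enumerate(sites):
        groups.setdefault(find(idx), []).append(s)

    clusters = []
    for members in groups.values():
        members.sort(
            key=lambda s: (
                -_AFFINITY_RANK[s.affinity_class],
                s.total_penalty,
                s.start,
                s.match_a.strand != "+",
            )
        )
        best = members[0]
        flags = tuple(sorted({f for s in members for f in s.flags}))
        clusters.append(
            SiteCluster(
                sequence_id=best.sequence_id,
                sites=tuple(members),
                start=min(s.start for s in members),
                end=max(s.end for s in members),
                affinity_class=best.affinity_class,
                score=bed_score(best.total_penalty, model)
                if best.affinity_class != "none" else 0,
                flags=flags,
            )
        )
    clusters.sort(key=lambda c: (c.start, c.end))
    return clusters


def scan_region(
    sequence: str,
    model: ConsensusModel | None = None,
    mode: str = "candidate",
    sequence_id: str = "seq",
) -> ScanResult:
    """Full scan: heptamer matches -> composite sites -> affinity -> clusters."""
    model = model or ConsensusModel()
    matches = scan_heptamers(sequence, model, sequence_id)
    sites = pair_composites(matches, model, mode)
    clusters = cluster_sites(sites, model)
    return ScanResult(
        sequence_id=sequence_id,
        matches=tuple(matches),
        sites=tuple(sites),
        clusters=tuple(clusters),
    )
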
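"""Regulatory-region classification and in-silico site editing.

The regulatory model: a Sox10-responsive region that also carries a
high-affinity composite Myrf site is synergistically co-activated by
the two factors; a Sox10-responsive region without a Myrf site is
repressed when Myrf is present (sequestration of Sox10); a region
without Sox10 sites does not respond.  Sox10 sites are supplied as
annotations (e.g. the dimeric C/C' site), never predicted.

``destroy_myrf_site`` mutates position 7 — the most disruptive tested
position — of every heptamer in a cluster; ``insert_myrf_site`` splices
a fully functional two-motif cassette (one helical turn spacing) into a
region.  Both mirror the reporter-construct edits that flip a region
between co-activation and repression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .motif import ConsensusModel, apply_position_mutation, reverse_complement
from .panel import CONSENSUS_REALIZATION
from .scanner import ScanResult, SiteCluster, scan_region

__all__ = [
    "Region",
    "RegionStateError",
    "classify_region",
    "destroy_myrf_site",
    "insert_myrf_site",
    "CASSETTE_SPACER_LEN",
]

_AFFINITY_RANK = {"none": 0, "weak": 1, "strong": 2}

CASSETTE_SPACER_LEN = 3
CASSETTE_LEN = 2 * 7 + CASSETTE_SPACER_LEN  # (c)3(c): 17 bp


class RegionStateError(RuntimeError):
    """Raised when an operation requires a scan the region does not have."""


@dataclass
class Region:
    """A named regulatory sequence with Sox10 annotations and scan state."""

    id: str
    sequence: str
    sox10_sites: tuple[tuple[int, int], ...] = ()
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    tss_distance_label: str | None = None
    myrf_scan: ScanResult | None = None
    response_class: str | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.sequence)
        self.sox10_sites = tuple((int(s), int(e)) for s, e in self.sox10_sites)
        for s, e in self.sox10_sites:
            if not (0 <= s < e <= n):
                raise ValueError(
                    f"Sox10 site [{s}, {e}) outside region {self.id!r} of length {n}"
                )

    def scan(self, model: ConsensusModel | None = None, mode: str = "candidate") -> "Region":
        """Scan the sequence for composite Myrf sites; returns self."""
        self.myrf_scan = scan_region(self.sequence, model, mode, sequence_id=self.id)
        return self


def classify_region(
    region: Region,
    model: ConsensusModel | None = None,
    min_affinity: str = "strong",
) -> str:
    """Classify the predicted response of a region to Myrf.

    ``co_activated`` — at least one Sox10 site and at least one Myrf
    cluster at or above *min_affinity*; ``myrf_repressed`` — Sox10 site
    present but no qualifying Myrf cluster; ``non_responsive`` — no
    Sox10 site.  The class is a pure function of Sox10-site presence and
    the best Myrf cluster affinity.
    """
    if min_affinity not in ("strong", "weak"):
        raise ValueError(f"min_affinity must be 'strong' or 'weak', got {min_affinity!r}")
    if region.myrf_scan is None:
        raise RegionStateError(f"region {region.id!r} has not been scanned")
    flags = list(region.flags)
    if not region.sox10_sites:
        cls = "non_responsive"
    else:
        need = _AFFINITY_RANK[min_affinity]
        qualifying = [
            c for c in region.myrf_scan.clusters
            if _AFFINITY_RANK[c.affinity_class] >= need
        ]
        if qualifying:
            cls = "co_activated"
            best = max(_AFFINITY_RANK[c.affinity_class] for c in qualifying)
            if best < _AFFINITY_RANK["strong"] and "weak_only_support" not in flags:
                flags.append("weak_only_support")
        else:
            cls = "myrf_repressed"
    region.response_class = cls
    region.flags = tuple(flags)
    return cls


def _mutate_heptamer(sequence: str, start: int, strand: str, position: int = 7) -> str:
    """Apply the transversion rule at a motif-local position of one heptamer."""
    window = sequence[start:start + 7]
    view = window if strand == "+" else reverse_complement(window)
    mutated = apply_position_mutation(view, position)
    new_window = mutated if strand == "+" else reverse_complement(mutated)
    return sequence[:start] + new_window + sequence[start + 7:]


def destroy_myrf_site(
    region: Region,
    cluster: SiteCluster,
    model: ConsensusModel | None = None,
    min_affinity: str = "strong",
    max_rounds: int = 5,
) -> Region:
    """Return a new region with every heptamer of *cluster* disrupted.

    Each heptamer receives the position-7 transversion (the most
    disruptive single change tested in vitro).  The returned region is
    rescanned and reclassified; after editing no cluster of weak or
    better affinity overlaps the original span.  Sox10 annotations and
    all sequence outside the cluster's heptamers are untouched.
    """
    model = model or ConsensusModel()
    if region.myrf_scan is None:
        raise RegionStateError(f"region {region.id!r} has not been scanned")
    if cluster not in region.myrf_scan.clusters:
        raise ValueError(f"cluster [{cluster.start}, {cluster.end}) not found in region {region.id!r}")
    span = (cluster.start, cluster.end)
    seq = region.sequence
    targets = {
        (m.start, m.strand)
        for site in cluster.sites
        for m in (site.match_a, site.match_b)
    }
    for _ in range(max_rounds):
        for start, strand in sorted(targets):
            seq = _mutate_heptamer(seq, start, strand)
        result = scan_region(seq, model, mode="candidate", sequence_id=region.id)
        leftover = {
            (m.start, m.strand)
            for c in result.clusters
            if _AFFINITY_RANK[c.affinity_class] >= _AFFINITY_RANK["weak"]
            and c.start < span[1] and c.end > span[0]
            for site in c.sites
            for m in (site.match_a, site.match_b)
        }
        if not leftover:
            break
        targets = leftover
    else:
        raise RuntimeError(
            f"could not disrupt cluster [{span[0]}, {span[1]}) of region {region.id!r}"
        )
    edited = replace(region, sequence=seq, myrf_scan=None, response_class=None)
    edited.scan(model, mode="candidate")
    classify_region(edited, model, min_affinity=min_affinity)
    return edited


def insert_myrf_site(
    region: Region,
    offset: int,
    model: ConsensusModel | None = None,
    min_affinity: str = "strong",
    seed: int = 0,
    max_attempts: int = 100,
) -> Region:
    """Return a new region with a functional two-motif cassette at *offset*.

    The cassette is CTGGCAC + 3 bp spacer + CTGGCAC (one helical turn
    between motif centres).  Spacer bases are rejection-sampled so the
    edited region gains exactly one strong cluster at the insertion
    point; annotation coordinates downstream of *offset* shift by the
    cassette length (17 bp).
    """
    model = model or ConsensusModel()
    if not 0 <= offset <= len(region.sequence):
        raise ValueError(f"offset {offset} outside region {region.id!r}")
    for s, e in region.sox10_sites:
        if s < offset < e:
            raise ValueError(
                f"offset {offset} falls inside annotated interval [{s}, {e}) "
                f"of region {region.id!r}"
            )
    rng = np.random.default_rng([seed, offset % (2**31)])
    bases = np.array(list("ACGT"))
    for _ in range(max_attempts):
        spacer = "".join(rng.choice(bases, size=CASSETTE_SPACER_LEN))
        cassette = CONSENSUS_REALIZATION + spacer + CONSENSUS_REALIZATION
        seq = region.sequence[:offset] + cassette + region.sequence[offset:]
        result = scan_region(seq, model, mode="candidate", sequence_id=region.id)
        # the planted pair must come back as a strong site inside the
        # cassette interval; junction strays may widen the enclosing
        # cluster but cannot weaken it (cluster affinity is max-combined)
        planted_ok = any(
            s.affinity_class == "strong" and s.start >= offset and s.end <= offset + CASSETTE_LEN
            for s in result.sites
        )
        if planted_ok:
            shifted = tuple(
                (s + CASSETTE_LEN, e + CASSETTE_LEN) if s >= offset else (s, e)
                for s, e in region.sox10_sites
            )
            edited = replace(
                region, sequence=seq, sox10_sites=shifted,
                myrf_scan=None, response_class=None,
            )
            edited.myrf_scan = result
            classify_region(edited, model, min_affinity=min_affinity)
            return edited
    raise RuntimeError(
        f"could not place a clean cassette at offset {offset} of region {region.id!r}"
    )
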
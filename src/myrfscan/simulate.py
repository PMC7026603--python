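"""Seeded synthetic-data generators with machine-checkable ground truth.

Every input class the pipeline consumes can be generated here with a
known truth: motif-free background DNA, region sets realising the three
regulatory scenarios (Sox10 + Myrf cassette, Sox10 only, neither), decoy
regions carrying only non-functional motif arrangements, and triage
tables with planted Venn/stage cardinalities.

Backgrounds are i.i.d. base sequences at a specified GC fraction with
motif-freeness enforced window by window: a random long sequence would
otherwise contain heptamer matches with near-certainty, so each new base
is accepted only if the window it completes fails to match the consensus
on both strands within the mismatch budget, with bounded backtracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motif import IUPAC, ConsensusModel, reverse_complement
from .panel import build_oligo, parse_oligo_spec
from .regions import Region
from .scanner import scan_heptamers, scan_region
from .triage import DeTable, PeakGeneTable, StageLists

__all__ = [
    "GenerationError",
    "generate_background",
    "RegionSetSpec",
    "RegionSet",
    "generate_region_set",
    "TriageSpec",
    "TriageSim",
    "generate_triage_tables",
    "DECOY_SPECS",
]

_BASES = "ACGT"

#: single motifs and off-phase / two-turn spacings that never bind strongly
DECOY_SPECS = ("(c)", "(c)4(c)", "(c)5(c)", "(c)6(c)", "(c)8(c)", "(c)13(c)")


class GenerationError(RuntimeError):
    """Raised when a generator cannot satisfy its constraints."""


def _pattern_sets(model: ConsensusModel) -> tuple[list[frozenset], list[frozenset]]:
    fwd = [IUPAC[s] for s in model.pattern]
    rc = [IUPAC[s] for s in reverse_complement(model.pattern)]
    return fwd, rc


def _window_clear(window: str, fwd, rc, budget: int) -> bool:
    mm_f = sum(1 for b, allowed in zip(window, fwd) if b not in allowed)
    mm_r = sum(1 for b, allowed in zip(window, rc) if b not in allowed)
    return mm_f > budget and mm_r > budget


def generate_background(
    length: int,
    gc: float = 0.45,
    seed: int = 0,
    model: ConsensusModel | None = None,
    max_backtracks: int = 20000,
) -> str:
    """Motif-free background DNA: no heptamer match on either strand.

    Bases are drawn i.i.d. at GC fraction *gc*; every completed 7-mer
    window is checked against the consensus on both strands and the
    construction backtracks when no admissible base exists.
    Deterministic per seed.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0, 1]")
    model = model or ConsensusModel()
    if length == 0:
        return ""
    fwd, rc = _pattern_sets(model)
    budget = model.max_total_mismatches
    k = model.length
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq: list[str] = []
    backtracks = 0
    while len(seq) < length:
        order = rng.permutation(4)
        weighted_first = rng.choice(4, p=probs)
        candidates = [weighted_first] + [b for b in order if b != weighted_first]
        placed = False
        for b in candidates:
            seq.append(_BASES[b])
            if len(seq) < k or _window_clear("".join(seq[-k:]), fwd, rc, budget):
                placed = True
                break
            seq.pop()
        if not placed:
            drop = min(3, len(seq))
            del seq[-drop:]
            backtracks += 1
            if backtracks > max_backtracks:
                raise GenerationError(
                    f"could not generate a motif-free background of length {length} "
                    f"at gc={gc} (exceeded {max_backtracks} backtracks)"
                )
    return "".join(seq)


def _plant(
    background: str,
    cassette_spec: str,
    offset: int,
    model: ConsensusModel,
    seed: int,
    max_attempts: int = 20,
) -> tuple[str, list[tuple[int, str]]]:
    """Overwrite background bases with the motifs/spacers of an oligo spec.

    Returns the edited sequence and the planted (start, strand) list.
    A splice junction can create a stray heptamer match against the
    fixed background context; the spacer seed and a small offset jitter
    (within +/- max_attempts/2 bp of the requested offset) are retried
    before giving up with a GenerationError.
    """
    first_error: str | None = None
    pre_existing = {(m.start, m.strand) for m in scan_heptamers(background, model)}
    for attempt in range(max_attempts):
        # alternate jitter 0, +1, -1, +2, -2, ... around the requested offset
        jitter = (attempt + 1) // 2 * (1 if attempt % 2 else -1)
        off = offset + jitter
        oligo = build_oligo(cassette_spec, model, seed=seed + attempt)
        left = oligo.motif_offsets[0]
        core = oligo.sequence[left: oligo.motif_offsets[-1] + 7]
        if offset < 0 or offset + len(core) > len(background):
            raise ValueError(
                f"cassette [{offset}, {offset + len(core)}) outside background"
            )
        if off < 0 or off + len(core) > len(background):
            continue
        seq = background[:off] + core + background[off + len(core):]
        planted = [
            (off + o - left, s)
            for o, s in zip(oligo.motif_offsets, oligo.motif_strands)
        ]
        # pre-existing matches at/after the splice point shift by nothing
        # (overwrite, not insertion), so coordinates are directly comparable
        expected = pre_existing | set(planted)
        found = {(m.start, m.strand) for m in scan_heptamers(seq, model)}
        if found == expected:
            return seq, planted
        if first_error is None:
            first_error = f"splice of {cassette_spec!r} at {off} produced stray matches"
    raise GenerationError(first_error or f"could not plant {cassette_spec!r}")


@dataclass(frozen=True)
class RegionSetSpec:
    """Counts and shapes for a synthetic region set (seed mandatory)."""

    seed: int
    n_mag_like: int = 10
    n_wnt7a_like: int = 10
    n_null: int = 0
    n_decoy: int = 0
    length: int = 300
    gc: float = 0.45
    cassette_spec: str = "(c)3(c)"
    sox10_len: int = 16

    def __post_init__(self) -> None:
        for name in ("n_mag_like", "n_wnt7a_like", "n_null", "n_decoy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.length < 60:
            raise ValueError("regions shorter than 60 bp leave no room for planting")
        parse_oligo_spec(self.cassette_spec)


@dataclass(frozen=True)
class RegionSet:
    regions: tuple[Region, ...]
    truth: pd.DataFrame  # region_id, kind, true_class, cassette/sox10 coordinates


def generate_region_set(
    spec: RegionSetSpec,
    model: ConsensusModel | None = None,
) -> RegionSet:
    """Regions realising the regulatory scenarios, with exact truth files.

    ``mag_like``: Sox10 site + functional Myrf cassette -> co_activated.
    ``wnt7a_like``: Sox10 site, no Myrf site -> myrf_repressed.
    ``null``: neither -> non_responsive.
    ``decoy``: non-functional motif arrangements (single heptamers,
    off-phase or two-turn spacings), no Sox10 site -> non_responsive and
    never a strong cluster.
    """
    model = model or ConsensusModel()
    rng = np.random.default_rng(spec.seed)
    regions: list[Region] = []
    rows: list[dict] = []
    kinds = (
        ["mag_like"] * spec.n_mag_like
        + ["wnt7a_like"] * spec.n_wnt7a_like
        + ["null"] * spec.n_null
        + ["decoy"] * spec.n_decoy
    )
    for i, kind in enumerate(kinds):
        rid = f"{kind}_{i:03d}"
        sox_start = cass_start = cass_end = None
        cassette = None
        for attempt in range(50):
            sub = int(rng.integers(0, 2**31))
            try:
                background = generate_background(spec.length, spec.gc, seed=sub, model=model)
                if kind == "mag_like":
                    cassette = spec.cassette_spec
                elif kind == "decoy":
                    cassette = DECOY_SPECS[i % len(DECOY_SPECS)]
                else:
                    cassette = None
                if cassette is not None:
                    motifs, spacers = parse_oligo_spec(cassette)
                    core_len = 7 * len(motifs) + sum(spacers)
                    lo = spec.sox10_len + 24
                    hi = spec.length - core_len - 4
                    requested = int(rng.integers(lo, hi + 1))
                    seq, planted = _plant(background, cassette, requested, model, seed=sub)
                    cass_start = planted[0][0]
                    cass_end = cass_start + core_len
                else:
                    seq = background
                break
            except GenerationError:
                continue
        else:
            raise GenerationError(f"could not construct region {rid}")
        if kind in ("mag_like", "wnt7a_like"):
            sox_start = 4
            sox10_sites = ((sox_start, sox_start + spec.sox10_len),)
            true_class = "co_activated" if kind == "mag_like" else "myrf_repressed"
        else:
            sox10_sites = ()
            true_class = "non_responsive"
        regions.append(Region(id=rid, sequence=seq, sox10_sites=sox10_sites))
        rows.append(
            {
                "region_id": rid,
                "kind": kind,
                "true_class": true_class,
                "cassette_spec": cassette if kind in ("mag_like", "decoy") else "",
                "cassette_start": cass_start if cass_start is not None else -1,
                "cassette_end": cass_end if cass_end is not None else -1,
                "sox10_start": sox_start if sox_start is not None else -1,
                "sox10_end": sox_start + spec.sox10_len if sox_start is not None else -1,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "region_id", "kind", "true_class", "cassette_spec",
            "cassette_start", "cassette_end", "sox10_start", "sox10_end",
        ],
    )
    return RegionSet(regions=tuple(regions), truth=truth)


@dataclass(frozen=True)
class TriageSpec:
    """Planted Venn/stage cardinalities for synthetic triage tables.

    Defaults reproduce the full-scale study shape: 594 genes passing the
    DE filter, 203 of them peak-associated, partitioned 64/48/91 by
    stage lists.  ``n_peak_only`` (peak-associated genes failing the DE
    filter) and ``n_failing_de`` (DE rows failing the cutoffs) are free
    margins.
    """

    seed: int
    n_de: int = 594
    n_overlap: int = 203
    stage_counts: tuple[int, int, int] = (64, 48, 91)
    n_peak_only: int = 1500
    n_failing_de: int = 300
    n_extra_stage: int = 50
    fold_cutoff: float = 2.0
    p_cutoff: float = 0.05
    margin: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n_de, self.n_overlap, self.n_peak_only, self.n_failing_de,
               self.n_extra_stage, *self.stage_counts) < 0:
            raise ValueError("all counts must be >= 0")
        if self.n_overlap > self.n_de:
            raise ValueError(
                f"overlap ({self.n_overlap}) cannot exceed DE-passing count ({self.n_de})"
            )
        if sum(self.stage_counts) != self.n_overlap:
            raise ValueError(
                f"stage counts {self.stage_counts} must sum to the overlap ({self.n_overlap})"
            )
        if not 0 < self.margin < 1:
            raise ValueError("margin must lie in (0, 1)")


@dataclass(frozen=True)
class TriageSim:
    de: DeTable
    peaks: PeakGeneTable
    stages: StageLists
    truth_candidates: frozenset
    truth_partition: tuple[frozenset, frozenset, frozenset]  # opc, ol, unchanged


def generate_triage_tables(spec: TriageSpec) -> TriageSim:
    """Synthetic DE/peak/stage tables that reproduce their planted truth.

    Passing genes draw log2 fold changes and p-values strictly inside
    the passing region with a configurable margin from the cutoffs (and
    failing genes strictly outside it), so cutoff comparisons never sit
    on a floating-point boundary.
    """
    rng = np.random.default_rng(spec.seed)
    log2_cut = -np.log2(spec.fold_cutoff)
    m = spec.margin

    total_genes = spec.n_de + spec.n_peak_only + spec.n_failing_de + 2 * spec.n_extra_stage
    ids = [f"G{i:06d}" for i in range(total_genes)]
    pos = 0

    def take(n: int) -> list[str]:
        nonlocal pos
        out = ids[pos:pos + n]
        pos += n
        return out

    de_pass = take(spec.n_de)
    peak_only = take(spec.n_peak_only)
    de_fail = take(spec.n_failing_de)
    extra_opc = take(spec.n_extra_stage)
    extra_ol = take(spec.n_extra_stage)

    rows = []
    for g in de_pass:
        rows.append(
            {
                "gene_id": g,
                "log2fc": float(rng.uniform(-6.0, log2_cut * (1 + m))),
                "pvalue": float(rng.uniform(0.0, spec.p_cutoff * (1 - m))),
            }
        )
    # failing rows: peak-only genes with DE rows (half of them) plus dedicated failures
    failing = de_fail + peak_only[: spec.n_peak_only // 2]
    for g in failing:
        if rng.random() < 0.5:  # fail on fold change
            lfc = float(rng.uniform(log2_cut * (1 - m), 3.0))
            p = float(rng.uniform(0.0, 1.0))
        else:  # fail on p-value
            lfc = float(rng.uniform(-6.0, log2_cut * (1 + m)))
            p = float(rng.uniform(spec.p_cutoff * (1 + m), 1.0))
        rows.append({"gene_id": g, "log2fc": lfc, "pvalue": p})
    de = DeTable(pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue"]))

    overlap = de_pass[: spec.n_overlap]
    peak_genes = overlap + peak_only
    peak_rows = []
    for j, g in enumerate(peak_genes):
        start = 1000 * (j + 1)
        peak_rows.append(
            {"gene_id": g, "peak_id": f"peak{j:06d}", "chrom": "chr1",
             "start": start, "end": start + 200}
        )
    # a second peak for a few genes keeps the association many-to-many
    for j, g in enumerate(overlap[: min(10, len(overlap))]):
        start = 10_000_000 + 1000 * j
        peak_rows.append(
            {"gene_id": g, "peak_id": f"peakx{j:03d}", "chrom": "chr2",
             "start": start, "end": start + 200}
        )
    peaks = PeakGeneTable(
        pd.DataFrame(peak_rows, columns=["gene_id", "peak_id", "chrom", "start", "end"])
    )

    n_opc, n_ol, _ = spec.stage_counts
    opc = overlap[:n_opc]
    ol = overlap[n_opc:n_opc + n_ol]
    unchanged = overlap[n_opc + n_ol:]
    stages = StageLists(
        opc_enriched=frozenset(opc) | frozenset(extra_opc),
        ol_enriched=frozenset(ol) | frozenset(extra_ol),
    )
    return TriageSim(
        de=de,
        peaks=peaks,
        stages=stages,
        truth_candidates=frozenset(overlap),
        truth_partition=(frozenset(opc), frozenset(ol), frozenset(unchanged)),
    )
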
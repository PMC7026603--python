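"""Target-gene triage: DE filter ∩ peak-associated genes, stage partition.

Direct target candidates of Sox10 are defined as genes that lose
expression when Sox10 is inactivated (fold change at or below a cutoff
at a p-value cutoff) *and* carry a ChIP-Seq binding peak nearby.  The
candidates are then partitioned by stage-enriched expression lists into
precursor-specific (OPC), oligodendrocyte-specific and unchanged sets.

The module also carries the small quantification helpers: ΔΔCt
percent-of-input recovery for ChIP-qPCR and mean ± SEM fold induction
for reporter assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DeTable",
    "PeakGeneTable",
    "StageLists",
    "TriageResult",
    "StagePartition",
    "intersect_targets",
    "stage_classify",
    "chip_enrichment",
    "normalize_to_max",
    "fold_induction",
    "FoldInduction",
    "assign_nearest_gene",
]


@dataclass(frozen=True)
class DeTable:
    """Differential-expression table: one row per gene.

    ``log2fc`` is knockout vs control, so downregulated targets are
    negative; ``pvalue`` in [0, 1]; gene ids unique.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "pvalue"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        dupes = self.frame["gene_id"][self.frame["gene_id"].duplicated()].tolist()
        if dupes:
            raise ValueError(f"duplicate gene_ids in DE table: {sorted(set(dupes))}")
        p = self.frame["pvalue"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("pvalues must lie in [0, 1]")

    @classmethod
    def read_tsv(cls, path) -> "DeTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class PeakGeneTable:
    """Many-to-many peak-to-gene associations with peak intervals."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "peak_id", "chrom", "start", "end"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"peak table missing columns: {sorted(missing)}")
        bad = self.frame[self.frame["start"] >= self.frame["end"]]
        if len(bad):
            raise ValueError(
                f"malformed peak intervals (start >= end): {bad['peak_id'].tolist()[:5]}"
            )

    @classmethod
    def read_tsv(cls, path) -> "PeakGeneTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    @property
    def genes(self) -> frozenset:
        return frozenset(self.frame["gene_id"])


@dataclass(frozen=True)
class StageLists:
    """Stage-enriched gene lists; the two lists must be disjoint."""

    opc_enriched: frozenset
    ol_enriched: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "opc_enriched", frozenset(self.opc_enriched))
        object.__setattr__(self, "ol_enriched", frozenset(self.ol_enriched))
        both = self.opc_enriched & self.ol_enriched
        if both:
            raise ValueError(
                f"genes present in both stage lists: {sorted(both)[:5]}"
            )


@dataclass(frozen=True)
class TriageResult:
    candidates: frozenset
    de_only: int
    peak_only: int
    overlap: int

    @property
    def venn(self) -> tuple[int, int, int]:
        return (self.de_only, self.peak_only, self.overlap)


@dataclass(frozen=True)
class StagePartition:
    opc_specific: frozenset
    ol_specific: frozenset
    unchanged: frozenset

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.opc_specific), len(self.ol_specific), len(self.unchanged))


def intersect_targets(
    de: DeTable,
    peaks: PeakGeneTable,
    fold_cutoff: float = 2.0,
    p_cutoff: float = 0.05,
) -> TriageResult:
    """Candidate targets: genes passing the DE filter with >= 1 peak.

    The DE filter is fold change <= -*fold_cutoff* on the linear scale
    (log2fc <= -log2(fold_cutoff)) at p <= *p_cutoff*.  Also reports the
    Venn cardinalities: DE-only, peak-only, and the overlap.
    """
    if fold_cutoff <= 0:
        raise ValueError("fold_cutoff must be positive")
    df = de.frame
    passing = frozenset(
        df.loc[
            (df["log2fc"] <= -math.log2(fold_cutoff)) & (df["pvalue"] <= p_cutoff),
            "gene_id",
        ]
    )
    peak_genes = peaks.genes
    overlap = passing & peak_genes
    return TriageResult(
        candidates=overlap,
        de_only=len(passing - peak_genes),
        peak_only=len(peak_genes - passing),
        overlap=len(overlap),
    )


def stage_classify(candidates, stages: StageLists) -> StagePartition:
    """Partition candidate genes by stage-enriched expression.

    Membership is by lookup in the OPC-enriched and oligodendrocyte-
    enriched lists; genes in neither list are ``unchanged``.  The three
    sets are disjoint and their union is the candidate set.
    """
    if candidates is None:
        raise ValueError("candidates must not be None")
    candidates = frozenset(candidates)
    opc = candidates & stages.opc_enriched
    ol = candidates & stages.ol_enriched
    return StagePartition(
        opc_specific=opc,
        ol_specific=ol,
        unchanged=candidates - opc - ol,
    )


def chip_enrichment(ct_ip: float, ct_input: float, input_fraction: float = 1.0) -> float:
    """ΔΔCt percent-of-input recovery for one ChIP-qPCR measurement.

    The input Ct is first adjusted for the fraction of chromatin used as
    input (subtracting log2(1/input_fraction)); recovery is then
    ``100 * 2**(ct_input_adjusted - ct_ip)`` percent.  One extra IP
    cycle halves the recovery.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError(f"input_fraction must be in (0, 1], got {input_fraction}")
    if not (math.isfinite(ct_ip) and math.isfinite(ct_input)):
        raise ValueError("Ct values must be finite")
    adjusted_input = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted_input - ct_ip)


def normalize_to_max(values) -> np.ndarray:
    """Scale a vector of enrichments so the highest value is 1."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return arr
    m = np.nanmax(arr)
    if not m > 0:
        raise ValueError("maximum must be positive to normalize")
    return arr / m


def assign_nearest_gene(peaks: pd.DataFrame, tss: pd.DataFrame) -> PeakGeneTable:
    """Non-canonical convenience: assign each peak to the gene with the nearest TSS.

    ``peaks`` needs columns peak_id/chrom/start/end; ``tss`` needs
    gene_id/chrom/pos.  Distance is TSS to peak midpoint, per
    chromosome.  Provided for exploration only — canonical peak-to-gene
    associations should arrive as a finished table.
    """
    for col in ("peak_id", "chrom", "start", "end"):
        if col not in peaks.columns:
            raise ValueError(f"peaks missing column {col!r}")
    for col in ("gene_id", "chrom", "pos"):
        if col not in tss.columns:
            raise ValueError(f"tss missing column {col!r}")
    rows = []
    for chrom, chunk in peaks.groupby("chrom"):
        genes = tss[tss["chrom"] == chrom]
        if genes.empty:
            continue
        mid = ((chunk["start"] + chunk["end"]) // 2).to_numpy()
        dist = np.abs(genes["pos"].to_numpy()[None, :] - mid[:, None])
        nearest = genes["gene_id"].to_numpy()[dist.argmin(axis=1)]
        for (_, peak), gene in zip(chunk.iterrows(), nearest):
            rows.append(
                {
                    "gene_id": gene,
                    "peak_id": peak["peak_id"],
                    "chrom": chrom,
                    "start": peak["start"],
                    "end": peak["end"],
                }
            )
    return PeakGeneTable(pd.DataFrame(rows, columns=["gene_id", "peak_id", "chrom", "start", "end"]))


@dataclass(frozen=True)
class FoldInduction:
    mean: float
    sem: float  # NaN when only one replicate
    n: int
    ratios: tuple[float, ...]


def fold_induction(with_effector, without_effector) -> FoldInduction:
    """Mean ± SEM of per-replicate activity ratios (baseline set to 1).

    Replicates are paired; each ratio is activity with effector divided
    by the matched baseline.  The no-effector condition reports exactly
    1 with SEM 0 by convention (ratios of a condition against itself).
    A single replicate pair reports SEM as NaN.
    """
    eff = np.asarray(with_effector, dtype=float)
    base = np.asarray(without_effector, dtype=float)
    if eff.size == 0 or eff.shape != base.shape:
        raise ValueError("need >= 1 paired replicate activities of equal length")
    if (base <= 0).any():
        raise ValueError("baseline activities must be positive")
    ratios = eff / base
    sem = float(stats.sem(ratios)) if ratios.size > 1 else float("nan")
    return FoldInduction(
        mean=float(ratios.mean()),
        sem=sem,
        n=int(ratios.size),
        ratios=tuple(float(r) for r in ratios),
    )
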
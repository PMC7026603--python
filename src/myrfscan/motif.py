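"""Myrf heptamer consensus model and single-motif matching.

The Myrf DNA-binding domain recognises the heptamer 5'-CTGGYAC-3'
(IUPAC Y = C or T).  High-affinity binding requires two such heptamers
in defined spacing (see :mod:`myrfscan.scanner`); this module holds the
grammar parameters — per-position mismatch penalties calibrated against
qualitative in-vitro binding outcomes — and the elementary operations on
a single heptamer window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ConsensusModel",
    "MotifMatch",
    "InvalidSequenceError",
    "match_heptamer",
    "apply_position_mutation",
    "reverse_complement",
    "validate_dna",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: purine -> non-complementary pyrimidine and vice versa
_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside the expected alphabet."""


def validate_dna(seq: str, *, alphabet: str = "ACGT", context: str = "sequence") -> str:
    """Uppercase *seq* and verify every character is in *alphabet*.

    Raises :class:`InvalidSequenceError` naming the first offending
    1-based position.
    """
    seq = seq.upper()
    allowed = set(alphabet)
    for i, base in enumerate(seq):
        if base not in allowed:
            raise InvalidSequenceError(
                f"invalid character {base!r} at position {i + 1} of {context} "
                f"(allowed: {alphabet})"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (accepts IUPAC degeneracy codes)."""
    seq = validate_dna(seq, alphabet="ACGTRYSWKMBDHVN")
    return seq.translate(_COMPLEMENT)[::-1]


def apply_position_mutation(motif: str, position: int) -> str:
    """Mutate one motif position: purine -> non-complementary pyrimidine and vice versa.

    The substitution map is A->C, C->A, G->T, T->G; *position* is 1-based
    within the motif.  The mutated base never satisfies the consensus at
    that position (including the degenerate position 5, where C->A and
    T->G both leave Y unmatched).
    """
    motif = validate_dna(motif, context="motif")
    if not 1 <= position <= len(motif):
        raise ValueError(
            f"position {position} out of range 1..{len(motif)} for motif {motif!r}"
        )
    i = position - 1
    return motif[:i] + _TRANSVERSION[motif[i]] + motif[i + 1:]


@dataclass(frozen=True)
class ConsensusModel:
    """Grammar parameters for composite Myrf site recognition.

    Parameters
    ----------
    pattern:
        7-symbol IUPAC consensus, default ``CTGGYAC``.
    position_penalties:
        Mismatch penalty per motif position 1..7.  Defaults are
        calibrated so that, summed over a composite site and compared to
        the thresholds, they reproduce the qualitative binding classes
        of the in-vitro mutagenesis panel: position 4 is nearly neutral,
        position 1 mild, positions 2/3/5/6 intermediate, position 7
        disruptive.
    allowed_spacers_high_affinity:
        Spacer lengths (bp strictly between the two heptamers) that
        support high-affinity binding; {3, 7} correspond to centre
        distances of 10 bp (one helical turn) and 14 bp (1.5 turns).
    candidate_spacer_range:
        Inclusive spacer interval used when searching genomic sequence
        for *candidate* sites (1 to 1.5 helical turns).
    max_total_mismatches:
        Mismatch budget, applied both per heptamer and summed over the
        two heptamers of a composite site.
    strong_threshold, weak_threshold:
        Total-penalty cutoffs separating strong / weak / no binding.
    """

    pattern: str = "CTGGYAC"
    position_penalties: tuple[float, ...] = (1.0, 2.0, 2.0, 0.5, 2.0, 2.0, 5.0)
    allowed_spacers_high_affinity: frozenset[int] = frozenset({3, 7})
    candidate_spacer_range: tuple[int, int] = (3, 8)
    max_total_mismatches: int = 2
    strong_threshold: float = 0.5
    weak_threshold: float = 2.0

    def __post_init__(self) -> None:
        pattern = validate_dna(self.pattern, alphabet="ACGTRYSWKMBDHVN", context="pattern")
        object.__setattr__(self, "pattern", pattern)
        object.__setattr__(self, "position_penalties", tuple(float(p) for p in self.position_penalties))
        object.__setattr__(
            self, "allowed_spacers_high_affinity",
            frozenset(int(s) for s in self.allowed_spacers_high_affinity),
        )
        object.__setattr__(
            self, "candidate_spacer_range",
            (int(self.candidate_spacer_range[0]), int(self.candidate_spacer_range[1])),
        )
        if len(self.pattern) != 7:
            raise ValueError(f"pattern must be 7 symbols, got {len(self.pattern)}")
        if len(self.position_penalties) != 7:
            raise ValueError("position_penalties must have 7 entries")
        if any(p < 0 for p in self.position_penalties):
            raise ValueError("penalties must be non-negative")
        if not self.allowed_spacers_high_affinity:
            raise ValueError("allowed_spacers_high_affinity must be non-empty")
        lo, hi = self.candidate_spacer_range
        if lo > hi:
            raise ValueError("candidate_spacer_range must be a non-empty interval")
        if self.max_total_mismatches < 0:
            raise ValueError("max_total_mismatches must be >= 0")
        if not self.strong_threshold < self.weak_threshold:
            raise ValueError("strong_threshold must be < weak_threshold")

    @property
    def length(self) -> int:
        return len(self.pattern)

    def allowed_bases(self, position: int) -> frozenset[str]:
        """Bases matching the consensus at 1-based *position* with zero penalty."""
        return IUPAC[self.pattern[position - 1]]

    def penalty_of(self, mismatch_positions) -> float:
        return float(sum(self.position_penalties[p - 1] for p in mismatch_positions))

    # -- flat config (de)serialisation -------------------------------------

    def to_config(self) -> dict[str, str]:
        lo, hi = self.candidate_spacer_range
        return {
            "pattern": self.pattern,
            "position_penalties": ",".join(_fmt(p) for p in self.position_penalties),
            "allowed_spacers_high_affinity": ",".join(
                str(s) for s in sorted(self.allowed_spacers_high_affinity)
            ),
            "candidate_spacer_min": str(lo),
            "candidate_spacer_max": str(hi),
            "max_total_mismatches": str(self.max_total_mismatches),
            "strong_threshold": _fmt(self.strong_threshold),
            "weak_threshold": _fmt(self.weak_threshold),
        }

    @classmethod
    def from_config(cls, cfg: dict[str, str]) -> "ConsensusModel":
        known = {
            "pattern", "position_penalties", "allowed_spacers_high_affinity",
            "candidate_spacer_min", "candidate_spacer_max",
            "max_total_mismatches", "strong_threshold", "weak_threshold",
        }
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        if "pattern" in cfg:
            kwargs["pattern"] = str(cfg["pattern"])
        if "position_penalties" in cfg:
            kwargs["position_penalties"] = tuple(
                float(x) for x in str(cfg["position_penalties"]).split(",")
            )
        if "allowed_spacers_high_affinity" in cfg:
            kwargs["allowed_spacers_high_affinity"] = frozenset(
                int(x) for x in str(cfg["allowed_spacers_high_affinity"]).split(",")
            )
        lo = cfg.get("candidate_spacer_min")
        hi = cfg.get("candidate_spacer_max")
        if lo is not None or hi is not None:
            default = cls.__dataclass_fields__["candidate_spacer_range"].default
            kwargs["candidate_spacer_range"] = (
                int(lo) if lo is not None else default[0],
                int(hi) if hi is not None else default[1],
            )
        if "max_total_mismatches" in cfg:
            kwargs["max_total_mismatches"] = int(cfg["max_total_mismatches"])
        if "strong_threshold" in cfg:
            kwargs["strong_threshold"] = float(cfg["strong_threshold"])
        if "weak_threshold" in cfg:
            kwargs["weak_threshold"] = float(cfg["weak_threshold"])
        return cls(**kwargs)


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass(frozen=True)
class MotifMatch:
    """One heptamer occurrence on either strand.

    ``start`` is the 0-based forward-strand offset of the window's first
    base; ``mismatch_positions`` are 1-based positions 5'->3' within the
    motif itself, regardless of strand; ``center`` is the forward-strand
    coordinate of the heptamer's central base (start + 3), the reference
    point for composite-site spacing.
    """

    sequence_id: str
    start: int
    strand: str
    mismatch_positions: tuple[int, ...]
    penalty: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def center(self) -> int:
        return self.start + 3

    @property
    def end(self) -> int:
        return self.start + 7

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)

    @property
    def signature(self) -> str:
        """Human-readable mismatch signature, e.g. ``consensus`` or ``mm4,7``."""
        if not self.mismatch_positions:
            return "consensus"
        return "mm" + ",".join(str(p) for p in self.mismatch_positions)


def match_heptamer(
    window: str,
    model: ConsensusModel | None = None,
    *,
    sequence_id: str = "",
    start: int = 0,
    strand: str = "+",
) -> MotifMatch | None:
    """Match one 7-base window against the consensus.

    Returns a :class:`MotifMatch` (mismatch positions in motif-local
    coordinates, penalty summed from the model's position weights), or
    ``None`` when the mismatch count exceeds the model's budget.  The
    window is read 5'->3' of the motif: for a minus-strand candidate pass
    the reverse complement of the forward-strand window.
    """
    model = model or ConsensusModel()
    window = validate_dna(window, context="window")
    if len(window) != model.length:
        raise ValueError(f"window must be {model.length} bases, got {len(window)}")
    mismatches = tuple(
        p for p in range(1, model.length + 1)
        if window[p - 1] not in model.allowed_bases(p)
    )
    if len(mismatches) > model.max_total_mismatches:
        return None
    return MotifMatch(
        sequence_id=sequence_id,
        start=start,
        strand=strand,
        mismatch_positions=mismatches,
        penalty=model.penalty_of(mismatches),
    )
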
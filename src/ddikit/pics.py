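"""The PICS data-analysis cascade.

PICS (Proteomic Identification of protease Cleavage Sites) exposes a
blocked, proteome-derived peptide library to a test protease; newly
created peptide N-termini are biotinylated, enriched and sequenced.
This module turns the resulting identification lists into a substrate
specificity matrix:

1. keep peptides carrying the biotinylation-derived N-terminal label;
2. confidence-filter (strict "over" thresholds: lenient for control
   runs so the background they capture is as complete as possible);
3. subtract background peptides seen in the mock reaction, the
   inactive-mutant reaction, or the unprocessed library;
4. map each surviving peptide back onto the proteome by exact substring
   search to reconstruct the four P residues preceding the cut
   (the four P' residues come from the MS peptide itself);
5. count amino-acid frequencies at P4..P1, P1'..P4'.

Peptides whose proteome occurrences disagree on the preceding
tetrapeptide contribute their P'-side only (configurable to drop them
entirely), since the P side cannot be assigned unambiguously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from ddikit.config import RunConfig
    from ddikit.io import SequenceRecord

logger = logging.getLogger("ddikit")

RUN_LABELS = frozenset({"test", "mock", "inactive", "library"})

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

POSITIONS = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")


class EmptyResultError(ValueError):
    """The cascade produced no cleavage windows."""


@dataclass(frozen=True)
class IdentifiedPeptide:
    """One MS-identified peptide: the atom of the PICS cascade."""

    sequence: str
    confidence: float
    nterm_labeled: bool
    run_label: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.run_label not in RUN_LABELS:
            raise ValueError(f"unknown run_label {self.run_label!r}")


@dataclass(frozen=True)
class CleavageWindow:
    """A reconstructed P4-P4' window around one cleavage site.

    The P'-side always comes from the MS peptide; the P-side is inferred
    computationally from the proteome and may be unknown (ambiguous or
    too close to the protein N-terminus).
    """

    p_side: str | None  # P4 P3 P2 P1, or None if unknown
    p_prime_side: str  # P1' P2' P3' P4'
    peptide: str
    protein_id: str | None
    p1_position: int | None  # 1-based position of P1 in the protein

    def __post_init__(self) -> None:
        if len(self.p_prime_side) != 4:
            raise ValueError("p_prime_side must be exactly 4 residues")
        if self.p_side is not None and len(self.p_side) != 4:
            raise ValueError("p_side must be exactly 4 residues or None")


@dataclass
class SpecificityMatrix:
    """Per-position amino-acid counts/frequencies over cleavage windows."""

    counts: pd.DataFrame  # index = POSITIONS, columns = 20 amino acids

    @property
    def position_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.position_counts.replace(0, np.nan)
        return self.counts.div(totals, axis=0).fillna(0.0)

    def argmax(self, position: str) -> str:
        return str(self.frequencies.loc[position].idxmax())

    def to_dict(self) -> dict:
        return {
            "positions": list(POSITIONS),
            "amino_acids": list(AMINO_ACIDS),
            "counts": self.counts.to_dict(orient="index"),
            "frequencies": self.frequencies.round(6).to_dict(orient="index"),
        }


def filter_labeled(peptides: Sequence[IdentifiedPeptide]) -> list[IdentifiedPeptide]:
    """Keep only peptides with a labeled (biotinylation-derived) N-terminus."""
    kept = [p for p in peptides if p.nterm_labeled]
    if peptides and not kept:
        logger.warning("filter_labeled: no labeled peptides survive")
    return kept


def threshold_filter(
    peptides: Sequence[IdentifiedPeptide],
    test_min: float = 0.8,
    control_min: float = 0.1,
    strict: bool = True,
) -> list[IdentifiedPeptide]:
    """Confidence filter: test runs against ``test_min``, control runs
    (mock/inactive/library) against ``control_min``.

    ``strict=True`` reads the thresholds as "over" (strict inequality),
    so a test peptide at exactly 0.80 is removed.
    """
    if not 0.0 <= test_min <= 1.0 or not 0.0 <= control_min <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")

    def keep(p: IdentifiedPeptide) -> bool:
        cut = test_min if p.run_label == "test" else control_min
        return p.confidence > cut if strict else p.confidence >= cut

    return [p for p in peptides if keep(p)]


def subtract_background(
    test: Sequence[IdentifiedPeptide],
    mock: Sequence[IdentifiedPeptide],
    inactive: Sequence[IdentifiedPeptide],
    library: Sequence[IdentifiedPeptide],
) -> list[IdentifiedPeptide]:
    """Remove test peptides whose sequence occurs in any control list.

    Matching is by exact sequence string; modifications are not compared.
    """
    background = {p.sequence for p in mock} | {p.sequence for p in inactive} | {
        p.sequence for p in library
    }
    return [p for p in test if p.sequence not in background]


def _occurrences(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) 0-based match starts."""
    out, start = [], haystack.find(needle)
    while start != -1:
        out.append(start)
        start = haystack.find(needle, start + 1)
    return out


def map_cleavage_sites(
    peptides: Sequence[IdentifiedPeptide],
    proteome: Sequence["SequenceRecord"],
    deduplicate: bool = True,
    ambiguous_p_side: str = "p_prime_only",
) -> list[CleavageWindow]:
    """Locate each peptide in the proteome and reconstruct its P4-P4' window.

    * occurrences agreeing on one preceding tetrapeptide -> known P side;
    * disagreeing occurrences, or occurrences starting within the first
      four residues of a protein -> P side unknown (or the peptide is
      dropped entirely when ``ambiguous_p_side="drop"``);
    * peptides not found anywhere, or shorter than the four P' residues,
      are dropped with a warning.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    if ambiguous_p_side not in ("p_prime_only", "drop"):
        raise ValueError(f"bad ambiguous_p_side {ambiguous_p_side!r}")

    sequences: list[str] = []
    seen: set[str] = set()
    for p in peptides:
        if deduplicate:
            if p.sequence in seen:
                continue
            seen.add(p.sequence)
        sequences.append(p.sequence)

    windows: list[CleavageWindow] = []
    for seq in sequences:
        if len(seq) < 4:
            logger.warning("map_cleavage_sites: peptide %r shorter than 4 residues, dropped", seq)
            continue
        hits: list[tuple[str, int]] = []  # (protein id, 0-based start)
        for protein in proteome:
            hits.extend((protein.identifier, s) for s in _occurrences(protein.residues, seq))
        if not hits:
            logger.warning("map_cleavage_sites: peptide %r not found in proteome, dropped", seq)
            continue
        by_id = {p.identifier: p.residues for p in proteome}
        candidates = {
            (pid, start): by_id[pid][start - 4 : start] for pid, start in hits if start >= 4
        }
        distinct = sorted(set(candidates.values()))
        if len(distinct) == 1:
            pid, start = next(k for k, v in candidates.items() if v == distinct[0])
            windows.append(
                CleavageWindow(
                    p_side=distinct[0],
                    p_prime_side=seq[:4],
                    peptide=seq,
                    protein_id=pid,
                    p1_position=start,  # 1-based position of the residue before start
                )
            )
        else:
            # zero usable occurrences (all near a protein N-terminus) or
            # conflicting preceding tetrapeptides
            if distinct and ambiguous_p_side == "drop":
                continue
            pid, start = hits[0]
            windows.append(
                CleavageWindow(
                    p_side=None,
                    p_prime_side=seq[:4],
                    peptide=seq,
                    protein_id=pid if len(hits) == 1 else None,
                    p1_position=start if len(hits) == 1 else None,
                )
            )
    return windows


def build_specificity_matrix(windows: Sequence[CleavageWindow]) -> SpecificityMatrix:
    """Per-position amino-acid frequency table over the given windows.

    Windows with unknown P side are excluded from the P4..P1 denominators
    only; their P' residues still count.
    """
    if not windows:
        raise EmptyResultError("no cleavage windows to build a specificity matrix from")
    counts = pd.DataFrame(0, index=list(POSITIONS), columns=list(AMINO_ACIDS), dtype=int)
    for w in windows:
        if w.p_side is not None:
            for pos, aa in zip(POSITIONS[:4], w.p_side):
                if aa in AMINO_ACIDS:
                    counts.loc[pos, aa] += 1
        for pos, aa in zip(POSITIONS[4:], w.p_prime_side):
            if aa in AMINO_ACIDS:
                counts.loc[pos, aa] += 1
    return SpecificityMatrix(counts=counts)


@dataclass
class PicsResult:
    matrix: SpecificityMatrix | None
    report: dict = field(default_factory=dict)


def run_pics(
    test: Sequence[IdentifiedPeptide],
    mock: Sequence[IdentifiedPeptide],
    inactive: Sequence[IdentifiedPeptide],
    library: Sequence[IdentifiedPeptide],
    proteome: Sequence["SequenceRecord"],
    config: "RunConfig | None" = None,
) -> PicsResult:
    """Run the full cascade in printed order and log survivor counts.

    Stage order: label filter -> confidence filter -> background
    subtraction -> proteome mapping -> frequency matrix. The report
    records the count surviving each stage; an empty final window list
    yields ``matrix=None`` with the error noted in the report.
    """
    from ddikit.config import RunConfig  # local import to avoid a cycle

    cfg = config or RunConfig()
    report: dict = {"input_counts": {
        "test": len(test), "mock": len(mock),
        "inactive": len(inactive), "library": len(library),
    }}

    lists = {"test": list(test), "mock": list(mock), "inactive": list(inactive), "library": list(library)}
    lists = {k: filter_labeled(v) for k, v in lists.items()}
    report["after_label_filter"] = {k: len(v) for k, v in lists.items()}

    lists = {
        k: threshold_filter(
            v, cfg.test_confidence_min, cfg.control_confidence_min, cfg.strict_thresholds
        )
        for k, v in lists.items()
    }
    report["after_confidence_filter"] = {k: len(v) for k, v in lists.items()}

    cleared = subtract_background(lists["test"], lists["mock"], lists["inactive"], lists["library"])
    report["after_background_subtraction"] = len(cleared)

    windows = map_cleavage_sites(
        cleared, proteome, deduplicate=cfg.deduplicate_peptides,
        ambiguous_p_side=cfg.ambiguous_p_side,
    )
    report["windows"] = len(windows)
    report["windows_with_known_p_side"] = sum(1 for w in windows if w.p_side is not None)

    if not windows:
        report["error"] = "no cleavage windows survived the cascade"
        logger.warning("run_pics: %s", report["error"])
        return PicsResult(matrix=None, report=report)
    return PicsResult(matrix=build_specificity_matrix(windows), report=report)
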
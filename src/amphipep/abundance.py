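"""riBAQ protein abundance and peptide-level molar recovery estimates.

iBAQ divides a protein's summed MS1 intensity by its count of theoretical
tryptic peptides of length 6-30; riBAQ renormalizes iBAQ values to sum to 1
per sample, approximating the relative molar distribution of proteins. The
maximum molar recovery of a peptide is then the riBAQ sum over proteins
containing it (exact tier) or a near-identical variant of it (homolog tier).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .digestion import TRYPSIN, CleavageRule, theoretical_peptide_count
from .seqio import ProteinRecord, ValidationError

logger = logging.getLogger(__name__)


def compute_ribaq(
    intensities: dict[str, float],
    sequences: dict[str, str],
    rule: CleavageRule = TRYPSIN,
    min_len: int = 6,
    max_len: int = 30,
) -> dict[str, float]:
    """Protein id -> riBAQ fraction (sums to 1).

    Proteins with zero theoretical peptides are excluded with a warning.
    """
    ibaq: dict[str, float] = {}
    for pid, intensity in intensities.items():
        if pid not in sequences:
            raise ValidationError(f"no sequence for quantified protein {pid!r}")
        if intensity < 0:
            raise ValidationError(f"negative intensity for {pid!r}")
        count = theoretical_peptide_count(sequences[pid], rule, min_len, max_len)
        if count == 0:
            logger.warning("protein %s has no theoretical peptides in [%d, %d]; excluded",
                           pid, min_len, max_len)
            continue
        ibaq[pid] = intensity / count
    total = sum(ibaq.values())
    if total <= 0:
        raise ValidationError("total iBAQ is zero; nothing to normalize")
    return {pid: v / total for pid, v in ibaq.items()}


def normalize_ribaq(values: dict[str, float]) -> dict[str, float]:
    """Renormalize precomputed riBAQ-like values to sum to 1."""
    total = sum(values.values())
    if total <= 0:
        raise ValidationError("riBAQ values sum to zero")
    if any(v < 0 for v in values.values()):
        raise ValidationError("riBAQ values must be non-negative")
    return {k: v / total for k, v in values.items()}


def window_identity(peptide: str, protein: str) -> float:
    """Best ungapped-window identity of the peptide against the protein.

    Maximum over all windows of (identical positions / peptide length);
    0 when the peptide is longer than the protein.
    """
    w = len(peptide)
    if w == 0 or w > len(protein):
        return 0.0
    best = 0
    for off in range(len(protein) - w + 1):
        ident = sum(1 for a, b in zip(peptide, protein[off : off + w]) if a == b)
        if ident > best:
            best = ident
            if best == w:
                break
    return best / w


@dataclass(frozen=True)
class PeptideAbundance:
    peptide: str
    exact_match_ribaq: float
    homolog_ribaq: float  # includes the exact tier
    exact_proteins: tuple[str, ...]
    homolog_proteins: tuple[str, ...]


def peptide_abundance(
    peptide: str,
    proteome: list[ProteinRecord],
    abundances: dict[str, float],
    homolog_threshold: float = 0.90,
) -> PeptideAbundance:
    """Summed riBAQ of proteins carrying the peptide.

    Exact tier: window identity of 1.0. Homolog tier: identity strictly above
    ``homolog_threshold`` (a superset of the exact tier). Quantified proteins
    absent from the proteome are excluded with a warning.
    """
    by_id = {rec.id: rec for rec in proteome}
    exact: list[str] = []
    homolog: list[str] = []
    for pid, ribaq in abundances.items():
        rec = by_id.get(pid)
        if rec is None:
            logger.warning("quantified protein %s not in proteome; excluded", pid)
            continue
        ident = window_identity(peptide, rec.sequence)
        if ident == 1.0:
            exact.append(pid)
        if ident > homolog_threshold:
            homolog.append(pid)
    return PeptideAbundance(
        peptide=peptide,
        exact_match_ribaq=sum(abundances[p] for p in exact),
        homolog_ribaq=sum(abundances[p] for p in homolog),
        exact_proteins=tuple(sorted(exact)),
        homolog_proteins=tuple(sorted(homolog)),
    )
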
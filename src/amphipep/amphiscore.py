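"""The three raw amphiphilicity scores.

All three are magnitudes of summed per-residue hydrophobicity contributions,
with the summation index starting at 1:

* helical score: residue n contributes at angle n * 100 degrees (5/9 pi),
  the turn per residue of an alpha helix; the score is the Euclidean norm
  of the resulting 2-D moment vector.
* strand score: residue n contributes at angle n * 180 degrees; equivalently
  the absolute alternating sum of hydrophobicity values.
* block score: the sequence is split after position k and the score is the
  absolute difference of the two segment sums, maximized over k (ties go to
  the smallest k).

Raw scores grow with peptide length; length correction is done exclusively
by the z-normalization in :mod:`amphipep.background`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .physchem import HydrophobicityScale, load_scale
from .seqio import ValidationError

ALPHA_ANGLE = 5.0 * math.pi / 9.0  # 100 degrees per residue
SCORE_TYPES = ("alpha", "beta", "gamma")


@dataclass(frozen=True)
class RawScore:
    score_type: str
    value: float
    split_k: int | None = None  # block score only: 1-based end of first segment

    def __post_init__(self) -> None:
        if self.score_type not in SCORE_TYPES:
            raise ValidationError(f"unknown score type {self.score_type!r}")
        if self.value < 0:
            raise ValidationError("raw scores are magnitudes and must be >= 0")


def _kd_vector(peptide: str, scale: HydrophobicityScale) -> np.ndarray:
    try:
        return np.array([scale[aa] for aa in peptide], dtype=float)
    except KeyError as exc:
        raise ValidationError(str(exc)) from None


def alpha_raw(peptide: str, scale: HydrophobicityScale | None = None) -> RawScore:
    """Helical-wheel moment: norm of sum K(aa_n)*(cos n*100deg, sin n*100deg)."""
    if not peptide:
        raise ValidationError("empty peptide")
    k = _kd_vector(peptide, scale or load_scale())
    n = np.arange(1, len(peptide) + 1)
    theta = n * ALPHA_ANGLE
    value = math.hypot(float(k @ np.cos(theta)), float(k @ np.sin(theta)))
    return RawScore("alpha", value)


def beta_raw(peptide: str, scale: HydrophobicityScale | None = None) -> RawScore:
    """Strand moment at 180 degrees per residue: |sum (-1)^n K(aa_n)|."""
    if not peptide:
        raise ValidationError("empty peptide")
    k = _kd_vector(peptide, scale or load_scale())
    signs = (-1.0) ** np.arange(1, len(peptide) + 1)
    return RawScore("beta", abs(float(k @ signs)))


def gamma_raw(peptide: str, scale: HydrophobicityScale | None = None) -> RawScore:
    """Two-block amphiphilicity: max over splits k of
    |sum_{n<=k} K(aa_n) - sum_{m>k} K(aa_m)|, with the argmax split recorded.
    """
    if len(peptide) < 2:
        raise ValidationError("block score needs length >= 2")
    k = _kd_vector(peptide, scale or load_scale())
    cs = np.cumsum(k)
    diffs = np.abs(2.0 * cs[:-1] - cs[-1])
    # smallest k on ties, robust to cumsum rounding noise
    split = int(np.argmax(diffs >= diffs.max() - 1e-9)) + 1
    return RawScore("gamma", float(diffs[split - 1]), split_k=split)


def score_all(peptide: str, scale: HydrophobicityScale | None = None) -> dict[str, RawScore]:
    scale = scale or load_scale()
    return {
        "alpha": alpha_raw(peptide, scale),
        "beta": beta_raw(peptide, scale),
        "gamma": gamma_raw(peptide, scale),
    }


# ---------------------------------------------------------------------------
# vectorized batch scoring (used for background sampling and bulk prediction)


def batch_scores(kmat: np.ndarray) -> dict[str, np.ndarray]:
    """Score a (n_peptides, length) matrix of hydrophobicity values.

    Returns raw score arrays for all three types, plus the block argmax splits
    under ``"gamma_split"``.
    """
    n_pep, w = kmat.shape
    n = np.arange(1, w + 1)
    theta = n * ALPHA_ANGLE
    alpha = np.hypot(kmat @ np.cos(theta), kmat @ np.sin(theta))
    beta = np.abs(kmat @ ((-1.0) ** n))
    cs = np.cumsum(kmat, axis=1)
    diffs = np.abs(2.0 * cs[:, :-1] - cs[:, -1:])
    top = diffs.max(axis=1, keepdims=True)
    split = (diffs >= top - 1e-9).argmax(axis=1) + 1  # smallest k on ties
    gamma = np.take_along_axis(diffs, split[:, None] - 1, axis=1)[:, 0]
    return {"alpha": alpha, "beta": beta, "gamma": gamma, "gamma_split": split}


def kd_matrix(peptides: list[str], scale: HydrophobicityScale | None = None) -> np.ndarray:
    """Stack equal-length peptides into a hydrophobicity matrix."""
    scale = scale or load_scale()
    if not peptides:
        return np.empty((0, 0))
    w = len(peptides[0])
    if any(len(p) != w for p in peptides):
        raise ValidationError("kd_matrix requires equal-length peptides")
    lut = np.full(128, np.nan)
    for aa, v in scale.values.items():
        lut[ord(aa)] = v
    codes = np.frombuffer("".join(peptides).encode("ascii"), dtype=np.uint8).reshape(-1, w)
    mat = lut[codes]
    if np.isnan(mat).any():
        raise ValidationError("non-canonical residue in batch")
    return mat
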
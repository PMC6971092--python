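"""Random-peptide score backgrounds and z-normalization.

For each (score type, length) a null distribution is estimated from random
peptides drawn i.i.d. from an average proteome composition. The helical and
strand nulls use the score formulas themselves. The two-block null is the
absolute block difference evaluated at the central split (k = floor(w/2)):
a random peptide provides a length-matched null for a hydrophobic/hydrophilic
divide at a given position, while taking the best split of every random
peptide would measure an extreme-value statistic on a different scale.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from . import amphiscore
from .physchem import HydrophobicityScale, load_scale
from .seqio import CANONICAL, ValidationError

DEFAULT_N = 40_000
DEFAULT_SEED = 20_20
DEFAULT_LENGTHS = range(7, 31)
DEFAULT_COMPOSITION = "swissprot_legacy"


@dataclass(frozen=True)
class CompositionTable:
    """Relative residue frequencies over the 20 canonical residues."""

    name: str
    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.frequencies) != CANONICAL:
            raise ValidationError(
                f"composition {self.name!r} must cover exactly the 20 canonical residues"
            )
        if any(v <= 0 for v in self.frequencies.values()):
            raise ValidationError(f"composition {self.name!r} has non-positive frequencies")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"composition {self.name!r} does not sum to 1 (got {total})")

    @property
    def residues(self) -> list[str]:
        return sorted(self.frequencies)

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([self.frequencies[r] for r in self.residues])


def load_composition(name: str = DEFAULT_COMPOSITION, path: str | Path | None = None) -> CompositionTable:
    p = Path(path) if path is not None else Path(
        str(resources.files("amphipep").joinpath("data", f"composition_{name}.tsv"))
    )
    if not p.exists():
        raise ValidationError(f"unknown composition {name!r} ({p} not found)")
    freqs: dict[str, float] = {}
    with open(p) as fh:
        lines = [r for r in fh if r.strip() and not r.startswith("#")]
    for row in csv.DictReader(lines, delimiter="\t"):
        freqs[row["residue"]] = float(row["frequency"])
    total = sum(freqs.values())
    freqs = {k: v / total for k, v in freqs.items()}
    return CompositionTable(name=name, frequencies=freqs)


@dataclass(frozen=True)
class BackgroundModel:
    score_type: str
    length: int
    mean: float
    sd: float
    n_samples: int
    seed: int
    composition_name: str

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValidationError("background SD must be positive")


def _rng_for(seed: int, length: int) -> np.random.Generator:
    # one stream per length so a partial build matches the full build
    return np.random.default_rng([seed, length])


def random_peptides(
    length: int,
    n: int,
    composition: CompositionTable | None = None,
    seed: int = DEFAULT_SEED,
) -> list[str]:
    """Draw ``n`` i.i.d. random peptides of the given length."""
    if n < 0 or length < 1:
        raise ValidationError("need n >= 0 and length >= 1")
    composition = composition or load_composition()
    rng = _rng_for(seed, length)
    idx = rng.choice(len(composition.residues), size=(n, length), p=composition.probabilities)
    letters = np.array(list(composition.residues))
    return ["".join(row) for row in letters[idx]]


def _sample_kd(
    length: int,
    n: int,
    composition: CompositionTable,
    scale: HydrophobicityScale,
    seed: int,
) -> np.ndarray:
    rng = _rng_for(seed, length)
    idx = rng.choice(len(composition.residues), size=(n, length), p=composition.probabilities)
    kvals = np.array([scale[r] for r in composition.residues])
    return kvals[idx]


def null_scores(kmat: np.ndarray) -> dict[str, np.ndarray]:
    """Null score samples for a (n, w) hydrophobicity matrix.

    Helical/strand nulls are the raw scores; the block null is the absolute
    block difference at the central split.
    """
    w = kmat.shape[1]
    batch = amphiscore.batch_scores(kmat)
    cs = np.cumsum(kmat, axis=1)
    mid = w // 2
    gamma_null = np.abs(2.0 * cs[:, mid - 1] - cs[:, -1])
    return {"alpha": batch["alpha"], "beta": batch["beta"], "gamma": gamma_null}


def build_background(
    lengths=DEFAULT_LENGTHS,
    n: int = DEFAULT_N,
    composition: CompositionTable | None = None,
    seed: int = DEFAULT_SEED,
    scale: HydrophobicityScale | None = None,
) -> dict[tuple[str, int], BackgroundModel]:
    """Build one BackgroundModel per (score type, length)."""
    composition = composition or load_composition()
    scale = scale or load_scale()
    models: dict[tuple[str, int], BackgroundModel] = {}
    for w in lengths:
        kmat = _sample_kd(w, n, composition, scale, seed)
        for stype, sample in null_scores(kmat).items():
            models[(stype, w)] = BackgroundModel(
                score_type=stype,
                length=w,
                mean=float(sample.mean()),
                sd=float(sample.std(ddof=1)),
                n_samples=n,
                seed=seed,
                composition_name=composition.name,
            )
    return models


def z_normalize(raw: amphiscore.RawScore, model: BackgroundModel, length: int | None = None) -> float:
    """z = (raw - mean) / sd against the matching (type, length) model."""
    if raw.score_type != model.score_type:
        raise ValidationError(
            f"score type mismatch: {raw.score_type} vs model {model.score_type}"
        )
    if length is not None and length != model.length:
        raise ValidationError(f"length mismatch: peptide {length} vs model {model.length}")
    return (raw.value - model.mean) / model.sd


# ---------------------------------------------------------------------------
# persistence

_HEADER = ["score_type", "length", "mean", "sd", "n_samples", "seed", "composition_name"]


def save_background(models: dict[tuple[str, int], BackgroundModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        some = next(iter(models.values()))
        fh.write(f"# background models: n={some.n_samples} seed={some.seed} "
                 f"composition={some.composition_name}\n")
        fh.write("\t".join(_HEADER) + "\n")
        for (stype, w) in sorted(models):
            m = models[(stype, w)]
            fh.write(
                f"{m.score_type}\t{m.length}\t{m.mean!r}\t{m.sd!r}\t"
                f"{m.n_samples}\t{m.seed}\t{m.composition_name}\n"
            )


def load_background(path: str | Path) -> dict[tuple[str, int], BackgroundModel]:
    models: dict[tuple[str, int], BackgroundModel] = {}
    with open(path) as fh:
        lines = [r for r in fh if r.strip() and not r.startswith("#")]
    for row in csv.DictReader(lines, delimiter="\t"):
        m = BackgroundModel(
            score_type=row["score_type"],
            length=int(row["length"]),
            mean=float(row["mean"]),
            sd=float(row["sd"]),
            n_samples=int(row["n_samples"]),
            seed=int(row["seed"]),
            composition_name=row["composition_name"],
        )
        models[(m.score_type, m.length)] = m
    return models
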
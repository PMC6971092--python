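"""Synthetic proteins, structure profiles and abundance tables with planted
amphiphilic motifs, so every pipeline stage can be tested without downloads.

Background residues are drawn from the same average composition as the null
model, so planted-motif enrichment is attributable to residue arrangement,
not composition shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amphiscore import ALPHA_ANGLE
from .background import CompositionTable, load_composition
from .seqio import ProteinRecord, ValidationError

HYDROPHOBIC = "LIVF"
HYDROPHILIC = "DEKNQS"
MOTIF_TYPES = ("alpha", "beta", "gamma")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_proteins: int = 3
    protein_length: tuple[int, int] = (60, 90)
    motif_types: tuple[str, ...] = MOTIF_TYPES  # cycled over proteins
    motif_length: tuple[int, int] = (12, 18)
    profile_mode: str = "permissive"  # permissive | realistic | absent
    abundance_concentration: float = 1.0  # Dirichlet concentration for riBAQ-ish masses
    composition_name: str = "swissprot_legacy"

    def __post_init__(self) -> None:
        if not 7 <= self.motif_length[0] <= self.motif_length[1] <= 30:
            raise ValidationError("planted motif lengths must lie within 7-30")
        if self.profile_mode not in ("permissive", "realistic", "absent"):
            raise ValidationError(f"unknown profile mode {self.profile_mode!r}")
        for t in self.motif_types:
            if t not in MOTIF_TYPES:
                raise ValidationError(f"unknown motif type {t!r}")


def _pick(rng: np.random.Generator, letters: str) -> str:
    return letters[rng.integers(0, len(letters))]


def make_motif(motif_type: str, length: int, rng: np.random.Generator) -> str:
    """Build a maximally amphiphilic motif of the requested conformation.

    * alpha: hydrophobic residues wherever the helical-wheel angle points into
      the hydrophobic face (period ~3.6), hydrophilic elsewhere;
    * beta: strict hydrophobic/hydrophilic alternation;
    * gamma: a hydrophobic block followed by a hydrophilic block.
    """
    out = []
    if motif_type == "alpha":
        for n in range(1, length + 1):
            face = math.cos(n * ALPHA_ANGLE)
            out.append(_pick(rng, HYDROPHOBIC) if face > 0.4 else _pick(rng, HYDROPHILIC))
    elif motif_type == "beta":
        for n in range(length):
            out.append(_pick(rng, HYDROPHOBIC) if n % 2 == 0 else _pick(rng, "DEKN"))
    elif motif_type == "gamma":
        half = length // 2
        out = [_pick(rng, HYDROPHOBIC + "A") for _ in range(half)]
        out += [_pick(rng, "DEKNQ") for _ in range(length - half)]
    else:
        raise ValidationError(f"unknown motif type {motif_type!r}")
    return "".join(out)


def _random_sequence(length: int, comp: CompositionTable, rng: np.random.Generator) -> str:
    letters = np.array(comp.residues)
    idx = rng.choice(len(letters), size=length, p=comp.probabilities)
    return "".join(letters[idx])


def make_proteins(spec: FixtureSpec) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Random-background proteins, one planted motif each; returns the records
    and a truth table (protein_id, start, end, motif_type, motif)."""
    rng = np.random.default_rng(spec.seed)
    comp = load_composition(spec.composition_name)
    records: list[ProteinRecord] = []
    truth_rows = []
    for i in range(spec.n_proteins):
        plen = int(rng.integers(spec.protein_length[0], spec.protein_length[1] + 1))
        mtype = spec.motif_types[i % len(spec.motif_types)]
        mlen = int(rng.integers(spec.motif_length[0], spec.motif_length[1] + 1))
        if mlen > plen:
            raise ValidationError("planted motif longer than protein")
        motif = make_motif(mtype, mlen, rng)
        seq = list(_random_sequence(plen, comp, rng))
        start0 = int(rng.integers(0, plen - mlen + 1))
        seq[start0 : start0 + mlen] = motif
        pid = f"synth{i + 1:03d}"
        records.append(ProteinRecord(id=pid, sequence="".join(seq)))
        truth_rows.append(
            {
                "protein_id": pid,
                "start": start0 + 1,
                "end": start0 + mlen,
                "motif_type": mtype,
                "motif": motif,
            }
        )
    return records, pd.DataFrame(truth_rows, columns=["protein_id", "start", "end", "motif_type", "motif"])


def make_profiles(
    spec: FixtureSpec, proteins: list[ProteinRecord], truth: pd.DataFrame
) -> pd.DataFrame | None:
    """Generic profile table for the fixture proteins (None in 'absent' mode).

    Permissive mode emits probability 1.0 everywhere; realistic mode emits a
    high probability of the planted conformation over the motif and low
    probabilities elsewhere.
    """
    if spec.profile_mode == "absent":
        return None
    rows = []
    spans = {
        r.protein_id: (r.start, r.end, r.motif_type) for r in truth.itertuples()
    }
    for rec in proteins:
        start, end, mtype = spans.get(rec.id, (0, -1, ""))
        for pos in range(1, len(rec.sequence) + 1):
            if spec.profile_mode == "permissive":
                p_h = p_e = 1.0
            else:
                inside = start <= pos <= end
                p_h = 0.8 if (inside and mtype == "alpha") else 0.1
                p_e = 0.8 if (inside and mtype == "beta") else 0.1
            rows.append(
                {
                    "id": rec.id,
                    "position": pos,
                    "p_helix": p_h,
                    "p_strand": p_e,
                    "p_coil": max(0.0, 1.0 - max(p_h, p_e)),
                }
            )
    return pd.DataFrame(rows)


def make_abundances(spec: FixtureSpec, proteins: list[ProteinRecord]) -> pd.DataFrame:
    """Positive MS1-style summed intensities per protein (Dirichlet-weighted)."""
    rng = np.random.default_rng([spec.seed, 777])
    k = len(proteins)
    weights = rng.dirichlet([spec.abundance_concentration] * k) if k else np.array([])
    total = 1e9
    return pd.DataFrame(
        {
            "protein_id": [rec.id for rec in proteins],
            "intensity": np.round(weights * total, 3),
        }
    )


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    proteins: list[ProteinRecord] = field(default_factory=list)
    truth: pd.DataFrame | None = None
    profiles: pd.DataFrame | None = None
    intensities: pd.DataFrame | None = None


def make_fixture(spec: FixtureSpec) -> FixtureBundle:
    proteins, truth = make_proteins(spec)
    return FixtureBundle(
        spec=spec,
        proteins=proteins,
        truth=truth,
        profiles=make_profiles(spec, proteins, truth),
        intensities=make_abundances(spec, proteins),
    )


def write_fixture_dir(spec: FixtureSpec, outdir) -> FixtureBundle:
    """Write a complete fixture directory (FASTA, profiles, intensities,
    truth table, spec echo)."""
    from pathlib import Path

    import yaml

    from .seqio import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = make_fixture(spec)
    write_fasta(bundle.proteins, outdir / "proteins.fasta")
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if bundle.profiles is not None:
        bundle.profiles.to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    bundle.intensities.to_csv(outdir / "intensities.tsv", sep="\t", index=False)
    with open(outdir / "fixture_spec.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "seed": spec.seed,
                "n_proteins": spec.n_proteins,
                "protein_length": list(spec.protein_length),
                "motif_types": list(spec.motif_types),
                "motif_length": list(spec.motif_length),
                "profile_mode": spec.profile_mode,
                "abundance_concentration": spec.abundance_concentration,
                "composition_name": spec.composition_name,
            },
            fh,
        )
    return bundle


def motif_recovery(predictions: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of planted motifs whose type's top-z prediction within the
    parent protein overlaps the planted span."""
    if truth.empty:
        return float("nan")
    hits = 0
    for row in truth.itertuples():
        sub = predictions[
            (predictions["parent_id"] == row.protein_id)
            & (predictions["score_type"] == row.motif_type)
        ]
        if sub.empty:
            continue
        top = sub.loc[sub["z"].idxmax()]
        if top["start"] <= row.end and top["end"] >= row.start:
            hits += 1
    return hits / len(truth)
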
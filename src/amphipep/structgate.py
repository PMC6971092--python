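"""Secondary-structure gating and assembly of the ranked prediction table.

Helical and strand candidates are only credible if the parent region can
actually adopt that conformation: their z-scores are set to 0 when the
average predicted probability of the conformation over the peptide is below
the gate threshold (strictly below; exactly 0.3 passes). Block-amphiphilic
(gamma) candidates are conformation-independent and never gated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import physchem
from .amphiscore import RawScore, batch_scores, kd_matrix
from .background import BackgroundModel, z_normalize
from .physchem import HydrophobicityScale, load_scale
from .seqio import PeptideCandidate, ProteinRecord, ValidationError, cluster_peptides, enumerate_peptides

logger = logging.getLogger(__name__)

GATE_THRESHOLD = 0.3
Z_THRESHOLD = 2.0
STATE_FOR_TYPE = {"alpha": "helix", "beta": "strand"}


@dataclass
class SSProfile:
    """Per-residue conformation probabilities, 1-based on the mature sequence."""

    protein_id: str
    p_helix: np.ndarray
    p_strand: np.ndarray
    p_coil: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.p_helix = np.asarray(self.p_helix, dtype=float)
        self.p_strand = np.asarray(self.p_strand, dtype=float)
        if self.p_coil is None:
            self.p_coil = np.clip(1.0 - self.p_helix - self.p_strand, 0.0, 1.0)
        self.p_coil = np.asarray(self.p_coil, dtype=float)
        for name, arr in (("helix", self.p_helix), ("strand", self.p_strand), ("coil", self.p_coil)):
            if ((arr < 0) | (arr > 1)).any():
                raise ValidationError(f"{self.protein_id}: p_{name} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.p_helix)


def load_ss_profiles(path) -> dict[str, SSProfile]:
    """Read the generic profile table (id, position, p_helix, p_strand, p_coil).

    Tab- or comma-delimited with a header. Positions must be contiguous from 1
    per protein; probabilities must lie in [0, 1]. Errors carry line numbers.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"id", "position", "p_helix", "p_strand", "p_coil"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("p_helix", "p_strand", "p_coil"):
        bad = df.index[(df[col] < 0) | (df[col] > 1)]
        if len(bad):
            raise ValidationError(f"{path}: {col} outside [0, 1] at line {bad[0] + 2}")
    profiles: dict[str, SSProfile] = {}
    for pid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        expected = np.arange(1, len(grp) + 1)
        if not np.array_equal(positions, expected):
            gap = int(expected[positions != expected][0])
            first_line = int(grp.index[0]) + 2
            raise ValidationError(
                f"{path}: profile for {pid!r} is not contiguous from 1 "
                f"(position {gap} missing or duplicated; records start at line {first_line})"
            )
        profiles[str(pid)] = SSProfile(
            protein_id=str(pid),
            p_helix=grp["p_helix"].to_numpy(),
            p_strand=grp["p_strand"].to_numpy(),
            p_coil=grp["p_coil"].to_numpy(),
        )
    return profiles


def convert_netsurfp(path, out_path=None) -> pd.DataFrame:
    """Map a NetSurfP-2.0-style CSV onto the generic profile table."""
    df = pd.read_csv(path)
    cols = {c.strip(): c for c in df.columns}
    try:
        out = pd.DataFrame(
            {
                "id": df[cols["id"]],
                "position": df[cols["n"]],
                "p_helix": df[cols["p[q3_H]"]],
                "p_strand": df[cols["p[q3_E]"]],
                "p_coil": df[cols["p[q3_C]"]],
            }
        )
    except KeyError as exc:
        raise ValidationError(f"{path}: not a recognizable NetSurfP-2.0 CSV ({exc})") from None
    if out_path is not None:
        out.to_csv(out_path, sep="\t", index=False)
    return out


def avg_probability(profile: SSProfile, start: int, end: int, state: str) -> float:
    """Arithmetic mean of the state probability over residues start..end (1-based)."""
    if not 1 <= start <= end <= len(profile):
        raise ValidationError(
            f"span {start}-{end} outside profile of length {len(profile)} "
            f"({profile.protein_id})"
        )
    arr = {"helix": profile.p_helix, "strand": profile.p_strand, "coil": profile.p_coil}[state]
    return float(arr[start - 1 : end].mean())


def gate(z: float, score_type: str, avg_prob: float | None, threshold: float = GATE_THRESHOLD) -> float:
    """Zero helical/strand scores whose conformation probability is below threshold.

    Gamma scores pass unchanged; the boundary value passes ("below" is strict).
    Idempotent. A missing probability (None) gates alpha/beta to 0.
    """
    if score_type == "gamma":
        return z
    if avg_prob is None or avg_prob < threshold:
        return 0.0
    return z


@dataclass(frozen=True)
class Prediction:
    candidate: PeptideCandidate
    score_type: str
    raw: float
    split_k: int | None
    avg_structure_prob: float | None
    gated: bool
    z: float


def predict(
    proteins: list[ProteinRecord],
    profiles: dict[str, SSProfile] | None,
    backgrounds: dict[tuple[str, int], BackgroundModel],
    scale: HydrophobicityScale | None = None,
    min_len: int = 7,
    max_len: int = 30,
    z_threshold: float = Z_THRESHOLD,
    gate_threshold: float = GATE_THRESHOLD,
    similarity_threshold: float = 0.70,
    pka_set: str = "lehninger",
    on_missing_profile: str = "gate",
) -> pd.DataFrame:
    """Run enumerate -> score -> z-normalize -> gate -> threshold -> cluster -> annotate.

    Returns one row per (candidate, passing score type), sorted by z
    descending. Proteins lacking a profile have their helical/strand
    candidates gated to 0 (``on_missing_profile="gate"``, with a warning) or
    raise (``"error"``).
    """
    profiles = profiles or {}
    scale = scale or load_scale()
    for w in range(min_len, max_len + 1):
        for stype in ("alpha", "beta", "gamma"):
            if (stype, w) not in backgrounds:
                raise ValidationError(f"no background model for ({stype}, {w})")

    rows: list[dict] = []
    for rec in proteins:
        profile = profiles.get(rec.id)
        if profile is not None and len(profile) != len(rec.sequence):
            raise ValidationError(
                f"profile length {len(profile)} != protein length {len(rec.sequence)} for {rec.id!r}"
            )
        if profile is None:
            if on_missing_profile == "error":
                raise ValidationError(f"no structure profile for protein {rec.id!r}")
            logger.warning(
                "no structure profile for %s: helical/strand candidates gated to 0", rec.id
            )
        candidates = enumerate_peptides(rec, min_len, max_len)
        by_len: dict[int, list[PeptideCandidate]] = {}
        for c in candidates:
            by_len.setdefault(c.length, []).append(c)
        for w, group in by_len.items():
            kmat = kd_matrix([c.sequence for c in group], scale)
            batch = batch_scores(kmat)
            for stype in ("alpha", "beta", "gamma"):
                model = backgrounds[(stype, w)]
                zs = (batch[stype] - model.mean) / model.sd
                for i, cand in enumerate(group):
                    z = float(zs[i])
                    avg_prob = None
                    gated = False
                    if stype in STATE_FOR_TYPE:
                        if profile is not None:
                            avg_prob = avg_probability(
                                profile, cand.start, cand.end, STATE_FOR_TYPE[stype]
                            )
                        z_gated = gate(z, stype, avg_prob, gate_threshold)
                        gated = z_gated != z or (avg_prob is None)
                        z = z_gated if not gated else 0.0
                    if z > z_threshold:
                        rows.append(
                            {
                                "parent_id": cand.parent_id,
                                "start": cand.start,
                                "end": cand.end,
                                "sequence": cand.sequence,
                                "length": w,
                                "score_type": stype,
                                "raw": float(batch[stype][i]),
                                "split_k": int(batch["gamma_split"][i]) if stype == "gamma" else None,
                                "avg_structure_prob": avg_prob,
                                "gated": gated,
                                "z": z,
                            }
                        )

    columns = [
        "parent_id", "start", "end", "sequence", "length", "score_type", "raw",
        "split_k", "avg_structure_prob", "gated", "z", "cluster", "best_type",
        "mw", "pI", "net_charge_ph7",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)

    df = pd.DataFrame(rows)

    # best_type marks, per candidate window, the score type with maximal z
    best = df.loc[df.groupby(["parent_id", "start", "end"])["z"].idxmax()]
    best_map = {
        (r.parent_id, r.start, r.end): r.score_type for r in best.itertuples()
    }
    df["best_type"] = [
        best_map[(r.parent_id, r.start, r.end)] == r.score_type for r in df.itertuples()
    ]

    # cluster hits within each score type
    df["cluster"] = ""
    for stype, grp in df.groupby("score_type"):
        cands = [
            PeptideCandidate(r.parent_id, r.start, r.end, r.sequence)
            for r in grp.itertuples()
        ]
        zmap = {c.key(): z for c, z in zip(cands, grp["z"])}
        clusters = cluster_peptides(
            cands, similarity_threshold, score_of=lambda p: zmap[p.key()]
        )
        assign = {}
        for ci, cl in enumerate(clusters, 1):
            for m in cl.members:
                assign[m.key()] = f"{stype}-{ci}"
        df.loc[grp.index, "cluster"] = [
            assign[(r.parent_id, r.start, r.end)] for r in grp.itertuples()
        ]

    props = {
        seq: physchem.annotate(seq, pka_set) for seq in df["sequence"].unique()
    }
    df["mw"] = [props[s].mw for s in df["sequence"]]
    df["pI"] = [props[s].pI for s in df["sequence"]]
    df["net_charge_ph7"] = [props[s].net_charge_ph7 for s in df["sequence"]]

    df = df.sort_values(["z", "parent_id", "start", "score_type"], ascending=[False, True, True, True])
    return df.reset_index(drop=True)[columns]
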